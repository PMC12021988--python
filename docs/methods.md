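# Methods

This package quantifies mantle–core (M-C) architecture in pancreatic islets
from cell-detection exports: per-cell nuclear boundary polygons, hormone
classes and per-islet boundary polygons, with coordinates in micrometres.
It implements four linked procedures — mantle/core labelling, the cell-level
type×position association, the per-islet randomness probability *r* with its
digital-sibling permutation null, and normalised earth-mover's distances
between binned distributions — plus a synthetic cohort generator that makes
every stage testable end to end without access to donor tissue data.

## Data model and study filters

A dataset is a collection of islets, each holding its detected cells.
Two interchangeable on-disk forms are supported: QuPath-style GeoJSON
FeatureCollections, and a pair of delimited tables with WKT geometry
columns. Study filters: endocrine clusters qualify as islets only when
their cross-sectional area strictly exceeds 1000 μm² (roughly five cells at
the observed packing density); cells unlabelled by any of the five hormones
(class `none`) are excluded; the remaining cells are dichotomised as beta vs
non-beta (alpha, delta, gamma, epsilon). Islets are filtered by area before
the `none` exclusion, and islets emptied by that exclusion are retained but
flagged, so the filter tallies always reconcile exactly. When an export
carries both a polygon and a reported area, the polygon is authoritative and
a >1% disagreement is recorded as a provenance warning, because the polygon
feeds the distance computation. Cells lacking an explicit parent islet are
assigned by centroid containment (boundary points count as inside); cells
contained by no islet go to an orphan list, never silently dropped.

## Mantle/core labelling

For each cell the minimal Euclidean distance between its nuclear contour and
its islet's border is computed curve-to-curve (exact segment-to-segment
minima via GEOS), not centroid-to-border; a centroid mode exists for
degraded inputs. A cell is a **mantle** cell when this distance is strictly
smaller than `d_min` = 8 μm — i.e. it is a first neighbour of the border —
and a **core** cell otherwise; nuclei touching or crossing the border get
distance 0 and are mantle by construction. Ties at exactly `d_min` go to
core. The islet border is used as ingested, with no smoothing or convex
hull, because folded borders are precisely what makes peripheral cells
ambiguous to the eye. Since distances do not depend on `d_min`, the
sensitivity sweep re-thresholds cached distances, and the pooled mantle
count is non-decreasing in `d_min` by construction.

Each islet is then summarised by six counts: N (cells), B (beta),
NB (non-beta), M (mantle), C (core), and NB_m (non-beta in the mantle),
with N = B + NB = M + C and NB + M − N ≤ NB_m ≤ min(NB, M) enforced as
invariants.

## Association analysis (cell level)

The pooled 2×2 table crosses binary type with position. Independence is
tested with Pearson's χ² (1 df) without continuity correction — counts are
in the tens of thousands, where the correction is immaterial. The effect
size is the cross-product odds ratio oriented as

    OR = (beta_mantle × nonbeta_core) / (beta_core × nonbeta_mantle)

so OR < 1 means beta cells are depleted from the mantle relative to
non-beta cells, i.e. adherence to the M-C hypothesis. When any cell of the
table is zero the Haldane–Anscombe +0.5 correction is applied to all four
cells. Confidence intervals are a 95% percentile bootstrap (default 500
resamples) with the median as the point summary. Two resampling units are
offered: `cells` (the default; realised as a multinomial redraw of the four
categories, which has exactly the distribution of resampling the cell list
with replacement) and `islets`, a cluster bootstrap that resamples whole
islet tables. The nine standard subgroups are
{all, control, t1d} × {all sizes, area < 10⁴ μm², area ≥ 10⁴ μm²}, a
documented convention that callers can override; per-subgroup seeds are
spawned deterministically from one master seed.

**Caveat on pooled inference over clustered cells.** Cells within an islet
are not independent samples: islets differ in beta fraction and in mantle
fraction, and this between-islet heterogeneity inflates the variance of any
pooled cell-level statistic beyond its iid approximation (a design effect).
Concretely, on synthetic θ=0 cohorts of 300 islets the cohort-to-cohort SD
of the pooled OR is about twice the multinomial (cell-bootstrap) standard
error, so the cell-level bootstrap CI under-covers and the pooled χ² test
rejects far above its nominal level (~13% at α=0.001 in our simulations)
even when no M-C structure exists. The islet-level cluster bootstrap is the
calibrated alternative and is what the acceptance suite uses for null
coverage; the cell-level default is retained for fidelity to the
contingency-table formulation, and the χ²'s anticonservatism under
heterogeneity is deliberately surfaced (and left failing) by the
calibration test rather than hidden. The islet-level *r* analysis below is
immune to this problem because it conditions on each islet's composition.

## Randomness probability r (islet level)

For an islet with counts (N, NB, M), a uniformly random arrangement of its
fixed type multiset over its fixed positions makes NB_m hypergeometric.
The randomness probability is the upper tail

    r = P(X ≥ NB_m),  X ~ Hypergeometric(N, NB, M)
      = Σ_{k=NB_m}^{min(NB,M)} C(NB,k)·C(N−NB,M−k) / C(N,M),

evaluated exactly via log-gamma binomial coefficients, summed from the top
of the support so small tails keep full relative precision. r = 1 whenever
NB_m = 0 or the configuration is forced (NB_m at the support's lower bound
NB + M − N). Small r is evidence of M-C structure; the tail convention is
"at least the observed count". **Constrained** islets — fewer than three
beta cells, three non-beta cells, or three core positions — cannot
meaningfully exhibit the structure (an all-non-beta islet, for instance,
admits exactly one arrangement and has r = 1); they are flagged, reported,
and excluded from the distributional comparison by default, with both
variants available.

**Digital siblings** realise the same null constructively: a sibling is a
copy of an observed islet with its type labels uniformly permuted over its
fixed cell positions, preserving geometry and all margins (N, NB, B, M, C)
while redrawing NB_m. Permuting labels is distributionally identical to
drawing NB_m from the hypergeometric law — a goodness-of-fit test in the
suite pins the two together — so bulk sibling populations use vectorised
hypergeometric draws, while the per-cell permutation is kept for
reconstruction of individual siblings. One sibling per islet per run is the
default; resampling robustness is assessed downstream. Because the tail
probability of a discrete law is superuniform, sibling r values satisfy
P(r ≤ q) ≤ q, which the suite checks on a q-grid.

## Earth mover's distances

1D (observed r vs sibling r, unconstrained islets): histograms use K
equidistant bins on [0,1] (default K = 20; the last bin is right-closed so
r = 1 is counted). The ground distance between bins i, j is
|cᵢ − cⱼ| / (c_K − c₁) — bin-centre distance normalised by the extreme
centre distance — so moving all mass between the two extreme bins costs
exactly 1 and the distance lies in [0,1]. The optimal plan is the monotone
CDF-matching (north-west corner) coupling, provably optimal for convex
costs on the line; an exact LP solves the same problem in the test suite as
an independent oracle (agreement to 1e-9). The plan is oriented
source = digital siblings → target = observed, so M-C structure appears as
plan mass strictly below the diagonal (r moved downward).

2D (control vs t1d cohorts on per-islet (beta fraction, area)): the area
axis is rescaled linearly by the pooled maximum area so both cohorts share
bin geometry on [0,1]²; a log-area variant is available since a linear axis
compresses small islets. The ground metric is the per-axis-normalised L1
distance |Δx|/x_range + |Δy|/y_range — the choice that makes the
corner-to-corner cost exactly 2, bounding the distance by 2; an L2
alternative (bound √2) sits behind a flag. The optimal plan is computed by
exact linear programming (HiGHS, feasibility tolerances 1e-10) restricted
to non-empty bins, which keeps the LP at the size of the occupied support
rather than K⁴ variables; no entropic approximation is used. Identical
histograms short-circuit to distance 0 with the identity plan. Degenerate
LPs can have non-unique plans; only the distance is asserted bit-stable.
Robustness sweeps repeat the distance over re-randomised sibling draws or
islet resamples (default 500) and over bin counts 8–40.

## Synthetic cohort generator

The generator emulates detection exports with known ground truth; its
defaults are the study conditions under which all tests run.

- **Islet boundaries**: star-shaped polygons (64 vertices), radius
  modulated by random harmonics of order 2–5 with total amplitude bounded
  at 0.45 × folding (default folding 0.3), rescaled to the target area
  exactly. Areas are log-normal with median 7000 μm² and log-SD 1.2,
  truncated above the 1000 μm² filter; with the default density of
  0.005 cells/μm² (five cells per 1000 μm²) this yields ≈70 cells per
  islet, so 3500 islets give ≈250k cells — the scale of a full study.
- **Cell placement**: inhibition (dart) sampling with minimum centroid
  separation 2 × nucleus radius (default 3 μm) where feasible; nuclei are
  circular 20-gons kept at least one radius inside the border.
- **Type assignment**: per-islet beta fraction is Beta-distributed —
  control mode 0.8, concentration 8; the t1d mode is depleted most strongly
  in the smallest islets via an exponential size coupling (scale 10⁴ μm²).
  Cell counts are exact (B = round(N·fraction)).
- **Adherence θ** acts per islet: with probability θ the islet is perfectly
  ordered (non-beta cells fill mantle positions first, ties randomised,
  overflow spilling into the core); otherwise labels are a uniform
  permutation. The mixture, rather than a per-cell softness, reproduces the
  qualitative picture of a low-r peak over a flat background with one
  interpretable knob. θ = 0 reproduces the digital-sibling null exactly
  (verified by goodness of fit), pooled OR decreases monotonically in θ and
  the observed-vs-sibling EMD increases.
- All randomness flows from one seed through per-islet substreams, so
  cohorts are byte-identically reproducible.

**What the generator does not emulate**: real islet borders are far more
folded than bounded star-shaped polygons, so the synthetic pooled mantle
fraction (~0.2 at default settings) is lower than values reported for real
tissue (~0.6); there is no vasculature, exocrine tissue, immune
infiltration, section-plane effects or 3D structure; hormone
misclassification is limited to an optional uniform `none` fraction.
Passing tests therefore validate the statistical machinery and its
calibration under a faithful null, not the biological realism of any
particular parameter value.

## Numerical and design choices

- Strict inequalities follow the stated rules exactly: islet area > 1000
  μm², mantle distance < 8 μm, constrained counts < 3.
- The r tail is computed in log space and clipped to [0,1]; the enumeration
  oracle covers every count combination with N ≤ 12.
- Histogram masses must sum to 1 within 1e-9; transport-plan marginals are
  checked to 1e-9.
- χ² on a table with a zero row/column margin raises (`degenerate table`)
  rather than returning NaN; empty subgroups yield flagged results, not
  exceptions.
- Analysis problem sizes: calibration tests use 10 × 300-islet θ=0
  cohorts, signal-recovery tests 250-islet θ=1 cohorts, type-I simulation
  2000 count-level cohort redraws on a fixed geometric skeleton (labels are
  independent of geometry, so redrawing geometry would not change their
  law), and the determinism check one full 3500-islet run (~260k cells).

## Known limitations

- The pooled χ² p-value is anticonservative for clustered heterogeneous
  data (see the association caveat); effect-size (OR) and islet-level (r)
  conclusions are the robust summaries.
- The 2D EMD depends on the area-axis normalisation (pooled maximum area),
  which is sensitive to the single largest islet; the log-area option
  mitigates this.
- `read_tabular` parses rows via pandas with per-row WKT decoding and is
  comfortable at 10⁵-cell scale, not optimised beyond it.
- The r statistic treats positions as exchangeable within an islet; no
  spatially explicit null (jittering, point processes) is provided.
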