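# islet-mc

Quantitative analysis of **mantle–core (M-C) architecture** in pancreatic
islets of Langerhans, starting from whole-slide cell-detection exports
(QuPath-style GeoJSON or tabular files with per-cell nuclear boundaries,
hormone classes, and per-islet boundary polygons, in μm).

Human islets have long been debated to show a mantle–core arrangement:
non-beta endocrine cells (alpha, delta, gamma, epsilon) preferentially
occupying a thin peripheral shell around a beta-cell-rich interior. This
package turns that question into reproducible statistics for researchers
working with multiplex-stained pancreas sections:

- **Mantle/core labelling** — each cell is *mantle* if the minimal distance
  from its nuclear contour to the islet border is < d_min = 8 μm (a first
  neighbour of the border), else *core*; exact curve-to-curve geometry.
- **Association analysis** — χ² test of independence between binary cell
  type (beta / non-beta) and position (mantle / core), with the odds ratio
  OR = (beta_mantle · nonbeta_core)/(beta_core · nonbeta_mantle) as effect
  size (OR < 1 ⇔ M-C adherence), bootstrap CIs, and nine standard
  subgroups (disease status × islet size).
- **Per-islet randomness probability** — for an islet with N cells, NB
  non-beta and M mantle positions, r = P(X ≥ NB_m) with
  X ~ Hypergeometric(N, NB, M): the probability that at least the observed
  number of non-beta cells occupies the mantle under random arrangement.
  Small r = strong M-C evidence; islets with fewer than three beta cells,
  non-beta cells or core positions are flagged *constrained* (r
  necessarily near 1).
- **Digital siblings** — a permutation null population: each islet copied
  with its type labels randomly rearranged over its fixed positions.
- **Earth mover's distance** — normalised 1D EMD (∈ [0,1]) between the
  observed and sibling r distributions, with an explicit transport plan,
  and normalised 2D EMD (∈ [0,2]) between cohorts on the
  (beta fraction × islet area) plane, both with bin-count and resampling
  robustness sweeps.
- **Synthetic cohort generator** — islet cohorts with tunable M-C
  adherence θ ∈ [0,1] and known ground truth, used by the whole test
  suite.

## Worked example

Generate a cohort with partial mantle-core adherence and run the full
pipeline (also available as `islet-mc run --config run.yaml`):

```python
import isletmc as m

cfg = m.SyntheticConfig(n_islets=800, adherence=0.6, t1d_fraction=0.4, seed=2026)
ds = m.apply_study_filters(m.generate_cohort(cfg))
m.annotate_positions(ds)                      # distances, mantle/core, counts

res = m.bootstrap_or(ds, n_resamples=500, seed=2027)
print(res.or_point, res.ci_low, res.ci_high, res.p_value)

obs = m.population_r_values(ds, "observed", include_constrained=False)
sib = m.population_r_values(ds, "siblings", seed=2028, include_constrained=False)
d = m.emd_1d(m.histogram_1d(sib["r"], 20), m.histogram_1d(obs["r"], 20))
print(d.distance)
```

The same analysis, scripted with narrative output, lives in `analysis/`:

```text
$ python analysis/01_generate_cohorts.py
wrote 800 islets / 63369 cells to .../results/cohort
  ordered (mantle-core) islets: 500
$ python analysis/02_association.py
nine-subgroup odds ratios (OR < 1 = mantle-core adherence):
        group_label  n_cells  or_median   ci_low  ci_high             p
      all/all-sizes    63369   0.237381 0.226470 0.248091  0.000000e+00
      ...
$ python analysis/03_randomness_emd.py
800 islets scored; 678 unconstrained, 122 constrained (excluded from the EMD)
emd-1d (siblings -> observed, 20 bins) = 0.36175
  transported mass moving r downward: 0.913, upward: 0.000
  observed mass in lowest r decile: 0.600 vs siblings 0.047
$ python analysis/04_cohort_emd2d.py
emd-2d (control vs t1d, 10x10 bins, area scale 367398 um^2) = 0.4113
```

Reading: with θ = 0.6 adherence the pooled OR ≈ 0.24 (≪ 1, CI excluding 1)
says non-beta cells are strongly enriched at the mantle; 60% of
unconstrained islets land in the lowest r decile versus 4.7% of their
randomly rearranged siblings, the EMD between the two r distributions is
0.36 on a [0,1] scale, and every unit of transported mass moves r downward
— the transport-plan signature of genuine M-C structure. The 2D distance
of 0.41 (on [0,2]) separates the t1d cohort, whose beta fraction is
depleted most in small islets, from control.

Real data enter through `read_qupath_geojson` / `read_tabular` (see the
column contracts in `src/isletmc/io.py`) followed by the same calls, or the
CLI: `islet-mc analyze association --cells cells.csv --islets islets.csv ...`.

## Layout

```
src/isletmc/        library: io, geometry, association, randomness, emd,
                    synthetic, pipeline, cli
analysis/           numbered narrative drivers writing results/
tests/              pytest suite incl. end-to-end acceptance checks
scripts/            acceptance.py (reference quantities)
docs/methods.md     models, assumptions, parameter choices, limitations
```
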