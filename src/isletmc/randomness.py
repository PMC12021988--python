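"""Per-islet randomness probability r and the digital-sibling null.

For an islet with N cells (NB non-beta) and M mantle positions, a uniformly
random arrangement of the fixed type multiset over the fixed positions makes
the number of non-beta mantle cells NB_m hypergeometric. The randomness
probability is the upper tail

    r = P(X >= NB_m),   X ~ Hypergeometric(N, NB, M),

so r = 1 means the observed arrangement (or a more mantle-segregated one) is
certain under randomness, while small r is evidence for mantle-core
structure. The tail is evaluated exactly via log-gamma binomial
coefficients. Digital siblings realise the same null constructively: an
islet's type labels are permuted uniformly over its fixed cell positions,
preserving geometry and composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .dataset import (
    IsletCounts,
    IsletRecord,
    StudyDataset,
    copy_islet,
    counts_from_cells,
)

CONSTRAINT_REASONS = ("too_few_beta", "too_few_nonbeta", "too_few_core")


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def r_tail_table(N: int, NB: int, M: int) -> np.ndarray:
    """P(X >= k) for k = 0..min(NB, M), X ~ Hypergeometric(N, NB, M).

    Computed from exact log-space pmf terms, summed from the top of the
    support so the smallest tails keep full relative precision.
    """
    if not (0 <= NB <= N and 0 <= M <= N):
        raise ValueError("invalid hypergeometric parameters")
    k_hi = min(NB, M)
    k_lo = max(0, NB + M - N)
    ks = np.arange(k_lo, k_hi + 1)
    logp = _log_comb(NB, ks) + _log_comb(N - NB, M - ks) - _log_comb(N, M)
    pmf = np.exp(logp)
    tail = np.zeros(k_hi + 1)
    tail[k_lo:] = np.cumsum(pmf[::-1])[::-1]
    tail[: k_lo + 1] = 1.0  # configurations at or below the forced minimum
    return np.minimum(tail, 1.0)


def r_value(counts: IsletCounts) -> float:
    """Probability that at least NB_m non-beta cells occupy the mantle by chance."""
    counts.validate()
    if counts.N == 0:
        raise ValueError("r value undefined for an empty islet")
    if counts.NB_m == 0:
        return 1.0
    tail = r_tail_table(counts.N, counts.NB, counts.M)
    return float(tail[counts.NB_m])


def classify_constrained(counts: IsletCounts):
    """Flag islets that cannot meaningfully exhibit a mantle-core structure.

    Constrained: fewer than three beta cells, non-beta cells, or core
    positions.
    """
    counts.validate()
    reasons = []
    if counts.B < 3:
        reasons.append("too_few_beta")
    if counts.NB < 3:
        reasons.append("too_few_nonbeta")
    if counts.C < 3:
        reasons.append("too_few_core")
    return bool(reasons), tuple(reasons)


@dataclass
class RValueRecord:
    islet_id: str
    counts: IsletCounts
    r: float
    constrained: bool
    constraint_reasons: tuple


def digital_sibling(islet: IsletRecord, rng: np.random.Generator) -> IsletRecord:
    """Random rearrangement of an islet's type labels over its fixed positions.

    Geometry and the counts N, NB, B, M, C are preserved exactly; only which
    cells carry which type changes, so NB_m is redrawn from its null law.
    """
    cells = islet.cells
    if any(c.position is None or c.binary_type is None for c in cells):
        raise ValueError(f"islet {islet.islet_id} must be annotated first")
    perm = rng.permutation(len(cells))
    labels = [(cells[i].hormone_class, cells[i].binary_type) for i in perm]
    sib = copy_islet(islet)
    for cell, (hc, bt) in zip(sib.cells, labels):
        cell.hormone_class = hc
        cell.binary_type = bt
    sib.counts = counts_from_cells(sib.cells) if cells else IsletCounts(0, 0, 0, 0, 0, 0)
    return sib


def sample_sibling_nbm(
    counts_list, n_replicates: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised NB_m draws for sibling populations, shape (n_replicates, n_islets).

    Drawing NB_m ~ Hypergeometric(N, NB, M) is distributionally identical to
    permuting labels with :func:`digital_sibling` and recounting.
    """
    nb = np.array([c.NB for c in counts_list])
    b = np.array([c.B for c in counts_list])
    m = np.array([c.M for c in counts_list])
    return rng.hypergeometric(nb, b, m, size=(n_replicates, len(counts_list)))


def sibling_r_values(
    counts_list, n_replicates: int, rng: np.random.Generator
) -> np.ndarray:
    """r values of sibling populations, shape (n_replicates, n_islets)."""
    tables = [r_tail_table(c.N, c.NB, c.M) for c in counts_list]
    nbm = sample_sibling_nbm(counts_list, n_replicates, rng)
    out = np.empty_like(nbm, dtype=float)
    for j, tab in enumerate(tables):
        out[:, j] = tab[nbm[:, j]]
    return out


def population_r_values(
    dataset: StudyDataset,
    which: str = "observed",
    n_replicates: int = 1,
    seed: int | None = None,
    include_constrained: bool = True,
) -> pd.DataFrame:
    """r value per islet (observed arrangement or digital-sibling draws).

    Empty islets are skipped. For siblings, each islet is independently
    rearranged ``n_replicates`` times and each rearrangement scored.
    """
    if which not in ("observed", "siblings"):
        raise ValueError(f"which must be 'observed' or 'siblings', got {which!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for islet in dataset.islets:
        if islet.counts is None:
            raise ValueError(f"islet {islet.islet_id} not annotated")
        if islet.counts.N == 0:
            continue
        constrained, reasons = classify_constrained(islet.counts)
        reps = range(n_replicates) if which == "siblings" else (0,)
        for rep in reps:
            if which == "observed":
                counts = islet.counts
            else:
                counts = digital_sibling(islet, rng).counts
            rows.append(
                {
                    "islet_id": islet.islet_id,
                    "replicate": rep,
                    "N": counts.N,
                    "NB": counts.NB,
                    "B": counts.B,
                    "M": counts.M,
                    "C": counts.C,
                    "NB_m": counts.NB_m,
                    "r": r_value(counts),
                    "constrained": constrained,
                    "reasons": ";".join(reasons),
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "islet_id", "replicate", "N", "NB", "B", "M", "C", "NB_m",
            "r", "constrained", "reasons",
        ],
    )
    if not include_constrained:
        frame = frame[~frame["constrained"]].reset_index(drop=True)
    return frame
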