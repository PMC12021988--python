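"""Synthetic islet cohorts with known ground-truth architecture.

The generator emulates the cell-detection exports the pipeline consumes:
islet boundary polygons with smooth radial folds, nuclear positions placed
by inhibition sampling, hormone classes drawn per cohort, and a single
adherence knob θ controlling mantle-core organisation. θ acts per islet: with
probability θ an islet's labels follow the mantle-core rule exactly (non-beta
cells fill mantle positions first), otherwise they are a uniform random
permutation — a mixture that reproduces a low-r peak over a flat background.

Cohort-level defaults mirror the study conditions the pipeline targets:
islet areas log-normal (median 7,000 μm², log-SD 1.2, truncated above
1,000 μm², giving ≈70 cells per islet on average at 5 cells / 1,000 μm²),
control beta fractions peaking at 0.8, and a t1d beta-fraction law whose
depletion is strongest in the smallest islets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .dataset import (
    BETA,
    NON_BETA,
    AnalysisParams,
    CellRecord,
    IsletRecord,
    StudyDataset,
)
from .geometry import boundary_distances

#: hormone classes drawn for non-beta cells, with fixed relative frequencies
_NON_BETA_CLASSES = ("alpha", "delta", "gamma", "epsilon")
_NON_BETA_WEIGHTS = (0.70, 0.20, 0.08, 0.02)


@dataclass
class SyntheticConfig:
    """Cohort-generation parameters (μm / μm² units throughout)."""

    n_islets: int = 500
    area_median: float = 7000.0
    area_sigma: float = 1.2  # log-space SD of the log-normal area law
    area_min: float = 1000.0
    truncate_area: bool = True
    cell_density: float = 0.005  # cells per μm² (~5 cells / 1000 μm²)
    nucleus_radius: float = 3.0
    control_beta_mode: float = 0.8
    t1d_beta_mode: float = 0.35
    beta_concentration: float = 8.0
    t1d_size_coupling: float = 0.5  # extra depletion for the smallest islets
    t1d_coupling_scale: float = 10_000.0  # μm² decay scale of the coupling
    t1d_fraction: float = 0.0  # fraction of islets in the t1d cohort
    none_fraction: float = 0.0  # unlabelled ('none') cells, for ingest tests
    adherence: float = 0.0  # θ: probability an islet is mantle-core ordered
    folding: float = 0.3  # boundary waviness amplitude in [0, 1]
    d_min: float = 8.0
    n_cases_control: int = 4
    n_cases_t1d: int = 6
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.adherence <= 1:
            raise ValueError("adherence must lie in [0, 1]")
        if not 0 <= self.folding <= 1:
            raise ValueError("folding must lie in [0, 1]")
        if self.cell_density <= 0 or self.area_median <= 0 or self.nucleus_radius <= 0:
            raise ValueError("densities, areas and radii must be positive")
        if not 0 <= self.t1d_fraction <= 1:
            raise ValueError("t1d_fraction must lie in [0, 1]")


def make_islet_boundary(
    area: float, folding: float, rng: np.random.Generator, n_vertices: int = 64
) -> Polygon:
    """Simple closed polygon of the requested area with smooth radial lobes.

    folding = 0 gives a near-circle; folding > 0 superimposes low-order
    harmonics with total amplitude bounded at 0.45 of the radius, keeping the
    curve star-shaped (hence simple).
    """
    if area <= 0:
        raise ValueError("area must be positive")
    phi = np.linspace(0.0, 2 * math.pi, n_vertices, endpoint=False)
    radial = np.ones_like(phi)
    amp_total = 0.45 * folding
    weights = rng.dirichlet(np.ones(4)) * amp_total
    for k, w in zip(range(2, 6), weights):
        radial += w * np.cos(k * phi + rng.uniform(0, 2 * math.pi))
    r0 = math.sqrt(area / math.pi)
    x = r0 * radial * np.cos(phi)
    y = r0 * radial * np.sin(phi)
    poly = Polygon(np.column_stack([x, y]))
    # rescale so the polygon area matches the target exactly
    s = math.sqrt(area / poly.area)
    poly = shapely.transform(poly, lambda c: c * s)
    return poly


def place_cells(
    boundary: Polygon,
    density: float,
    nucleus_radius: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Nuclear centroids inside the boundary by inhibition (dart) sampling.

    Centroids keep a minimum separation of 2×radius where feasible and stay
    at least one radius inside the islet border, so nuclei never cross it.
    If the requested density is infeasible for the area, fewer cells are
    returned (count recorded by the caller).
    """
    if density <= 0:
        raise ValueError("density must be positive")
    area = boundary.area
    n_target = int(rng.poisson(area * density))
    if n_target == 0:
        return np.empty((0, 2))
    eroded = boundary.buffer(-nucleus_radius)
    if eroded.is_empty:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = eroded.bounds
    sep = 2.0 * nucleus_radius
    cell_size = sep / math.sqrt(2.0)
    grid: dict = {}
    accepted: list = []

    def far_enough(p):
        gx, gy = int(p[0] // cell_size), int(p[1] // cell_size)
        for dx in (-2, -1, 0, 1, 2):
            for dy in (-2, -1, 0, 1, 2):
                for q in grid.get((gx + dx, gy + dy), ()):
                    if (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 < sep * sep:
                        return False
        return True

    budget = 40 * n_target
    batch = max(256, 4 * n_target)
    tried = 0
    while len(accepted) < n_target and tried < budget:
        xs = rng.uniform(minx, maxx, size=batch)
        ys = rng.uniform(miny, maxy, size=batch)
        inside = shapely.contains_xy(eroded, xs, ys)
        tried += batch
        for x, y in zip(xs[inside], ys[inside]):
            if len(accepted) >= n_target:
                break
            p = (x, y)
            if far_enough(p):
                accepted.append(p)
                grid.setdefault(
                    (int(x // cell_size), int(y // cell_size)), []
                ).append(p)
    return np.asarray(accepted).reshape(-1, 2)


def _circle_polygon(center, radius: float, n: int = 20) -> Polygon:
    phi = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    return Polygon(
        np.column_stack(
            [center[0] + radius * np.cos(phi), center[1] + radius * np.sin(phi)]
        )
    )


def assign_types(
    distances: np.ndarray,
    beta_fraction: float,
    theta: float,
    d_min: float,
    rng: np.random.Generator,
):
    """Binary type labels for placed cells, with per-islet adherence regime.

    Exact counts: B = round(N × beta_fraction), NB = N − B. With probability
    θ the islet is 'ordered' — non-beta cells fill mantle positions first
    (ties randomised, overflow spilling into the core); otherwise labels are
    a uniform permutation. Returns (types, regime).
    """
    if not 0 <= beta_fraction <= 1 or not 0 <= theta <= 1:
        raise ValueError("beta_fraction and theta must lie in [0, 1]")
    distances = np.asarray(distances, dtype=float)
    n = distances.size
    n_beta = int(round(n * beta_fraction))
    types = np.array([BETA] * n_beta + [NON_BETA] * (n - n_beta), dtype=object)
    ordered = bool(rng.random() < theta)
    if not ordered:
        return types[rng.permutation(n)], "random"
    mantle = distances < d_min
    # random order within mantle and within core, mantle first
    order = np.concatenate(
        [
            rng.permutation(np.flatnonzero(mantle)),
            rng.permutation(np.flatnonzero(~mantle)),
        ]
    )
    out = np.empty(n, dtype=object)
    n_nonbeta = n - n_beta
    out[order[:n_nonbeta]] = NON_BETA
    out[order[n_nonbeta:]] = BETA
    return out, "ordered"


def _beta_params(mode: float, concentration: float):
    # mode/concentration parametrisation of a Beta law (concentration > 2)
    a = mode * (concentration - 2.0) + 1.0
    b = (1.0 - mode) * (concentration - 2.0) + 1.0
    return a, b


def _t1d_mode(area: float, cfg: SyntheticConfig) -> float:
    depletion = cfg.t1d_size_coupling * math.exp(-area / cfg.t1d_coupling_scale)
    return cfg.t1d_beta_mode * (1.0 - depletion)


def resample_null_cohorts(
    skeleton_counts,
    n_cohorts: int,
    rng: np.random.Generator,
    beta_mode: float = 0.8,
    beta_concentration: float = 8.0,
) -> np.ndarray:
    """Pooled 2×2 tables of fresh θ=0 cohorts on fixed islet geometry.

    Each cohort redraws every islet's beta fraction from the cohort law and
    its mantle composition from the uniform-arrangement null, exactly the
    label model of :func:`generate_cohort` at θ=0; only the geometry (cell
    counts N and mantle positions M per islet) is reused, since labels do
    not depend on it. Returns an (n_cohorts, 4) array of
    [beta_mantle, beta_core, nonbeta_mantle, nonbeta_core] counts.
    """
    ns = np.array([c.N for c in skeleton_counts])
    ms = np.array([c.M for c in skeleton_counts])
    a, b = _beta_params(beta_mode, beta_concentration)
    out = np.empty((n_cohorts, 4), dtype=np.int64)
    for i in range(n_cohorts):
        frac = rng.beta(a, b, size=ns.size)
        n_beta = np.round(ns * frac).astype(np.int64)
        nb = ns - n_beta
        nbm = rng.hypergeometric(nb, n_beta, ms)
        nbm_tot = nbm.sum()
        nb_tot = nb.sum()
        out[i] = (
            ms.sum() - nbm_tot,
            (ns - ms).sum() - (nb_tot - nbm_tot),
            nbm_tot,
            nb_tot - nbm_tot,
        )
    return out


def generate_cohort(config: SyntheticConfig) -> StudyDataset:
    """Generate a full study dataset plus ground-truth sidecars.

    The output passes the study filters and position annotation unchanged.
    Ground truth (per-islet regime and counts, per-cell distances and
    positions) is stored in ``provenance['ground_truth_islets']`` and
    ``provenance['ground_truth_cells']`` for test oracles.
    """
    rng = np.random.default_rng(config.seed)
    n_t1d = int(round(config.n_islets * config.t1d_fraction))
    statuses = ["t1d"] * n_t1d + ["control"] * (config.n_islets - n_t1d)
    islets = []
    truth_islets = []
    truth_cells = []
    warnings = []
    # per-islet substreams so cohorts are reproducible under any scheduling
    substreams = rng.spawn(config.n_islets)
    for idx, (status, sub) in enumerate(zip(statuses, substreams)):
        islet_id = f"synt-{idx:05d}"
        if status == "control":
            case_id = f"ctrl-{idx % config.n_cases_control:02d}"
        else:
            case_id = f"t1d-{idx % config.n_cases_t1d:02d}"
        # area law: log-normal, optionally truncated above the islet filter
        while True:
            area = float(
                np.exp(np.log(config.area_median) + config.area_sigma * sub.normal())
            )
            if not config.truncate_area or area > config.area_min * 1.05:
                break
        boundary = make_islet_boundary(area, config.folding, sub)
        xy = place_cells(boundary, config.cell_density, config.nucleus_radius, sub)
        n = len(xy)
        expect = boundary.area * config.cell_density
        if n < 0.5 * expect:
            warnings.append(
                f"{islet_id}: placed {n} cells of ~{expect:.0f} expected (density infeasible)"
            )
        nuclei = [_circle_polygon(p, config.nucleus_radius) for p in xy]
        dists = boundary_distances(nuclei, boundary)
        if status == "control":
            mode = config.control_beta_mode
        else:
            mode = _t1d_mode(area, config)
        a, b = _beta_params(mode, config.beta_concentration)
        beta_fraction = float(sub.beta(a, b))
        types, regime = assign_types(
            dists, beta_fraction, config.adherence, config.d_min, sub
        )
        cells = []
        n_none = 0
        for j, (p, nuc, d, t) in enumerate(zip(xy, nuclei, dists, types)):
            if t == BETA:
                hormone = "beta"
            else:
                hormone = sub.choice(_NON_BETA_CLASSES, p=_NON_BETA_WEIGHTS)
            if config.none_fraction > 0 and sub.random() < config.none_fraction:
                hormone = "none"
                n_none += 1
            cell_id = f"{islet_id}-c{j:04d}"
            cells.append(
                CellRecord(
                    cell_id=cell_id,
                    islet_id=islet_id,
                    case_id=case_id,
                    centroid=(float(p[0]), float(p[1])),
                    nuclear_boundary=nuc,
                    hormone_class=hormone,
                )
            )
            truth_cells.append(
                {
                    "cell_id": cell_id,
                    "islet_id": islet_id,
                    "boundary_distance_um": float(d),
                    "position": "mantle" if d < config.d_min else "core",
                    "true_type": t,
                }
            )
        mantle = dists < config.d_min
        is_nb = types == NON_BETA
        truth_islets.append(
            {
                "islet_id": islet_id,
                "case_id": case_id,
                "disease_status": status,
                "regime": regime,
                "area_um2": boundary.area,
                "N": n,
                "B": int(np.sum(~is_nb)),
                "NB": int(np.sum(is_nb)),
                "M": int(np.sum(mantle)),
                "C": int(np.sum(~mantle)),
                "NB_m": int(np.sum(is_nb & mantle)),
                "n_none": n_none,
            }
        )
        centroid = boundary.centroid
        islets.append(
            IsletRecord(
                islet_id=islet_id,
                case_id=case_id,
                disease_status=status,
                boundary=boundary,
                area=float(boundary.area),
                centroid=(float(centroid.x), float(centroid.y)),
                cells=cells,
            )
        )
    params = AnalysisParams(d_min=config.d_min, rng_seed=config.seed)
    return StudyDataset(
        islets=islets,
        params=params,
        provenance={
            "source": "synthetic",
            "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
            "warnings": warnings,
            "ground_truth_islets": pd.DataFrame(truth_islets),
            "ground_truth_cells": pd.DataFrame(truth_cells),
        },
    )
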