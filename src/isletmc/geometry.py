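"""Mantle/core geometry: nuclear-boundary-to-islet-boundary distances.

A cell is a *mantle* cell when the minimal Euclidean distance between the
contour of its nucleus and the border of its islet is strictly smaller than
``d_min`` (default 8 μm) — i.e. it is a first neighbour of the islet border —
and a *core* cell otherwise. Distances are curve-to-curve (exact
segment-to-segment minima, handled by shapely's GEOS backend), not
centroid-based; a centroid mode exists for degraded inputs lacking nuclear
contours.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

from .dataset import CORE, MANTLE, IsletCounts, StudyDataset, counts_from_cells


def polygon_min_distance(nuclear_boundary: Polygon, islet_boundary: Polygon) -> float:
    """Minimal distance (μm) between the nuclear contour and the islet border.

    Returns 0 when the curves touch or cross (nuclei straddling the border
    are first neighbours of it by construction).
    """
    for name, poly in (("nuclear", nuclear_boundary), ("islet", islet_boundary)):
        if not isinstance(poly, Polygon) or len(poly.exterior.coords) < 4:
            raise ValueError(f"degenerate {name} polygon (needs >= 3 vertices)")
        if not poly.is_valid:
            raise ValueError(f"{name} polygon is not simple")
    a = nuclear_boundary.exterior
    b = islet_boundary.exterior
    if a.intersects(b):
        return 0.0
    return float(a.distance(b))


def classify_position(distance: float, d_min: float) -> str:
    """Label a cell mantle (distance < d_min, strictly) or core."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    return MANTLE if distance < d_min else CORE


def boundary_distances(
    nuclear_boundaries: Iterable[Polygon], islet_boundary: Polygon
) -> np.ndarray:
    """Vectorised curve-to-curve distances for all nuclei of one islet."""
    geoms = np.asarray(
        [g.exterior for g in nuclear_boundaries], dtype=object
    )
    if geoms.size == 0:
        return np.empty(0)
    ring = islet_boundary.exterior
    d = shapely.distance(geoms, ring)
    d[shapely.intersects(geoms, ring)] = 0.0
    return d


def annotate_positions(
    dataset: StudyDataset,
    d_min: Optional[float] = None,
    mode: str = "boundary",
) -> StudyDataset:
    """Fill boundary_distance and position on every cell; cache islet counts.

    ``mode='centroid'`` measures from the nuclear centroid instead of the
    nuclear contour (for inputs without usable nuclear boundaries).
    """
    if mode not in ("boundary", "centroid"):
        raise ValueError(f"unknown mode {mode!r}")
    d_min = dataset.params.d_min if d_min is None else float(d_min)
    for islet in dataset.islets:
        if islet.boundary is None:
            raise ValueError(f"islet {islet.islet_id} has no boundary polygon")
        if not islet.cells:
            islet.counts = IsletCounts(0, 0, 0, 0, 0, 0)
            continue
        if mode == "boundary":
            dists = boundary_distances(
                [c.nuclear_boundary for c in islet.cells], islet.boundary
            )
        else:
            pts = np.asarray([Point(c.centroid) for c in islet.cells], dtype=object)
            dists = shapely.distance(pts, islet.boundary.exterior)
            inside = shapely.covers(islet.boundary, pts)
            dists[~inside] = 0.0
        for cell, d in zip(islet.cells, dists):
            cell.boundary_distance = float(d)
            cell.position = classify_position(float(d), d_min)
        islet.counts = counts_from_cells(islet.cells)
    return dataset


def pooled_counts(dataset: StudyDataset) -> IsletCounts:
    """Sum per-islet counts over the whole dataset."""
    tot = np.zeros(6, dtype=int)
    for islet in dataset.islets:
        if islet.counts is None:
            raise ValueError(f"islet {islet.islet_id} not annotated")
        c = islet.counts
        tot += (c.N, c.NB, c.B, c.M, c.C, c.NB_m)
    return IsletCounts(*map(int, tot))


def sensitivity_sweep_dmin(dataset: StudyDataset, d_values) -> pd.DataFrame:
    """Pooled counts and odds ratio for each candidate mantle threshold.

    Distances do not depend on d_min, so the sweep re-thresholds the cached
    per-cell distances. Pooled mantle count M is non-decreasing in d_min.
    """
    from .association import ContingencyTable, odds_ratio

    d_values = list(d_values)
    if not d_values:
        raise ValueError("d_values must be non-empty")
    if any(c.boundary_distance is None for c in dataset.iter_cells()):
        annotate_positions(dataset)

    dist = np.array([c.boundary_distance for c in dataset.iter_cells()])
    is_beta = np.array([c.binary_type == "beta" for c in dataset.iter_cells()])
    rows = []
    for d in d_values:
        if d <= 0:
            raise ValueError("d_min values must be positive")
        mantle = dist < d
        table = ContingencyTable(
            beta_mantle=int(np.sum(is_beta & mantle)),
            beta_core=int(np.sum(is_beta & ~mantle)),
            nonbeta_mantle=int(np.sum(~is_beta & mantle)),
            nonbeta_core=int(np.sum(~is_beta & ~mantle)),
        )
        rows.append(
            {
                "d_min": float(d),
                "N": int(dist.size),
                "NB": int(np.sum(~is_beta)),
                "B": int(np.sum(is_beta)),
                "M": int(np.sum(mantle)),
                "C": int(np.sum(~mantle)),
                "NB_m": table.nonbeta_mantle,
                "odds_ratio": odds_ratio(table),
            }
        )
    return pd.DataFrame(rows)
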