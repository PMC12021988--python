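"""Core data model for islet architecture analysis.

A study dataset is a collection of islets, each carrying its detected
endocrine cells. Geometry is held as shapely objects with coordinates in
micrometres; all counts and labels derived downstream (mantle/core position,
binary cell type) are annotated in place on these records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

HORMONE_CLASSES = ("alpha", "beta", "delta", "epsilon", "gamma", "none")
NON_BETA_CLASSES = frozenset({"alpha", "delta", "epsilon", "gamma"})

BETA = "beta"
NON_BETA = "non-beta"
MANTLE = "mantle"
CORE = "core"


@dataclass
class AnalysisParams:
    """Study-level parameters.

    d_min: mantle threshold in μm — a cell whose nuclear boundary lies
        strictly closer than this to the islet boundary is a mantle cell.
    min_islet_area: clusters must exceed this area (μm²) to count as islets.
    alpha_level: significance threshold for the independence test.
    n_bootstrap: bootstrap resample count for odds-ratio CIs.
    """

    d_min: float = 8.0
    min_islet_area: float = 1000.0
    alpha_level: float = 0.001
    n_bootstrap: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        if self.min_islet_area <= 0:
            raise ValueError("min_islet_area must be positive")
        if not 0 < self.alpha_level < 1:
            raise ValueError("alpha_level must lie in (0, 1)")


@dataclass
class CellRecord:
    """One detected endocrine cell.

    ``binary_type`` (beta / non-beta) is set by the study filters;
    ``position`` (mantle / core) and ``boundary_distance`` by the
    mantle-core geometry stage.
    """

    cell_id: str
    islet_id: str
    case_id: str
    centroid: tuple
    nuclear_boundary: Polygon
    hormone_class: str
    binary_type: Optional[str] = None
    position: Optional[str] = None
    boundary_distance: Optional[float] = None

    def __post_init__(self) -> None:
        if self.hormone_class not in HORMONE_CLASSES:
            raise ValueError(
                f"unknown hormone class {self.hormone_class!r} for cell {self.cell_id}"
            )
        if self.binary_type is not None:
            expected = BETA if self.hormone_class == BETA else NON_BETA
            if self.hormone_class == "none":
                raise ValueError("cells of class 'none' carry no binary type")
            if self.binary_type != expected:
                raise ValueError(
                    f"binary_type {self.binary_type!r} inconsistent with "
                    f"hormone class {self.hormone_class!r}"
                )


@dataclass
class IsletCounts:
    """Per-islet cell counts characterising the mantle-core configuration.

    N: total cells; NB: non-beta; B: beta; M: mantle; C: core;
    NB_m: non-beta cells located in the mantle.
    """

    N: int
    NB: int
    B: int
    M: int
    C: int
    NB_m: int

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        vals = (self.N, self.NB, self.B, self.M, self.C, self.NB_m)
        if any(int(v) != v or v < 0 for v in vals):
            raise ValueError(f"counts must be non-negative integers: {self}")
        if self.N != self.NB + self.B:
            raise ValueError(f"N != NB + B in {self}")
        if self.N != self.M + self.C:
            raise ValueError(f"N != M + C in {self}")
        if not 0 <= self.NB_m <= min(self.NB, self.M):
            raise ValueError(f"NB_m out of range in {self}")
        # mantle positions not fillable by non-beta must hold beta cells
        if self.NB_m < self.NB + self.M - self.N:
            raise ValueError(f"NB_m below forced minimum in {self}")


@dataclass
class IsletRecord:
    islet_id: str
    case_id: str
    disease_status: str
    boundary: Polygon
    area: float
    centroid: tuple
    cells: list = field(default_factory=list)
    counts: Optional[IsletCounts] = None

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"islet {self.islet_id}: area must be positive")


@dataclass
class StudyDataset:
    """All islets of a study plus analysis parameters and provenance.

    ``provenance`` records source files, ingest warnings, orphan cells and
    filter tallies so every downstream count is auditable.
    """

    islets: list = field(default_factory=list)
    params: AnalysisParams = field(default_factory=AnalysisParams)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [i.islet_id for i in self.islets]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate islet_id in dataset")

    @property
    def n_islets(self) -> int:
        return len(self.islets)

    @property
    def n_cells(self) -> int:
        return sum(len(i.cells) for i in self.islets)

    def iter_cells(self) -> Iterator[CellRecord]:
        for islet in self.islets:
            yield from islet.cells

    def islet(self, islet_id: str) -> IsletRecord:
        for i in self.islets:
            if i.islet_id == islet_id:
                return i
        raise KeyError(islet_id)

    def cells_frame(self) -> pd.DataFrame:
        rows = []
        for islet in self.islets:
            for c in islet.cells:
                rows.append(
                    {
                        "cell_id": c.cell_id,
                        "islet_id": c.islet_id,
                        "case_id": c.case_id,
                        "centroid_x_um": c.centroid[0],
                        "centroid_y_um": c.centroid[1],
                        "hormone_class": c.hormone_class,
                        "binary_type": c.binary_type,
                        "boundary_distance_um": c.boundary_distance,
                        "position": c.position,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "cell_id",
                "islet_id",
                "case_id",
                "centroid_x_um",
                "centroid_y_um",
                "hormone_class",
                "binary_type",
                "boundary_distance_um",
                "position",
            ],
        )

    def islets_frame(self) -> pd.DataFrame:
        rows = []
        for i in self.islets:
            row = {
                "islet_id": i.islet_id,
                "case_id": i.case_id,
                "disease_status": i.disease_status,
                "area_um2": i.area,
                "centroid_x_um": i.centroid[0],
                "centroid_y_um": i.centroid[1],
                "n_cells": len(i.cells),
            }
            if i.counts is not None:
                row.update(
                    N=i.counts.N, NB=i.counts.NB, B=i.counts.B,
                    M=i.counts.M, C=i.counts.C, NB_m=i.counts.NB_m,
                )
            rows.append(row)
        return pd.DataFrame(rows)


def counts_from_cells(cells) -> IsletCounts:
    """Cross-tabulate annotated cells into the six per-islet counts."""
    n = len(cells)
    b = sum(1 for c in cells if c.binary_type == BETA)
    m = sum(1 for c in cells if c.position == MANTLE)
    nb_m = sum(1 for c in cells if c.binary_type == NON_BETA and c.position == MANTLE)
    for c in cells:
        if c.binary_type is None or c.position is None:
            raise ValueError(f"cell {c.cell_id} lacks type or position annotation")
    return IsletCounts(N=n, NB=n - b, B=b, M=m, C=n - m, NB_m=nb_m)


def copy_islet(islet: IsletRecord, cells=None) -> IsletRecord:
    """Shallow copy of an islet, optionally with a replacement cell list."""
    new_cells = [replace(c) for c in (islet.cells if cells is None else cells)]
    return replace(islet, cells=new_cells, counts=None)
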