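"""Reading and writing detection exports, and the study filters.

Two interchangeable on-disk representations are supported:

* QuPath-style GeoJSON FeatureCollections — one file of islet boundary
  polygons, one of cell features (nuclear-boundary polygons or centroids)
  with a ``classification`` property;
* two delimited tables mirroring the exported islet / cell data frames,
  with geometry carried as WKT columns.

Coordinates are treated as micrometres; readers accept a ``scale`` factor
for exports in pixels. Hormone classifications are matched
case-insensitively with a user-extensible synonym map (e.g. "INS" → beta).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import shapely
import shapely.wkt
from shapely.geometry import Point, Polygon
from shapely.strtree import STRtree

from .dataset import (
    BETA,
    HORMONE_CLASSES,
    NON_BETA,
    AnalysisParams,
    CellRecord,
    IsletRecord,
    StudyDataset,
)

#: default marker→class synonyms, extended (not replaced) by the caller's map
DEFAULT_SYNONYMS = {
    "ins": "beta",
    "insulin": "beta",
    "gcg": "alpha",
    "glucagon": "alpha",
    "sst": "delta",
    "somatostatin": "delta",
    "ppy": "gamma",
    "pp": "gamma",
    "ghrl": "epsilon",
    "ghrelin": "epsilon",
}

AREA_TOLERANCE = 0.01  # relative mismatch between reported and polygon area


class IngestError(ValueError):
    """Malformed or inconsistent detection export."""


def _normalise_class(raw, synonyms: Optional[Mapping[str, str]], where: str) -> str:
    label = str(raw).strip().lower()
    table = dict(DEFAULT_SYNONYMS)
    if synonyms:
        table.update({k.lower(): v for k, v in synonyms.items()})
    label = table.get(label, label)
    if label not in HORMONE_CLASSES:
        raise IngestError(f"{where}: unknown classification {raw!r}")
    return label


def _scale_polygon(poly: Polygon, scale: float) -> Polygon:
    if scale == 1.0:
        return poly
    return shapely.transform(poly, lambda c: c * scale)


def read_qupath_geojson(
    islet_path,
    cell_path,
    case_meta: Optional[Mapping[str, str]] = None,
    synonyms: Optional[Mapping[str, str]] = None,
    scale: float = 1.0,
    params: Optional[AnalysisParams] = None,
    nucleus_radius: float = 3.0,
) -> StudyDataset:
    """Build a dataset from islet and cell GeoJSON FeatureCollections.

    Cells lacking an explicit ``islet_id`` property are assigned to the
    islet whose polygon covers their centroid (boundary counts as inside);
    cells covered by no islet go to the orphan list in provenance. Point
    cell features get a substitute disc of ``nucleus_radius`` μm.
    """
    islet_path, cell_path = Path(islet_path), Path(cell_path)
    provenance: dict = {
        "source": "geojson",
        "files": [str(islet_path), str(cell_path)],
        "warnings": [],
        "orphans": [],
    }
    islets: dict = {}
    for idx, feat in enumerate(_load_features(islet_path)):
        try:
            props = feat.get("properties", {})
            geom = feat["geometry"]
            if geom["type"] != "Polygon":
                raise KeyError("geometry must be Polygon")
            poly = _scale_polygon(Polygon(geom["coordinates"][0]), scale)
            islet_id = str(props["islet_id"])
            case_id = str(props.get("case_id", ""))
            status = props.get("disease_status")
            if status is None and case_meta is not None:
                status = case_meta.get(case_id)
            if status is None:
                raise KeyError("disease_status missing (supply case_meta)")
        except (KeyError, IndexError, TypeError) as exc:
            raise IngestError(f"islet feature {idx} of {islet_path.name}: {exc}") from exc
        if islet_id in islets:
            raise IngestError(f"duplicate islet_id {islet_id!r}")
        reported = props.get("area_um2")
        area = float(poly.area)
        if reported is not None and abs(float(reported) - area) > AREA_TOLERANCE * area:
            provenance["warnings"].append(
                f"islet {islet_id}: reported area {reported} differs from "
                f"polygon area {area:.1f} by >1%; polygon is authoritative"
            )
        c = poly.centroid
        islets[islet_id] = IsletRecord(
            islet_id=islet_id,
            case_id=case_id,
            disease_status=str(status),
            boundary=poly,
            area=area,
            centroid=(float(c.x), float(c.y)),
        )

    ordered = list(islets.values())
    tree = STRtree([i.boundary for i in ordered])
    for idx, feat in enumerate(_load_features(cell_path)):
        where = f"cell feature {idx} of {cell_path.name}"
        try:
            props = feat.get("properties", {})
            geom = feat["geometry"]
            if geom["type"] == "Polygon":
                nuc = _scale_polygon(Polygon(geom["coordinates"][0]), scale)
                cen = nuc.centroid
                centroid = (float(cen.x), float(cen.y))
            elif geom["type"] == "Point":
                centroid = tuple(float(v) * scale for v in geom["coordinates"][:2])
                nuc = Point(centroid).buffer(nucleus_radius, quad_segs=5)
                provenance["substituted_nuclei"] = True
            else:
                raise KeyError("geometry must be Polygon or Point")
            hormone = _normalise_class(props["classification"], synonyms, where)
            cell_id = str(props.get("cell_id", f"cell-{idx}"))
        except (KeyError, IndexError, TypeError) as exc:
            raise IngestError(f"{where}: {exc}") from exc
        islet_id = props.get("islet_id")
        if islet_id is not None:
            islet_id = str(islet_id)
            if islet_id not in islets:
                raise IngestError(f"{where}: unknown islet_id {islet_id!r}")
            parent = islets[islet_id]
        else:
            pt = Point(centroid)
            hits = [
                k for k in tree.query(pt) if shapely.covers(ordered[k].boundary, pt)
            ]
            parent = ordered[min(hits)] if hits else None
        record_kwargs = dict(
            cell_id=cell_id,
            centroid=centroid,
            nuclear_boundary=nuc,
            hormone_class=hormone,
        )
        if parent is None:
            provenance["orphans"].append(
                CellRecord(islet_id="", case_id="", **record_kwargs)
            )
        else:
            parent.cells.append(
                CellRecord(
                    islet_id=parent.islet_id, case_id=parent.case_id, **record_kwargs
                )
            )
    return StudyDataset(
        islets=ordered, params=params or AnalysisParams(), provenance=provenance
    )


def _load_features(path: Path):
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise IngestError(f"{path.name}: not valid JSON ({exc})") from exc
    if doc.get("type") != "FeatureCollection" or "features" not in doc:
        raise IngestError(f"{path.name}: expected a GeoJSON FeatureCollection")
    return doc["features"]


def write_geojson(dataset: StudyDataset, islet_path, cell_path, precision: int = 6):
    """Write the dataset back out as two GeoJSON FeatureCollections."""

    def coords(poly):
        return [
            [[round(x, precision), round(y, precision)] for x, y in poly.exterior.coords]
        ]

    islet_feats = []
    cell_feats = []
    for islet in dataset.islets:
        islet_feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": coords(islet.boundary)},
                "properties": {
                    "islet_id": islet.islet_id,
                    "case_id": islet.case_id,
                    "disease_status": islet.disease_status,
                    "area_um2": round(islet.area, precision),
                    "object_type": "islet",
                },
            }
        )
        for c in islet.cells:
            props = {
                "cell_id": c.cell_id,
                "islet_id": c.islet_id,
                "classification": c.hormone_class,
                "object_type": "cell",
            }
            if c.position is not None:
                props["position"] = c.position
                props["boundary_distance_um"] = round(c.boundary_distance, precision)
            cell_feats.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": coords(c.nuclear_boundary),
                    },
                    "properties": props,
                }
            )
    for path, feats in ((islet_path, islet_feats), (cell_path, cell_feats)):
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


REQUIRED_CELL_COLUMNS = (
    "cell_id", "islet_id", "case_id", "centroid_x_um", "centroid_y_um", "hormone_class",
)
REQUIRED_ISLET_COLUMNS = (
    "islet_id", "case_id", "disease_status", "boundary_wkt", "area_um2",
)


def _read_delimited(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", encoding="utf-8")


def read_tabular(
    cell_table,
    islet_table,
    synonyms: Optional[Mapping[str, str]] = None,
    scale: float = 1.0,
    nucleus_radius: Optional[float] = None,
    params: Optional[AnalysisParams] = None,
) -> StudyDataset:
    """Build a dataset from delimited cell and islet tables.

    When the cell table has no ``nuclear_boundary_wkt`` column, a disc of
    ``nucleus_radius`` μm centred on each centroid is substituted and the
    substitution is flagged in provenance.
    """
    cells_df = _read_delimited(cell_table)
    islets_df = _read_delimited(islet_table)
    for col in REQUIRED_ISLET_COLUMNS:
        if col not in islets_df.columns:
            raise IngestError(f"islet table: missing required column {col!r}")
    for col in REQUIRED_CELL_COLUMNS:
        if col not in cells_df.columns:
            raise IngestError(f"cell table: missing required column {col!r}")
    if islets_df["islet_id"].duplicated().any():
        dupes = islets_df.loc[islets_df["islet_id"].duplicated(), "islet_id"].iloc[0]
        raise IngestError(f"duplicate islet_id {dupes!r} in islet table")

    provenance: dict = {
        "source": "tabular",
        "files": [str(cell_table), str(islet_table)],
        "warnings": [],
        "orphans": [],
    }
    islets: dict = {}
    for _, row in islets_df.iterrows():
        poly = _scale_polygon(shapely.wkt.loads(row["boundary_wkt"]), scale)
        area = float(poly.area)
        reported = float(row["area_um2"]) * scale * scale
        if abs(reported - area) > AREA_TOLERANCE * area:
            provenance["warnings"].append(
                f"islet {row['islet_id']}: reported area {reported:.1f} differs "
                f"from polygon area {area:.1f} by >1%; polygon is authoritative"
            )
        c = poly.centroid
        islets[str(row["islet_id"])] = IsletRecord(
            islet_id=str(row["islet_id"]),
            case_id=str(row["case_id"]),
            disease_status=str(row["disease_status"]),
            boundary=poly,
            area=area,
            centroid=(float(c.x), float(c.y)),
        )

    has_wkt = "nuclear_boundary_wkt" in cells_df.columns
    if not has_wkt:
        if nucleus_radius is None:
            raise IngestError(
                "cell table has no nuclear_boundary_wkt column; "
                "pass nucleus_radius to substitute discs"
            )
        provenance["substituted_nuclei"] = True
    has_position = "position" in cells_df.columns and "boundary_distance_um" in cells_df.columns
    for i, row in cells_df.iterrows():
        islet_id = str(row["islet_id"])
        if islet_id not in islets:
            raise IngestError(f"cell row {i}: unknown islet_id {islet_id!r}")
        centroid = (float(row["centroid_x_um"]) * scale, float(row["centroid_y_um"]) * scale)
        if has_wkt and isinstance(row["nuclear_boundary_wkt"], str):
            nuc = _scale_polygon(shapely.wkt.loads(row["nuclear_boundary_wkt"]), scale)
        else:
            nuc = Point(centroid).buffer(nucleus_radius, quad_segs=5)
        hormone = _normalise_class(row["hormone_class"], synonyms, f"cell row {i}")
        cell = CellRecord(
            cell_id=str(row["cell_id"]),
            islet_id=islet_id,
            case_id=str(row["case_id"]),
            centroid=centroid,
            nuclear_boundary=nuc,
            hormone_class=hormone,
        )
        if "binary_type" in cells_df.columns and isinstance(row.get("binary_type"), str):
            cell.binary_type = row["binary_type"]
        if has_position and isinstance(row["position"], str):
            cell.position = row["position"]
            cell.boundary_distance = float(row["boundary_distance_um"])
        islets[islet_id].cells.append(cell)
    return StudyDataset(
        islets=list(islets.values()),
        params=params or AnalysisParams(),
        provenance=provenance,
    )


def write_tabular(
    dataset: StudyDataset,
    cell_table,
    islet_table,
    include_boundaries: bool = True,
    precision: int = 6,
):
    """Write the dataset as delimited cell and islet tables (WKT geometry)."""
    cells = dataset.cells_frame()
    if include_boundaries:
        wkts = [
            shapely.to_wkt(c.nuclear_boundary, rounding_precision=precision)
            for c in dataset.iter_cells()
        ]
        cells["nuclear_boundary_wkt"] = wkts
    islets = pd.DataFrame(
        [
            {
                "islet_id": i.islet_id,
                "case_id": i.case_id,
                "disease_status": i.disease_status,
                "boundary_wkt": shapely.to_wkt(i.boundary, rounding_precision=precision),
                "area_um2": i.area,
            }
            for i in dataset.islets
        ]
    )
    cells.to_csv(cell_table, index=False)
    islets.to_csv(islet_table, index=False)


def apply_study_filters(dataset: StudyDataset) -> StudyDataset:
    """Apply the study's inclusion rules; returns a new dataset with tallies.

    Rules: clusters must exceed the minimum islet area (strict >, default
    1000 μm²) to count as islets; cells unlabelled by any hormone ('none')
    are excluded; remaining cells get their binary type (beta vs non-beta).
    Islets emptied by the 'none' exclusion are retained and flagged so the
    tallies stay auditable. Idempotent.
    """
    params = dataset.params
    kept_islets = []
    tallies = {
        "islets_in": dataset.n_islets,
        "islets_removed_small": 0,
        "cells_in": dataset.n_cells,
        "cells_in_removed_islets": 0,
        "cells_removed_none": 0,
        "cells_kept": 0,
        "empty_islets": [],
    }
    for islet in dataset.islets:
        if not islet.area > params.min_islet_area:
            tallies["islets_removed_small"] += 1
            tallies["cells_in_removed_islets"] += len(islet.cells)
            continue
        kept_cells = []
        for c in islet.cells:
            if c.hormone_class == "none":
                tallies["cells_removed_none"] += 1
                continue
            c.binary_type = BETA if c.hormone_class == BETA else NON_BETA
            kept_cells.append(c)
        new = IsletRecord(
            islet_id=islet.islet_id,
            case_id=islet.case_id,
            disease_status=islet.disease_status,
            boundary=islet.boundary,
            area=islet.area,
            centroid=islet.centroid,
            cells=kept_cells,
        )
        if not kept_cells:
            tallies["empty_islets"].append(islet.islet_id)
        tallies["cells_kept"] += len(kept_cells)
        kept_islets.append(new)
    provenance = dict(dataset.provenance)
    provenance["filters"] = tallies
    return StudyDataset(islets=kept_islets, params=params, provenance=provenance)
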