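"""Detection-export readers/writers and the study filters."""

import json

import numpy as np
import pandas as pd
import pytest

import isletmc as m
from isletmc.io import IngestError, apply_study_filters

from conftest import make_cell, make_islet, square


def small_cohort(seed=31, none_fraction=0.1):
    cfg = m.SyntheticConfig(
        n_islets=15, t1d_fraction=0.4, none_fraction=none_fraction,
        area_median=4000, seed=seed,
    )
    return m.generate_cohort(cfg)


def counts_signature(ds):
    frame = ds.cells_frame()
    return (
        ds.n_islets,
        ds.n_cells,
        frame["hormone_class"].value_counts().to_dict(),
    )


class TestRoundTrip:
    def test_tabular_round_trip(self, tmp_path):
        ds = small_cohort()
        m.write_tabular(ds, tmp_path / "cells.csv", tmp_path / "islets.csv")
        back = m.read_tabular(tmp_path / "cells.csv", tmp_path / "islets.csv")
        assert counts_signature(back) == counts_signature(ds)
        a = ds.cells_frame()
        b = back.cells_frame()
        np.testing.assert_allclose(a["centroid_x_um"], b["centroid_x_um"], atol=1e-6)
        np.testing.assert_allclose(a["centroid_y_um"], b["centroid_y_um"], atol=1e-6)
        for orig, new in zip(ds.islets, back.islets):
            assert new.area == pytest.approx(orig.area, rel=1e-6)
            assert new.disease_status == orig.disease_status

    def test_geojson_round_trip(self, tmp_path):
        ds = small_cohort(seed=32)
        m.write_geojson(ds, tmp_path / "islets.geojson", tmp_path / "cells.geojson")
        back = m.read_qupath_geojson(
            tmp_path / "islets.geojson", tmp_path / "cells.geojson"
        )
        assert counts_signature(back) == counts_signature(ds)
        for orig, new in zip(ds.islets, back.islets):
            assert new.area == pytest.approx(orig.area, rel=1e-6)

    def test_annotated_positions_survive_tabular_round_trip(self, tmp_path):
        ds = apply_study_filters(small_cohort(seed=33, none_fraction=0.0))
        m.annotate_positions(ds)
        m.write_tabular(ds, tmp_path / "c.csv", tmp_path / "i.csv")
        back = m.read_tabular(tmp_path / "c.csv", tmp_path / "i.csv")
        a = ds.cells_frame()
        b = back.cells_frame()
        assert (a["position"] == b["position"]).all()
        np.testing.assert_allclose(
            a["boundary_distance_um"], b["boundary_distance_um"], atol=1e-6
        )


class TestGeoJSONReader:
    def _write(self, tmp_path, islet_feats, cell_feats):
        ip, cp = tmp_path / "islets.geojson", tmp_path / "cells.geojson"
        ip.write_text(json.dumps({"type": "FeatureCollection", "features": islet_feats}))
        cp.write_text(json.dumps({"type": "FeatureCollection", "features": cell_feats}))
        return ip, cp

    def _islet_feature(self, islet_id="i0", side=60.0):
        ring = [[0, 0], [side, 0], [side, side], [0, side], [0, 0]]
        return {
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {
                "islet_id": islet_id, "case_id": "k0", "disease_status": "control",
            },
        }

    def _cell_feature(self, cx, cy, classification, islet_id=None, cell_id="c0"):
        ring = [[cx - 2, cy - 2], [cx + 2, cy - 2], [cx + 2, cy + 2],
                [cx - 2, cy + 2], [cx - 2, cy - 2]]
        props = {"cell_id": cell_id, "classification": classification}
        if islet_id is not None:
            props["islet_id"] = islet_id
        return {
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": props,
        }

    def test_explicit_parent_ids(self, tmp_path):
        cells = [self._cell_feature(10 + 5 * i, 10, "beta", islet_id="i0",
                                    cell_id=f"c{i}") for i in range(5)]
        ip, cp = self._write(tmp_path, [self._islet_feature()], cells)
        ds = m.read_qupath_geojson(ip, cp)
        assert ds.n_islets == 1 and ds.n_cells == 5

    def test_none_class_retained_at_ingest(self, tmp_path):
        ip, cp = self._write(
            tmp_path, [self._islet_feature()],
            [self._cell_feature(10, 10, "none", islet_id="i0")],
        )
        ds = m.read_qupath_geojson(ip, cp)
        assert ds.n_cells == 1
        assert next(ds.iter_cells()).hormone_class == "none"

    def test_orphan_cell_reported_not_dropped(self, tmp_path):
        ip, cp = self._write(
            tmp_path, [self._islet_feature(side=60)],
            [self._cell_feature(500, 500, "beta")],  # outside every islet
        )
        ds = m.read_qupath_geojson(ip, cp)
        assert ds.n_cells == 0
        assert len(ds.provenance["orphans"]) == 1

    def test_containment_assignment_boundary_counts_inside(self, tmp_path):
        ip, cp = self._write(
            tmp_path, [self._islet_feature(side=60)],
            [self._cell_feature(60, 30, "alpha")],  # centroid exactly on border
        )
        ds = m.read_qupath_geojson(ip, cp)
        assert ds.n_cells == 1 and not ds.provenance["orphans"]

    def test_synonym_map_case_insensitive(self, tmp_path):
        ip, cp = self._write(
            tmp_path, [self._islet_feature()],
            [self._cell_feature(10, 10, "INS", islet_id="i0"),
             self._cell_feature(20, 10, "Gcg", islet_id="i0", cell_id="c1")],
        )
        classes = {c.hormone_class for c in m.read_qupath_geojson(ip, cp).iter_cells()}
        assert classes == {"beta", "alpha"}

    def test_unknown_classification_raises(self, tmp_path):
        ip, cp = self._write(
            tmp_path, [self._islet_feature()],
            [self._cell_feature(10, 10, "mystery", islet_id="i0")],
        )
        with pytest.raises(IngestError, match="mystery"):
            m.read_qupath_geojson(ip, cp)

    def test_malformed_feature_names_index(self, tmp_path):
        bad = {"type": "Feature", "geometry": {"type": "Polygon"}, "properties": {}}
        ip, cp = self._write(tmp_path, [self._islet_feature(), bad], [])
        with pytest.raises(IngestError, match="feature 1"):
            m.read_qupath_geojson(ip, cp)

    def test_not_json_raises(self, tmp_path):
        ip = tmp_path / "islets.geojson"
        ip.write_text("not json at all {")
        with pytest.raises(IngestError, match="JSON"):
            m.read_qupath_geojson(ip, ip)

    def test_pixel_scale_factor(self, tmp_path):
        ip, cp = self._write(
            tmp_path, [self._islet_feature(side=60)],
            [self._cell_feature(10, 10, "beta", islet_id="i0")],
        )
        ds = m.read_qupath_geojson(ip, cp, scale=0.5)
        assert ds.islets[0].area == pytest.approx(60 * 60 * 0.25)
        assert next(ds.iter_cells()).centroid[0] == pytest.approx(5.0)

    def test_area_mismatch_warning(self, tmp_path):
        feat = self._islet_feature()
        feat["properties"]["area_um2"] = 5000.0  # true area is 3600
        ip, cp = self._write(tmp_path, [feat], [])
        ds = m.read_qupath_geojson(ip, cp)
        assert any("differs" in w for w in ds.provenance["warnings"])
        assert ds.islets[0].area == pytest.approx(3600.0)


class TestTabularReader:
    def test_missing_column_named(self, tmp_path):
        pd.DataFrame({"islet_id": ["i0"], "boundary_wkt": ["POLYGON((0 0,1 0,1 1,0 0))"],
                      "disease_status": ["control"], "area_um2": [1.0]}).to_csv(
            tmp_path / "islets.csv", index=False)
        pd.DataFrame({"cell_id": ["c0"], "islet_id": ["i0"]}).to_csv(
            tmp_path / "cells.csv", index=False)
        with pytest.raises(IngestError, match="case_id"):
            m.read_tabular(tmp_path / "cells.csv", tmp_path / "islets.csv")

    def test_duplicate_islet_id_raises(self, tmp_path):
        ds = small_cohort(seed=35)
        m.write_tabular(ds, tmp_path / "cells.csv", tmp_path / "islets.csv")
        islets = pd.read_csv(tmp_path / "islets.csv")
        pd.concat([islets, islets.iloc[[0]]]).to_csv(tmp_path / "islets.csv", index=False)
        with pytest.raises(IngestError, match="duplicate islet_id"):
            m.read_tabular(tmp_path / "cells.csv", tmp_path / "islets.csv")

    def test_unknown_islet_reference_raises(self, tmp_path):
        ds = small_cohort(seed=36)
        m.write_tabular(ds, tmp_path / "cells.csv", tmp_path / "islets.csv")
        cells = pd.read_csv(tmp_path / "cells.csv")
        cells.loc[0, "islet_id"] = "missing-islet"
        cells.to_csv(tmp_path / "cells.csv", index=False)
        with pytest.raises(IngestError, match="missing-islet"):
            m.read_tabular(tmp_path / "cells.csv", tmp_path / "islets.csv")

    def test_disc_substitution_when_no_boundaries(self, tmp_path):
        ds = small_cohort(seed=37)
        m.write_tabular(ds, tmp_path / "cells.csv", tmp_path / "islets.csv",
                        include_boundaries=False)
        with pytest.raises(IngestError, match="nucleus_radius"):
            m.read_tabular(tmp_path / "cells.csv", tmp_path / "islets.csv")
        back = m.read_tabular(tmp_path / "cells.csv", tmp_path / "islets.csv",
                              nucleus_radius=3.0)
        assert back.provenance["substituted_nuclei"] is True
        cell = next(back.iter_cells())
        assert cell.nuclear_boundary.area == pytest.approx(np.pi * 9, rel=0.05)

    def test_tab_delimited_accepted(self, tmp_path):
        ds = small_cohort(seed=38)
        cells = tmp_path / "cells.tsv"
        islets = tmp_path / "islets.tsv"
        m.write_tabular(ds, tmp_path / "c.csv", tmp_path / "i.csv")
        pd.read_csv(tmp_path / "c.csv").to_csv(cells, sep="\t", index=False)
        pd.read_csv(tmp_path / "i.csv").to_csv(islets, sep="\t", index=False)
        back = m.read_tabular(cells, islets)
        assert back.n_cells == ds.n_cells


class TestStudyFilters:
    def _dataset_with_areas(self, *areas):
        islets = []
        for k, area in enumerate(areas):
            side = float(np.sqrt(area))
            poly = square(side / 2, side / 2, side / 2)
            islets.append(
                m.IsletRecord(
                    islet_id=f"i{k}", case_id="k", disease_status="control",
                    boundary=poly, area=poly.area,
                    centroid=(side / 2, side / 2),
                )
            )
        return m.StudyDataset(islets=islets)

    def test_area_threshold_is_strict(self):
        ds = apply_study_filters(self._dataset_with_areas(999.0, 1001.0))
        assert [i.islet_id for i in ds.islets] == ["i1"]
        assert ds.provenance["filters"]["islets_removed_small"] == 1

    def test_none_cells_excluded_and_typed(self):
        cells = [make_cell(f"c{i}", "i0", 10 + i, 10, "beta") for i in range(9)]
        cells.append(make_cell("c9", "i0", 30, 30, "none"))
        ds = m.StudyDataset(islets=[make_islet("i0", cells=cells)])
        out = apply_study_filters(ds)
        assert out.n_cells == 9
        assert out.provenance["filters"]["cells_removed_none"] == 1
        assert all(c.binary_type == "beta" for c in out.iter_cells())

    def test_nonbeta_classes_mapped(self):
        cells = [make_cell(f"c{i}", "i0", 10 + i, 10, h)
                 for i, h in enumerate(["alpha", "delta", "epsilon", "gamma", "beta"])]
        out = apply_study_filters(m.StudyDataset(islets=[make_islet("i0", cells=cells)]))
        types = [c.binary_type for c in out.iter_cells()]
        assert types == ["non-beta"] * 4 + ["beta"]

    def test_all_none_islet_retained_flagged_empty(self):
        cells = [make_cell(f"c{i}", "i0", 10 + i, 10, "none") for i in range(4)]
        out = apply_study_filters(m.StudyDataset(islets=[make_islet("i0", cells=cells)]))
        assert out.n_islets == 1 and out.n_cells == 0
        assert out.provenance["filters"]["empty_islets"] == ["i0"]

    def test_idempotent(self):
        ds = small_cohort(seed=39)
        once = apply_study_filters(ds)
        twice = apply_study_filters(once)
        assert counts_signature(once) == counts_signature(twice)
        assert twice.provenance["filters"]["cells_removed_none"] == 0

    def test_cell_conservation(self):
        ds = small_cohort(seed=40)
        out = apply_study_filters(ds)
        t = out.provenance["filters"]
        assert t["cells_in"] == (
            t["cells_kept"] + t["cells_removed_none"] + t["cells_in_removed_islets"]
        )
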