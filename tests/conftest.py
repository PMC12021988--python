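import numpy as np
import pytest
from shapely.geometry import Polygon

import isletmc as m


def square(cx, cy, half):
    return Polygon(
        [(cx - half, cy - half), (cx + half, cy - half),
         (cx + half, cy + half), (cx - half, cy + half)]
    )


def make_cell(cell_id, islet_id, cx, cy, hormone, half=2.0, case_id="case-0"):
    return m.CellRecord(
        cell_id=cell_id,
        islet_id=islet_id,
        case_id=case_id,
        centroid=(cx, cy),
        nuclear_boundary=square(cx, cy, half),
        hormone_class=hormone,
    )


def make_islet(islet_id, side=60.0, cells=(), status="control", case_id="case-0"):
    poly = square(side / 2, side / 2, side / 2)
    return m.IsletRecord(
        islet_id=islet_id,
        case_id=case_id,
        disease_status=status,
        boundary=poly,
        area=poly.area,
        centroid=(side / 2, side / 2),
        cells=list(cells),
    )


@pytest.fixture
def square_dataset():
    """One 60x60 μm islet with 6 hand-placed cells of known position.

    Cells at 4 μm from the border (nucleus contour to islet border: 2 μm,
    mantle) and at the centre (contour distance 26 μm, core).
    """
    cells = [
        make_cell("c0", "i0", 4, 30, "beta"),      # contour 2 μm from border
        make_cell("c1", "i0", 56, 30, "alpha"),
        make_cell("c2", "i0", 30, 4, "delta"),
        make_cell("c3", "i0", 30, 30, "beta"),     # centre: contour 28 μm away
        make_cell("c4", "i0", 24, 30, "beta"),
        make_cell("c5", "i0", 36, 30, "gamma"),
    ]
    islet = make_islet("i0", cells=cells)
    ds = m.StudyDataset(islets=[islet])
    return m.apply_study_filters(ds)


def _cohort(**kw):
    cfg = m.SyntheticConfig(**kw)
    ds = m.apply_study_filters(m.generate_cohort(cfg))
    m.annotate_positions(ds)
    # carry the generator ground truth through the filter copy
    return ds


@pytest.fixture(scope="session")
def null_cohort():
    """θ=0 cohort: random arrangements, control beta-fraction law."""
    return _cohort(n_islets=120, adherence=0.0, t1d_fraction=0.5, seed=11)


@pytest.fixture(scope="session")
def ordered_cohort():
    """θ=1 cohort: every islet follows the mantle-core rule exactly."""
    return _cohort(n_islets=120, adherence=1.0, t1d_fraction=0.5, seed=12)


@pytest.fixture(scope="session")
def mixed_cohort():
    return _cohort(n_islets=80, adherence=0.5, t1d_fraction=0.4, seed=13)
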