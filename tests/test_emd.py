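"""Earth mover's distance: histograms, 1D CDF construction, 2D LP, sweeps."""

import numpy as np
import pytest

import isletmc as m
from isletmc.emd import Histogram1D, Histogram2D, emd_lp, islet_beta_area


def hist1(mass, k=None):
    mass = np.asarray(mass, dtype=float)
    k = mass.size if k is None else k
    return Histogram1D(np.linspace(0, 1, k + 1), mass, n_samples=100)


def point_hist2(kx, ky, i, j):
    mass = np.zeros((kx, ky))
    mass[i, j] = 1.0
    return Histogram2D(np.linspace(0, 1, kx + 1), np.linspace(0, 1, ky + 1),
                       mass, n_samples=1)


def random_hist(rng, k):
    mass = rng.dirichlet(np.ones(k) * 0.5)
    return hist1(mass)


def lp_oracle_1d(source, target):
    """Exact LP optimal transport on the 1D ground metric (oracle path)."""
    centers = source.centers
    cost = np.abs(centers[:, None] - centers[None, :]) / (centers[-1] - centers[0])
    dist, _ = emd_lp(source.mass, target.mass, cost)
    return dist


class TestHistogram1D:
    def test_all_ones_land_in_last_bin(self):
        h = m.histogram_1d(np.ones(50), n_bins=10)
        assert h.mass[-1] == 1.0 and h.mass[:-1].sum() == 0.0

    def test_uniform_draws_spread_evenly(self):
        rng = np.random.default_rng(2)
        h = m.histogram_1d(rng.uniform(size=2000), n_bins=10)
        assert np.all(np.abs(h.mass - 0.1) < 5 * np.sqrt(0.1 * 0.9 / 2000))

    def test_metadata_and_validation(self):
        h = m.histogram_1d([0.2, 0.4, 0.9], n_bins=5)
        assert h.n_samples == 3
        with pytest.raises(ValueError):
            m.histogram_1d([], n_bins=5)
        with pytest.raises(ValueError):
            m.histogram_1d([1.5], n_bins=5)
        with pytest.raises(ValueError):
            m.histogram_1d([0.5], n_bins=1)


class TestEMD1D:
    def test_identical_histograms_zero(self):
        h = m.histogram_1d(np.linspace(0, 1, 37), 20)
        assert m.emd_1d(h, h).distance == 0.0

    def test_opposite_extremes_one(self):
        lo = hist1([1] + [0] * 19)
        hi = hist1([0] * 19 + [1])
        assert m.emd_1d(lo, hi).distance == 1.0

    @pytest.mark.parametrize("k", [2, 5, 20])
    def test_adjacent_bins_cost(self, k):
        a = hist1([1] + [0] * (k - 1))
        mass_b = np.zeros(k)
        mass_b[1] = 1.0
        assert m.emd_1d(a, hist1(mass_b)).distance == pytest.approx(1 / (k - 1))

    def test_mismatched_edges_raise(self):
        with pytest.raises(ValueError):
            m.emd_1d(hist1(np.ones(10) / 10), hist1(np.ones(12) / 12))

    def test_cdf_construction_matches_lp_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            k = int(rng.integers(3, 25))
            a, b = random_hist(rng, k), random_hist(rng, k)
            assert m.emd_1d(a, b).distance == pytest.approx(lp_oracle_1d(a, b), abs=1e-9)

    def test_plan_marginals_and_consistency(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a, b = random_hist(rng, 15), random_hist(rng, 15)
            res = m.emd_1d(a, b)
            np.testing.assert_allclose(res.transport_plan.sum(axis=1), a.mass, atol=1e-9)
            np.testing.assert_allclose(res.transport_plan.sum(axis=0), b.mass, atol=1e-9)
            assert np.all(res.transport_plan >= 0)

    def test_metric_axioms(self):
        rng = np.random.default_rng(14)
        for _ in range(15):
            a, b, c = (random_hist(rng, 12) for _ in range(3))
            dab = m.emd_1d(a, b).distance
            dba = m.emd_1d(b, a).distance
            dac = m.emd_1d(a, c).distance
            dcb = m.emd_1d(c, b).distance
            assert dab == pytest.approx(dba, abs=1e-9)
            assert dab >= 0
            assert dab <= dac + dcb + 1e-9
        a = random_hist(rng, 12)
        assert m.emd_1d(a, a).distance == 0.0


class TestEMD2D:
    def test_identical_zero(self):
        rng = np.random.default_rng(3)
        mass = rng.dirichlet(np.ones(25)).reshape(5, 5)
        h = Histogram2D(np.linspace(0, 1, 6), np.linspace(0, 1, 6), mass, 10)
        assert m.emd_2d(h, h).distance == 0.0

    def test_opposite_corners_cost_two(self):
        a = point_hist2(10, 10, 0, 0)
        b = point_hist2(10, 10, 9, 9)
        assert m.emd_2d(a, b).distance == pytest.approx(2.0, abs=1e-12)

    def test_full_x_range_costs_one(self):
        a = point_hist2(10, 10, 0, 3)
        b = point_hist2(10, 10, 9, 3)
        assert m.emd_2d(a, b).distance == pytest.approx(1.0, abs=1e-12)

    def test_l2_corner_is_sqrt2(self):
        a = point_hist2(8, 8, 0, 0)
        b = point_hist2(8, 8, 7, 7)
        assert m.emd_2d(a, b, metric="l2").distance == pytest.approx(np.sqrt(2), abs=1e-9)

    def test_mismatched_geometry_raises(self):
        with pytest.raises(ValueError):
            m.emd_2d(point_hist2(10, 10, 0, 0), point_hist2(8, 8, 0, 0))

    def test_plan_marginals(self):
        rng = np.random.default_rng(4)
        a_mass = rng.dirichlet(np.ones(16)).reshape(4, 4)
        b_mass = rng.dirichlet(np.ones(16)).reshape(4, 4)
        edges = np.linspace(0, 1, 5)
        res = m.emd_2d(Histogram2D(edges, edges, a_mass, 10),
                       Histogram2D(edges, edges, b_mass, 10))
        plan = res.transport_plan
        np.testing.assert_allclose(plan.sum(axis=1), a_mass.ravel(), atol=1e-9)
        np.testing.assert_allclose(plan.sum(axis=0), b_mass.ravel(), atol=1e-9)

    def test_metric_axioms_2d(self):
        rng = np.random.default_rng(6)
        edges = np.linspace(0, 1, 5)

        def h():
            return Histogram2D(edges, edges, rng.dirichlet(np.ones(16)).reshape(4, 4), 10)

        a, b, c = h(), h(), h()
        dab = m.emd_2d(a, b).distance
        assert dab == pytest.approx(m.emd_2d(b, a).distance, abs=1e-9)
        assert dab <= m.emd_2d(a, c).distance + m.emd_2d(c, b).distance + 1e-9


class TestRobustness1D:
    def test_self_comparison_near_zero(self):
        rng0 = np.random.default_rng(10)
        observed = rng0.uniform(size=400)

        def gen(rng):
            return observed[rng.integers(0, observed.size, observed.size)]

        resamples, sweep = m.robustness_1d(
            observed, gen, bin_counts=[8, 20, 40], n_resamples=30, seed=1
        )
        assert (resamples["emd"] < 2 / np.sqrt(observed.size)).all()
        assert len(sweep) == 3

    def test_deterministic_given_seed(self):
        observed = np.linspace(0, 1, 100)

        def gen(rng):
            return rng.uniform(size=100)

        r1, s1 = m.robustness_1d(observed, gen, bin_counts=[10], n_resamples=10, seed=3)
        r2, s2 = m.robustness_1d(observed, gen, bin_counts=[10], n_resamples=10, seed=3)
        assert r1.equals(r2) and s1.equals(s2)


class TestCohortHistograms:
    def test_masses_and_shared_geometry(self, mixed_cohort):
        ctrl, t1d = m.cohort_histograms(mixed_cohort, bins_per_axis=10)
        frame = islet_beta_area(mixed_cohort)
        assert ctrl.n_samples == (frame["disease_status"] == "control").sum()
        assert t1d.n_samples == (frame["disease_status"] == "t1d").sum()
        np.testing.assert_array_equal(ctrl.x_edges, t1d.x_edges)
        assert ctrl.area_scale == t1d.area_scale == frame["area_um2"].max()

    def test_all_beta_islets_mass_in_last_x_bin(self):
        from conftest import make_islet
        from isletmc.dataset import IsletCounts

        islets = []
        for k, status in enumerate(["control", "control", "t1d", "t1d"]):
            islet = make_islet(f"i{k}", side=40 + 5 * k, status=status)
            islet.counts = IsletCounts(N=10, NB=0, B=10, M=4, C=6, NB_m=0)
            islets.append(islet)
        ds = m.StudyDataset(islets=islets)
        ctrl, t1d = m.cohort_histograms(ds, bins_per_axis=5)
        for h in (ctrl, t1d):
            # beta fraction 1.0 falls in the right-closed last x bin
            assert h.mass[-1, :].sum() == pytest.approx(1.0)

    def test_missing_cohort_raises(self, null_cohort):
        only_control = m.StudyDataset(
            islets=[i for i in null_cohort.islets if i.disease_status == "control"],
            params=null_cohort.params,
        )
        with pytest.raises(ValueError, match="t1d"):
            m.cohort_histograms(only_control)


class TestRobustness2D:
    def _twin_dataset(self, cohort):
        """Control islets duplicated into a fake t1d cohort: identical stats."""
        twins = []
        for i in cohort.islets:
            if i.disease_status != "control":
                continue
            clone = m.IsletRecord(
                islet_id=i.islet_id + "-twin",
                case_id="t1d-clone",
                disease_status="t1d",
                boundary=i.boundary,
                area=i.area,
                centroid=i.centroid,
                cells=[],
            )
            clone.counts = i.counts
            twins.append(clone)
        keep = [i for i in cohort.islets if i.disease_status == "control"]
        return m.StudyDataset(islets=keep + twins, params=cohort.params)

    def test_identical_cohorts_give_zero_everywhere(self, null_cohort):
        ds = self._twin_dataset(null_cohort)
        resamples, sweep = m.robustness_2d(
            ds, bin_counts=[8, 12], n_resamples=5, seed=2
        )
        assert np.allclose(sweep["emd"], 0.0, atol=1e-12)
        assert len(sweep) == 2

    def test_default_bin_range_has_33_rows(self, mixed_cohort):
        _, sweep = m.robustness_2d(mixed_cohort, n_resamples=2, seed=3)
        assert len(sweep) == 33
        assert sweep["n_bins"].tolist() == list(range(8, 41))

    def test_resamples_reproducible(self, mixed_cohort):
        r1, _ = m.robustness_2d(mixed_cohort, bin_counts=[8], n_resamples=8, seed=5)
        r2, _ = m.robustness_2d(mixed_cohort, bin_counts=[8], n_resamples=8, seed=5)
        assert r1.equals(r2)
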