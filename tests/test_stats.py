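import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from rbcpop.stats import (
    CBCRecord,
    CellSample,
    SQRT2,
    SubjectSeries,
    _new_fraction,
    _old_fraction,
    compute_indices,
    new_cell_fraction,
    old_cell_fraction,
    paired_deltas,
    u_projection,
)


def gaussian_cells(rng, n=50_000, mcv=90.0, mch=30.0, sd_v=10.0, sd_h=3.0, corr=0.9):
    cov = np.array([[sd_v**2, corr * sd_v * sd_h], [corr * sd_v * sd_h, sd_h**2]])
    vh = rng.multivariate_normal([mcv, mch], cov, size=n)
    vh = np.clip(vh, 1.0, None)
    return CellSample(v=vh[:, 0], h=vh[:, 1], retic=np.zeros(n, bool))


class TestIndices:
    def test_two_cell_example(self):
        cells = CellSample(
            v=np.r_[np.full(60, 90.0), np.full(60, 110.0)],
            h=np.full(120, 30.0),
            retic=np.zeros(120, bool),
        )
        idx = compute_indices(cells)
        assert idx["MCV_fL"] == pytest.approx(100.0)
        assert idx["MCH_pg"] == pytest.approx(30.0)
        assert idx["MCHC_gdL"] == pytest.approx(30.0)

    def test_identical_cells_have_zero_widths(self):
        cells = CellSample(v=np.full(200, 88.0), h=np.full(200, 29.0),
                           retic=np.zeros(200, bool))
        idx = compute_indices(cells)
        assert idx["RDW_pct"] == pytest.approx(0.0, abs=1e-10)
        assert idx["CHDW_pct"] == pytest.approx(0.0, abs=1e-10)

    def test_mchc_identity(self, rng):
        cells = gaussian_cells(rng, n=5000)
        idx = compute_indices(cells)
        assert idx["MCHC_gdL"] * idx["MCV_fL"] == pytest.approx(100.0 * idx["MCH_pg"])

    def test_hgb_hct_from_concentration(self):
        cells = CellSample(v=np.full(200, 90.0), h=np.full(200, 30.0),
                           retic=np.zeros(200, bool))
        idx = compute_indices(cells, rbc_concentration=5.0)
        # 30 pg * 5e6 cells/uL = 150 g/L = 15 g/dL; 90 fL * 5e6/uL = 45%
        assert idx["HGB_gdL"] == pytest.approx(15.0)
        assert idx["HCT_pct"] == pytest.approx(45.0)
        # internal consistency: MCHC = 100 * HGB / HCT
        assert 100 * idx["HGB_gdL"] / idx["HCT_pct"] == pytest.approx(idx["MCHC_gdL"])

    def test_retic_indices_absent_when_unflagged(self, rng):
        cells = gaussian_cells(rng, n=1000)
        idx = compute_indices(cells)
        assert idx["rMCV_fL"] is None
        assert idx["rRDW_pct"] is None

    def test_generator_draw_matches_settings(self, baseline_draw):
        """A 50k-cell synthetic baseline draw lands in the normal ranges the
        fixture is calibrated to."""
        idx = baseline_draw.indices
        assert 80.0 <= idx["MCV_fL"] <= 100.0
        assert 30.0 <= idx["MCHC_gdL"] <= 36.0
        assert 11.0 <= idx["RDW_pct"] <= 15.0
        assert 0.5 <= idx["rFraction_pct"] <= 2.5


class TestUProjection:
    def test_mean_cell_maps_to_sqrt2(self, rng):
        cells = gaussian_cells(rng, n=2000)
        u = u_projection(cells)
        assert u.mean() == pytest.approx(SQRT2, rel=1e-12)

    def test_homogeneity(self, rng):
        """A cell at half the mean volume and hemoglobin has u = sqrt(2)/2."""
        v = np.full(200, 90.0)
        h = np.full(200, 30.0)
        v[0], h[0] = 45.0, 15.0
        v[1], h[1] = 135.0, 45.0  # keep means at (90, 30)
        cells = CellSample(v=v, h=h, retic=np.zeros(200, bool))
        u = u_projection(cells)
        assert u[0] == pytest.approx(SQRT2 * 45.0 / 90.0)

    @given(k=st.floats(0.1, 10.0))
    def test_scale_invariance(self, k):
        rng = np.random.default_rng(7)
        cells = gaussian_cells(rng, n=500)
        scaled = CellSample(v=cells.v * k, h=cells.h * k, retic=cells.retic)
        np.testing.assert_allclose(u_projection(scaled), u_projection(cells), rtol=1e-12)

    def test_permutation_invariance_of_statistics(self, rng):
        cells = gaussian_cells(rng, n=3000)
        perm = rng.permutation(len(cells))
        shuffled = CellSample(v=cells.v[perm], h=cells.h[perm], retic=cells.retic[perm])
        assert old_cell_fraction(shuffled) == old_cell_fraction(cells)
        assert new_cell_fraction(shuffled) == new_cell_fraction(cells)
        assert compute_indices(shuffled)["RDW_pct"] == pytest.approx(
            compute_indices(cells)["RDW_pct"])


class TestTailFractions:
    def test_gaussian_old_fraction_is_phi_minus_one(self, rng):
        """For Gaussian u the mass below median - sd is Phi(-1) ~ 0.1587."""
        u = rng.normal(10.0, 1.5, size=50_000)
        assert _old_fraction(u) == pytest.approx(norm.cdf(-1), abs=0.005)

    def test_independent_joint_tail_product(self, rng):
        """Independent (u, [Hb]): joint corner mass is Phi(-1) * (1 - Phi(1))."""
        u = rng.normal(10.0, 1.5, size=50_000)
        hb = rng.normal(33.0, 1.5, size=50_000)
        expected = norm.cdf(-1) * (1 - norm.cdf(1))
        assert _new_fraction(u, hb, mode="joint") == pytest.approx(expected, abs=0.004)

    def test_conditional_mode_rescales_by_high_u_mass(self, rng):
        u = rng.normal(10.0, 1.5, size=50_000)
        hb = rng.normal(33.0, 1.5, size=50_000)
        joint = _new_fraction(u, hb, mode="joint")
        cond = _new_fraction(u, hb, mode="conditional")
        high = np.mean(u > np.median(u) + np.std(u))
        assert cond == pytest.approx(joint / high, rel=1e-9)

    def test_complementarity(self, rng):
        u = rng.normal(0.0, 1.0, size=20_000)
        f = _old_fraction(u)
        cut = np.median(u) - np.std(u)
        assert f + np.mean(u >= cut) == pytest.approx(1.0)

    def test_mass_at_median_does_not_qualify(self):
        u = np.r_[np.full(600, 5.0), np.full(200, 4.0), np.full(200, 6.0)]
        base = _old_fraction(u)
        u2 = np.r_[u, np.full(100, 5.0)]  # add mass exactly at the median
        assert _old_fraction(u2) <= base

    def test_no_high_u_subset_gives_zero(self):
        u = np.full(2000, 3.0)
        hb = np.full(2000, 33.0)
        with pytest.warns(UserWarning):
            assert _new_fraction(u, hb) == 0.0

    @given(k=st.floats(0.2, 5.0))
    def test_fractions_scale_invariant(self, k):
        rng = np.random.default_rng(3)
        cells = gaussian_cells(rng, n=2000)
        scaled = CellSample(v=cells.v * k, h=cells.h * k, retic=cells.retic)
        assert old_cell_fraction(scaled) == pytest.approx(old_cell_fraction(cells))
        assert new_cell_fraction(scaled) == pytest.approx(new_cell_fraction(cells))

    def test_minimum_cells_enforced(self, rng):
        cells = gaussian_cells(rng, n=500)
        with pytest.raises(ValueError):
            old_cell_fraction(cells)


class TestPairedDeltas:
    def _series(self, rng, perturb=0.0):
        recs = []
        for t in (1.0, 3.0, 5.0, 7.0, 9.5, 29.0):
            cells = gaussian_cells(np.random.default_rng(42), n=5000)
            if perturb and t > 8.0:
                cells = CellSample(v=cells.v, h=cells.h * (1 + perturb), retic=cells.retic)
            recs.append(CBCRecord(time=t, cells=cells))
        return SubjectSeries(subject_id="T", records=recs, loss_time=8.0)

    def test_identical_draws_give_zero_deltas(self, rng):
        d = paired_deltas(self._series(rng))
        for label in ("early", "late"):
            for k, v in d[label].items():
                assert v == pytest.approx(0.0, abs=1e-12)

    def test_perturbed_post_draws_register(self, rng):
        d = paired_deltas(self._series(rng, perturb=0.02))
        assert d["early"]["MCHC_gdL"] > 0
        assert d["late"]["MCHC_gdL"] > 0

    def test_missing_late_class_reports_none(self, rng):
        recs = [CBCRecord(time=t, cells=gaussian_cells(np.random.default_rng(1), 5000))
                for t in (1.0, 3.0, 9.0)]
        series = SubjectSeries(subject_id="T", records=recs, loss_time=8.0)
        d = paired_deltas(series)
        assert d["late"]["MCHC_gdL"] is None
        assert d["early"]["MCHC_gdL"] is not None

    def test_requires_loss_time(self, rng):
        s = self._series(rng)
        s.loss_time = None
        with pytest.raises(ValueError):
            paired_deltas(s)
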