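"""Vessel density Q, vessel size index and vortex-loop MTI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from vaimri.metrics import (
    mti_loop_area,
    vessel_density_q,
    vessel_size_index,
    voxelwise_vai,
)
from vaimri.relaxometry import FirstPassWindow


class TestVesselDensityQ:
    def test_identity_window_means(self):
        x = np.ones(13)
        assert vessel_density_q(x, x, "ratio_of_means") == pytest.approx(1.0)

    def test_ratio_of_means_closed_form(self):
        dr2 = np.full(13, 2.0)
        dr2s = np.full(13, 8.0)
        # 2 / 8^(2/3) = 2/4
        assert vessel_density_q(dr2, dr2s, "ratio_of_means") == pytest.approx(0.5)

    @pytest.mark.parametrize("estimator", ["slope", "ratio_of_means", "pointwise"])
    def test_constant_window_power_law(self, estimator):
        dr2s = np.full(13, 5.0)
        dr2 = 0.39 * dr2s ** (2.0 / 3.0)
        assert vessel_density_q(dr2, dr2s, estimator) == pytest.approx(0.39)

    @pytest.mark.parametrize("estimator", ["slope", "pointwise"])
    def test_exact_on_varying_power_law(self, estimator):
        """Slope and pointwise estimators invert the power law exactly."""
        dr2s = np.linspace(0.5, 10.0, 13)
        dr2 = 0.39 * dr2s ** (2.0 / 3.0)
        assert vessel_density_q(dr2, dr2s, estimator) == pytest.approx(0.39)

    def test_ratio_of_means_within_5pct_for_factor2_variation(self):
        """The window-mean estimator stays within 5% when dR2* varies by
        at most a factor of 2 over the window."""
        dr2s = np.linspace(5.0, 10.0, 13)
        dr2 = 0.39 * dr2s ** (2.0 / 3.0)
        q = vessel_density_q(dr2, dr2s, "ratio_of_means")
        assert q == pytest.approx(0.39, rel=0.05)

    def test_nonpositive_mean_invalid(self):
        assert np.isnan(
            vessel_density_q(np.ones(13), -np.ones(13), "ratio_of_means")
        )
        assert np.isnan(
            vessel_density_q(-np.ones(13), np.ones(13), "ratio_of_means")
        )

    def test_missing_values_invalid(self):
        x = np.ones(13)
        y = x.copy()
        y[4] = np.nan
        assert np.isnan(vessel_density_q(y, x))

    def test_unknown_estimator(self):
        with pytest.raises(ValueError):
            vessel_density_q(np.ones(13), np.ones(13), "median")


class TestVesselSizeIndex:
    def test_formula_constant(self):
        assert vessel_size_index(1.0, 1.0, 1.0) == pytest.approx(0.867)

    def test_worked_example(self):
        # D = 800 um^2/s, rCBV = 3.2%, Q = 0.39 -> ~18 um
        vsi = vessel_size_index(800.0, 0.032, 0.39)
        assert vsi == pytest.approx(18.0, abs=0.05)

    def test_q_power_law(self):
        base = vessel_size_index(800.0, 0.032, 0.39)
        assert vessel_size_index(800.0, 0.032, 4 * 0.39) == pytest.approx(
            base / 8.0
        )

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(
        st.floats(min_value=0.1, max_value=10.0),
        st.floats(min_value=100.0, max_value=3000.0),
        st.floats(min_value=0.005, max_value=0.2),
        st.floats(min_value=0.1, max_value=1.0),
    )
    def test_diffusion_scaling(self, c, d, rcbv, q):
        """VSI(c^2 D, rCBV, Q) = c * VSI(D, rCBV, Q) exactly."""
        assert vessel_size_index(c**2 * d, rcbv, q) == pytest.approx(
            c * vessel_size_index(d, rcbv, q), rel=1e-12
        )

    def test_nonpositive_inputs_invalid(self):
        assert np.isnan(vessel_size_index(-1.0, 0.03, 0.4))
        assert np.isnan(vessel_size_index(800.0, 0.0, 0.4))
        assert np.isnan(vessel_size_index(800.0, 0.03, -0.4))


SQUARE_X = np.array([0.0, 0.0, 1.0, 1.0])
SQUARE_Y = np.array([0.0, 1.0, 1.0, 0.0])


class TestMTI:
    def test_clockwise_unit_square_positive(self):
        assert mti_loop_area(SQUARE_X, SQUARE_Y) == pytest.approx(1.0)

    def test_reversal_negates(self):
        assert mti_loop_area(SQUARE_X[::-1], SQUARE_Y[::-1]) == pytest.approx(
            -1.0
        )

    def test_collinear_zero(self):
        x = np.linspace(0, 1, 13)
        assert mti_loop_area(x, 2 * x) == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_three_points_invalid(self):
        assert np.isnan(mti_loop_area(np.ones(2), np.ones(2)))

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(
        hnp.arrays(float, 13, elements=st.floats(-5, 5)),
        hnp.arrays(float, 13, elements=st.floats(-5, 5)),
        st.integers(1, 12),
    )
    def test_cyclic_invariance_and_antisymmetry(self, x, y, shift):
        a = mti_loop_area(x, y)
        assert mti_loop_area(np.roll(x, shift), np.roll(y, shift)) == (
            pytest.approx(a, abs=1e-9)
        )
        assert mti_loop_area(x[::-1], y[::-1]) == pytest.approx(-a, abs=1e-9)


class TestVoxelwise:
    def test_matches_scalar_ops(self):
        rng = np.random.default_rng(0)
        n_t = 13
        dr2s = rng.uniform(1, 10, size=(2, 1, 1, n_t))
        dr2 = 0.4 * dr2s ** (2 / 3)
        w = FirstPassWindow(peak_index=5, start=0, end=12, clamped=False)
        d = np.full((2, 1, 1), 800.0)
        rcbv = np.full((2, 1, 1), 0.032)
        maps = voxelwise_vai(dr2s, dr2, w, d, rcbv)
        for i in range(2):
            assert maps.q[i, 0, 0] == pytest.approx(
                0.4, rel=1e-9
            )
            assert maps.mti[i, 0, 0] == pytest.approx(
                mti_loop_area(dr2[i, 0, 0], dr2s[i, 0, 0])
            )
            assert maps.vsi[i, 0, 0] == pytest.approx(
                vessel_size_index(800.0, 0.032, maps.q[i, 0, 0])
            )

    def test_all_invalid_warns(self):
        w = FirstPassWindow(peak_index=2, start=0, end=4, clamped=False)
        dr2s = np.full((1, 1, 1, 5), np.nan)
        with pytest.warns(UserWarning, match="invalid"):
            maps = voxelwise_vai(
                dr2s, dr2s, w, np.ones((1, 1, 1)), np.ones((1, 1, 1))
            )
        assert not maps.validity.any()

    def test_grid_mismatch_reports_shapes(self):
        w = FirstPassWindow(peak_index=2, start=0, end=4, clamped=False)
        with pytest.raises(ValueError, match="mismatch"):
            voxelwise_vai(
                np.ones((2, 1, 1, 5)),
                np.ones((2, 1, 1, 5)),
                w,
                np.ones((3, 1, 1)),
                np.ones((2, 1, 1)),
            )

    def test_curve_averaging_matches_voxelwise_on_homogeneous_roi(self):
        from vaimri.metrics import roi_vai_from_curves

        rng = np.random.default_rng(5)
        base = rng.uniform(1, 10, size=13)
        dr2s = np.tile(base, (4, 1, 1, 1))
        dr2 = 0.4 * dr2s ** (2 / 3)
        w = FirstPassWindow(peak_index=5, start=0, end=12, clamped=False)
        mask = np.ones((4, 1, 1), bool)
        roi = roi_vai_from_curves(dr2s, dr2, w, mask, 800.0, 0.032)
        maps = voxelwise_vai(
            dr2s, dr2, w, np.full((4, 1, 1), 800.0), np.full((4, 1, 1), 0.032)
        )
        assert roi["Q"] == pytest.approx(np.nanmean(maps.q), rel=1e-12)
        assert roi["MTI"] == pytest.approx(np.nanmean(maps.mti), rel=1e-12)

    def test_noise_free_phantom_recovery(self, default_phantom):
        """Forward-model inversion: every perfused voxel recovers its
        ground-truth Q within 2%."""
        import vaimri as v

        ds = default_phantom
        s0, vg = v.estimate_baseline(ds.ge)
        dr2s = v.delta_r2_series(ds.ge, s0, vg)
        s0s, vs = v.estimate_baseline(ds.se)
        dr2 = v.delta_r2_series(ds.se, s0s, vs)
        nawm = ds.roi_set["NAWM"]
        curve = np.nanmean(dr2s[nawm], axis=0)
        peak = v.find_bolus_peak(curve, 8)
        w = v.first_pass_window(peak, ds.ge.params.n_dynamics)
        maps = voxelwise_vai(
            dr2s, dr2, w, ds.truth["d"] * 1e6, ds.truth["rcbv"]
        )
        perfused = np.isfinite(ds.truth["q"]) & (ds.truth["rcbv"] > 0)
        ratio = maps.q[perfused] / ds.truth["q"][perfused]
        assert np.all(np.abs(ratio - 1) < 0.02)
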