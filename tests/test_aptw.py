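"""B0 correction of APTw spectra and MTR-asymmetry quantification."""

import numpy as np
import pytest
from scipy.interpolate import CubicSpline

import cestpipe as cp
from cestpipe.errors import ConfigError, DataError
from cestpipe.io import PipelineConfig
from cestpipe.wassr import B0Map


class TestNormalize:
    def test_no_saturation_gives_unity(self):
        grid = cp.make_offset_grid(-2, 2, 1.0)
        s0 = np.full((3, 3), 2.0)
        stack = cp.ZSpectrumStack(
            np.broadcast_to(s0[..., None], (3, 3, 5)).copy(), s0, grid
        )
        z, usable = cp.normalize(stack)
        assert usable.all()
        np.testing.assert_allclose(z, 1.0)

    def test_zero_signal(self):
        grid = cp.make_offset_grid(-2, 2, 1.0)
        stack = cp.ZSpectrumStack(np.zeros((3, 3, 5)), np.ones((3, 3)), grid)
        z, _ = cp.normalize(stack)
        np.testing.assert_allclose(z, 0.0)

    def test_nonpositive_s0_marked_not_raised(self):
        grid = cp.make_offset_grid(-2, 2, 1.0)
        s0 = np.ones((3, 3))
        s0[1, 1] = 0.0
        stack = cp.ZSpectrumStack(np.ones((3, 3, 5)) * 0.5, s0, grid)
        z, usable = cp.normalize(stack)
        assert not usable[1, 1]
        assert np.isnan(z[1, 1]).all()
        assert usable.sum() == 8


class TestCorrectVoxel:
    def test_zero_shift_is_identity(self):
        grid = cp.aptw_grid()
        pools = [cp.PoolSpec(0.0, 0.8, 1.6), cp.PoolSpec(3.5, 0.03, 1.0)]
        z = cp.zspectrum_model(grid, pools)
        corrected, available = cp.correct_voxel(grid, z, 0.0)
        assert available.all()
        np.testing.assert_allclose(corrected, z, atol=1e-6)

    def test_correction_recentres_water(self):
        # voxel with true shift 0.2 ppm: after correction the spectrum
        # minimum (located by refitting) returns to 0 within resolution
        shift = 0.2
        grid = cp.wassr_grid()
        z = cp.zspectrum_model(grid, [cp.PoolSpec(0.0, 0.5, 0.5)], shift)
        corrected, available = cp.correct_voxel(grid, z, shift)
        sub = cp.OffsetGrid(grid.offsets_ppm[available])
        fit = cp.fit_wassr_voxel(sub, corrected[available], order=10)
        assert abs(fit.shift_ppm) <= 0.0150001  # fine step + edge loss

    def test_out_of_range_samples_unavailable(self):
        grid = cp.aptw_grid()
        z = cp.zspectrum_model(grid, [cp.PoolSpec(0.0, 0.8, 1.6)], 0.5)
        corrected, available = cp.correct_voxel(grid, z, 0.5)
        assert not available[-1]  # +6 ppm needs a sample at +6.5
        assert np.isnan(corrected[-1])
        assert available[grid.index_of(3.5)]  # analysis offsets still fine

    def test_non_finite_shift_rejected(self):
        grid = cp.aptw_grid()
        with pytest.raises(DataError):
            cp.correct_voxel(grid, np.ones(len(grid)), np.nan)

    def test_spline_and_nearest_fine_agree(self):
        grid = cp.aptw_grid()
        z = cp.zspectrum_model(
            grid, [cp.PoolSpec(0.0, 0.8, 1.6), cp.PoolSpec(3.5, 0.03, 1.0)],
            0.17,
        )
        c1, _ = cp.correct_voxel(grid, z, 0.17, method="nearest-fine")
        c2, _ = cp.correct_voxel(grid, z, 0.17, method="spline")
        sel = np.isfinite(c1) & np.isfinite(c2)
        assert np.max(np.abs(c1[sel] - c2[sel])) < 1e-3


class TestMTRAsym:
    def test_symmetric_zero(self):
        grid = cp.make_offset_grid(-4, 4, 0.5)
        z = np.ones(len(grid)) * 0.7
        assert cp.mtr_asym(z, grid, 3.5) == pytest.approx(0.0)

    def test_arithmetic_identity(self):
        grid = cp.make_offset_grid(-4, 4, 0.5)
        z = np.ones(len(grid))
        z[grid.index_of(-3.5)] = 0.60
        z[grid.index_of(3.5)] = 0.55
        assert cp.mtr_asym(z, grid, 3.5) == pytest.approx(5.0)

    def test_antisymmetry_in_evaluation_offset(self):
        grid = cp.make_offset_grid(-4, 4, 0.5)
        rng = np.random.default_rng(0)
        z = rng.uniform(0.3, 1.0, len(grid))
        assert cp.mtr_asym(z, grid, -3.5) == pytest.approx(
            -cp.mtr_asym(z, grid, 3.5)
        )

    def test_offset_not_on_grid(self):
        grid = cp.make_offset_grid(-4, 4, 0.5)
        with pytest.raises(ConfigError):
            cp.mtr_asym(np.ones(len(grid)), grid, 3.3)


class TestAPTwMap:
    def test_oracle_equivalence_noiseless(self, clean_phantom):
        _, aptw_stack, wassr_stack, truth = clean_phantom
        brain = truth.roi_masks["brain"]
        b0 = cp.b0_map(wassr_stack, brain)
        amap = cp.aptw_map(aptw_stack, b0, brain)
        assert amap.valid[brain].all()
        err = np.abs(amap.aptw_percent - truth.true_aptw_map)[amap.valid]
        assert err.max() <= 0.05

    def test_correction_beats_no_correction(self, shifted_phantom):
        _, aptw_stack, wassr_stack, truth = shifted_phantom
        brain = truth.roi_masks["brain"]
        b0 = cp.b0_map(wassr_stack, brain)
        corrected = cp.aptw_map(aptw_stack, b0, brain)
        uncorrected = cp.aptw_map(
            aptw_stack, b0, brain, apply_correction=False
        )
        e_c = (corrected.aptw_percent - truth.true_aptw_map)[corrected.valid]
        e_u = (uncorrected.aptw_percent - truth.true_aptw_map)[
            uncorrected.valid
        ]
        assert np.sqrt(np.mean(e_c**2)) < np.sqrt(np.mean(e_u**2))
        assert np.max(np.abs(e_c)) < np.max(np.abs(e_u))

    def test_corrected_error_within_interpolation_bound(self, shifted_phantom):
        # residual error after correction is explained by cubic-spline
        # resampling of the 0.5-ppm-sampled spectrum: derive the worst-case
        # bound directly from the closed-form model over the shift range
        # (+/- shift-estimate and fine-grid slack), then require the
        # pipeline not to exceed it
        spec, aptw_stack, wassr_stack, truth = shifted_phantom
        brain = truth.roi_masks["brain"]
        b0 = cp.b0_map(wassr_stack, brain)
        amap = cp.aptw_map(aptw_stack, b0, brain)
        err = np.abs(amap.aptw_percent - truth.true_aptw_map)[amap.valid]

        x = aptw_stack.grid.offsets_ppm
        bound = 0.0
        for pools in (
            spec.tissues()["hippocampus"].pools,
            spec.tissues()["cortex"].pools,
        ):
            true_val = cp.true_mtr_asym(pools, 3.5)
            for d in np.linspace(-0.3, 0.3, 121):
                z = cp.zspectrum_model(x, pools, b0_shift=d)
                s = CubicSpline(x, z, bc_type="natural")
                for slack in (-0.015, 0.0, 0.015):
                    v = 100 * (s(-3.5 + d + slack) - s(3.5 + d + slack))
                    bound = max(bound, abs(v - true_val))
        assert err.max() <= bound + 1e-6

    def test_amide_amplitude_monotonically_raises_aptw(self):
        grid = cp.aptw_grid()
        water = cp.PoolSpec(0.0, 0.8, 1.6)
        noe = cp.PoolSpec(-3.5, 0.05, 3.0)
        values = []
        for a in (0.0, 0.01, 0.03, 0.05, 0.08):
            pools = [water, noe, cp.PoolSpec(3.5, a, 1.0)] if a else [water, noe]
            values.append(cp.true_mtr_asym(pools, 3.5))
        assert np.all(np.diff(values) > 0)

    def test_invalid_b0_propagates(self, clean_phantom):
        _, aptw_stack, wassr_stack, truth = clean_phantom
        brain = truth.roi_masks["brain"]
        b0 = cp.b0_map(wassr_stack, brain)
        b0.valid[16, 16] = False
        amap = cp.aptw_map(aptw_stack, b0, brain)
        assert not amap.valid[16, 16]

    def test_analysis_offset_must_be_on_grid(self, clean_phantom):
        _, aptw_stack, wassr_stack, truth = clean_phantom
        brain = truth.roi_masks["brain"]
        b0 = cp.b0_map(wassr_stack, brain)
        with pytest.raises(ConfigError):
            cp.aptw_map(
                aptw_stack, b0, brain,
                PipelineConfig(analysis_offset_ppm=3.3),
            )


class TestMTRAsymCurve:
    def test_curve_at_analysis_offset_matches_map(self, clean_phantom):
        _, aptw_stack, wassr_stack, truth = clean_phantom
        roi = truth.roi_masks["left_hippocampus"]
        b0 = cp.b0_map(wassr_stack, truth.roi_masks["brain"])
        curve = cp.mean_mtr_asym_curve(aptw_stack, b0, roi)
        amap = cp.aptw_map(aptw_stack, b0, roi)
        i = int(np.flatnonzero(np.isclose(curve.offsets_ppm, 3.5))[0])
        assert curve.mean_percent[i] == pytest.approx(
            amap.values(roi).mean(), abs=1e-9
        )
        assert set(curve.offsets_ppm) <= set(
            x for x in aptw_stack.grid.offsets_ppm if x > 0
        )

    def test_empty_roi_rejected(self, clean_phantom):
        _, aptw_stack, wassr_stack, truth = clean_phantom
        b0 = cp.b0_map(wassr_stack, truth.roi_masks["brain"])
        outside = np.zeros(aptw_stack.shape, bool)
        outside[0, 0] = True  # background corner: S0 tiny but positive, B0 invalid
        with pytest.raises(DataError):
            cp.mean_mtr_asym_curve(aptw_stack, b0, outside)
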