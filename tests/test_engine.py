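"""Synthetic dose engine: closed form vs. numeric oracle, monotonicity, noise."""

import numpy as np
import pytest

from smallfield import (
    DEFAULT_GEOMETRY,
    DEFAULT_KERNEL,
    BeamGeometry,
    ESSPair,
    FieldSpec,
    NoiseModel,
    ScatterKernel,
    add_measurement_noise,
    central_dose,
    fit_kernel,
    penumbra_20_80,
    simulate_fof_grid,
    simulate_profile,
)
from smallfield.engine import FWHM_PER_SIGMA


def single_kernel(sigma_mm):
    return ScatterKernel(((1.0, sigma_mm, sigma_mm),))


class TestCentralDose:
    def test_saturates_at_weight_sum_for_large_fields(self):
        # every side/(2*sqrt(2)*s) > 2 => both erf factors ~ 1
        kernel = ScatterKernel(((0.9, 1.5, 1.5), (0.1, 6.0, 6.0)))
        dose = central_dose(FieldSpec(4.0, 4.0), ESSPair(1.5, 1.5), kernel)
        assert dose == pytest.approx(1.0, rel=0.01)

    def test_single_component_square_field_closed_form(self, dose_oracle):
        # effective sigma 2 mm from ess sqrt(2^2 - 1^2)... keep it direct:
        # source 0, kernel sigma 2 mm, square side 5 mm
        kernel = single_kernel(2.0)
        field = FieldSpec(0.5, 0.5)
        dose = central_dose(field, ESSPair(0, 0), kernel)
        assert dose == pytest.approx(0.622048404036, rel=1e-9)
        assert dose == pytest.approx(
            dose_oracle(field, ESSPair(0, 0), kernel, DEFAULT_GEOMETRY), rel=1e-3
        )

    def test_no_blur_transmits_everything(self):
        delta_like = single_kernel(0.01)
        for side in (0.05, 0.5, 2.0):
            assert central_dose(FieldSpec(side, side), ESSPair(0, 0), delta_like) == pytest.approx(
                1.0, abs=1e-6
            )

    def test_fwhm_interpretation_rescales_sigma(self):
        field = FieldSpec(0.5, 0.5)
        as_fwhm = central_dose(field, ESSPair(1.2, 1.2, "fwhm"), DEFAULT_KERNEL)
        as_sigma = central_dose(
            field, ESSPair(1.2 / FWHM_PER_SIGMA, 1.2 / FWHM_PER_SIGMA), DEFAULT_KERNEL
        )
        assert as_fwhm == pytest.approx(as_sigma, rel=1e-12)

    def test_matches_numeric_convolution_on_random_parameters(self, dose_oracle):
        rng = np.random.default_rng(21)
        for _ in range(5):
            field = FieldSpec(rng.uniform(0.5, 2.5), rng.uniform(0.5, 2.5))
            ess = ESSPair(rng.uniform(0, 1.5), rng.uniform(0, 1.5))
            n = int(rng.integers(1, 3))
            w = rng.uniform(0.2, 1.0, n)
            w /= w.sum()
            sig = rng.uniform(0.8, 6.0, (n, 2))
            kernel = ScatterKernel(tuple((wi, s[0], s[1]) for wi, s in zip(w, sig)))
            closed = central_dose(field, ess, kernel, DEFAULT_GEOMETRY)
            numeric = dose_oracle(field, ess, kernel, DEFAULT_GEOMETRY)
            assert closed == pytest.approx(numeric, rel=1e-3)

    def test_monotone_in_sides_and_in_ess(self):
        for side in (0.5, 0.7, 1.0):
            d0 = central_dose(FieldSpec(side, side), ESSPair(0.4, 0.4))
            assert central_dose(FieldSpec(side + 0.1, side), ESSPair(0.4, 0.4)) > d0
            assert central_dose(FieldSpec(side, side + 0.1), ESSPair(0.4, 0.4)) > d0
            assert central_dose(FieldSpec(side, side), ESSPair(0.6, 0.4)) < d0
            assert central_dose(FieldSpec(side, side), ESSPair(0.4, 0.6)) < d0

    def test_projection_factor_follows_geometry(self):
        close_mlc = BeamGeometry(sad_mm=1000.0, collimator_distance_mm=400.0)
        assert close_mlc.projection_factor == pytest.approx(1.5)
        # stronger projection blurs more -> lower small-field dose
        d_default = central_dose(FieldSpec(0.5, 0.5), ESSPair(1.0, 1.0), DEFAULT_KERNEL)
        d_close = central_dose(FieldSpec(0.5, 0.5), ESSPair(1.0, 1.0), DEFAULT_KERNEL, close_mlc)
        assert d_close < d_default


class TestFofGrid:
    def test_msr_cell_exactly_one_and_deterministic(self):
        g1 = simulate_fof_grid(ESSPair(0.7, 0.7))
        g2 = simulate_fof_grid(ESSPair(0.7, 0.7))
        assert g1.cell(4.0, 4.0) == 1.0
        assert np.array_equal(g1.values, g2.values)

    def test_nondecreasing_along_each_axis(self):
        g = simulate_fof_grid(ESSPair(0.7, 0.7))
        assert (np.diff(g.values, axis=0) >= 0).all()
        assert (np.diff(g.values, axis=1) >= 0).all()

    def test_larger_essx_lowers_narrow_x_field(self):
        cells = [
            simulate_fof_grid(ESSPair(essx, 0.7)).cell(4.0, 0.5)
            for essx in (0.0, 0.5, 1.0, 1.5)
        ]
        assert all(b < a for a, b in zip(cells, cells[1:]))

    def test_zero_ess_majorizes_large_ess(self):
        # raw central doses majorize strictly; FOF ratios inherit this up to
        # the msr normalization (whose dose also drops with ESS), so the grid
        # comparison carries a small tolerance
        for y in (0.5, 1.0, 2.0, 4.0):
            for x in (0.5, 1.0, 2.0, 4.0):
                f = FieldSpec(y, x)
                assert central_dose(f, ESSPair(0, 0)) > central_dose(f, ESSPair(1.5, 1.5))
        g0 = simulate_fof_grid(ESSPair(0, 0))
        g1 = simulate_fof_grid(ESSPair(1.5, 1.5))
        assert (g0.values >= g1.values - 2e-4).all()


class TestProfiles:
    def test_symmetric_by_construction(self):
        p = simulate_profile(FieldSpec(0.5, 2.0), "X", ESSPair(0.7, 0.7))
        assert np.allclose(p.values, p.values[::-1], atol=1e-12)

    def test_penumbra_grows_with_matching_ess(self):
        widths = []
        for essx in (0.0, 0.5, 1.0, 1.5):
            p = simulate_profile(FieldSpec(2.0, 2.0), "X", ESSPair(essx, 0.7))
            widths.append(np.mean(penumbra_20_80(p)))
        assert all(b > a for a, b in zip(widths, widths[1:]))

    def test_detector_averaging_broadens_penumbra(self):
        sharp = simulate_profile(FieldSpec(1.0, 1.0), "X", ESSPair(0.7, 0.7))
        averaged = simulate_profile(
            FieldSpec(1.0, 1.0), "X", ESSPair(0.7, 0.7), detector_diameter_mm=2.2
        )
        assert np.mean(penumbra_20_80(averaged)) >= np.mean(penumbra_20_80(sharp))

    def test_integral_matches_closed_form(self):
        # each component's lateral shape integrates exactly to the field width
        field = FieldSpec(1.0, 2.0)
        ess = ESSPair(0.7, 0.7)
        for axis, w_along, w_orth in (("X", 20.0, 10.0), ("Y", 10.0, 20.0)):
            p = simulate_profile(field, axis, ess, sampling_mm=0.1)
            numeric = np.trapezoid(p.values, p.positions_mm)
            from smallfield.engine import _axis_factor
            import math

            expected = 0.0
            for wk, kx, ky in DEFAULT_KERNEL.components:
                s_orth = math.hypot(
                    ess.sigma_y_mm if axis == "X" else ess.sigma_x_mm,
                    ky if axis == "X" else kx,
                )
                expected += wk * _axis_factor(w_orth, s_orth) * w_along
            assert numeric == pytest.approx(expected, rel=5e-3)

    def test_bad_sampling_rejected(self):
        with pytest.raises(ValueError, match="sampling"):
            simulate_profile(FieldSpec(1, 1), "X", ESSPair(0, 0), sampling_mm=0.0)


class TestNoise:
    def test_zero_sd_leaves_grid_unchanged(self):
        calc = simulate_fof_grid(ESSPair(0.7, 0.7))
        noisy = add_measurement_noise(calc, NoiseModel(0.0, 0.0, seed=3))
        assert np.array_equal(noisy.values, calc.values)
        assert noisy.kind == "measured"

    def test_same_seed_reproduces_same_grid(self):
        calc = simulate_fof_grid(ESSPair(0.7, 0.7))
        a = add_measurement_noise(calc, NoiseModel(seed=42))
        b = add_measurement_noise(calc, NoiseModel(seed=42))
        c = add_measurement_noise(calc, NoiseModel(seed=43))
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_msr_cell_never_perturbed(self):
        calc = simulate_fof_grid(ESSPair(0.7, 0.7))
        noisy = add_measurement_noise(calc, NoiseModel(seed=9))
        assert noisy.cell(4.0, 4.0) == 1.0

    def test_empirical_sd_matches_model(self):
        calc = simulate_fof_grid(ESSPair(0.7, 0.7))
        small, large = [], []
        for seed in range(1000):
            noisy = add_measurement_noise(calc, NoiseModel(seed=seed))
            small.append(noisy.cell(0.5, 4.0) / calc.cell(0.5, 4.0) - 1)
            large.append(noisy.cell(2.0, 2.0) / calc.cell(2.0, 2.0) - 1)
        # SE of an SD estimate ~ sd / sqrt(2(n-1)); allow 3 SE
        se_small = 1.8 / np.sqrt(2 * 999)
        se_large = 0.9 / np.sqrt(2 * 999)
        assert 100 * np.std(small, ddof=1) == pytest.approx(1.8, abs=3 * se_small)
        assert 100 * np.std(large, ddof=1) == pytest.approx(0.9, abs=3 * se_large)


class TestKernelFit:
    def test_recovers_two_component_kernel_grid(self):
        truth = ScatterKernel(((0.85, 1.8, 1.8), (0.15, 14.0, 14.0)))
        ess = ESSPair(0.7, 0.7)
        target = simulate_fof_grid(ess, truth)
        fitted, rms = fit_kernel(target, ess, n_components=2)
        refit = simulate_fof_grid(ess, fitted)
        assert np.abs(refit.values - target.values).max() < 1e-4
        assert rms < 1e-4

    def test_underparameterized_fit_reports_residual(self):
        truth = ScatterKernel(((0.75, 1.2, 1.2), (0.25, 16.0, 16.0)))
        target = simulate_fof_grid(ESSPair(0.7, 0.7), truth)
        _, rms = fit_kernel(target, ESSPair(0.7, 0.7), n_components=1)
        assert rms > 1e-3  # structure a single Gaussian cannot represent
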