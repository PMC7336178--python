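"""Fitting and dose: profile arithmetic, power-law recovery, dose model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scansaxs import RegionClass, ScanGrid, default_geometry, make_phantom, simulate_scan
from scansaxs.fitmodel import (
    DEFAULT_FIT_QRANGE,
    DoseParams,
    dose,
    fit_power_law,
    fit_region_profile,
    normalize_exposure,
    row_matched_background,
    subtract_background,
)
from scansaxs.reduce import RadialProfile, azimuthal_integrate, darkfield
from scansaxs.segment import segment_darkfield
from scansaxs.simulate import ExpectationEngine, phantom_from_cells
from scansaxs.population import reduced_scale_config


def _profile(q, intensity, n_pixels=None):
    q = np.asarray(q, dtype=float)
    if n_pixels is None:
        n_pixels = np.full(q.size, 100, dtype=int)
    return RadialProfile(q_centers=q, intensity=np.asarray(intensity, float),
                         n_pixels=np.asarray(n_pixels))


def _model_profile(K, alpha, B, n=150, q_range=DEFAULT_FIT_QRANGE):
    q = np.linspace(q_range[0], q_range[1], n)
    return _profile(q, K * q**alpha + B)


class TestProfileArithmetic:
    def test_unit_exposure_is_identity(self):
        prof = _model_profile(2.0, -3.0, 0.1)
        out = normalize_exposure(prof, 1.0)
        np.testing.assert_array_equal(out.intensity, prof.intensity)

    def test_exposure_scaling_linear(self):
        prof = _model_profile(2.0, -3.0, 0.1)
        np.testing.assert_allclose(
            normalize_exposure(prof, 2.0).intensity, prof.intensity / 2.0
        )

    def test_nonpositive_exposure_rejected(self):
        with pytest.raises(ValueError):
            normalize_exposure(_model_profile(1, -4, 0), 0.0)

    def test_subtracting_profile_from_itself_is_zero(self):
        prof = _model_profile(2.0, -3.0, 0.1)
        assert (subtract_background(prof, prof).intensity == 0).all()

    def test_constant_difference(self):
        q = np.linspace(0.2, 1.7, 40)
        out = subtract_background(_profile(q, np.full(40, 5.0)),
                                  _profile(q, np.full(40, 2.0)))
        assert (out.intensity == 3.0).all()

    def test_negative_differences_retained(self):
        q = np.linspace(0.2, 1.7, 40)
        out = subtract_background(_profile(q, np.full(40, 1.0)),
                                  _profile(q, np.full(40, 2.0)))
        assert (out.intensity == -1.0).all()

    def test_invalid_bins_propagate(self):
        q = np.linspace(0.2, 1.7, 5)
        sig = _profile(q, [1, 2, 3, 4, 5], n_pixels=[10, 0, 10, 10, 10])
        sig.intensity[1] = np.nan
        bg = _profile(q, [1, 1, np.nan, 1, 1], n_pixels=[10, 10, 0, 10, 10])
        out = subtract_background(sig, bg)
        assert np.isnan(out.intensity[1]) and np.isnan(out.intensity[2])
        assert out.n_pixels[1] == 0 and out.n_pixels[2] == 0

    def test_binning_mismatch_rejected(self):
        a = _model_profile(1, -4, 0, n=40)
        b = _model_profile(1, -4, 0, n=41)
        with pytest.raises(ValueError):
            subtract_background(a, b)


class TestPowerLawFit:
    def test_noiseless_recovery_exact(self):
        # the model lies in the fit class: parameters back to 1e-6 relative
        for K in (0.5, 2.0, 50.0):
            for alpha in (-5.0, -4.1, -3.0, -1.5):
                for B in (0.0, 0.1, 5.0):
                    fit = fit_power_law(_model_profile(K, alpha, B))
                    assert fit.converged
                    assert fit.K == pytest.approx(K, rel=1e-6)
                    assert fit.alpha == pytest.approx(alpha, rel=1e-6)
                    assert fit.B == pytest.approx(B, abs=max(1e-6 * K, 1e-9))

    def test_scale_equivariance(self):
        prof = _model_profile(2.0, -3.5, 0.2)
        base = fit_power_law(prof)
        scaled = fit_power_law(
            _profile(prof.q_centers, prof.intensity * 7.0, prof.n_pixels)
        )
        assert scaled.K == pytest.approx(7 * base.K, rel=1e-6)
        assert scaled.B == pytest.approx(7 * base.B, abs=1e-6)
        assert scaled.alpha == pytest.approx(base.alpha, abs=1e-8)

    def test_fixed_additive_constant(self):
        fit = fit_power_law(_model_profile(3.0, -4.0, 0.0), fix_b=0.0)
        assert fit.b_fixed and fit.B == 0.0
        assert fit.alpha == pytest.approx(-4.0, rel=1e-8)

    def test_too_few_bins_rejected(self):
        prof = _model_profile(1.0, -4.0, 0.0, n=5)
        with pytest.raises(ValueError, match="valid bins"):
            fit_power_law(prof)

    def test_poisson_noise_bias_small(self):
        # per-cell averaged profiles at realistic counting statistics
        rng = np.random.default_rng(42)
        geom = default_geometry()
        ones = np.ones(geom.shape)
        npix = azimuthal_integrate(ones, geom, n_bins=150).n_pixels
        q = azimuthal_integrate(ones, geom, n_bins=150).q_centers
        exposure, n_patterns = 1.34, 400
        errors, covered = [], 0
        n_cells = 60
        for _ in range(n_cells):
            K = rng.lognormal(np.log(0.05), 0.4)
            alpha = rng.normal(-4.1, 0.1)
            B = rng.uniform(0.001, 0.005)
            lam = (K * q**alpha + B) * exposure * npix * n_patterns
            lam[npix == 0] = 0
            counts = rng.poisson(lam)
            scale = np.maximum(npix, 1) * exposure * n_patterns
            intensity = np.where(npix > 0, counts / scale, np.nan)
            sigma = np.sqrt(np.maximum(counts, 1)) / scale  # Poisson weights
            fit = fit_power_law(_profile(q, intensity, npix), sigma=sigma)
            if fit.converged:
                errors.append(fit.alpha - alpha)
                covered += abs(fit.alpha - alpha) <= fit.alpha_err
        assert len(errors) >= 0.95 * n_cells
        assert abs(np.mean(errors)) < 0.08
        assert 0.5 <= covered / len(errors) <= 0.85


class TestDose:
    def test_default_fast_scan_dose(self):
        # 1.34 ms, 0.5 um steps, 1.7e12 ph/s at 13 keV -> ~4.8e6 Gy
        assert dose(DoseParams()) == pytest.approx(4.84e6, rel=0.01)

    def test_linear_in_exposure(self):
        d1 = dose(DoseParams(exposure=1.34e-3))
        d2 = dose(DoseParams(exposure=20e-3))
        assert d2 / d1 == pytest.approx(20 / 1.34, rel=1e-12)

    def test_inverse_step_area(self):
        base = dose(DoseParams())
        halved = dose(DoseParams(step_y=0.25e-6, step_z=0.25e-6))
        assert halved == pytest.approx(4 * base, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-4, max_value=10.0))
    def test_multiplicative_in_flux(self, factor):
        base = dose(DoseParams())
        assert dose(DoseParams(flux=1.7e12 * factor)) == pytest.approx(
            base * factor, rel=1e-9
        )

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            DoseParams(flux=0.0)


class TestBackgroundStrategies:
    def test_row_matched_single_pixel_row(self, small_scan):
        phantom, geom, stack = small_scan
        labels = segment_darkfield(
            darkfield(stack).values, window_fraction=0.35, surroundings_margin=8
        )
        cid = 1
        rows, cols = labels.cell_indices(cid)
        point = (int(rows[0]), int(cols[0]))
        prof = row_matched_background(stack, labels, cid, point, n_bins=80)
        # oracle: integrate the average of exactly those surroundings frames
        srows, scols = labels.surroundings_indices(cid)
        in_row = srows == point[0]
        from scansaxs.reduce import average_pattern

        expected = azimuthal_integrate(
            average_pattern(stack, (srows[in_row], scols[in_row])), geom, n_bins=80
        )
        np.testing.assert_allclose(
            prof.intensity[prof.valid], expected.intensity[expected.valid]
        )

    def test_wrong_cell_point_rejected(self, small_scan):
        _, _, stack = small_scan
        labels = segment_darkfield(darkfield(stack).values, window_fraction=0.35)
        with pytest.raises(ValueError, match="does not belong"):
            row_matched_background(stack, labels, 1, (0, 0))

    def test_row_matched_removes_flux_drift(self):
        # with a row-dependent beam drift, row-matched subtraction stays
        # unbiased while whole-surroundings subtraction does not
        grid = ScanGrid(50, 60)
        phantom = make_phantom(1, grid, seed=8)
        geom = default_geometry((64, 64))
        drift = np.linspace(0.7, 1.3, grid.n_rows)
        stack = simulate_scan(phantom, geom, seed=18, row_flux=drift)
        labels = segment_darkfield(
            darkfield(stack).values, window_fraction=0.5, surroundings_margin=25
        )
        assert labels.n_cells == 1
        rows, cols = labels.cell_indices(1, RegionClass.CYTOPLASM)
        # pick the cytoplasm pixel on the most off-center row
        k = int(np.argmax(np.abs(rows - grid.n_rows / 2)))
        point = (int(rows[k]), int(cols[k]))
        cell = phantom.cells[0]
        truth_bg = ExpectationEngine(
            phantom_from_cells([], grid, phantom.background), geom
        ).pattern(0, 0)
        true_cell = drift[point[0]] * (
            truth_bg + cell.K_cyt * _qpow(geom, cell.alpha_cyt) + cell.B
        )
        sig = azimuthal_integrate(stack.frame(*point), geom, n_bins=80)
        row_bg = row_matched_background(stack, labels, 1, point, n_bins=80)
        srows, scols = labels.surroundings_indices(1)
        from scansaxs.reduce import average_pattern

        global_bg = azimuthal_integrate(
            average_pattern(stack, (srows, scols)), geom, n_bins=80
        )
        truth_prof = azimuthal_integrate(
            np.where(geom.mask, np.nan, true_cell - drift[point[0]] * truth_bg)
            * stack.exposure,
            geom, n_bins=80,
        )
        res_row = subtract_background(sig, row_bg)
        res_glob = subtract_background(sig, global_bg)
        sel = res_row.valid & res_glob.valid & truth_prof.valid
        bias_row = np.nanmean(res_row.intensity[sel] - truth_prof.intensity[sel])
        bias_glob = np.nanmean(res_glob.intensity[sel] - truth_prof.intensity[sel])
        assert abs(bias_row) < abs(bias_glob)

    def test_nucleus_prefactor_exceeds_cytoplasm(self, default_scan, default_scan_file):
        # nuclei are denser/thicker: fitted K ranks nucleus > cytoplasm
        phantom, geom, stack = default_scan
        cfg = reduced_scale_config()
        labels = segment_darkfield(
            darkfield(stack).values,
            window_fraction=cfg.bradley_window_fraction,
            sensitivity=cfg.bradley_sensitivity,
        )
        K_nuc, K_cyt = [], []
        for cid in range(1, labels.n_cells + 1):
            bg_idx = labels.surroundings_indices(cid)
            if bg_idx[0].size == 0:
                continue
            try:
                fn, _ = fit_region_profile(
                    stack, labels.cell_indices(cid, RegionClass.NUCLEUS), bg_idx,
                    n_bins=150,
                )
                fc, _ = fit_region_profile(
                    stack, labels.cell_indices(cid, RegionClass.CYTOPLASM), bg_idx,
                    n_bins=150,
                )
            except ValueError:
                continue
            if fn.converged and fc.converged:
                K_nuc.append(fn.K)
                K_cyt.append(fc.K)
        assert len(K_nuc) >= 10
        assert np.mean(K_nuc) > np.mean(K_cyt)


def _qpow(geom, alpha):
    from scansaxs import build_qmap

    q = build_qmap(geom).q.copy()
    q[q == 0] = q[q > 0].min()
    return q**alpha
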