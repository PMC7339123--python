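"""DSC thermogram synthesis, feature extraction and deconvolution."""

import numpy as np
import pytest

import bilayerlab as bl
from bilayerlab.constants import GAS_CONSTANT_R, celsius_to_kelvin
from bilayerlab.dsc import Thermogram, enthalpy_for_fwhm, vant_hoff_fwhm


GRID = np.arange(28.0, 46.0, 0.02)


def single_scan(t_m=41.3, fwhm=0.4, dh_cal=30_000.0, grid=GRID, **kw):
    comp = bl.MeltingComponent(t_m, enthalpy_for_fwhm(t_m, fwhm), dh_cal)
    return bl.gen_thermogram([comp], grid, **kw)


class TestVantHoffCurve:
    def test_peak_located_at_t_m(self):
        scan = single_scan()
        assert GRID[np.argmax(scan.cp_excess)] == pytest.approx(41.3, abs=0.02)

    def test_area_equals_calorimetric_enthalpy(self):
        scan = single_scan()
        area = np.trapezoid(scan.cp_excess, scan.temperature)
        assert area == pytest.approx(30_000.0, rel=0.01)

    @pytest.mark.parametrize("width", [0.2, 0.4, 1.0, 2.0, 4.0])
    def test_fwhm_closed_form(self, width):
        """Full width at half maximum equals 3.5255*R*T_m^2/dH_vH."""
        t_m = 41.3
        grid = np.arange(t_m - 8 * width - 1, t_m + 8 * width + 1, min(width / 50, 0.02))
        scan = single_scan(t_m=t_m, fwhm=width, grid=grid)
        measured = bl.extract_features(scan).t_half
        expected = 3.5255 * GAS_CONSTANT_R * celsius_to_kelvin(t_m) ** 2 / enthalpy_for_fwhm(t_m, width)
        assert measured == pytest.approx(expected, rel=0.02)
        assert vant_hoff_fwhm(t_m, enthalpy_for_fwhm(t_m, width)) == pytest.approx(width, rel=1e-12)

    def test_component_additivity(self):
        c1 = bl.MeltingComponent(39.0, enthalpy_for_fwhm(39.0, 1.0), 15_000.0)
        c2 = bl.MeltingComponent(41.0, enthalpy_for_fwhm(41.0, 1.0), 15_000.0)
        both = bl.gen_thermogram([c1, c2], GRID)
        s1 = bl.gen_thermogram([c1], GRID)
        s2 = bl.gen_thermogram([c2], GRID)
        np.testing.assert_array_equal(both.cp_excess, s1.cp_excess + s2.cp_excess)

    def test_grid_not_covering_component_is_an_error(self):
        with pytest.raises(bl.ConfigurationError, match="41.3"):
            single_scan(grid=np.arange(40.0, 42.0, 0.02))


class TestPreprocess:
    def test_idempotent_on_baselined_scan(self):
        scan = single_scan()
        out = bl.preprocess(scan)
        np.testing.assert_allclose(out.cp_excess, scan.cp_excess, atol=1e-9 * scan.cp_excess.max())

    def test_add_then_remove_linear_baseline(self):
        clean = single_scan()
        tilted = single_scan(baseline_coeffs=(0.01, 250.0))
        out = bl.preprocess(tilted)
        peak = clean.cp_excess.max()
        assert np.max(np.abs(out.cp_excess - clean.cp_excess)) <= 0.01 * peak

    def test_flat_zero_scan_unchanged(self):
        scan = Thermogram(GRID, np.zeros_like(GRID))
        out = bl.preprocess(scan)
        np.testing.assert_allclose(out.cp_excess, 0.0, atol=1e-12)

    def test_peak_filling_scan_is_an_error(self):
        # one enormous peak spanning the whole (short) scan
        grid = np.arange(40.0, 42.6, 0.02)
        comp = bl.MeltingComponent(41.3, enthalpy_for_fwhm(41.3, 4.0), 30_000.0)
        y = bl.vant_hoff_excess_cp(grid, 41.3, comp.vant_hoff_enthalpy, comp.calorimetric_enthalpy)
        with pytest.raises(bl.DomainError):
            bl.preprocess(Thermogram(grid, y))


class TestExtractFeatures:
    def test_control_roundtrip(self, control_thermogram):
        f = bl.extract_features(bl.preprocess(control_thermogram))
        assert f.ok
        assert f.t_m == pytest.approx(41.3, abs=0.02)
        assert f.t_p == pytest.approx(33.9, abs=0.02)
        assert f.t_half == pytest.approx(0.40, abs=0.02)
        assert not f.pretransition_abolished

    def test_single_component_reports_pretransition_abolished(self):
        f = bl.extract_features(bl.preprocess(single_scan()))
        assert f.pretransition_abolished
        assert f.t_p is None

    def test_scale_equivariance(self):
        scan = single_scan()
        halved = Thermogram(scan.temperature, scan.cp_excess / 2)
        f1 = bl.extract_features(scan)
        f2 = bl.extract_features(halved)
        assert f2.t_m == pytest.approx(f1.t_m, abs=1e-9)
        assert f2.t_half == pytest.approx(f1.t_half, rel=1e-9)
        assert f2.enthalpy == pytest.approx(f1.enthalpy / 2, rel=1e-9)

    def test_flat_scan_reports_no_peak(self):
        f = bl.extract_features(Thermogram(GRID, np.zeros_like(GRID)))
        assert not f.ok
        assert f.reason == "no_peak"

    def test_feature_errors_grow_with_noise(self):
        """Median feature error increases monotonically over a noise ladder."""
        peak = single_scan().cp_excess.max()
        med_errs = []
        for rel_sd in (0.001, 0.004, 0.016, 0.064):
            errs = []
            for seed in range(50):
                scan = single_scan(noise_sd=rel_sd * peak, seed=seed, fwhm=1.0)
                f = bl.extract_features(bl.preprocess(scan))
                errs.append(abs(f.t_m - 41.3) + abs(f.t_half - 1.0))
            med_errs.append(np.median(errs))
        assert all(a <= b * 1.05 for a, b in zip(med_errs, med_errs[1:]))


class TestDeconvolve:
    def test_single_component_identity(self):
        comps = bl.deconvolve(single_scan(fwhm=1.0))
        assert len(comps) == 1
        assert comps[0].t_m == pytest.approx(41.3, abs=0.02)

    def test_two_components_resolved(self):
        c1 = bl.MeltingComponent(39.0, enthalpy_for_fwhm(39.0, 1.0), 15_000.0)
        c2 = bl.MeltingComponent(41.0, enthalpy_for_fwhm(41.0, 1.0), 15_000.0)
        scan = bl.gen_thermogram([c1, c2], GRID)
        comps = bl.deconvolve(scan)
        assert len(comps) == 2
        assert comps[0].t_m == pytest.approx(39.0, abs=0.1)
        assert comps[1].t_m == pytest.approx(41.0, abs=0.1)

    def test_unresolvable_separation_collapses_to_one(self):
        c1 = bl.MeltingComponent(40.975, enthalpy_for_fwhm(40.975, 1.0), 15_000.0)
        c2 = bl.MeltingComponent(41.025, enthalpy_for_fwhm(41.025, 1.0), 15_000.0)
        scan = bl.gen_thermogram([c1, c2], GRID)
        assert len(bl.deconvolve(scan)) == 1

    def test_enthalpy_conservation(self):
        c1 = bl.MeltingComponent(39.0, enthalpy_for_fwhm(39.0, 1.0), 20_000.0)
        c2 = bl.MeltingComponent(41.5, enthalpy_for_fwhm(41.5, 0.6), 10_000.0)
        scan = bl.gen_thermogram([c1, c2], GRID)
        comps = bl.deconvolve(scan)
        total = sum(c.calorimetric_enthalpy for c in comps)
        assert total == pytest.approx(30_000.0, rel=0.05)

    def test_estimator_reconstruction(self):
        est = bl.VantHoffDeconvolver().fit(single_scan(fwhm=1.0))
        recon = est.predict(GRID)
        np.testing.assert_allclose(recon, single_scan(fwhm=1.0).cp_excess, atol=0.01 * recon.max())


class TestShifts:
    def _features(self, scan):
        return bl.extract_features(bl.preprocess(scan))

    def test_identical_scans_zero_shifts(self, control_thermogram):
        f = self._features(control_thermogram)
        s = bl.shifts_vs_control(f, f)
        assert s.minus_delta_t_m == 0.0
        assert s.delta_t_half == 0.0
        assert s.delta_t_p == 0.0
        assert not s.pretransition_abolished

    def test_downshift_sign_convention(self, control_thermogram):
        """A main transition moved from 41.3 to 36.5 C is reported as a
        positive downshift of 4.8 C."""
        treated = single_scan(t_m=36.5, fwhm=4.0, dh_cal=25_000.0, grid=np.arange(22.0, 50.0, 0.02))
        s = bl.shifts_vs_control(self._features(control_thermogram), self._features(treated))
        assert s.minus_delta_t_m == pytest.approx(4.8, abs=0.05)
        assert s.pretransition_abolished
        assert s.delta_t_p is None

    def test_abolished_pretransition_is_flagged_not_zero(self, control_thermogram):
        treated = single_scan(t_m=40.0, fwhm=1.0)
        s = bl.shifts_vs_control(self._features(control_thermogram), self._features(treated))
        assert s.pretransition_abolished
        assert s.delta_t_p is None
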