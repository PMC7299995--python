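"""Spectrum fitting, inclusion rule, calibration and quantification tests."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import coccomap as cm
from coccomap.spectrum import (CalibrationError, CalibrationStandard,
                               CollinearityError, ConfigurationError, FitResult,
                               build_templates, element_inclusion, fit_spectrum)


def _render_summed(ppm: dict, inst, library):
    """Noiseless single-pixel spectrum for a uniform composition."""
    inst2 = inst.model_copy(update={"contaminant_lines": {}})
    elements = {el: np.full((1, 1), float(v)) for el, v in ppm.items()}
    if "Ca" not in elements:
        elements["Ca"] = np.zeros((1, 1))
    spec = cm.SpecimenMap(elements, pixel_size_nm=50.0)
    cube = cm.render_spectra(spec, inst2, library, seed=0, poisson=False)
    return cube.counts[0, 0].astype(float)


class TestFitSpectrum:
    def test_noiseless_single_line_exact(self, inst_small, library):
        T, _ = build_templates(["Sr"], library, inst_small)
        y = 500.0 * T[:, 0]
        fit = fit_spectrum(y, ["Sr"], library, inst_small, weights="none")
        assert fit.amplitude("Sr") == pytest.approx(500.0, abs=1e-6)

    def test_overlapping_ni_cu_recovered_within_3_sigma(self, inst_small, library):
        """Ni Ka sits on the Cu Ka shoulder; both amplitudes still resolve."""
        T, _ = build_templates(["Ni", "Cu"], library, inst_small)
        truth = np.array([400.0, 4000.0])         # SNR >> 10
        rng = np.random.default_rng(0)
        y = rng.poisson(T @ truth + 0.5).astype(float)
        fit = fit_spectrum(y, ["Ni", "Cu"], library, inst_small, weights="poisson")
        for el, t in zip(("Ni", "Cu"), truth):
            assert abs(fit.amplitude(el) - t) < 3 * fit.sigma(el)

    def test_matches_brute_force_grid_oracle(self, inst_small, library):
        """The bounded linear fit lands on the exhaustive 2-D grid optimum."""
        T, _ = build_templates(["Ni", "Cu"], library, inst_small)
        rng = np.random.default_rng(1)
        y = rng.poisson(T @ np.array([300.0, 2500.0]) + 1.0).astype(float)
        fit = fit_spectrum(y, ["Ni", "Cu"], library, inst_small,
                           weights="none", bg_degree=0)
        # oracle: exhaustive search over (a_Ni, a_Cu, flat background)
        step = 2.0
        a_ni = np.arange(200.0, 400.0 + step, step)
        a_cu = np.arange(2400.0, 2600.0 + step, step)
        best, arg = np.inf, None
        ones = np.ones_like(y)
        for ai in a_ni:
            for aj in a_cu:
                r = y - ai * T[:, 0] - aj * T[:, 1]
                b = r.mean()                       # optimal flat background
                sse = np.sum((r - b * ones) ** 2)
                if sse < best:
                    best, arg = sse, (ai, aj)
        assert abs(fit.amplitude("Ni") - arg[0]) <= step
        assert abs(fit.amplitude("Cu") - arg[1]) <= step

    def test_pb_l_lines_bleed_into_as_channel(self, inst_small, library):
        """Pb L-lines overlap As Ka: a Pb-only spectrum yields a nonzero As* fit."""
        T, _ = build_templates(["Pb"], library, inst_small)
        y = 2000.0 * T[:, 0]
        fit = fit_spectrum(y, ["As", "Se"], library, inst_small, weights="none")
        assert fit.amplitude("As") > 3 * fit.sigma("As")

    def test_collinear_candidates_rejected_naming_pair(self, inst_small):
        lib = pd.DataFrame({
            "element": ["Aa", "Bb"], "line": ["Ka", "Ka"],
            "energy_keV": [8.0, 8.0], "rel_intensity": [1.0, 1.0],
            "sensitivity": [1e-3, 1e-3]})
        y = np.zeros(len(inst_small.bin_edges) - 1)
        with pytest.raises(CollinearityError, match="Aa.*Bb"):
            fit_spectrum(y, ["Aa", "Bb"], lib, inst_small)

    def test_unexcitable_element_rejected(self, inst_small, library):
        inst = inst_small.model_copy(update={"incident_energy_keV": 10.0})
        with pytest.raises(ConfigurationError, match="Sr"):
            build_templates(["Sr"], library, inst)

    def test_linearity_in_concentration(self, inst_small, library):
        y1 = _render_summed({"Ca": 1e5, "Sr": 1e3}, inst_small, library)
        y2 = _render_summed({"Ca": 2e5, "Sr": 2e3}, inst_small, library)
        f1 = fit_spectrum(y1, ["Ca", "Sr"], library, inst_small, weights="none")
        f2 = fit_spectrum(y2, ["Ca", "Sr"], library, inst_small, weights="none")
        for el in ("Ca", "Sr"):
            assert f2.amplitude(el) == pytest.approx(2 * f1.amplitude(el), rel=1e-6)


class TestInclusion:
    @pytest.mark.parametrize("amplitude,sigma,expected", [
        (100.0, 10.0, True),            # 100 > 3*10
        (10.0, 10.0, False),            # 10 < 3*10
    ])
    def test_z_rule(self, amplitude, sigma, expected):
        df = pd.DataFrame({"amplitude": [amplitude], "amplitude_sigma": [sigma],
                           "included": [True]}, index=pd.Index(["Sr"]))
        fit = FitResult(elements=df, background_coef=np.zeros(3), residual_norm=0.0)
        assert ("Sr" in element_inclusion(fit, 3.0)) is expected

    def test_absent_element_excluded_across_replicates(
            self, small_specimen, inst_small, library, candidates):
        """V is absent from the specimen; the 3-sigma rule drops it in >=19/20
        Poisson replicates (bound fixed by simulation before freezing)."""
        excluded = 0
        for seed in range(20):
            cube = cm.render_spectra(small_specimen, inst_small, seed=seed,
                                     poisson=True)
            ysum = cube.counts.sum(axis=(0, 1))
            fit = fit_spectrum(ysum, candidates, library, inst_small,
                               weights="poisson")
            if "V" not in element_inclusion(fit, 3.0):
                excluded += 1
        assert excluded >= 19

    def test_detection_floor_10_ppm(self, library):
        """A uniform 10 ppm trace on a full-template specimen passes inclusion."""
        inst = cm.InstrumentConfig(energy_step_keV=0.02)
        thickness = cm.make_geometry(cm.GeometryConfig(pixel_size_nm=100.0))
        models = {"Se": cm.IncorporationModel(mode="absent", coat_field_scale=10.0)}
        spec = cm.make_element_fields(thickness, models, seed=0)
        cube = cm.render_spectra(spec, inst, seed=0, poisson=True)
        ysum = cube.counts.sum(axis=(0, 1))
        fit = fit_spectrum(ysum, ["Ca", "Se", "Ar", "Si", "Cu", "Kr"],
                           library, inst, weights="poisson")
        assert "Se" in element_inclusion(fit, 3.0)


class TestCalibration:
    def test_recovers_true_flux_area_scale(self, standard_calibration, inst_small):
        _, cal = standard_calibration
        assert cal.flux_area_scale == pytest.approx(
            inst_small.flux_area_scale_true, rel=0.01)

    def test_consistent_amplitudes_zero_residual(self, library):
        sens = cm.sensitivities(library)
        k, dwell = 5.0, 0.2
        cert = {"Ca": 100.0, "Fe": 200.0, "Zn": 300.0, "Sr": 50.0}
        amps = {el: k * sens[el] * dwell * v for el, v in cert.items()}
        cal = cm.calibrate(CalibrationStandard(cert, amps), library, dwell)
        assert cal.flux_area_scale == pytest.approx(k, rel=1e-12)
        assert np.allclose(cal.residuals, 0.0, atol=1e-12)

    def test_discrepant_element_carries_residual(self, library):
        sens = cm.sensitivities(library)
        k, dwell = 5.0, 0.2
        cert = {"Ca": 100.0, "Fe": 200.0, "Zn": 300.0, "Sr": 50.0}
        amps = {el: k * sens[el] * dwell * v for el, v in cert.items()}
        amps["Fe"] *= 1.10
        cal = cm.calibrate(CalibrationStandard(cert, amps), library, dwell)
        assert cal.residuals.abs().idxmax() == "Fe"
        assert cal.residuals["Fe"] > 0

    def test_single_element_warns_and_solves_exactly(self, library):
        sens = cm.sensitivities(library)
        amps = {"Ca": 5.0 * sens["Ca"] * 0.2 * 100.0}
        with pytest.warns(UserWarning, match="single-element"):
            cal = cm.calibrate(CalibrationStandard({"Ca": 100.0}, amps),
                               library, 0.2)
        assert cal.flux_area_scale == pytest.approx(5.0, rel=1e-12)

    def test_zero_amplitude_rejected(self, library):
        with pytest.raises(CalibrationError):
            cm.calibrate(CalibrationStandard({"Ca": 100.0}, {"Ca": 0.0}),
                         library, 0.2)

    def test_poisson_calibration_unbiased(self, inst_small, library):
        """k estimates over 100 Poisson standards are unbiased within 3 MC SE."""
        cert = {"Ca": 116.0, "Fe": 184.0, "Cu": 160.0, "Zn": 127.0, "Sr": 100.0}
        ks = []
        for seed in range(100):
            std = cm.synthetic_standard(cert, inst_small, seed=seed,
                                        n_pixels=4000, poisson=True)
            ks.append(cm.calibrate(std, library, inst_small.dwell_s).flux_area_scale)
        ks = np.array(ks)
        se = ks.std(ddof=1) / np.sqrt(ks.size)
        assert abs(ks.mean() - inst_small.flux_area_scale_true) < 3 * se


class TestQuantify:
    def test_zero_amplitude_zero_ppm(self, standard_calibration, library, inst_small):
        _, cal = standard_calibration
        maps = {"Ca": np.array([[100.0]]), "Sr": np.array([[0.0]])}
        spec = cm.quantify(maps, cal, library, inst_small.dwell_s, 50.0)
        assert spec["Sr"][0, 0] == 0.0

    def test_instrument_channels_never_quantified(self, standard_calibration,
                                                  library, inst_small):
        _, cal = standard_calibration
        maps = {"Ca": np.array([[100.0]]), "Ar": np.array([[50.0]]),
                "Kr": np.array([[5.0]]), "Cu": np.array([[500.0]])}
        spec = cm.quantify(maps, cal, library, inst_small.dwell_s, 50.0)
        assert set(spec.elements) == {"Ca"}

    def test_as_channel_reported_merged(self, standard_calibration, library,
                                        inst_small):
        _, cal = standard_calibration
        maps = {"Ca": np.array([[100.0]]), "As": np.array([[10.0]])}
        spec = cm.quantify(maps, cal, library, inst_small.dwell_s, 50.0)
        assert "As*" in spec.elements and "As" not in spec.elements

    def test_missing_sensitivity_rejected(self, standard_calibration, library,
                                          inst_small):
        _, cal = standard_calibration
        maps = {"Ca": np.array([[100.0]]), "Xx": np.array([[1.0]])}
        with pytest.raises(ConfigurationError, match="Xx"):
            cm.quantify(maps, cal, library, inst_small.dwell_s, 50.0)

    def test_sensitivity_scale_invariance(self, inst_small, library):
        """Quantified ppm does not depend on the sensitivity table's scale."""
        cert = {"Ca": 116.0, "Fe": 184.0, "Sr": 100.0}
        std = cm.synthetic_standard(cert, inst_small)
        maps = {"Ca": np.array([[250.0]]), "Sr": np.array([[12.0]])}
        results = []
        for scale in (1.0, 7.3):
            lib = library.copy()
            lib["sensitivity"] = lib["sensitivity"] * scale
            cal = cm.calibrate(std, lib, inst_small.dwell_s)
            spec = cm.quantify(maps, cal, lib, inst_small.dwell_s, 50.0)
            results.append((spec["Ca"][0, 0], spec["Sr"][0, 0]))
        np.testing.assert_allclose(results[0], results[1], rtol=1e-9)
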