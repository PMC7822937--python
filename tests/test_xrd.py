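"""Peak fitting, instrument correction, Scherrer / Williamson-Hall and lattice."""

import numpy as np
import pytest

from ribchron.constants import CAGLIOTI_UVW, SCHERRER_K, XRAY_WAVELENGTH_NM, XRD_FIT_WINDOWS
from ribchron.synthetic import RenderOptions, render_diffraction
from ribchron.xrd import (
    DiffractionPattern,
    analyze_patterns,
    bragg_two_theta_deg,
    caglioti_fwhm_deg,
    correct_instrument,
    fit_peak,
    hexagonal_d_spacing,
    lattice_parameters,
    scherrer_cl,
    split_pseudo_voigt,
    williamson_hall,
)


def _pattern(fwhm=0.4, centre=25.9, eta=0.5, amp=1000.0, lo=10.0, hi=80.0):
    x = np.arange(lo, hi, 0.01)
    y = 10.0 + split_pseudo_voigt(x, amp, centre, fwhm, fwhm, eta)
    return DiffractionPattern(x, y)


class TestFitPeak:
    def test_noiseless_fwhm_recovery(self):
        pk = fit_peak(_pattern(fwhm=0.4), (23.0, 27.0), "002")
        assert pk.fwhm_obs_deg == pytest.approx(0.4, rel=0.005)
        assert pk.position_deg == pytest.approx(25.9, abs=1e-3)

    def test_gaussian_limit(self):
        sigma = 0.2
        fwhm_true = 2 * np.sqrt(2 * np.log(2)) * sigma
        x = np.arange(23.0, 27.0, 0.01)
        y = 5.0 + 800 * np.exp(-0.5 * ((x - 25.0) / sigma) ** 2)
        pk = fit_peak(DiffractionPattern(x, y), (23.0, 27.0), "002")
        assert pk.eta_mix < 0.05
        assert pk.fwhm_obs_deg == pytest.approx(fwhm_true, rel=0.01)

    def test_asymmetric_widths_recovered(self):
        x = np.arange(23.0, 27.0, 0.01)
        y = 5.0 + split_pseudo_voigt(x, 900, 25.2, 0.3, 0.5, 0.4)
        pk = fit_peak(DiffractionPattern(x, y), (23.0, 27.0), "002")
        assert pk.fwhm_left_deg == pytest.approx(0.3, rel=0.02)
        assert pk.fwhm_right_deg == pytest.approx(0.5, rel=0.02)

    def test_empty_window_errors(self):
        with pytest.raises(Exception):
            fit_peak(_pattern(), (23.0, 23.05), "002")


class TestInstrumentCorrection:
    def test_quadrature_identity(self):
        b_inst = caglioti_fwhm_deg(13.0)
        b_obs = np.sqrt(2) * b_inst
        b_sample = correct_instrument(b_obs, 13.0)
        assert np.degrees(b_sample) == pytest.approx(b_inst, rel=1e-9)

    def test_negligible_instrument_leaves_beta(self):
        b_sample = correct_instrument(0.5, 13.0, caglioti=(0.0, 0.0, 1e-12))
        assert np.degrees(b_sample) == pytest.approx(0.5, rel=1e-6)

    def test_nonphysical_broadening_rejected(self):
        b_inst = caglioti_fwhm_deg(13.0)
        with pytest.raises(ValueError):
            correct_instrument(0.5 * b_inst, 13.0)

    def test_lorentzian_mode(self):
        b_inst = caglioti_fwhm_deg(13.0)
        b = correct_instrument(b_inst + 0.3, 13.0, mode="lorentzian")
        assert np.degrees(b) == pytest.approx(0.3, rel=1e-9)


class TestScherrer:
    def test_algebraic_inversion(self):
        for theta in (0.15, 0.25, 0.4):
            beta = SCHERRER_K * XRAY_WAVELENGTH_NM / (10.0 * np.cos(theta))
            assert scherrer_cl(beta, theta) == pytest.approx(10.0, rel=1e-12)

    def test_inverse_proportionality(self):
        cl1 = scherrer_cl(0.005, 0.22)
        cl2 = scherrer_cl(0.010, 0.22)
        assert cl1 == pytest.approx(2 * cl2, rel=1e-12)

    def test_defaults(self):
        assert SCHERRER_K == 0.9
        assert XRAY_WAVELENGTH_NM == 0.15406


class TestWilliamsonHall:
    def _points(self, L, eps, c=6.884):
        out = []
        for l in (2, 4):
            d = c / l
            theta = np.arcsin(1.5406 / (2 * d))
            bcos = 4 * eps * np.sin(theta) + SCHERRER_K * XRAY_WAVELENGTH_NM / L
            out.append((bcos / np.cos(theta), theta))
        return out

    def test_two_point_exact_inversion(self):
        L, eps = williamson_hall(self._points(25.0, 0.003))
        assert L == pytest.approx(25.0, rel=1e-10)
        assert eps == pytest.approx(0.003, rel=1e-10)

    def test_strain_free_limit_matches_scherrer(self):
        pts = self._points(18.0, 0.0)
        L, eps = williamson_hall(pts)
        assert eps == pytest.approx(0.0, abs=1e-12)
        assert L == pytest.approx(scherrer_cl(*pts[0]), rel=1e-9)

    def test_strain_broadens_004_more(self):
        base = self._points(25.0, 0.0)
        strained = self._points(25.0, 0.004)
        extra_002 = strained[0][0] - base[0][0]
        extra_004 = strained[1][0] - base[1][0]
        assert extra_004 > extra_002 > 0

    def test_degenerate_points_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            williamson_hall([(0.005, 0.2), (0.005, 0.2)])

    def test_negative_intercept_rejected(self):
        with pytest.raises(ValueError):
            williamson_hall([(0.0001, 0.2), (0.01, 0.45)])


class TestLattice:
    def test_reference_lattice_roundtrip(self):
        a, c = 9.418, 6.884
        p002 = bragg_two_theta_deg(hexagonal_d_spacing(0, 0, 2, a, c))
        p004 = bragg_two_theta_deg(hexagonal_d_spacing(0, 0, 4, a, c))
        p030 = bragg_two_theta_deg(hexagonal_d_spacing(0, 3, 0, a, c))
        a_est, c_est = lattice_parameters(p002, p004, p030)
        assert a_est == pytest.approx(a, rel=5e-4)
        assert c_est == pytest.approx(c, rel=5e-4)

    def test_ideal_lattice_consistent_c(self):
        p002 = bragg_two_theta_deg(3.442)
        p004 = bragg_two_theta_deg(1.721)
        c1 = 2 * 3.442
        _, c_est = lattice_parameters(p002, p004, 32.9)
        assert c_est == pytest.approx(c1, rel=1e-9)

    def test_larger_030_angle_means_smaller_a(self):
        p002, p004 = 25.87, 53.19
        a1, _ = lattice_parameters(p002, p004, 32.5)
        a2, _ = lattice_parameters(p002, p004, 33.5)
        assert a2 < a1

    def test_inconsistent_c_warns(self):
        with pytest.warns(UserWarning):
            lattice_parameters(25.87, 54.2, 32.9)


@pytest.fixture(scope="module")
def record():
    return {"a_axis": 9.418, "c_axis": 6.884, "Size": 28.0, "Strain": 0.0045,
            "CL030": 9.0, "CL210": 12.0}


@pytest.fixture(scope="module")
def patterns(record):
    rng = np.random.default_rng(42)
    return render_diffraction(record, rng, RenderOptions())


class TestFullReduction:

    def test_bragg_law_consistency_of_stepped_scans(self, patterns):
        pk2 = fit_peak(patterns["stepped_002"], XRD_FIT_WINDOWS["002"], "002")
        pk4 = fit_peak(patterns["stepped_004"], XRD_FIT_WINDOWS["004"], "004")
        d2 = 1.5406 / (2 * np.sin(np.radians(pk2.position_deg / 2)))
        d4 = 1.5406 / (2 * np.sin(np.radians(pk4.position_deg / 2)))
        assert d4 == pytest.approx(d2 / 2, rel=0.002)

    def test_full_roundtrip(self, record, patterns):
        res = analyze_patterns(patterns["wide"], patterns["stepped_002"],
                               patterns["stepped_004"])
        assert res.a_axis_A == pytest.approx(record["a_axis"], rel=1e-3)
        assert res.c_axis_A == pytest.approx(record["c_axis"], rel=1e-3)
        assert res.size_nm == pytest.approx(record["Size"], rel=0.02)
        assert res.CL030_nm == pytest.approx(record["CL030"], rel=0.02)

    def test_intensity_scale_invariance(self, patterns):
        res1 = analyze_patterns(patterns["wide"], patterns["stepped_002"],
                                patterns["stepped_004"])
        scaled = {k: DiffractionPattern(p.two_theta_deg, p.intensity * 5.0, p.scan_kind)
                  for k, p in patterns.items()}
        res2 = analyze_patterns(scaled["wide"], scaled["stepped_002"],
                                scaled["stepped_004"])
        assert res2.CL002_nm == pytest.approx(res1.CL002_nm, rel=1e-3)
        assert res2.strain == pytest.approx(res1.strain, rel=0.02)

    def test_scherrer_equals_wh_size_when_strain_free(self):
        rng = np.random.default_rng(7)
        rec = {"a_axis": 9.418, "c_axis": 6.884, "Size": 22.0, "Strain": 0.0,
               "CL030": 9.0, "CL210": 12.0}
        pats = render_diffraction(rec, rng, RenderOptions(xrd_noise_frac=0.0))
        res = analyze_patterns(pats["wide"], pats["stepped_002"], pats["stepped_004"])
        assert res.size_nm == pytest.approx(res.CL002_nm, rel=0.01)
        assert res.size_nm == pytest.approx(22.0, rel=0.01)
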