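"""Form factors, Guinier analysis and structure factors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coildyn.sas import (
    GaussCoilParams,
    HardSphereParams,
    ScatteringCurve,
    StructureFactorCurve,
    estimate_structure_factor,
    fit_gauss_coil,
    fit_hard_sphere,
    gauss_coil_formfactor,
    guinier_fit,
    hard_sphere_sq,
    kratky_transform,
    stiff_segment_q,
)
from coildyn.synthetic import make_saxs


def debye_function(RG, q):
    """Closed-form Debye function of a Gaussian chain (independent oracle)."""
    x = (q * RG) ** 2
    return 2 * (np.exp(-x) + x - 1) / x**2


class TestGaussCoil:
    @pytest.mark.parametrize("RG,nu", [(30.0, 0.45), (45.0, 0.53), (60.0, 0.6), (40.0, 1.0)])
    def test_forward_limit_is_one(self, RG, nu):
        P = gauss_coil_formfactor(GaussCoilParams(RG=RG, nu=nu), np.array([0.0]))
        assert P[0] == pytest.approx(1.0, abs=1e-12)

    def test_reduces_to_debye_at_nu_half(self):
        RG = 45.0
        q = np.geomspace(0.01, 10.0, 200) / RG
        P = gauss_coil_formfactor(GaussCoilParams(RG=RG, nu=0.5), q)
        assert P == pytest.approx(debye_function(RG, q), rel=1e-6)

    def test_small_q_series_matches_guinier_expansion(self):
        # P ~ 1 - q^2 RG^2/3 for any nu
        p = GaussCoilParams(RG=35.0, nu=0.56)
        q = np.array([1e-5, 2e-5])
        P = gauss_coil_formfactor(p, q)
        assert P == pytest.approx(1 - q**2 * p.RG**2 / 3, rel=1e-9)

    @given(nu=st.floats(0.45, 0.6), RG=st.floats(30.0, 60.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotonically_decreasing_in_q(self, nu, RG):
        q = np.geomspace(1e-3, 0.7, 120)
        P = gauss_coil_formfactor(GaussCoilParams(RG=RG, nu=nu), q)
        assert np.all(np.diff(P) < 0)

    @pytest.mark.parametrize("nu", [0.1, 0.2, 1.2])
    def test_rejects_nu_outside_domain(self, nu):
        with pytest.raises(ValueError):
            GaussCoilParams(RG=40.0, nu=nu)


class TestGaussCoilFit:
    def test_noise_free_self_consistency(self, gauss_curve_exact):
        curve, truth = gauss_curve_exact
        fit = fit_gauss_coil(curve, init=GaussCoilParams(RG=30.0, nu=0.5))
        assert fit.params.RG == pytest.approx(truth.RG, rel=1e-4)
        assert fit.params.nu == pytest.approx(truth.nu, rel=1e-4)

    def test_noisy_recovery_within_three_sigma(self):
        truth = GaussCoilParams(RG=45.0, nu=0.53)
        curve, _ = make_saxs(truth, noise_frac=0.02, seed=4)
        fit = fit_gauss_coil(curve)
        assert abs(fit.params.RG - truth.RG) < 3 * fit.stderr.RG
        assert abs(fit.params.nu - truth.nu) < 3 * fit.stderr.nu

    def test_distinguishes_compact_from_swollen_exponent(self):
        """nu = 0.48 vs 0.53 separate at 2% noise (2-sigma intervals disjoint)."""
        fits = []
        for nu, seed in [(0.48, 11), (0.53, 12)]:
            curve, _ = make_saxs(GaussCoilParams(RG=45.0, nu=nu),
                                 noise_frac=0.02, seed=seed)
            fits.append(fit_gauss_coil(curve))
        lo, hi = sorted(fits, key=lambda f: f.params.nu)
        assert lo.params.nu + 2 * lo.stderr.nu < hi.params.nu - 2 * hi.stderr.nu

    def test_too_few_points_rejected(self):
        q = np.linspace(0.01, 0.1, 5)
        with pytest.raises(ValueError):
            fit_gauss_coil(ScatteringCurve(q, np.ones(5), np.ones(5) * 0.01))


class TestGuinier:
    def test_pure_gaussian_intensity_is_exact(self):
        R = 25.0
        q = np.geomspace(0.002, 0.2, 100)
        I = np.exp(-(R * q) ** 2 / 3)
        res = guinier_fit(ScatteringCurve(q, I, 0.01 * I), qmaxR_limit=1.3)
        assert res.RGuinier == pytest.approx(R, rel=1e-9)
        assert res.qmaxR <= 1.3 + 1e-9

    def test_gauss_coil_radius_within_five_percent(self):
        p = GaussCoilParams(RG=30.0, nu=0.5)
        q = np.geomspace(0.003, 0.3, 150)
        I = gauss_coil_formfactor(p, q)
        res = guinier_fit(ScatteringCurve(q, I, 0.01 * I), qmaxR_limit=1.1)
        assert res.RGuinier == pytest.approx(30.0, rel=0.05)

    def test_flat_curve_flagged_below_resolution(self):
        q = np.linspace(0.01, 0.3, 60)
        I = np.ones_like(q)
        res = guinier_fit(ScatteringCurve(q, I, 0.01 * I))
        assert res.RGuinier < 1.0
        assert res.below_resolution

    def test_radius_approaches_true_rg_as_limit_shrinks(self):
        """R_Guinier/R_G -> 1 monotonically as the q_max R limit decreases."""
        p = GaussCoilParams(RG=40.0, nu=0.5)
        q = np.geomspace(0.001, 0.3, 400)
        I = gauss_coil_formfactor(p, q)
        curve = ScatteringCurve(q, I, 0.01 * I)
        ratios = [guinier_fit(curve, qmaxR_limit=lim).RGuinier / p.RG
                  for lim in (1.3, 0.9, 0.5)]
        assert ratios == sorted(ratios)                 # monotone approach
        assert all(r < 1.0 for r in ratios)
        assert ratios[-1] == pytest.approx(1.0, abs=0.02)

    def test_insufficient_range_raises(self):
        q = np.linspace(0.2, 0.5, 30)                   # all points beyond limit
        I = np.exp(-(40.0 * q) ** 2 / 3) + 1e-30
        with pytest.raises(ValueError):
            guinier_fit(ScatteringCurve(q, I, np.full(30, 1e-32)), qmaxR_limit=1.1)


def test_kratky_transform_is_elementwise():
    q = np.array([0.01, 0.1, 0.2])
    curve = ScatteringCurve(q, np.array([4.0, 2.0, 1.0]), np.array([0.1, 0.2, 0.3]))
    qk, y, s = kratky_transform(curve)
    assert np.array_equal(qk, q)
    assert y == pytest.approx(q**2 * curve.I)
    assert s == pytest.approx(q**2 * curve.sigma)


class TestStructureFactor:
    def test_identical_inputs_give_unity(self, gauss_curve_exact):
        curve, _ = gauss_curve_exact
        sq = estimate_structure_factor(curve, curve, c_conc=1.0, c_dil=1.0)
        assert sq.S == pytest.approx(np.ones_like(sq.S), rel=1e-12)

    def test_recovers_constructed_py_factor(self, gauss_curve_exact):
        dilute, _ = gauss_curve_exact
        hs = HardSphereParams(R_hs=40.0, phi=0.1)
        S_true = hard_sphere_sq(hs, dilute.q)
        conc = ScatteringCurve(dilute.q, dilute.I * S_true * 10, dilute.sigma,
                               meta={"concentration": 10.0})
        sq = estimate_structure_factor(conc, dilute, c_conc=10.0, c_dil=1.0)
        assert sq.S == pytest.approx(S_true, rel=1e-10)

    def test_sigma_follows_quotient_propagation(self, rng):
        q = np.linspace(0.01, 0.3, 50)
        Ic = 2.0 + rng.random(50)
        Id = 1.0 + rng.random(50)
        sc, sd = 0.05 * Ic, 0.03 * Id
        sq = estimate_structure_factor(
            ScatteringCurve(q, Ic, sc), ScatteringCurve(q, Id, sd),
            c_conc=1.0, c_dil=1.0)
        expected = (Ic / Id) * np.sqrt((sc / Ic) ** 2 + (sd / Id) ** 2)
        assert sq.sigma == pytest.approx(expected, rel=1e-12)

    def test_negative_dilute_points_masked_with_warning(self):
        q = np.linspace(0.01, 0.3, 30)
        Ic = np.ones(30)
        Id = np.ones(30)
        Id[10] = -1.0
        with pytest.warns(UserWarning):
            sq = estimate_structure_factor(
                ScatteringCurve(q, Ic, 0.01 * Ic),
                ScatteringCurve(q, Id, np.full(30, 0.01)),
                c_conc=1.0, c_dil=1.0)
        assert np.all(np.isfinite(sq.S))


class TestHardSphere:
    def test_vanishing_volume_fraction_is_ideal(self):
        q = np.geomspace(1e-4, 1.0, 50)
        S = hard_sphere_sq(HardSphereParams(R_hs=30.0, phi=0.0), q)
        assert S == pytest.approx(np.ones_like(q))

    @pytest.mark.parametrize("phi", [0.05, 0.2])
    def test_compressibility_limit(self, phi):
        """S(0) = (1-phi)^4/(1+2 phi)^2, the PY compressibility value."""
        S0 = hard_sphere_sq(HardSphereParams(R_hs=30.0, phi=phi), np.array([0.0]))[0]
        assert S0 == pytest.approx((1 - phi) ** 4 / (1 + 2 * phi) ** 2, abs=1e-8)

    def test_large_q_asymptote(self):
        S = hard_sphere_sq(HardSphereParams(R_hs=30.0, phi=0.3), np.array([2.0]))
        assert S[0] == pytest.approx(1.0, abs=1e-3)

    def test_series_and_closed_form_join_smoothly(self):
        # kernel switch at A = 2 R q = 0.9
        hs = HardSphereParams(R_hs=1.0, phi=0.2)
        q = np.linspace(0.449, 0.451, 21)
        S = hard_sphere_sq(hs, q)
        assert np.all(np.abs(np.diff(S, 2)) < 1e-8)

    def test_fit_recovers_exact_curve(self):
        q = np.geomspace(0.005, 0.5, 80)
        truth = HardSphereParams(R_hs=35.0, phi=0.15)
        S = hard_sphere_sq(truth, q)
        fit = fit_hard_sphere(StructureFactorCurve(q, S, 0.01 * np.ones_like(S)))
        assert fit.params.R_hs == pytest.approx(truth.R_hs, rel=1e-6)
        assert fit.params.phi == pytest.approx(truth.phi, rel=1e-6)

    def test_fit_recovers_noisy_curve_within_three_sigma(self, rng):
        q = np.geomspace(0.005, 0.5, 80)
        truth = HardSphereParams(R_hs=35.0, phi=0.15)
        S = hard_sphere_sq(truth, q)
        sig = 0.02 * S
        noisy = S + rng.standard_normal(S.size) * sig
        fit = fit_hard_sphere(StructureFactorCurve(q, noisy, sig))
        assert abs(fit.params.R_hs - truth.R_hs) < 3 * fit.stderr.R_hs
        assert abs(fit.params.phi - truth.phi) < 3 * fit.stderr.phi

    def test_flat_input_yields_zero_volume_fraction(self):
        q = np.geomspace(0.005, 0.5, 60)
        fit = fit_hard_sphere(StructureFactorCurve(q, np.ones(60), np.full(60, 0.01)))
        assert fit.params.phi == pytest.approx(0.0, abs=1e-4)

    def test_phi_domain(self):
        with pytest.raises(ValueError):
            HardSphereParams(R_hs=30.0, phi=0.8)


class TestStiffSegment:
    def test_printed_examples(self):
        assert stiff_segment_q(19.1) == pytest.approx(0.1)
        assert stiff_segment_q(38.2) == pytest.approx(0.05)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            stiff_segment_q(0.0)
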