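"""Lineshape contracts: symmetry, normalization, oracles, Bingham limits."""

import numpy as np
import pytest
from scipy.integrate import quad

from fourpool.lineshapes import (
    BinghamODF,
    Lineshape,
    _sl_kernel,
    absorption_rate,
    bingham_g,
    bingham_odf_eval,
    gaussian_g,
    lorentzian_g,
    super_lorentzian_g,
)

T2 = 13e-6


def sl_oracle(dnu: float, t2: float) -> float:
    """Adaptive-quadrature reference for the orientation integral."""
    v, _ = quad(lambda c: _sl_kernel(dnu, t2, c), 0.0, 1.0,
                epsabs=1e-14, epsrel=1e-11, limit=400)
    return v


class TestSuperLorentzian:
    def test_even_function(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(1e3, 1e5, 100)
        np.testing.assert_allclose(super_lorentzian_g(d, T2),
                                   super_lorentzian_g(-d, T2), rtol=1e-12)

    def test_unit_area(self):
        """Total spectral area is one (including the central spike)."""
        parts = [quad(lambda d: super_lorentzian_g(d, T2, cutoff_hz=0.0),
                      a, b, limit=500)[0]
                 for a, b in ((1e-2, 1e3), (1e3, 1e5), (1e5, 2e6))]
        assert 2 * sum(parts) == pytest.approx(1.0, abs=1e-3)

    def test_strictly_decreasing_wing(self):
        d = np.linspace(5e3, 100e3, 300)
        g = super_lorentzian_g(d, T2)
        assert np.all(np.diff(g) < 0)

    def test_matches_adaptive_quadrature(self):
        for dnu in (2e3, 5e3, 15e3, 50e3, 200e3):
            for t2 in (8e-6, 13.3e-6, 25e-6):
                assert super_lorentzian_g(dnu, t2) == pytest.approx(
                    sl_oracle(dnu, t2), rel=1e-4)

    def test_on_resonance_refused(self):
        with pytest.raises(ValueError, match="effective-flip"):
            super_lorentzian_g(500.0, T2)


class TestOtherShapes:
    @pytest.mark.parametrize("fn", [gaussian_g, lorentzian_g])
    def test_unit_area_and_symmetry(self, fn):
        area, _ = quad(lambda d: fn(d, T2), -np.inf, np.inf)
        assert area == pytest.approx(1.0, abs=1e-3)
        assert fn(12e3, T2) == pytest.approx(fn(-12e3, T2), rel=1e-12)

    def test_nonpositive_t2_rejected(self):
        with pytest.raises(ValueError):
            gaussian_g(1e4, 0.0)


class TestAbsorptionRate:
    def test_quadratic_in_amplitude(self):
        shape = Lineshape("super_lorentzian")
        r1 = absorption_rate(1e4, 15e3, shape, T2)
        r2 = absorption_rate(2e4, 15e3, shape, T2)
        assert r2 == pytest.approx(4 * r1, rel=1e-12)

    def test_zero_amplitude(self):
        assert absorption_rate(0.0, 15e3, Lineshape("gaussian"), T2) == 0.0

    def test_against_quadrature_oracle(self):
        """R_RF = pi * w1^2 * g with g from independent adaptive quadrature."""
        shape = Lineshape("super_lorentzian")
        w1 = 2 * np.pi * 500.0
        for dnu in (5e3, 15e3, 40e3):
            expect = 0.5 * w1**2 * sl_oracle(dnu, 13.3e-6)
            assert absorption_rate(w1, dnu, shape, 13.3e-6) == pytest.approx(
                expect, rel=1e-4)


class TestBingham:
    def test_odf_eval_examples(self):
        odf = BinghamODF(kappa1=5.0, kappa2=5.0)
        assert bingham_odf_eval(odf.mu0, odf) == pytest.approx(1.0)
        assert bingham_odf_eval((1, 0, 0), odf) == pytest.approx(np.exp(-5))
        rng = np.random.default_rng(1)
        for _ in range(10):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            assert bingham_odf_eval(u, odf) == pytest.approx(
                bingham_odf_eval(-u, odf), rel=1e-12)

    def test_isotropic_limit_equals_super_lorentzian(self):
        odf = BinghamODF(0.0, 0.0)
        for dnu in (5e3, 20e3, 60e3):
            assert bingham_g(dnu, 11.3e-6, odf) == pytest.approx(
                super_lorentzian_g(dnu, 11.3e-6), rel=1e-6)

    def test_symmetric(self):
        odf = BinghamODF(2.0, 5.0, theta_fb_deg=70.0)
        assert bingham_g(20e3, 11.3e-6, odf) == pytest.approx(
            bingham_g(-20e3, 11.3e-6, odf), rel=1e-12)

    def test_against_independent_spherical_grid(self):
        """Dense trapezoidal lat-long quadrature as an independent oracle."""
        odf = BinghamODF(5.0, 5.0, theta_fb_deg=70.0)
        t2, dnu = 11.3e-6, 20e3
        n_t, n_p = 4000, 400
        th = (np.arange(n_t) + 0.5) * np.pi / n_t
        ph = (np.arange(n_p) + 0.5) * 2 * np.pi / n_p
        TH, PH = np.meshgrid(th, ph, indexing="ij")
        u = np.stack([np.sin(TH) * np.cos(PH), np.sin(TH) * np.sin(PH),
                      np.cos(TH)], axis=-1)
        w = np.sin(TH) * (np.pi / n_t) * (2 * np.pi / n_p)
        beta = bingham_odf_eval(u.reshape(-1, 3), odf).reshape(TH.shape)
        cos_a = u @ odf.field_direction()
        vals = _sl_kernel(dnu, t2, cos_a)
        oracle = np.sum(w * beta * vals) / np.sum(w * beta)
        assert bingham_g(dnu, t2, odf) == pytest.approx(oracle, rel=1e-6)

    def test_monotone_convergence_to_isotropic(self):
        sl = super_lorentzian_g(20e3, 11.3e-6)
        errs = [abs(bingham_g(20e3, 11.3e-6, BinghamODF(k, k)) - sl)
                for k in (1.0, 0.1, 0.01)]
        assert errs[0] > errs[1] > errs[2]

    def test_invalid_odf_rejected(self):
        with pytest.raises(ValueError):
            BinghamODF(5.0, 1.0)  # kappa1 > kappa2
        with pytest.raises(ValueError):
            BinghamODF(1.0, 2.0, mu1=(1, 0, 0), mu2=(1, 0, 0))
        with pytest.raises(ValueError):
            BinghamODF(1.0, 2.0, f0=0.0)
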