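"""Derived quantities, Arrhenius analysis and z-spectrum utilities."""

import numpy as np
import pytest
from scipy import constants

from fourpool.analysis import (
    arrhenius_fit,
    correlation_time,
    derived_quantities,
    mt_ratios,
    mtr_decomposition,
    simulate_zspectrum,
)


class TestDerivedQuantities:
    def test_mixing_time_from_reference_values(self, series):
        d21 = derived_quantities(series)[0]
        # 1 / (1.10 * (0.337 + 0.431))
        assert d21.tau_m == pytest.approx(1.1837, abs=1e-3)

    def test_transverse_shutter_time(self, series):
        d35 = derived_quantities(series)[2]
        # 1 / (26.85 - 8.19)
        assert d35.tau_2 == pytest.approx(0.05359, abs=1e-4)

    def test_corrected_fractions_sum_to_one(self, series):
        for d in derived_quantities(series):
            assert sum(d.corrected_fractions.values()) == pytest.approx(1.0,
                                                                        abs=1e-12)
            assert 0.0 <= d.mwf <= 1.0
            assert 0.0 <= d.mpf <= 1.0

    def test_degenerate_shutter_returns_sentinel(self, p35):
        p = p35.replace(R1_MW=p35.R1_IEW)
        d = derived_quantities(p, temperature_c=35.0)
        assert np.isinf(d.tau_1)

    def test_pure_closed_form(self, series):
        """Identical inputs give bitwise identical summaries."""
        a = derived_quantities(series)[1]
        b = derived_quantities(series)[1]
        assert a == b


class TestArrhenius:
    def test_exact_exponential_recovered(self):
        temps = np.array([294.0, 301.0, 308.0])
        k = 10.0 * np.exp(-20000.0 / (constants.R * temps))
        res = arrhenius_fit(k, temps, "rate", kelvin=True)
        assert res.ea_kj_mol == pytest.approx(20.0, rel=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.reliability == "reliable"
        assert res.prefactor == pytest.approx(10.0, rel=1e-9)

    def test_r1_convention_flips_sign(self):
        temps = np.array([294.0, 301.0, 308.0])
        tau = 1e-12 * np.exp(+15000.0 / (constants.R * temps))
        res = arrhenius_fit(tau, temps, "correlation_time", kelvin=True)
        assert res.ea_kj_mol == pytest.approx(15.0, rel=1e-9)

    def test_scattered_values_discarded(self):
        res = arrhenius_fit([1.0, 3.0, 1.1], [294.0, 301.0, 308.0],
                            "rate", kelvin=True)
        assert res.r_squared < 0.81
        assert res.reliability == "discarded"

    def test_input_validation(self):
        with pytest.raises(ValueError):
            arrhenius_fit([1.0, 2.0], [294.0, 301.0], "rate")
        with pytest.raises(ValueError):
            arrhenius_fit([1.0, -2.0, 3.0], [294.0, 301.0, 308.0], "rate")


class TestCorrelationTime:
    def test_scaling_laws(self):
        base = correlation_time(0.5, 1.5e-10)
        assert correlation_time(1.0, 1.5e-10) == pytest.approx(2 * base)
        assert correlation_time(0.5, 3.0e-10) == pytest.approx(64 * base)

    def test_myelin_water_rate_gives_about_19ps(self):
        tau = correlation_time(1.40, 151.5e-12)
        assert tau == pytest.approx(19.8e-12, rel=0.02)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            correlation_time(0.0)


class TestMTRatios:
    def test_no_saturation_gives_zero(self):
        out = mt_ratios(1.0, 1.0, 1.0, s_dual_cos=1.0, s_dual_alt=1.0)
        assert out["MTR"] == 0.0
        assert out["ihMTR_cos"] == 0.0
        assert out["ihMTR_alt"] == 0.0

    def test_complete_saturation(self):
        out = mt_ratios(1.0, 0.5, 0.5, s_dual_cos=0.0)
        assert out["MTR"] == 1.0

    def test_equal_dual_and_single_gives_zero_ihmtr(self):
        out = mt_ratios(1.0, 0.6, 0.6, s_dual_cos=0.6)
        assert out["ihMTR_cos"] == pytest.approx(0.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            mt_ratios(0.0, 1.0, 1.0, s_dual_cos=1.0)


class TestZSpectrum:
    def test_symmetric_saturation(self, p35):
        """Single-sided spectra are even in the offset for even lineshapes."""
        sp = simulate_zspectrum(p35, "MT+", offsets_hz=(12e3,), n_rf=50)
        sm = simulate_zspectrum(p35, "MT-", offsets_hz=(12e3,), n_rf=50)
        assert sp.s_over_s0[0] == pytest.approx(sm.s_over_s0[0], abs=1e-8)

    def test_decomposition_vanishes_without_mt(self, p35):
        p = p35.replace(k_IEW_NM=0.0, k_MW_M=0.0)
        mtr = mtr_decomposition(p, "total", offsets_hz=(5e3, 20e3, 50e3),
                                b1_rms=50.0, n_rf=100)
        assert np.all(mtr < 0.01)

    def test_components_additive_at_low_power(self, p35):
        offs = (5e3, 10e3)
        kw = dict(offsets_hz=offs, b1_rms=50.0, n_rf=100)
        tot = mtr_decomposition(p35, "total", **kw)
        nm = mtr_decomposition(p35, "NM", **kw)
        m = mtr_decomposition(p35, "M", **kw)
        np.testing.assert_allclose(nm + m, tot, rtol=0.10)

    def test_result_validates_range(self):
        from fourpool.analysis import ZSpectrumResult
        with pytest.raises(ValueError):
            ZSpectrumResult(offsets_hz=(1e4,), mode="MTcos",
                            s_over_s0=(1.2,), te=4e-3)
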