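"""Parameter packing, estimation machinery and the biexponential fit."""

import numpy as np
import pandas as pd
import pytest

from fourpool.fitting import (
    FourPoolModel,
    ParameterVector,
    biexp_fit,
    confidence_and_correlation,
    two_pool_start,
)
from fourpool.synthetic import EchoTrainDataset


class TestParameterVector:
    def test_pack_unpack_roundtrip_4pm(self, series):
        spec = ParameterVector.four_pool(series.temperatures_c)
        x = spec.pack(series)
        back = spec.unpack(x, series)
        np.testing.assert_allclose(spec.pack(back), x, rtol=1e-14)
        for t in series.temperatures_c:
            assert back.at(t).A_BW == pytest.approx(series.at(t).A_BW,
                                                    abs=1e-14)

    def test_default_free_parameter_count_is_44(self, series):
        spec = ParameterVector.four_pool(series.temperatures_c)
        assert spec.n_free == 44
        assert len(spec.affected_temps()) == 44

    def test_pack_unpack_roundtrip_2pm(self, series):
        spec = ParameterVector.two_pool(series.temperatures_c)
        assert spec.n_free == 24
        start2 = two_pool_start(series)
        x = spec.pack(start2)
        back = spec.unpack(x, start2)
        np.testing.assert_allclose(spec.pack(back), x, rtol=1e-14)
        p = back.entries[0]
        assert p.A_MW == 0.0 and p.A_M == 0.0
        assert p.A_IEW + p.A_NM + p.A_BW == pytest.approx(1.0, abs=1e-14)

    def test_fixed_entries_not_packed(self, series):
        spec = ParameterVector.four_pool(series.temperatures_c,
                                         fixed=("f_b1", "R1_BW", "R2_BW"))
        assert spec.n_free == 44 - 1 - 6

    def test_simplex_overflow_renormalized(self, series):
        spec = ParameterVector.four_pool(series.temperatures_c)
        x = spec.pack(series)
        x[:4] = (0.4, 0.4, 0.2, 0.2)  # tissue fractions sum to 1.2
        back = spec.unpack(x, series)
        fr = back.entries[0].fractions()
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)
        assert fr["BW"] == 0.0


class TestModelObjective:
    def test_residual_zero_at_truth(self, series, reduced_setup):
        suite, flips, ds = reduced_setup
        model = FourPoolModel(ds, suite=suite, flips=flips)
        r = model._residual(model.spec.pack(series), series)
        assert np.max(np.abs(r)) < 1e-12

    def test_invariant_to_row_order(self, series, reduced_setup):
        suite, flips, ds = reduced_setup
        shuffled = ds.frame.sample(frac=1.0, random_state=0)
        m1 = FourPoolModel(ds, suite=suite, flips=flips)
        m2 = FourPoolModel(EchoTrainDataset(frame=shuffled, flips=flips),
                           suite=suite, flips=flips)
        np.testing.assert_array_equal(m1.y, m2.y)

    def test_start_outside_bounds_rejected(self, series, reduced_setup):
        suite, flips, ds = reduced_setup
        spec = ParameterVector.four_pool(
            series.temperatures_c, bounds={"f_b1": (0.99, 1.1)})
        model = FourPoolModel(ds, suite=suite, flips=flips, spec=spec)
        with pytest.raises(ValueError, match="bounds"):
            model.fit(series)

    def test_restricted_fit_recovers_perturbed_rates(self, series,
                                                     reduced_setup):
        """Freeing only the aqueous R2s, the fit returns to the truth."""
        suite, flips, ds = reduced_setup
        sub = ds.frame[ds.frame["temperature"] == 35.0]
        free = {"R2_IEW", "R2_MW"}
        fixed = tuple(n for n in
                      ParameterVector.four_pool((35.0,)).shared_names +
                      ParameterVector.four_pool((35.0,)).per_temp_names
                      if n not in free)
        spec = ParameterVector.four_pool((35.0,), fixed=fixed)
        model = FourPoolModel(EchoTrainDataset(frame=sub, flips=flips),
                              suite=suite, flips=flips, spec=spec)
        p35 = series.at(35.0)
        start = series.from_pairs([(35.0, p35.replace(
            R2_IEW=p35.R2_IEW * 1.05, R2_MW=p35.R2_MW * 0.95))])
        res = model.fit(start)
        assert res.series.at(35.0).R2_IEW == pytest.approx(p35.R2_IEW,
                                                           rel=1e-6)
        assert res.series.at(35.0).R2_MW == pytest.approx(p35.R2_MW,
                                                          rel=1e-6)


class TestConfidence:
    def test_ci_scales_linearly_with_noise(self):
        rng = np.random.default_rng(0)
        jac = rng.normal(size=(100, 3))
        resid = rng.normal(size=100)
        ci1, corr1, _, _ = confidence_and_correlation(jac, resid)
        ci2, corr2, _, _ = confidence_and_correlation(jac, 2 * resid)
        np.testing.assert_allclose(ci2, 2 * ci1, rtol=1e-12)
        np.testing.assert_allclose(corr1, corr2, atol=1e-12)

    def test_correlation_matrix_contract(self):
        rng = np.random.default_rng(1)
        jac = rng.normal(size=(50, 4))
        _, corr, cov, flag = confidence_and_correlation(
            jac, rng.normal(size=50))
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        assert not flag


class TestBiexp:
    def test_exact_recovery(self):
        te = np.arange(1, 81) * 4e-3
        y = 0.5 * np.exp(-te / 0.030) + 0.5 * np.exp(-te / 0.120)
        fit = biexp_fit(y, te)
        assert not fit.degenerate
        assert fit.t2_short == pytest.approx(0.030, rel=1e-6)
        assert fit.t2_long == pytest.approx(0.120, rel=1e-6)
        assert fit.frac_short == pytest.approx(0.5, rel=1e-6)

    def test_monoexponential_flagged_degenerate(self):
        te = np.arange(1, 41) * 4e-3
        fit = biexp_fit(np.exp(-te / 0.05), te)
        assert fit.degenerate

    def test_too_few_echoes_rejected(self):
        with pytest.raises(ValueError):
            biexp_fit([1, 0.9, 0.8], [0.004, 0.008, 0.012])

    def test_nonpositive_amplitudes_rejected(self):
        te = np.arange(1, 11) * 4e-3
        with pytest.raises(ValueError):
            biexp_fit(np.linspace(1, -0.1, 10), te)


def test_two_pool_start_is_valid_series(series):
    s2 = two_pool_start(series)
    for _, p in s2:
        assert p.A_IEW + p.A_NM + p.A_BW == pytest.approx(1.0, abs=1e-12)
        assert p.A_MW == 0.0 and p.A_M == 0.0
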