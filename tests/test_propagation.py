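"""Propagator algebra, RF events, spoiling and full-protocol evolution."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fourpool.pools import build_generator, equilibrium_state
from fourpool.propagation import (
    RFEvent,
    SequenceEngine,
    apply_rf_event,
    echo_amplitude,
    effective_flip_table,
    perfect_spoil,
    propagate_interval,
)
from fourpool.protocols import (
    build_protocol,
    cosine_mt_pulse,
    cpmg_protocol,
    rect_pulse,
    ti_grid,
)

from test_pools import random_params


def decoupled_water(p):
    return p.replace(k_IEW_MW=0.0, k_IEW_NM=0.0, k_MW_M=0.0)


class TestPropagateInterval:
    def test_zero_interval_is_identity(self, p35):
        L = build_generator(p35)
        np.testing.assert_array_equal(propagate_interval(L, 0.0).matrix,
                                      np.eye(12))

    def test_semigroup_property(self, p35):
        L = build_generator(p35, 1e3, 0.0, 2e3, "transparent")
        p_ab = propagate_interval(L, 7e-3).matrix
        p_a = propagate_interval(L, 3e-3).matrix
        p_b = propagate_interval(L, 4e-3).matrix
        np.testing.assert_allclose(p_ab, p_b @ p_a, atol=1e-10)

    def test_negative_duration_rejected(self, p35):
        with pytest.raises(ValueError):
            propagate_interval(build_generator(p35), -1e-3)

    def test_ir_recovery_closed_form(self, p35):
        """Decoupled pool relaxes as Mz(t) = A + (Mz0 - A) exp(-R1 t)."""
        p = decoupled_water(p35)
        L = build_generator(p)
        m = equilibrium_state(p)
        m[3] = -p.A_IEW  # inverted IEW
        for t in (0.05, 0.4, 2.0):
            mt = propagate_interval(L, t).matrix @ m
            expect = p.A_IEW + (-p.A_IEW - p.A_IEW) * np.exp(-p.R1_IEW * t)
            assert mt[3] == pytest.approx(expect, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_matches_ode_integration(self, seed):
        """exp(-dt L) agrees with adaptive ODE integration of the system."""
        p = random_params(seed)
        L = build_generator(p, 2e3, 1e3, 8e3, "transparent")
        m0 = equilibrium_state(p)
        m0[1], m0[3] = 0.2, 0.1
        m_prop = propagate_interval(L, 10e-3).matrix @ m0
        sol = solve_ivp(lambda t, y: -L @ y, (0, 10e-3), m0,
                        rtol=1e-11, atol=1e-14, method="DOP853")
        np.testing.assert_allclose(m_prop, sol.y[:, -1], atol=1e-8)


class TestRFEvents:
    def test_effective_flip_zero_leaves_semisolid(self, p35):
        ev = rect_pulse(180.0, 40e-6, label="inv")
        m = equilibrium_state(p35)
        out = apply_rf_event(m, ev, p35, flips={"inv": (0.0, 0.0)})
        assert out[4] == pytest.approx(m[4], rel=1e-6)
        assert out[8] == pytest.approx(m[8], rel=1e-6)

    def test_effective_flip_180_inverts_semisolid(self, p35):
        ev = rect_pulse(180.0, 40e-6, label="inv")
        m = equilibrium_state(p35)
        out = apply_rf_event(m, ev, p35, flips={"inv": (np.pi, np.pi)})
        assert out[4] == pytest.approx(-m[4], rel=1e-6)
        assert out[8] == pytest.approx(-m[8], rel=1e-6)

    def test_pure_nutation_rotates_z_to_transverse(self, p35):
        p = decoupled_water(p35).replace(R1_IEW=0.0, R2_IEW=0.0, f_b1=1.0)
        ev = rect_pulse(90.0, 40e-6, semisolid="transparent", label="p90")
        out = apply_rf_event(equilibrium_state(p), ev, p)
        assert abs(out[3]) < 1e-9
        assert abs(out[2]) == pytest.approx(p.A_IEW, abs=1e-9)

    def test_effective_flip_requires_on_resonance(self):
        with pytest.raises(ValueError):
            RFEvent(amp_hz=(1e4,), seg_dur=1e-5, offset_hz=2e3,
                    semisolid="effective_flip")

    def test_f_b1_scales_rotation(self, p35):
        p = decoupled_water(p35).replace(R1_IEW=0.0, R2_IEW=0.0)
        ev = rect_pulse(90.0, 20e-6, semisolid="transparent", label="p90")
        out_nom = apply_rf_event(equilibrium_state(p.replace(f_b1=1.0)), ev,
                                 p.replace(f_b1=1.0))
        assert abs(out_nom[3]) < 1e-9
        p_cal = p.replace(f_b1=0.985)
        out_cal = apply_rf_event(equilibrium_state(p_cal), ev, p_cal)
        expect = p.A_IEW * np.cos(0.985 * np.pi / 2)
        assert out_cal[3] == pytest.approx(expect, abs=1e-9)

    def test_shaped_pulse_grid_matches_exact_segments(self, p35):
        """Amplitude-grid interpolation stays within its 1e-5 error budget."""
        from scipy.linalg import expm
        ev = cosine_mt_pulse(750.0, 0.25e-3)
        eng = SequenceEngine(p35)
        p_grid = eng.pulse(ev)
        exact = np.eye(12)
        for a, f in zip(ev.amp_hz, ev.phases()):
            exact = expm(-ev.seg_dur * eng._segment_generator(a, f, ev)) @ exact
        assert np.max(np.abs(p_grid - exact)) < 1e-5


class TestPerfectSpoil:
    def test_equilibrium_unchanged(self, p35):
        m = equilibrium_state(p35)
        np.testing.assert_array_equal(perfect_spoil(m), m)

    def test_transverse_zeroed_longitudinal_kept(self, p35):
        m = equilibrium_state(p35)
        m[1], m[6], m[9] = 0.3, -0.1, 0.05
        out = perfect_spoil(m)
        assert out[1] == out[6] == out[9] == 0.0
        assert out[3] == m[3] and out[4] == m[4]

    def test_idempotent(self, p35):
        m = np.arange(12, dtype=float)
        np.testing.assert_array_equal(perfect_spoil(perfect_spoil(m)),
                                      perfect_spoil(m))


class TestSimulateProtocol:
    def test_equilibrium_cpmg_conserves_with_no_decay(self, p35):
        """With R2 = 0 and exchange off, the first echo is the aqueous sum."""
        p = decoupled_water(p35).replace(R2_IEW=0.0, R2_MW=0.0, R2_BW=0.0)
        prot = cpmg_protocol(n_echo=8, tr=60.0)  # fully relaxed
        eng = SequenceEngine(p, effective_flip_table(prot.rf_events(), p))
        amps = eng.simulate(prot)
        target = p.A_IEW + p.A_MW + p.A_BW
        assert amps[0, 0] == pytest.approx(target, abs=5e-4)

    def test_long_ti_recovers_unprepared_signal(self, p35):
        ir = build_protocol(1, n_echo=8, prep_values=(10.0,))
        ref = cpmg_protocol(n_echo=8)
        flips = effective_flip_table(ir.rf_events(), p35)
        eng = SequenceEngine(p35, flips)
        a_ir = eng.simulate(ir)[0, 0]
        a_ref = eng.simulate(ref)[0, 0]
        assert a_ir == pytest.approx(a_ref, rel=0.01)

    def test_amplitudes_bounded(self, p35):
        prot = build_protocol(3, n_echo=12, prep_values=ti_grid(6))
        amps = SequenceEngine(
            p35, effective_flip_table(prot.rf_events(), p35)).simulate(prot)
        assert np.all(amps >= 0.0) and np.all(amps <= 1.0)

    def test_steady_state_solve_matches_iteration(self, p35):
        prot = build_protocol(7, n_echo=10, prep_values=(100,))
        eng = SequenceEngine(p35, effective_flip_table(prot.rf_events(), p35))
        first, unit, total, read_dur = eng._readout(prot)
        p_prep, prep_dur = eng.compose(prot.expand(100))
        cycle = eng.free(prot.tr - prep_dur - read_dur) @ eng.spoil \
            @ total @ p_prep
        m_solve = eng.steady_state(cycle)
        m_iter = equilibrium_state(p35)
        for _ in range(60):
            m_iter = cycle @ m_iter
        np.testing.assert_allclose(m_solve, m_iter, atol=1e-10)

    def test_events_exceeding_tr_rejected(self, p35):
        prot = build_protocol(1, n_echo=80, prep_values=(12.9,))
        eng = SequenceEngine(p35, effective_flip_table(prot.rf_events(), p35))
        with pytest.raises(ValueError, match="exceed TR"):
            eng.simulate(prot)
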