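"""The relaxometry protocol suite and z-spectrum acquisitions.

Twenty-two preparation schemes, all sharing one CPMG readout (echo spacing
4 ms, 20 us rectangular excitation, 200 us composite refocusing):

* 1-2    inversion recovery with a 40 us hard or a 5 ms adiabatic (BIR-4)
         inversion pulse; 23 log-spaced evolution times in [770 us, 10 s],
         TR = 13 s.
* 3      transient magnetization transfer: a 6 ms composite on-resonant MT
         pulse (16 alternating-phase rectangular sub-pulses) that saturates
         the semisolid pools, followed by the same evolution-time grid.
* 4-12   steady-state MT: trains of cosine-modulated Gaussian pulses
         (tau_p = 2 ms, bands at +-15 kHz), 16 acquisitions with the pulse
         count stepping 20..320; three RMS amplitudes (500/750/1000 Hz)
         crossed with three inter-pulse gaps (0.25/2.25/4.25 ms); TR = 6 s.
* 13-16  Goldman-Shen filters: 90x - tau_f - 90(-+x) with tau_f = 1 or
         50 ms, storing the surviving magnetization up or down, then the
         evolution-time grid.
* 17-22  steady-state MT preparation followed by (optionally) a hard
         inversion and continued MT irradiation during the evolution period
         whenever it fits (TI > tau_s + tau_p).

z-spectra use a 300-pulse Gaussian saturation train at 42 offsets with four
saturation modes (single-sided +, single-sided -, alternating dual-sided,
cosine-modulated dual-sided) and a single-sample readout at a given TE.

Exact evolution-time lists and some train parameters of the original
acquisitions are not published; the defaults here are nominal
reconstructions (documented in docs/methods.md) and everything is
overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .propagation import RFEvent

__all__ = [
    "ProtocolSpec",
    "build_protocol",
    "build_zspectrum_protocol",
    "full_suite",
    "reduced_suite",
    "cpmg_protocol",
    "cosine_modulated_envelope",
    "gaussian_envelope",
    "rect_pulse",
    "excitation_90",
    "composite_refocus",
    "inversion_rect",
    "mt_composite_pulse",
    "bir4_pulse",
    "gaussian_mt_pulse",
    "cosine_mt_pulse",
    "ZSPEC_OFFSETS_HZ",
    "suite_counts",
]

DTE = 4e-3                  # CPMG echo spacing (s)
N_ECHO_DEFAULT = 80
TI_MIN, TI_MAX = 770e-6, 10.0
MT_TAU_P = 2e-3             # MT pulse duration (s)
MT_DNU_HZ = 15e3            # cosine-modulation band offset (Hz)
N_RF_PRE_DEFAULT = 100      # pre-inversion train length, protocols 17-22
SEG_SHAPED = 10e-6          # segment length for shaped pulses (s)
SEG_MODULATED = 2e-6        # segment length for cosine-modulated pulses (s)

#: printed z-spectrum offset list: 0-30 kHz in 1 kHz steps, 32-40 in 2 kHz
#: steps, then 45, 50, 60, 70, 80, 95 kHz (42 values)
ZSPEC_OFFSETS_HZ = tuple(
    1e3 * v for v in (*range(0, 31), *range(32, 41, 2), 45, 50, 60, 70, 80, 95)
)


def ti_grid(n: int = 23) -> tuple[float, ...]:
    """Logarithmically spaced evolution times over [770 us, 10 s]."""
    return tuple(np.geomspace(TI_MIN, TI_MAX, n))


def n_rf_grid(n: int = 16, step: int = 20) -> tuple[int, ...]:
    """Pulse-count schedule for steady-state MT (20, 40, ..., 320)."""
    return tuple(step * (i + 1) for i in range(n))


# ---------------------------------------------------------------------------
# pulses

def rect_pulse(flip_deg: float, duration: float, phase: float = 0.0,
               semisolid: str = "effective_flip", label: str = "") -> RFEvent:
    """Single-segment rectangular pulse at a nominal water flip angle."""
    amp = (flip_deg / 360.0) / duration
    return RFEvent(amp_hz=(amp,), seg_dur=duration, phase=phase,
                   semisolid=semisolid, label=label)


def excitation_90() -> RFEvent:
    return rect_pulse(90.0, 20e-6, label="exc90")


def inversion_rect() -> RFEvent:
    return rect_pulse(180.0, 40e-6, label="inv_rect")


def composite_refocus() -> RFEvent:
    """90x-180y-90x composite refocusing pulse, 200 us total.

    Semisolid handling is ``transparent``: no absorption term (the pulse is
    on-resonant) and no effective-flip factor, but relaxation and
    magnetization transfer stay active throughout, which is the pathway
    that couples the semisolid pools into the CPMG decay.
    """
    tau = 200e-6 / 3.0
    a90 = 0.25 / tau
    a180 = 0.5 / tau
    return RFEvent(amp_hz=(a90, a180, a90), seg_dur=tau,
                   phase=(0.0, np.pi / 2, 0.0), semisolid="transparent",
                   label="refocus")


def mt_composite_pulse(n_sub: int = 16, duration: float = 6e-3) -> RFEvent:
    """Composite on-resonant MT pulse (transient MT preparation).

    Nominal reconstruction: alternating-phase rectangular sub-pulses, each
    a nominal 360 degrees on water (zero net water rotation), whose
    cumulative action saturates the semisolid pools; the semisolid effect
    enters through the effective-flip table.
    """
    sub = duration / n_sub
    amp = 1.0 / sub  # 360 degrees per sub-pulse
    phases = tuple(0.0 if i % 2 == 0 else np.pi for i in range(n_sub))
    return RFEvent(amp_hz=(amp,) * n_sub, seg_dur=sub, phase=phases,
                   semisolid="effective_flip", label="mt_comp")


def bir4_pulse(flip_deg: float = 180.0, duration: float = 5e-3,
               peak_hz: float = 864.0, zeta: float = 10.0,
               tan_kappa: float = 20.0, dw_max_hz: float = 10e3,
               seg_dur: float = SEG_SHAPED) -> RFEvent:
    """BIR-4 adiabatic pulse with tanh/tan amplitude/frequency modulation.

    The frequency sweep is folded into the per-segment phase, with the two
    standard phase jumps of +-(pi + flip/2) at tau_p/4 and 3 tau_p/4.  The
    vendor's exact modulation is not public; this nominal shape is adequate
    because residual imperfection is absorbed by the fitted/supplied
    effective flip angles.
    """
    n = max(4, int(round(duration / seg_dur)))
    t = (np.arange(n) + 0.5) * (duration / n)
    x = 4.0 * t / duration  # in [0, 4)
    kappa = np.arctan(tan_kappa)

    seg = np.minimum(x.astype(int), 3)
    xr = x - seg  # position within quarter, [0, 1)
    amp = np.where((seg == 0) | (seg == 2),
                   np.tanh(zeta * (1.0 - xr)), np.tanh(zeta * xr)) * peak_hz
    sweep_arg = np.where(seg == 0, xr,
                         np.where(seg == 3, xr - 1.0,
                                  np.where(seg == 1, xr - 1.0, xr)))
    dw = dw_max_hz * np.tan(kappa * sweep_arg) / tan_kappa

    phase = np.cumsum(2.0 * np.pi * dw * (duration / n))
    dphi = np.pi + np.deg2rad(flip_deg) / 2.0
    phase = phase + np.where(x >= 1.0, dphi, 0.0) - np.where(x >= 3.0, 2 * dphi, 0.0)
    return RFEvent(amp_hz=tuple(amp), seg_dur=duration / n,
                   phase=tuple(phase), semisolid="effective_flip",
                   label="inv_bir4")


def gaussian_envelope(tau_p: float, n_seg: int) -> np.ndarray:
    """Unit-peak truncated Gaussian (sigma = tau_p/6), segment centers."""
    t = (np.arange(n_seg) + 0.5) * (tau_p / n_seg)
    sigma = tau_p / 6.0
    return np.exp(-0.5 * ((t - tau_p / 2.0) / sigma) ** 2)


def cosine_modulated_envelope(tau_p: float, dnu_hz: float, b1_rms_hz: float,
                              tau_s: float = 0.0,
                              seg_dur: float = SEG_MODULATED) -> np.ndarray:
    """Cosine-modulated Gaussian MT envelope, sampled (amplitudes in Hz).

    The Gaussian carrier is multiplied by cos(2*pi*dnu*t), producing equal
    spectral bands at +-dnu, and the peak is scaled so that the
    root-mean-squared amplitude over one train period (pulse plus gap
    ``tau_s``) equals ``b1_rms_hz``; for dnu != 0 this reproduces the
    sqrt(2) amplitude scaling relative to an unmodulated pulse.
    """
    if tau_p <= 0:
        raise ValueError("tau_p must be > 0")
    if dnu_hz != 0.0:
        # resolve the modulation with at least 10 segments per carrier cycle
        seg_dur = min(seg_dur, 1.0 / (10.0 * abs(dnu_hz)))
    n = max(2, int(round(tau_p / seg_dur)))
    t = (np.arange(n) + 0.5) * (tau_p / n)
    env = gaussian_envelope(tau_p, n) * np.cos(2.0 * np.pi * dnu_hz * (t - tau_p / 2.0))
    rms = np.sqrt(np.sum(env**2) * (tau_p / n) / (tau_p + tau_s))
    return env * (b1_rms_hz / rms)


def cosine_mt_pulse(b1_rms_hz: float, tau_s: float, dnu_hz: float = MT_DNU_HZ,
                    tau_p: float = MT_TAU_P) -> RFEvent:
    """One cosine-modulated MT pulse of a steady-state saturation train."""
    env = cosine_modulated_envelope(tau_p, dnu_hz, b1_rms_hz, tau_s)
    return RFEvent(amp_hz=tuple(env), seg_dur=tau_p / len(env),
                   offset_hz=0.0, sat_offset_hz=abs(dnu_hz),
                   semisolid="absorption",
                   label=f"mtcos_b{b1_rms_hz:g}_s{tau_s * 1e3:g}_d{dnu_hz:g}")


def gaussian_mt_pulse(offset_hz: float, b1_rms_hz: float, tau_s: float,
                      tau_p: float = MT_TAU_P,
                      seg_dur: float = SEG_SHAPED) -> RFEvent:
    """One off-resonant Gaussian MT pulse (single-sided saturation)."""
    n = max(2, int(round(tau_p / seg_dur)))
    env = gaussian_envelope(tau_p, n)
    rms = np.sqrt(np.sum(env**2) * (tau_p / n) / (tau_p + tau_s))
    env = env * (b1_rms_hz / rms)
    return RFEvent(amp_hz=tuple(env), seg_dur=tau_p / n, offset_hz=offset_hz,
                   sat_offset_hz=offset_hz, semisolid="absorption",
                   label=f"mtg_o{offset_hz:g}_b{b1_rms_hz:g}_s{tau_s * 1e3:g}")


def gs_pulse(phase: float, label: str) -> RFEvent:
    return rect_pulse(90.0, 20e-6, phase=phase, label=label)


# ---------------------------------------------------------------------------

@dataclass
class ProtocolSpec:
    """Declarative description of one preparation + readout experiment."""

    id: int | str
    kind: str                       # none | IR_rect | IR_bir4 | transient_MT |
                                    # steady_MT | GS | IR_plus_MT | zspec
    prep_values: tuple              # TI (s), N_RF, or offset (Hz) per acquisition
    tr: float
    n_echo: int = N_ECHO_DEFAULT
    dte: float = DTE
    readout_kind: str = "cpmg"      # cpmg | fid
    te: float | None = None         # fid readout sampling time
    exc_pulse: RFEvent = field(default_factory=excitation_90)
    ref_pulse: RFEvent = field(default_factory=composite_refocus)
    inv_pulse: RFEvent | None = None
    mt_pulse: RFEvent | None = None
    mt_pulse_alt: RFEvent | None = None
    tau_s: float | None = None
    n_rf_pre: int = 0
    tau_f: float | None = None
    gs_first: RFEvent | None = None
    gs_final: RFEvent | None = None
    invert: bool = False
    mt_mode: str | None = None
    b1_rms: float | None = None

    def __post_init__(self) -> None:
        if self.n_echo < 1:
            raise ValueError("n_echo must be >= 1")
        if self.readout_kind == "fid" and self.te is None:
            raise ValueError("fid readout requires te")

    # -- helpers ---------------------------------------------------------
    def _evolution_delay(self, ti: float, prep_pulse: RFEvent | None) -> float:
        """Evolution delay from preparation to excitation for a given TI.

        TI is measured from the center of short preparation pulses and from
        the end of long (>= 1 ms) ones.
        """
        d = ti - self.exc_pulse.duration / 2.0
        if prep_pulse is not None and prep_pulse.duration < 1e-3:
            d -= prep_pulse.duration / 2.0
        if d < 0:
            raise ValueError(f"evolution time {ti} too short for pulse timing")
        return d

    def expand(self, value) -> list:
        """Preparation steps of one acquisition (see SequenceEngine.compose)."""
        k = self.kind
        if k == "none":
            return []
        if k in ("IR_rect", "IR_bir4"):
            return [("pulse", self.inv_pulse), ("spoil",),
                    ("delay", self._evolution_delay(value, self.inv_pulse))]
        if k == "transient_MT":
            return [("pulse", self.mt_pulse), ("spoil",),
                    ("delay", self._evolution_delay(value, self.mt_pulse))]
        if k == "steady_MT":
            return [("train", self.mt_pulse, self.tau_s, int(value)), ("spoil",)]
        if k == "GS":
            return [("pulse", self.gs_first), ("delay", self.tau_f),
                    ("pulse", self.gs_final), ("spoil",),
                    ("delay", self._evolution_delay(value, self.gs_final))]
        if k == "IR_plus_MT":
            steps: list = [("train", self.mt_pulse, self.tau_s, self.n_rf_pre),
                           ("spoil",)]
            prep = self.inv_pulse if self.invert else None
            if self.invert:
                steps += [("pulse", self.inv_pulse), ("spoil",)]
            ti_eff = self._evolution_delay(value, prep)
            unit = self.mt_pulse.duration + self.tau_s
            if value > unit:
                n_fill = int(ti_eff // unit)
                steps += [("train", self.mt_pulse, self.tau_s, n_fill),
                          ("delay", ti_eff - n_fill * unit)]
            else:
                steps += [("delay", ti_eff)]
            return steps
        if k == "zspec":
            return self._expand_zspec(value)
        raise ValueError(f"unknown protocol kind {k!r}")

    def _expand_zspec(self, offset_hz: float) -> list:
        n = self.n_rf_pre
        if self.mt_mode == "MTcos":
            ev = cosine_mt_pulse(self.b1_rms, self.tau_s, dnu_hz=offset_hz)
            return [("train", ev, self.tau_s, n), ("spoil",)]
        if self.mt_mode == "MT+":
            ev = gaussian_mt_pulse(offset_hz, self.b1_rms, self.tau_s)
            return [("train", ev, self.tau_s, n), ("spoil",)]
        if self.mt_mode == "MT-":
            ev = gaussian_mt_pulse(-offset_hz, self.b1_rms, self.tau_s)
            return [("train", ev, self.tau_s, n), ("spoil",)]
        if self.mt_mode == "MT+-":
            ev = gaussian_mt_pulse(offset_hz, self.b1_rms, self.tau_s)
            ev2 = gaussian_mt_pulse(-offset_hz, self.b1_rms, self.tau_s)
            return [("train", ev, self.tau_s, n, ev2), ("spoil",)]
        raise ValueError(f"unknown z-spectrum mode {self.mt_mode!r}")

    def rf_events(self) -> list[RFEvent]:
        """All RF events of this protocol (for effective-flip calibration)."""
        evs = [self.exc_pulse, self.ref_pulse]
        for ev in (self.inv_pulse, self.mt_pulse, self.mt_pulse_alt,
                   self.gs_first, self.gs_final):
            if ev is not None:
                evs.append(ev)
        return evs

    def with_overrides(self, **kw) -> "ProtocolSpec":
        return replace(self, **kw)


# ---------------------------------------------------------------------------

_STEADY_MT_GRID = {
    pid: (b1, ts)
    for pid, (b1, ts) in enumerate(
        ((b1, ts) for b1 in (500.0, 750.0, 1000.0)
         for ts in (0.25e-3, 2.25e-3, 4.25e-3)), start=4)
}
_GS_GRID = {13: (1e-3, "up"), 14: (1e-3, "down"),
            15: (50e-3, "up"), 16: (50e-3, "down")}
_IRMT_GRID = {17: (0.25e-3, True), 18: (0.25e-3, False),
              19: (2.25e-3, True), 20: (2.25e-3, False),
              21: (4.25e-3, True), 22: (4.25e-3, False)}
_IRMT_B1_RMS = 750.0   # nominal train amplitude for protocols 17-22


def build_protocol(pid: int, *, n_echo: int = N_ECHO_DEFAULT,
                   prep_values: Sequence | None = None,
                   b1_rms: float | None = None, tau_s: float | None = None,
                   n_rf_pre: int = N_RF_PRE_DEFAULT) -> ProtocolSpec:
    """Build one of the 22 relaxometry protocols by id."""
    if pid in (1, 2):
        inv = inversion_rect() if pid == 1 else bir4_pulse()
        return ProtocolSpec(id=pid, kind="IR_rect" if pid == 1 else "IR_bir4",
                            prep_values=tuple(prep_values) if prep_values else ti_grid(),
                            tr=13.0, n_echo=n_echo, inv_pulse=inv)
    if pid == 3:
        return ProtocolSpec(id=pid, kind="transient_MT",
                            prep_values=tuple(prep_values) if prep_values else ti_grid(),
                            tr=13.0, n_echo=n_echo, mt_pulse=mt_composite_pulse())
    if pid in _STEADY_MT_GRID:
        b1_def, ts_def = _STEADY_MT_GRID[pid]
        b1 = b1_rms if b1_rms is not None else b1_def
        ts = tau_s if tau_s is not None else ts_def
        if b1 not in (500.0, 750.0, 1000.0):
            raise ValueError("B1_RMS must be one of 500/750/1000 Hz")
        if round(ts * 1e3, 3) not in (0.25, 2.25, 4.25):
            raise ValueError("tau_s must be one of 0.25/2.25/4.25 ms")
        return ProtocolSpec(id=pid, kind="steady_MT",
                            prep_values=tuple(prep_values) if prep_values else n_rf_grid(),
                            tr=6.0, n_echo=n_echo, tau_s=ts,
                            mt_pulse=cosine_mt_pulse(b1, ts))
    if pid in _GS_GRID:
        tau_f, direction = _GS_GRID[pid]
        final_phase = np.pi if direction == "up" else 0.0
        return ProtocolSpec(id=pid, kind="GS",
                            prep_values=tuple(prep_values) if prep_values else ti_grid(),
                            tr=13.0, n_echo=n_echo, tau_f=tau_f,
                            gs_first=gs_pulse(0.0, "gs90_x"),
                            gs_final=gs_pulse(final_phase,
                                              "gs90_mx" if direction == "up" else "gs90_px"))
    if pid in _IRMT_GRID:
        ts_def, invert = _IRMT_GRID[pid]
        ts = tau_s if tau_s is not None else ts_def
        b1 = b1_rms if b1_rms is not None else _IRMT_B1_RMS
        return ProtocolSpec(id=pid, kind="IR_plus_MT",
                            prep_values=tuple(prep_values) if prep_values else ti_grid(),
                            tr=13.0, n_echo=n_echo, tau_s=ts,
                            n_rf_pre=n_rf_pre, invert=invert,
                            inv_pulse=inversion_rect(),
                            mt_pulse=cosine_mt_pulse(b1, ts))
    raise ValueError(f"unknown protocol id {pid!r}")


def cpmg_protocol(n_echo: int = N_ECHO_DEFAULT, tr: float = 13.0) -> ProtocolSpec:
    """Fully relaxed CPMG acquisition without preparation."""
    return ProtocolSpec(id="cpmg", kind="none", prep_values=(0.0,),
                        tr=tr, n_echo=n_echo)


def build_zspectrum_protocol(mode: str = "MTcos",
                             offsets: Sequence[float] | None = None,
                             te: float = 4e-3, b1_rms: float = 500.0,
                             tau_s: float = 0.25e-3,
                             n_rf: int = 300) -> ProtocolSpec:
    """z-spectrum acquisition: saturation train, 90-degree pulse, sample at TE.

    ``mode`` is one of ``MT+``, ``MT-``, ``MT+-`` (offset alternation) or
    ``MTcos`` (cosine modulation).
    """
    if mode not in ("MT+", "MT-", "MT+-", "MTcos"):
        raise ValueError(f"unknown z-spectrum mode {mode!r}")
    spec = ProtocolSpec(
        id="zspec", kind="zspec",
        prep_values=tuple(offsets) if offsets is not None else ZSPEC_OFFSETS_HZ,
        tr=6.0, n_echo=1, readout_kind="fid", te=te,
        tau_s=tau_s, n_rf_pre=n_rf, mt_mode=mode, b1_rms=b1_rms)
    return spec


def full_suite(n_echo: int = N_ECHO_DEFAULT) -> list[ProtocolSpec]:
    """All 22 relaxometry protocols with default acquisition grids."""
    return [build_protocol(pid, n_echo=n_echo) for pid in range(1, 23)]


def reduced_suite(n_echo: int = 10, n_ti: int = 8,
                  protocol_ids: Sequence[int] = (1, 3, 13, 15, 7, 17)
                  ) -> list[ProtocolSpec]:
    """Scaled-down suite retaining every protocol family.

    Defaults: 10 echoes, 8 evolution times, and one steady-state MT plus
    one IR+MT protocol -- small enough for routine parameter-recovery runs
    while still constraining all model parameters.
    """
    tis = ti_grid(n_ti)
    out = []
    for pid in protocol_ids:
        if pid in _STEADY_MT_GRID:
            out.append(build_protocol(pid, n_echo=n_echo,
                                      prep_values=n_rf_grid(n_ti, 40)))
        else:
            out.append(build_protocol(pid, n_echo=n_echo, prep_values=tis))
    return out


def suite_counts(suite: Sequence[ProtocolSpec],
                 n_temperatures: int = 3) -> tuple[int, int]:
    """(acquisitions per temperature, total data points) of a suite."""
    n_acq = sum(len(p.prep_values) for p in suite)
    n_points = n_acq * n_temperatures * suite[0].n_echo if suite else 0
    return n_acq, n_points
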