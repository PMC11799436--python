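"""Five-pool white-matter spin system: parameters and the Bloch-McConnell generator.

The model comprises two aqueous tissue-water pools -- intra-/extracellular
water (IEW) and myelin water (MW) -- each coupled by magnetization transfer
to an associated semisolid pool (non-myelin NM, myelin M), plus a small
non-exchanging bulk-water pool (BW) on the sample surface.  Chemical
exchange connects IEW and MW; the only exchange pairs are IEW<->MW,
IEW<->NM and MW<->M.

Transverse magnetization of the semisolid pools is neglected (their T2 is
of order 10 us), so the full state is the 12-component homogeneous vector

    M = (1/2, Mx^IEW, My^IEW, Mz^IEW, Mz^NM,
              Mx^MW,  My^MW,  Mz^MW,  Mz^M,
              Mx^BW,  My^BW,  Mz^BW)^T

and the dynamics are dM/dt = -L M with the order-12 generator built by
:func:`build_generator`.  The constant leading element 1/2 carries the
longitudinal recovery terms, which makes the equation homogeneous and the
piecewise evolution a pure matrix product.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .lineshapes import Lineshape, absorption_rate

__all__ = [
    "POOLS",
    "AQUEOUS_POOLS",
    "SEMISOLID_POOLS",
    "STATE_DIM",
    "STATE_LABELS",
    "TRANSVERSE_IDX",
    "AQUEOUS_XYZ",
    "SEMISOLID_Z",
    "FourPoolParams",
    "TemperatureSeries",
    "fundamental_to_directional",
    "build_generator",
    "equilibrium_state",
]

POOLS = ("IEW", "NM", "MW", "M", "BW")
AQUEOUS_POOLS = ("IEW", "MW", "BW")
SEMISOLID_POOLS = ("NM", "M")

STATE_DIM = 12
STATE_LABELS = (
    "1/2",
    "Mx_IEW", "My_IEW", "Mz_IEW",
    "Mz_NM",
    "Mx_MW", "My_MW", "Mz_MW",
    "Mz_M",
    "Mx_BW", "My_BW", "Mz_BW",
)

#: (x, y, z) state indices of each aqueous pool
AQUEOUS_XYZ = {"IEW": (1, 2, 3), "MW": (5, 6, 7), "BW": (9, 10, 11)}
#: z state index of each semisolid pool
SEMISOLID_Z = {"NM": 4, "M": 8}
#: all aqueous transverse indices (zeroed by perfect spoiling)
TRANSVERSE_IDX = (1, 2, 5, 6, 9, 10)

#: magnetization-transfer pairs (aqueous, semisolid)
MT_PAIRS = (("IEW", "NM"), ("MW", "M"))


def fundamental_to_directional(k_fund: float, a_l: float, a_m: float) -> tuple[float, float]:
    """Directional exchange rates from a fundamental rate constant.

    The directional rates k_{l,m} (loss from pool l) and k_{m,l} (loss from
    pool m) are tied by the equilibrium condition k_{l,m} M0^l = k_{m,l} M0^m,
    so both derive from one fundamental constant:

        k_{l,m} = k_fund * A^m,   k_{m,l} = k_fund * A^l.

    Parameters
    ----------
    k_fund : fundamental exchange rate constant (1/s), >= 0.
    a_l, a_m : fractional pool sizes of the two pools, in [0, 1].

    Returns
    -------
    (k_lm, k_ml) : directional rates in 1/s.
    """
    if k_fund < 0:
        raise ValueError("fundamental exchange rate must be >= 0")
    if not (0.0 <= a_l <= 1.0 and 0.0 <= a_m <= 1.0):
        raise ValueError("pool fractions must lie in [0, 1]")
    return k_fund * a_m, k_fund * a_l


@dataclass(frozen=True)
class FourPoolParams:
    """All model parameters of the five-pool system at one temperature.

    Fractions are dimensionless and sum to one; relaxation and exchange
    rates are in 1/s; the semisolid ``T2`` values are dipolar line-width
    parameters in seconds (order 1e-5), not genuine Bloch relaxation times.
    ``f_b1`` is the global transmit-amplitude scaling factor.
    """

    A_IEW: float
    A_NM: float
    A_MW: float
    A_M: float
    A_BW: float
    R1_IEW: float
    R1_NM: float
    R1_MW: float
    R1_M: float
    R1_BW: float
    R2_IEW: float
    R2_MW: float
    R2_BW: float
    T2_NM: float
    T2_M: float
    k_IEW_MW: float
    k_IEW_NM: float
    k_MW_M: float
    f_b1: float = 1.0
    lineshape_NM: Lineshape = field(default_factory=lambda: Lineshape("super_lorentzian"))
    lineshape_M: Lineshape = field(default_factory=lambda: Lineshape("super_lorentzian"))

    def __post_init__(self) -> None:
        fr = self.fractions()
        if any(v < 0 for v in fr.values()):
            raise ValueError("pool fractions must be >= 0")
        if abs(sum(fr.values()) - 1.0) > 1e-12:
            raise ValueError("pool fractions must sum to 1 within 1e-12")
        for name in ("R1_IEW", "R1_NM", "R1_MW", "R1_M", "R1_BW",
                     "R2_IEW", "R2_MW", "R2_BW",
                     "k_IEW_MW", "k_IEW_NM", "k_MW_M"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("T2_NM", "T2_M"):
            t2 = getattr(self, name)
            if not (0.0 < t2 < 1e-3):
                raise ValueError(f"{name} must lie in (0, 1e-3) s")
        if not (0.5 < self.f_b1 < 1.5):
            raise ValueError("f_b1 must lie in (0.5, 1.5)")

    # -- accessors -------------------------------------------------------
    def fractions(self) -> dict[str, float]:
        return {p: getattr(self, f"A_{p}") for p in POOLS}

    def r1(self, pool: str) -> float:
        return getattr(self, f"R1_{pool}")

    def r2(self, pool: str) -> float:
        return getattr(self, f"R2_{pool}")

    def lineshape(self, pool: str) -> Lineshape:
        return getattr(self, f"lineshape_{pool}")

    def t2_semisolid(self, pool: str) -> float:
        return getattr(self, f"T2_{pool}")

    def directional_rates(self) -> dict[tuple[str, str], float]:
        """All six directional rates keyed by (from, to)."""
        out: dict[tuple[str, str], float] = {}
        for (l, m), k in ((("IEW", "MW"), self.k_IEW_MW),
                          (("IEW", "NM"), self.k_IEW_NM),
                          (("MW", "M"), self.k_MW_M)):
            k_lm, k_ml = fundamental_to_directional(
                k, getattr(self, f"A_{l}"), getattr(self, f"A_{m}"))
            out[(l, m)] = k_lm
            out[(m, l)] = k_ml
        return out

    def replace(self, **changes) -> "FourPoolParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class TemperatureSeries:
    """Parameter sets at several temperatures with optionally shared fractions.

    When ``shared`` is set, all entries must have identical pool fractions
    and transmit scaling (the study's assumption that fractional pool sizes
    and the B1 calibration are temperature independent).
    """

    temperatures_c: tuple[float, ...]
    entries: tuple[FourPoolParams, ...]
    shared: bool = True

    def __post_init__(self) -> None:
        if len(self.temperatures_c) != len(self.entries):
            raise ValueError("temperatures and entries must have equal length")
        t = np.asarray(self.temperatures_c, dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.shared and len(self.entries) > 1:
            ref = self.entries[0]
            for e in self.entries[1:]:
                same = all(
                    abs(getattr(e, f"A_{p}") - getattr(ref, f"A_{p}")) < 1e-12
                    for p in POOLS
                ) and abs(e.f_b1 - ref.f_b1) < 1e-12
                if not same:
                    raise ValueError(
                        "shared series requires identical fractions and f_b1")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(zip(self.temperatures_c, self.entries))

    def at(self, temperature_c: float) -> FourPoolParams:
        for t, e in self:
            if abs(t - temperature_c) < 1e-9:
                return e
        raise KeyError(f"no entry at {temperature_c} degC")

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[float, FourPoolParams]],
                   shared: bool = True) -> "TemperatureSeries":
        temps, entries = zip(*pairs)
        return cls(tuple(float(t) for t in temps), tuple(entries), shared)


def equilibrium_state(params: FourPoolParams) -> np.ndarray:
    """Thermal-equilibrium state vector: Mz^l = A^l, transverse zero."""
    m = np.zeros(STATE_DIM)
    m[0] = 0.5
    for p, (_, _, iz) in AQUEOUS_XYZ.items():
        m[iz] = getattr(params, f"A_{p}")
    for p, iz in SEMISOLID_Z.items():
        m[iz] = getattr(params, f"A_{p}")
    return m


def build_generator(
    params: FourPoolParams,
    w1x: float = 0.0,
    w1y: float = 0.0,
    omega: float = 0.0,
    semisolid_mode: str = "absorption",
    sat_offset_hz: float | None = None,
    r_rf: dict[str, float] | None = None,
) -> np.ndarray:
    """Assemble the order-12 dynamic matrix L of dM/dt = -L M.

    Parameters
    ----------
    w1x, w1y : RF field components in rad/s (already scaled by f_B1 where
        applicable; the caller owns transmit scaling).
    omega : carrier offset Omega = 2*pi*dnu in rad/s seen by the aqueous
        pools.
    semisolid_mode :
        ``"absorption"`` -- semisolid saturation through the RF absorption
        rate R_RF^m = pi * w1^2 * g^m(offset, T2^m), evaluated at
        ``sat_offset_hz`` (default: the carrier offset).  Invalid for
        on-resonant irradiation of a divergent lineshape.
        ``"transparent"`` -- R_RF = 0 but semisolid relaxation/exchange
        dynamics remain active (used during on-resonant refocusing pulses).
        ``"frozen"`` -- semisolid z-components are held constant (their rows
        are zeroed) while still feeding magnetization transfer into the
        aqueous pools; an effective-flip factor is applied separately by
        the caller.

    Row 1 of the returned matrix is identically zero so that the leading
    1/2 element of the state is conserved.
    """
    for v in (w1x, w1y, omega):
        if not np.isfinite(v):
            raise ValueError("non-finite RF parameters")
    if semisolid_mode not in ("absorption", "transparent", "frozen"):
        raise ValueError(f"unknown semisolid_mode {semisolid_mode!r}")

    L = np.zeros((STATE_DIM, STATE_DIM))
    rates = params.directional_rates()

    # aqueous Bloch blocks
    for pool, (ix, iy, iz) in AQUEOUS_XYZ.items():
        r1 = params.r1(pool)
        r2 = params.r2(pool)
        m0 = getattr(params, f"A_{pool}")
        L[ix, ix] = r2
        L[ix, iy] = omega
        L[ix, iz] = -w1y
        L[iy, ix] = -omega
        L[iy, iy] = r2
        L[iy, iz] = w1x
        L[iz, ix] = w1y
        L[iz, iy] = -w1x
        L[iz, iz] = r1
        L[iz, 0] = -2.0 * r1 * m0

    # chemical exchange IEW <-> MW (all three components)
    k_im = rates[("IEW", "MW")]
    k_mi = rates[("MW", "IEW")]
    for ci, cm in zip(AQUEOUS_XYZ["IEW"], AQUEOUS_XYZ["MW"]):
        L[ci, ci] += k_im
        L[ci, cm] -= k_mi
        L[cm, cm] += k_mi
        L[cm, ci] -= k_im

    # magnetization transfer between each aqueous pool and its semisolid pool
    w1_amp = float(np.hypot(w1x, w1y))
    if sat_offset_hz is None:
        sat_offset_hz = omega / (2.0 * np.pi)
    for aq, ss in MT_PAIRS:
        k_as = rates[(aq, ss)]   # loss from aqueous
        k_sa = rates[(ss, aq)]   # loss from semisolid
        ix, iy, iz = AQUEOUS_XYZ[aq]
        js = SEMISOLID_Z[ss]
        # aqueous loses all three components to the (invisible) semisolid
        for c in (ix, iy, iz):
            L[c, c] += k_as
        # only longitudinal magnetization is returned
        L[iz, js] -= k_sa
        L[js, iz] -= k_as
        rate = 0.0
        if semisolid_mode == "absorption" and w1_amp != 0.0:
            if r_rf is not None:
                rate = r_rf.get(ss, 0.0)
            else:
                rate = absorption_rate(w1_amp, sat_offset_hz,
                                       params.lineshape(ss),
                                       params.t2_semisolid(ss))
        L[js, js] = params.r1(ss) + k_sa + rate
        L[js, 0] = -2.0 * params.r1(ss) * getattr(params, f"A_{ss}")

    if semisolid_mode == "frozen":
        for js in SEMISOLID_Z.values():
            L[js, :] = 0.0

    return L
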