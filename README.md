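# fourpool

Four-pool Bloch-McConnell relaxometry and magnetization transfer in white
matter.

## The problem

Proton relaxation in white matter is governed by several coupled proton
reservoirs: intra-/extracellular water (IEW) and myelin water (MW), each
exchanging longitudinal magnetization with an associated semisolid pool —
nonaqueous non-myelin tissue (NM) and nonaqueous myelin (M) — plus a small
non-exchanging film of bulk water (BW) on the surface of an ex vivo sample.
Simple models (a single T1, or a two-pool MT model) conflate these
reservoirs, which limits how specifically quantitative MRI parameters can be
tied to myelination.  This package implements the full four-pool (+ BW)
analysis for users who want to simulate, fit, or interrogate such models:
MR physicists developing quantitative myelin imaging, and anyone needing a
tested Bloch-McConnell sequence simulator with semisolid pools.

## The model

Each pool `l ∈ {IEW, NM, MW, M, BW}` has a fractional size `A^l`
(normalized, `Σ A^l = 1`) and relaxation rates `R_{1,2}^l = 1/T_{1,2}^l`.
Exchange is parameterized by fundamental rate constants
`k_{l↔m} = k_{l,m}/A^m = k_{m,l}/A^l` for the three pairs IEW↔MW, IEW↔NM
and MW↔M.  Because semisolid T2 is of order 10 µs, semisolid transverse
magnetization is dropped and the state is the 12-component homogeneous
vector

```
M = (½, Mx^IEW, My^IEW, Mz^IEW, Mz^NM, Mx^MW, My^MW, Mz^MW, Mz^M, Mx^BW, My^BW, Mz^BW)ᵀ
```

evolving as `dM/dt = −L·M`, where the order-12 generator `L` collects Bloch
rotation/relaxation blocks for the aqueous pools, exchange couplings, and an
RF absorption rate `R_RF^m = π ω₁² g^m(Δν, T2^m)` on the semisolid diagonal
(with a super-Lorentzian, Gaussian, Lorentzian, or fiber-orientation-
weighted "Bingham" lineshape `g`).  A pulse sequence is simulated as an
ordered product of interval propagators `P = exp(−Δt L)`; the periodic
steady state of a TR loop is obtained exactly as the fixed point of the
full-cycle matrix.  On-resonant hard pulses, where the absorption-rate
picture breaks down, act on the semisolid pools through effective flip
angles (`Mz^m → cos(α_eff^m)·Mz^m`).

On top of the simulator sit:

* declarative builders for 22 relaxometry protocols (inversion recovery
  with hard/adiabatic pulses, transient and steady-state MT preparation,
  Goldman-Shen filters, IR±MT combinations — all with a shared CPMG
  readout) and for z-spectrum acquisitions with four saturation modes;
* `FourPoolModel` / `TwoPoolModel` — joint bounded least-squares estimation
  of all 44 parameters from concatenated multi-protocol, multi-temperature
  data (fractions and the transmit scaling f_B1 shared across temperatures),
  returning a `FitResult` with estimates, 95% confidence intervals, the
  parameter correlation matrix and residual diagnostics;
* derived physical quantities (myelin water fraction, macromolecular pool
  fraction, water mixing time τ_m, shutter times τ_1/τ_2, weighted aqueous
  rates), Arrhenius analysis of temperature series, rotational correlation
  times, z-spectrum simulation and MTR/ihMTR decompositions;
* a synthetic-data generator that forward-simulates the full 22-protocol,
  three-temperature acquisition suite (443 acquisitions × 80 echoes × 3
  temperatures = 106,320 points) from the packaged reference parameter
  table with additive Gaussian noise.

## Worked example

```python
import numpy as np
from fourpool import (reference_parameters, cpmg_protocol, SequenceEngine,
                      effective_flip_table, biexp_fit, derived_quantities,
                      arrhenius_fit)

series = reference_parameters()          # published estimates at 21/28/35 degC
p35 = series.at(35.0)

# forward-simulate a fully relaxed CPMG train and fit two components
prot = cpmg_protocol(n_echo=80)
flips = effective_flip_table(prot.rf_events(), p35)
amps = SequenceEngine(p35, flips).simulate(prot)[0]
fit = biexp_fit(amps, np.arange(1, 81) * prot.dte)
print(f"T2_short = {fit.t2_short*1e3:.1f} ms, short fraction = {fit.frac_short:.3f}")

d21, _, d35 = derived_quantities(series)
print(f"myelin water fraction: {d21.mwf:.3f}")
print(f"water mixing time: {d21.tau_m:.2f} s (21 degC) -> {d35.tau_m:.2f} s (35 degC)")

arr = arrhenius_fit([p.R1_IEW for _, p in series], [294.15, 301.15, 308.15],
                    convention="correlation_time", kelvin=True)
print(f"E_a(R1_IEW) = {arr.ea_kj_mol:.1f} kJ/mol ({arr.reliability})")
```

Output:

```
T2_short = 31.9 ms, short fraction = 0.574
myelin water fraction: 0.561
water mixing time: 1.18 s (21 degC) -> 0.70 s (35 degC)
E_a(R1_IEW) = 10.3 kJ/mol (reliable)
```

The biexponential CPMG description is shorter than the intrinsic
`T2^MW = 37 ms` because the multiexponential analysis ignores the
semisolid pools, whose exchange pathway drains transverse aqueous
magnetization; the short fraction 0.574 essentially equals the model's
myelin water fraction.  The mixing time ~1 s against the transverse
shutter time ~54 ms is what makes the two water components separable in
CPMG experiments in the first place.

A thin CLI mirrors the main workflows:

```
fourpool generate --sigma 0.003 --seed 1 --out data.csv
fourpool fit --data data.csv --model 4pm --out fit.json
fourpool derive --out derived.csv
fourpool zspec --mode MTcos --te 0.004 --out zspec.csv
```

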