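# Methods

## Model

The spin system is a five-pool white-matter model: two aqueous tissue-water
pools (intra-/extracellular water IEW, myelin water MW), one semisolid pool
coupled to each (non-myelin NM to IEW, myelin M to MW), and a non-exchanging
bulk-water pool BW representing surface water on an ex vivo sample.  The
exchange topology is fixed: IEW↔MW (chemical exchange of all magnetization
components), IEW↔NM and MW↔M (magnetization transfer of longitudinal
magnetization only; transverse magnetization handed to a semisolid pool is
lost, so the directional rates also appear as decay terms on the aqueous
transverse components).  Directional rates derive from fundamental constants
via `k_{l,m} = k_{l↔m} A^m`, which enforces detailed balance exactly.

Semisolid transverse magnetization is neglected (dipolar line widths of
order 10 µs), leaving a 12-dimensional state.  The constant leading element
½ makes the equation homogeneous, so longitudinal recovery is part of the
linear map and every sequence segment is a matrix product.  Two consequences
are used throughout:

* **Exact steady state.** The periodic state of a repeated TR cycle is the
  fixed point of the full-cycle matrix `C`; row 0 of `C` is `(1, 0, …)`, so
  the fixed point follows from one 11×11 linear solve.  This replaces dummy
  repetitions and is exact for any TR.  (A power-iteration fallback covers
  the pathological no-relaxation case.)
* **Batched echo trains.** All acquisitions of a protocol share one
  echo-unit matrix, so CPMG trains are propagated for all preparation
  values simultaneously.

### Semisolid pools under RF

Off-resonant irradiation saturates a semisolid pool at the absorption rate
`R_RF^m = π ω₁² g^m(Δν, T2^m)`.  Lineshapes are exposed in a per-Hz
normalization (unit area over offset frequency ν, including the integrable
on-resonance spike of the super-Lorentzian), and the absorption rate is
computed as `ω₁² g_ν/2`, which is numerically identical to the
angular-frequency convention above.  The super-Lorentzian is the standard
orientation average of Gaussian lines with width ∝ |3cos²θ−1|; it diverges
on resonance, so its evaluation is refused below 1 kHz.

The "Bingham" lineshape weights the single-orientation line by a scaled
Bingham fiber-orientation density `β(u) = f₀ exp(−κ₁(μ₁·u)² − κ₂(μ₂·u)²)`,
normalized by `∫β du` (average-then-renormalize; with κ₁ = κ₂ = 0 it reduces
to the super-Lorentzian).  The main-field direction is `μ₀` tilted by the
fiber-to-field angle θ_FB (default 70°) toward μ₁.  The concentration
parameters are user inputs (they come from diffusion-based fiber-orientation
estimation, which is out of scope here).

On-resonant hard pulses violate the absorption-rate picture
(`γ²B₁²T₁T₂ ≫ 1`).  For those events the semisolid rows of the generator
are frozen during the pulse (their values still feed transfer into the
aqueous pools) and the semisolid z-components are multiplied once per pulse
by `cos(α_eff^m)`.  The effective flip angles are a calibration table, by
default computed from a damped-Bloch model of the pulse envelope (transverse
lifetime set to `T2^m`, no longitudinal relaxation); they travel with a
synthetic dataset and are treated as known inputs by the fits (flags allow
freeing them).  Composite refocusing pulses are handled as `transparent`:
no absorption term and no flip factor, but relaxation and exchange stay
active for the full 200 µs — this is the pathway that couples the semisolid
pools into the CPMG decay and shortens the apparent biexponential T2s.

## Protocols

The acquisition suite mirrors a 22-protocol relaxometry session with one
CPMG readout (ΔTE = 4 ms, 20 µs rectangular 90° excitation, 200 µs
90x–180y–90x composite refocusing, 80 echoes) at three temperatures:

| ids | preparation | key parameters |
|-----|-------------|----------------|
| 1–2 | inversion recovery | 40 µs hard / 5 ms BIR-4; 23 log-spaced TIs in [770 µs, 10 s]; TR 13 s |
| 3 | transient MT | 6 ms composite on-resonant pulse; same TI grid |
| 4–12 | steady-state MT | cosine-modulated Gaussian trains (τ_p 2 ms, bands ±15 kHz), N_RF = 20…320; B1_RMS ∈ {500, 750, 1000} Hz × τ_s ∈ {0.25, 2.25, 4.25} ms; TR 6 s |
| 13–16 | Goldman-Shen | 90x–τ_f–90∓x, τ_f ∈ {1, 50} ms, store up/down |
| 17–22 | MT + IR | pre-inversion MT train, optional hard inversion, MT train continuing through the evolution period when TI > τ_s+τ_p |

Several details of the original acquisitions are not published and are
nominal reconstructions, chosen once: the exact TI list (log-spaced
endpoints are known), the pre-inversion train length for protocols 17–22
(100 pulses at 750 Hz RMS), the internals of the transient-MT composite
pulse (16 alternating-phase 360° rectangular sub-pulses — zero net water
rotation, strong semisolid saturation), the BIR-4 modulation functions
(standard tanh/tan with ζ = 10, tan κ = 20, 10 kHz sweep), and the
protocol-id mapping of the steady-MT grid (B1-major).  Cosine-modulated
envelopes are normalized so the train's RMS amplitude (over pulse + gap)
equals the nominal B1_RMS, which reproduces the √2 peak scaling.

z-spectra use 300-pulse Gaussian trains (B1_RMS 500 Hz, τ_p 2 ms, τ_s
250 µs) at 42 offsets (0–95 kHz) in four modes (single-sided ±, alternating
dual-sided, cosine-modulated) with a single sample at a chosen TE after a
90° pulse; the unsaturated reference replaces the train by an equal delay.

## Numerical choices

* Lineshape quadrature: 512-point Gauss-Legendre in cos θ (verified against
  adaptive quadrature to better than 10⁻⁴ relative); Bingham lineshape:
  1024×256 Gauss-Legendre × trapezoidal spherical grid (isotropic limit
  agrees with the super-Lorentzian to ~10⁻⁹).
* Shaped pulses are sampled into ≤10 µs segments (≤2 µs, or a tenth of the
  carrier period, for cosine-modulated pulses).  Long shaped pulses use
  segment propagators interpolated quadratically on a 33-node amplitude
  grid (error budget 10⁻⁵, tested against exact per-segment exponentials);
  products are evaluated by pairwise tree reduction.
* Matrix exponentials via scipy's scaling-and-squaring; propagators are
  memoized per engine (one engine per parameter set), keyed by event label
  and delay duration.
* The joint fit uses bounded trust-region least squares with an unweighted
  objective, a structured forward-difference Jacobian (relative step 10⁻⁶)
  that exploits the temperature-block sparsity (per-temperature parameters
  touch only their own residual block: 54 instead of 132 single-temperature
  simulations per Jacobian), and multi-start with early stopping as a guard
  against local minima of the strongly correlated 44-parameter problem.
  Confidence intervals are linearized (`cov = s²(JᵀJ)⁻¹`, 95% two-sided).
* The biexponential CPMG fit is seeded from log-linear fits of the decay
  tail and the early excess, then refined by Levenberg-Marquardt in
  log-parameters; effectively monoexponential input (component ratio
  < 1.05, vanishing amplitude, or no improvement over a single exponential)
  returns a degenerate flag.

### Parameterization and bounds

Free parameters (default 44): shared block — four tissue fractions (BW by
normalization) and the transmit scaling f_B1; per temperature — three
fundamental exchange rates, five R1, three aqueous R2, two semisolid line
widths.  Bounds are broad physical ranges (fractions [0,1]; k ∈ [0.1, 200]
s⁻¹; R1 ∈ [0.1, 10] s⁻¹; aqueous R2 ∈ [1, 100] s⁻¹; semisolid T2 ∈ [5, 30]
µs; f_B1 ∈ [0.9, 1.1]), except the bulk-water pool, whose relaxation rates
are confined to free-water values (R1 ∈ [0.1, 1], R2 ∈ [0.1, 2.5] s⁻¹) —
without this the pool can masquerade as a tissue-water compartment.  The
two-pool comparator (one aqueous + one semisolid pool + BW, run through the
same simulator with the myelin pools emptied) frees the semisolid and
bulk-water fractions with A_BW capped at 2% for the same reason.

## Synthetic data

`generate_dataset` forward-simulates the suite from the packaged reference
table (shared fractions 0.337/0.431/0.044/0.181/0.007, f_B1 = 0.985, and
the per-temperature rates/widths at 21/28/35 °C) and adds i.i.d. Gaussian
noise, default σ = 0.003 of the total equilibrium magnetization — the
residual scale of the reference four-pool analysis.  The full suite yields
443 acquisitions × 80 echoes × 3 temperatures = 106,320 points.

What the generator emulates: the acquisition grid, the protocol-dependent
preparation physics, shared-fraction structure across temperatures, and the
noise floor.  What it does not: real pulse-envelope imperfections, B0/B1
inhomogeneity beyond a global f_B1, temperature drift, Rician magnitude
bias (noise is additive Gaussian on real-valued amplitudes — appropriate in
the high-SNR regime), spatial encoding, stimulated-echo residues (spoiling
is perfect), and any physics outside the generating model (dipolar-order
reservoirs, lineshape deviations).  Passing recovery tests therefore shows
the estimator is consistent and well-conditioned under the model's own
assumptions, not that real tissue obeys the model.

## Test problem sizes

The routine recovery study runs on a reduced suite — protocols 1, 3, 13,
15, 7, 17 with 8 evolution times and 10 echoes (1,440 points) — chosen to
retain every protocol family while keeping a 44-parameter fit interactive.
The noise-dispersion study fits the full 106,320-point suite for ten noise
realizations, warm-started at the generating values (it measures estimator
scatter, not basin attraction, which the noise-free perturbed-start test
covers).  The model-comparison test uses the reduced suite with 32 echoes,
since the two-pool model's mis-fit expresses itself mainly in the late part
of the echo train.

## Known limitations

* The two-pool comparator fitted to four-pool-generated data converges to a
  semisolid fraction a few hundredths *above* the combined four-pool value
  (the corresponding test documents the measured gap); constraining the
  fraction verifiably worsens the fit, so this is the genuine optimum under
  the idealized generating model rather than an optimizer artifact.
* Effective flip angles are calibration inputs rather than jointly fitted
  parameters; with real data they would need to be freed (supported via
  parameter flags) since no generating model is available to compute them.
* Dipolar-order (Provotorov) reservoirs are not modeled, so inhomogeneous
  MT amplitudes can be *measured* on simulated dual-sided spectra but not
  predicted mechanistically; cosine-modulated saturation keeps this
  consistent with the modeled physics.
* Exact experimental timing details (TI lists, train lengths, composite
  pulse internals) are nominal reconstructions; quantities that depend on
  the acquisition grid only through its coverage are insensitive to this,
  but per-acquisition signal values are not bit-comparable to the original
  raw data.
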