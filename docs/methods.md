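# Methods

## Model

The striatal beat frequency (SBF) circuit codes elapsed time in the pattern of
phases of `N_in` cortical oscillators, read out by a striatal coincidence
detector.  All oscillators reset at trial onset.  Two input populations are
implemented:

* **SBF-sin** — phase oscillators `v_i(t) = a cos(2π f_i t)`, the analytically
  tractable reduction of any limit-cycle neuron near its bifurcation.
* **SBF-ML** — Morris–Lecar conductance neurons (voltage + slow potassium
  gating), the standard type-II (Hopf) parameter set: C = 20 µF/cm²,
  g_L = 2, E_L = −60 mV, g_Ca = 4.4, E_Ca = 120 mV, g_K = 8, E_K = −84 mV,
  v1 = −1.2, v2 = 18, v3 = 2, v4 = 30 mV, φ = 0.031 ms⁻¹.  φ was chosen so
  that the achievable firing band (≈7.6–13.2 Hz over I ∈ [87.6, 180] µA/cm²,
  monotone f–I) covers the alpha band 8–12 Hz used everywhere.  Integration is
  fixed-step RK4, dt = 0.1 ms (halving dt changes the measured period by far
  less than 0.5%); spikes are upward 0-mV crossings; a bank is calibrated by
  inverse interpolation of a sampled f–I curve plus vectorized secant
  refinement to < 1% rate error per neuron.  For the coincidence readout each
  ML voltage trace is affinely rescaled to [−1, 1] over the probe window and
  its temporal mean is subtracted, matching the zero-mean sine states and
  removing the population-rate pedestal from the dot product.

Reference memory: over `N_trials` fixed-interval trials, trial j stores the
oscillator states at its memorized criterion `T_j`, and the weights are the
normalized trial average `w_i = u_i / max|u_i|`, `u_i = ⟨v_i(T_j)⟩_j`, so
`|w_i| ≤ 1` (a positively defined variant `(1+u_i)/2` peaks at the same
place).  The probe output is the dot product `out(t) = Σ_i w_i v_i(t)` of a
single output neuron (a stub exists for several, but identical, detectors).

## Noise

Both noise sources are multiplicative factors `1 + ξ` with zero-mean `ξ` of
fractional SD σ (Gaussian, uniform on ±√3σ, or centred scaled Poisson with
rate λ = 100 — multiplicative jitter is what the scalar result σ_out ∝ T
requires; additive jitter would give a T-independent width):

* **criterion-time noise**: `T_j = T(1+ξ_j)`, one draw per FI trial;
* **frequency noise**: `f_ij = f_i(1+ξ_ij)` during probe trials only, drawn
  once per (oscillator, trial) or shared by all oscillators within a trial.

All randomness derives from one master seed via `numpy` `SeedSequence`
spawning; identical configurations reproduce bit-identical outputs.

## Closed forms

With equally spaced frequencies `f_k = f_min + k·df`, the noiseless output is
`½[S(t−T) + S(t+T)]` with `S(x) = cos(a₀x)·sin(b₀x)/sin(b₀x/N_in)`,
`a₀ = π(f_max+f_min−df)`, `b₀ = π(f_max−f_min)`; the envelope tends to
`N_in/2` at the peak (evaluated via `sinc` ratios so the removable
singularities never 0/0) and its half-height width `2u*/b₀`
(`sinc(u*) = ½`, u* ≈ 1.8955) is independent of T.

Averaging the weights over Gaussian criterion jitter damps oscillator f by
`exp(−2π²f²T²σ_T²)`; with an unbounded uniform frequency continuum the output
is the Gaussian `exp(−(t−T)²/(2(Tσ_T)²))`.  The finite-band form is the
band-limited Gaussian-damped cosine transform — the same Gaussian times a
difference of two complex error functions, evaluated through the Faddeeva
function `wofz` because the naive complex `erf` overflows at band-scale
arguments.  Frequency noise damps by `exp(−2π²f²σ_f²t²)` (time-dependent), and
the unbounded-band output is `(1/t)·exp(−(t−T)²/(2σ_f²t²))` — this
transcription was selected by requiring the closed form to reproduce the
model's published sweep statistics (see "skewness and width sweep" below); the
candidate without the 1/t prefactor and the candidate retaining the mirror
term centred at −T both fail that cross-check decisively.  Its exact argmax is
`T(√(1+4σ_f²)−1)/(2σ_f²)`, equal to the general prediction `T/(1+σ_f²)` to
O(σ_f⁴) — at σ_f ≤ 0.3 the two differ by less than a 250-point probe grid can
resolve.

## What the trial average is

A subtlety governs all finite-band numerics: the *signed* trial average of the
criterion-noise output decoheres.  Its expected amplitude carries the damping
factor above, which at f = 8 Hz, T = 10 s, σ_T = 0.1 is e^−1263 ≈ 0 — once
the criterion jitter exceeds one oscillation period, per-trial carriers cancel
and the mean trace is residual noise.  The observable trial statistic is the
*magnitude* of the match.  The experiment runners therefore average by RMS
across trials, `√⟨out_j(t)²⟩_j`, whose expectation is
`√(pdf_T ⊛ K²)` (criterion density smoothed by the squared noiseless kernel):
a Gaussian of width `√2·T·σ_T`.  Widths measured this way grow linearly in T
with slopes ≈ 1.3–1.4·σ_T, which is the pattern the model is known for.  The
same applies to finite-band frequency noise: with per-oscillator independent
jitter both the mean and the variance of the trace are flat in t once
2πfσ_f T ≫ 1, so the scalar-experiment runner draws one clock-speed
multiplier per probe trial shared by the whole bank (trial-to-trial clock
variability) and averages by RMS, which leaves the long-tailed scalar output.
The signed-mean path is retained in `sbftime.core` as the object the closed
forms describe; Monte-Carlo cross-checks against the closed forms run in
regimes where the coherent mean is resolvable (σ·f·T ≲ 1).

## Measurement conventions

* **Gaussian-fit σ** (simulated SBF-sin traces): nonlinear least squares of
  `A·exp(−(t−µ)²/2σ²)` on the contiguous sub-trace ≥ 10% of the peak — the
  contiguity clause keeps long tails and secondary echoes out of the fit.
  Before fitting, the incoherent variance pedestal (lower decile of the
  squared trace) is subtracted, and a 2%-span moving average removes
  carrier-commensurate ripple (the Poisson criterion lattice, step σT/√λ, can
  resonate with the ~10 Hz carrier); the width bias of both is ≪ 1%.
* **Half-height width** `x2 − x1` and half-width ratio `Δτ₂/Δτ₁` (analytic
  sweeps, in normalized time t/t_peak; also the width measure for SBF-ML,
  reported as FWHM/2.3548): crossings located by linear interpolation between
  bracketing grid points; peak/crossing localization on simulated traces uses
  a 5%-span Hann smoothing so single noisy samples cannot masquerade as the
  peak.
* **Envelopes**: local-maxima interpolation (kept ≥ the raw trace pointwise)
  or the analytic-signal magnitude (Hilbert), the latter used for noiseless
  width measurements; noiseless widths are measured in a window
  [0.25T, 1.75T] around the criterion, which excludes the onset transient and
  the commensurate-phase echo near 2T of harmonic-rich ML banks.

## Experiment defaults (the study conditions)

* Bank: 1000 oscillators, 8–12 Hz, amplitude 1 (SBF-sin); probe grids of
  20 samples per fastest cycle on [0, 3T] for raw traces, 500-point grids on
  [0.05T, 2.4T] for smooth trial statistics.
* Criteria {5, 10, 20, 30, 40, 50} s (the published pair {10, 30} extended so
  regressions have ≥ 4 points); 1000 FI trials; 1000 probe trials; 10
  replicates for stochastic slope estimates, reported mean ± SD.
* SBF-ML experiments run desk-scale: 200 neurons (enough that the incoherent
  RMS pedestal stays below half height), criteria {4, 6, 8, 10} s, 2000 FI
  trials, 3 replicates.  ML banks use *stratified-uniform* frequencies (one
  uniform draw per df-wide bin, seeded): frequencies uniformly distributed
  over the band as the model specifies, without the exact commensurability
  of the analytic grid — harmonic-rich ML waveforms turn an equally spaced
  grid into strong fractional band revivals (echoes at (1/df)/h for harmonic
  h) that contaminate width measurements.
* Skewness and width sweep: the unbounded-band frequency-noise form is
  evaluated on [10⁻⁴T, 8T] (400 000 points) for 101 values of σ_f in [0, 1];
  the half-width ratio is fitted with a quadratic in σ_f, and the normalized
  half-height width with a line on σ_f < 0.5.  At σ_f = 0 the ratio is set to
  its exact symmetric-limit value 1.

## What the synthetic conditions do and do not show

The generators emulate the idealized circuit: deterministic oscillators,
noise confined to the two named parameters, instantaneous weight storage, a
linear readout.  Passing tests show that scalar invariance emerges from the
stated noise sources in this architecture — not that real striatal neurons
implement it: there is no synaptic plasticity, no spiking output neuron, no
channel noise inside the ML dynamics (frequency jitter enters through the
bias current / frequency map), and behavioural response thresholds are not
modelled.

## Known limitations

* The finite-band closed forms are coherent (signed-mean) objects; in the
  alpha band at behavioural σ values they describe an expectation that is
  numerically zero, and the RMS statistics the experiments measure match them
  in shape only through the pdf-convolution argument above.
* Small ML banks (≲ 50 neurons) show band-revival echoes and a variance
  pedestal comparable to the peak; width estimates there need the
  half-height convention and pedestal subtraction, and remain noisier than
  the sine model's.
* The ML slope estimates at σ_T = 0.2 have replicate-to-replicate spread of
  order 10–20% even at desk scale; slopes are reported as means over
  replicates.
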