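# Methods

## Model overview and assumptions

`cohear` predicts binaural detection thresholds from the second-order
interaural statistics of the stimulus alone.  The processing chain is:

1. **Stimulus → spectral densities.**  Every stimulus is a rectangular band
   of Gaussian noise of angular bandwidth Δω centered at ω0 (500 Hz in the
   whole battery), with interaural correlation ρ_N, an IPD spectrum Δφ(ω),
   and optionally a tone at ω0 with IPD Δψ and power SNR relative to the
   unit-power noise.  Its interaural cross-spectral density has a continuous
   part (ρ_N/Δω)·e^{iΔφ(ω)} over the band (only coherent energy appears in
   the cross spectrum) and a discrete line SNR·e^{iΔψ}; the auto densities
   are 1/Δω plus a line SNR.  Continuous and line parts are never mixed: a
   tone is not a density, and smearing it onto a grid would make results
   grid-width dependent.

2. **Peripheral filter.**  A single gammatone power spectrum
   |H(ω)|² = [1 + (ω−ω0)²/(4π²b²)]^{−n}, with
   b = ERB·(n−1)!²/(π(2n−2)!·2^{2−2n}).  The exponent uses b² — this is the
   dimensionally consistent form, and it is what makes the defining property
   ∫|H(ω)|² dω/2π = ERB hold exactly (verified by quadrature in the tests:
   79.000 Hz for n=4, ERB=79).  Defaults n=4, ERB=79 Hz, center 500 Hz are
   fixed, not fitted: 79 Hz is a standard estimate of the monaural
   peripheral bandwidth at 500 Hz.

3. **Complex correlation coefficient.**  γ = ∫S_lr|H|²dω /
   √(∫S_ll|H|²dω·∫S_rr|H|²dω); |γ| ∈ [0,1] is the interaural coherence,
   arg(γ) the mean IPD.  This spectral route gives the *expected value* of
   γ exactly (infinitely long signals); token-to-token variability is
   deliberately outside the model.

4. **Decision model.**  Binaural branch: d′_bin = |z[ρ̂γ_ref] − z[ρ̂γ_tgt]|/σ_bin
   where z[·] applies arctanh to the modulus and preserves the argument.
   The factor ρ̂ ∈ (0,1) caps the usable coherence (equivalently: internal
   uncorrelated noise), keeping the transform finite at |γ| = 1.  Monaural
   branch: d′_mon = SNR_eff/σ_mon with SNR_eff = SNR·|H(ω0)|² / ∫S_noise|H|²dω,
   a linear power ratio (it models the post-filter energy increment, which
   is proportional to SNR).  The cues combine as independent Gaussian
   channels, d′ = √(d′_bin² + d′_mon²).

### Sign and phase conventions

γ is defined as ⟨l_a r_a*⟩/norm.  With this choice a *right-ear delay* Δt
(IPD spectrum Δφ(ω) = ωΔt, left leading) yields arg γ = +ω0Δt wrapped to
(−π, π] — e.g. +0.3π for Δt = 2.3 ms at 500 Hz — and a right channel equal
to the Hilbert transform of the left gives γ = +i.  The waveform
synthesizer applies e^{−iΔφ(ω)} to the right channel's coherent spectrum
(a physical delay), so the empirical and analytic routes share one
convention.  arg(0) is defined as 0 so the z-transform is total.

## Threshold solving

For a fixed noise stimulus and filter, γ of noise+tone is a rational
function of SNR: γ(s) = (I_cross + s·h0·e^{iΔψ})/(I_auto + s·h0), with
I_cross, I_auto the two filtered band integrals and h0 = |H(ω0)|².  The
`ThresholdKernel` computes those two quadratures once; after that, solving
d′(SNR) = d′_target for any model parameters is scalar arithmetic.  Since
d′ is monotone non-decreasing in SNR for every stimulus in the battery
(asserted numerically in the tests), the threshold is found by bracketed
root-finding (Brent) on log₁₀ SNR over [−8, +4] after a coarse sign-change
scan — deterministic and tolerance-controlled (relative d′ tolerance 1e−6),
in contrast to general constrained minimization.  Stimuli that provide no
usable cue (e.g. a diotic tone in fully coherent noise with no monaural
pathway) raise an error naming the bracket.

Quadrature: adaptive (`scipy.integrate.quad`) over the noise band
intersected with ±12 ERB around the filter center, relative tolerance
1e−10.  The 4th-order gammatone tail decays as (ω−ω0)^{−8}, so the 12-ERB
truncation error is far below the threshold tolerance.

### Degenerate and edge inputs

- Bands nominally extending below 0 Hz (bandwidth sweeps such as 3.2–6.4
  kHz at a 500 Hz center) are truncated at zero frequency with the spectral
  *level* 1/Δω preserved.  The tone's reference power remains the nominal
  unit noise power.  This keeps the broadband asymptote exact: each
  bandwidth doubling halves the noise density inside the filter, so the
  N0Sπ threshold improves by 10·log₁₀2 ≈ 3.01 dB per octave.
- `ThresholdKernel.from_densities` (explicit density sets, e.g. re-scaled
  ones) interprets SNR relative to the noise power carried by the densities,
  making all thresholds invariant to an overall level scaling.
- Zero stimulus energy through the filter raises a "degenerate stimulus"
  error rather than returning NaN.

## Closed forms

- **Incoherence detection**: the z-transform is invertible, so the smallest
  detectable correlation decrease from ρ_ref is
  Δρ = ρ_ref − tanh(arctanh(ρ̂ρ_ref) − d′σ_bin)/ρ̂, with an error if even
  ρ_tgt = −1 cannot reach criterion.  Sensitivity is best near full
  correlation (arctanh compresses near ±1), which the tests assert.
- **IPD discrimination**: two unit-coherence stimuli lie on the z-circle of
  radius arctanh ρ̂; the chord subtending Δσ equals d′σ_bin at threshold,
  giving Δσ_thr = 2·arcsin(d′σ_bin/(2·arctanh ρ̂)) and an ITD equivalent
  Δσ_thr/(2πf).  The chord identity (closed form ↔ z-space distance) is
  asserted to 1e−9 across a parameter sweep.

## Study battery and parameters

The eight studies are encoded by their stimulus manipulation: constant-IPD
noises with variable correlation (pollack1959 — incoherence detection,
robinson1963, bernstein1996), whole-noise delay Δφ = ωΔt (langford1964,
vanderheijden1999), envelope-only delay Δφ = (ω−ω0)Δt (rabiner1966),
whole-stimulus delay with Δψ = ω0Δt + π (bernstein1985), and the bandwidth
study with N0Sπ/NπS0/N0S0 configurations (vandepar1999).  Default condition
grids are dense programmatic sweeps (e.g. Δt in 0.1 ms steps) because the
original sampled points are only partly recoverable; printed bandwidths
(0.9, 1.0, 1.1 kHz) are taken at face value.  The recorded per-study and
joint parameter sets are inputs copied from the published table, not
quantities this package estimates.

`d_target = 1` is the convention for all tone-in-noise studies; each
study's actual psychometric threshold definition is absorbed into
σ_bin/σ_mon, so re-fitted σ values are identified only up to that common
scale.  For incoherence detection the criterion d′ is exposed as a curve
parameter.

## Fitting

`BinauralDetectionModel` is a scikit-learn estimator: X is a DataFrame of
(study_id + condition columns), y the observed thresholds in dB (Δρ for
incoherence detection), and `fit` minimizes mean squared residual in those
units — equivalently maximizes R², which `score` reports (identical to the
package's own `r_squared`).  Optimization is bounded L-BFGS-B
(ρ̂ ∈ [0.5, 0.999], σ ∈ [0.01, 10]) from six fixed start points plus the
constructor's parameters; the surface can have shallow ridges, and the
multistart is deterministic, so fits are reproducible without a seed.
Parameter sets for which some condition has no threshold are charged a
large fixed residual rather than discarded, keeping the loss finite.
Noise-free synthetic thresholds over the robinson1963 grid are recovered to
well under 1% with R² > 0.9999; with 0.5 dB Gaussian jitter recovery is
within 10% at that grid size (both asserted in the tests).

## Waveform synthesizer (Monte-Carlo cross-check)

`generate_token_pair` realizes the stimulus statistics in a finite token:
complex-Gaussian spectra on the FFT bins inside the band, a shared and an
independent component mixed as right = ρ_N·shared·e^{−iΔφ(ω)} +
√(1−ρ_N²)·indep (the IPD spectrum shapes only the coherent part), scaled
for unit expected per-channel power, plus a tone of amplitude √(2·SNR)
with its IPD split ±Δψ/2 between the ears.  `estimate_gamma` applies the
gammatone *magnitude* response zero-phase (γ is invariant to common phase
response, so discarding the filter phase avoids group-delay bookkeeping),
forms analytic signals, and averages per-token γ̂ over the ensemble,
reporting a combined real/imag standard error.

What the synthesizer emulates: the second-order interaural statistics of
infinitely long stationary stimuli.  What it does not: token-to-token noise
energy variability (known to shape diotic thresholds at small bandwidths),
reproducible-noise-token effects, and any peripheral transduction beyond
linear filtering — so agreement of the two routes validates the spectral
computation, not those phenomena.  Envelope-only delayed waveforms are not
synthesized; that condition is defined spectrally and validated through the
analytic route only.

Default validation: 12 stimuli (ρ_N ∈ {0, 0.5, 1} × Δt ∈ {0, 1.5 ms} ×
tone {absent, SNR 0.25 anti-phasic}), 50 tokens of 1 s at 16 kHz, pass
criterion |γ_analytic − mean γ̂| < 3 SE.  One token-second at 900 Hz
bandwidth carries ~10³ independent samples, so the residual estimator bias
(order 1/T·BW) sits well below the 3-SE band at this ensemble size.

## Known limitations

- Predictions for N0Sπ and NπS0 are identical by construction (the model is
  insensitive to the absolute mean IPD); real listeners are ~4 dB worse in
  NπS0.  Capturing that requires non-sinusoidal IPD-rate channels, outside
  this model's scope.
- Diotic (N0S0) bandwidth dependence at narrow bands is under-predicted:
  the expected-value model has no noise-energy variability.
- Single frequency channel, no phase-locking loss: no frequency dependence
  of binaural advantage beyond the filter.
- Published parameter values are tied to digitized behavioral data and a
  threshold-d′ convention; this package reproduces the model's structural
  predictions and its fitting machinery, not the original table's exact
  fitted values.
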