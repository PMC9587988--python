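# cohear

Binaural unmasking predictions from the **complex interaural correlation
coefficient** — a single-channel, two-parameter-per-branch model of how
listeners detect tones in noise with two ears.

## The problem

A tone masked by noise becomes easier to detect when tone and masker differ
interaurally (the binaural masking level difference): an anti-phasic 500-Hz
tone in diotic noise is detectable some 15 dB below its diotic counterpart.
Mammalian physiology suggests interaural time/phase differences are encoded
by the relative activity of just two broad hemispheric channels with best
IPDs near ±π/4 — a rate code, not a delay-line place code.  `cohear`
implements a mathematical formulation of that two-channel code and uses it
to predict detection thresholds across a classic battery of eight
psychoacoustic studies.

## The model

Writing `l_a(t)`, `r_a(t)` for the analytic ear signals, the two channels
are equivalent to the single complex correlation coefficient

    γ = ⟨l_a r_a*⟩ / √(⟨|l_a|²⟩⟨|r_a|²⟩),

whose modulus |γ| is the *interaural coherence* (inverse of IPD-fluctuation
strength) and whose argument is the mean IPD.  For stationary stimuli γ is
computed exactly from the interaural cross-spectral density S_lr(ω) of the
stimulus weighted by the power spectrum |H(ω)|² of a 4th-order gammatone
filter (ERB 79 Hz, centered 500 Hz):

    γ = ∫S_lr|H|²dω / √(∫S_ll|H|²dω ∫S_rr|H|²dω).

Detection combines two independent cues at criterion sensitivity d′:

    d′_bin = |z[ρ̂γ_ref] − z[ρ̂γ_tgt]| / σ_bin      (Fisher-z feature space)
    d′_mon = SNR_eff / σ_mon                        (post-filter energy cue)
    d′     = √(d′_bin² + d′_mon²),

where z[·] arctanh's the modulus and keeps the argument, and ρ̂ < 1 caps the
usable coherence.  Threshold SNR is the root of d′(SNR) = d′_target.  The
same geometry yields closed forms for incoherence-detection thresholds and
for IPD discrimination, Δσ_thr = 2·arcsin(d′σ_bin / 2·arctanh ρ̂).

## Worked example

Broadband noise (900 Hz band at 500 Hz) carrying a 2.3 ms ITD, anti-phasic
target tone:

```python
import math, numpy as np
from cohear import (GammatoneSpec, StimulusSpec, build_cspd, gamma_from_cspd,
                    published_model_params, solve_threshold_snr,
                    ipd_threshold_as_itd)
from cohear.stimuli import TWO_PI

filt = GammatoneSpec()                      # n=4, ERB 79 Hz, 500 Hz
spec = StimulusSpec(lambda w: np.asarray(w) * 2.3e-3,  # IPD spectrum = ω·Δt
                    1.0, math.pi, TWO_PI * 900.0)

g = gamma_from_cspd(build_cspd(spec), filt)
print(f"coherence |gamma| = {g.modulus:.4f}")
print(f"mean IPD arg(gamma) = {g.argument/math.pi:.4f} pi rad")

params = published_model_params("vanderheijden1999")
thr = solve_threshold_snr(spec, math.pi, filt, params)
print(f"threshold SNR = {10*math.log10(thr):.2f} dB")
print(f"ITD-equivalent IPD threshold = {ipd_threshold_as_itd(params)*1e6:.1f} us")
```

prints

```
coherence |gamma| = 0.8779
mean IPD arg(gamma) = 0.3000 pi rad
threshold SNR = -22.53 dB
ITD-equivalent IPD threshold = 41.1 us
```

The 2.3 ms delay leaves the filtered stimulus partially coherent
(|γ| ≈ 0.88) with its mean IPD at the wrapped carrier phase 0.3π; the model
then predicts the anti-phasic tone becomes detectable at −22.5 dB SNR, and
the same parameter set implies a 41 μs ITD discrimination threshold for
500-Hz tones.

There is also a sklearn-style estimator for fitting the three model
parameters to observed thresholds:

```python
from cohear import BinauralDetectionModel
est = BinauralDetectionModel().fit(X, y)   # X: study_id + condition columns
est.params_, est.score(X, y)               # fitted parameters, R²
```

and a CLI: `cohear predict|fit|validate|ipd-threshold --help`.  The
`validate` subcommand cross-checks the analytic coherence route against a
Monte-Carlo waveform synthesis on a 12-stimulus suite.

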