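"""Monte-Carlo waveform oracle for the analytic coherence route.

Synthesizes finite-duration binaural noise(+tone) tokens with prescribed
interaural correlation, IPD spectrum, and tone, then estimates the complex
correlation coefficient empirically from analytic signals:

    γ̂ = ⟨l_a(t) r_a*(t)⟩_t / sqrt(⟨|l_a|²⟩_t ⟨|r_a|²⟩_t),

time averages standing in for ensemble averages.  Across an ensemble of
independent tokens, mean(γ̂) must agree with the exact spectral-density
computation within sampling error — the package's independent cross-check.

Synthesis conventions: the correlated noise pair is built by mixing a shared
and an independent Gaussian spectrum (right = ρ_N·shared + √(1−ρ_N²)·indep);
the noise IPD spectrum is imposed on the coherent (shared) part of the right
channel as e^{−iΔφ(ω)} (a physical right-ear delay, so the estimated mean
IPD comes out at +Δφ); the tone IPD is split symmetrically, ±Δψ/2 per ear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from .coherence import GammatoneSpec, gammatone_power
from .stimuli import StimulusSpec, TWO_PI

__all__ = [
    "TokenPair",
    "EnsembleEstimate",
    "generate_token_pair",
    "estimate_gamma",
    "write_wav",
]


@dataclass(frozen=True)
class TokenPair:
    """One sampled binaural noise(+tone) token."""

    left: np.ndarray
    right: np.ndarray
    sample_rate: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.left) != len(self.right):
            raise ValueError("left and right must have equal length")
        if not (np.all(np.isfinite(self.left)) and np.all(np.isfinite(self.right))):
            raise ValueError("token samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.left) / self.sample_rate


@dataclass(frozen=True)
class EnsembleEstimate:
    """Across-token mean of γ̂ with a combined (real²+imag²)^½ standard error."""

    gamma_hat: complex
    n_tokens: int
    standard_error: float


def generate_token_pair(
    spec: StimulusSpec,
    duration: float = 1.0,
    sample_rate: float = 16000.0,
    seed: int = 0,
) -> TokenPair:
    """Synthesize one binaural token realizing the stimulus statistics.

    Band-limited Gaussian noise with expected interaural correlation ρ_N and
    expected per-channel power one, plus (optionally) a tone of power
    ``spec.snr`` at the center frequency.  Deterministic given ``seed``.
    """
    f0 = spec.center_frequency / TWO_PI
    if sample_rate < 8.0 * f0:
        raise ValueError(
            f"sample_rate {sample_rate} Hz too low: need >= 8x center frequency ({8*f0} Hz)"
        )
    lo, hi = spec.band
    if hi / TWO_PI >= sample_rate / 2.0:
        raise ValueError("sample_rate too low for the upper band edge")
    if duration * spec.noise_bandwidth / TWO_PI < 10.0:
        warnings.warn(
            "duration x bandwidth < 10: too few independent samples for a "
            "stable coherence estimate",
            stacklevel=2,
        )

    n = int(round(duration * sample_rate))
    omega = TWO_PI * np.fft.rfftfreq(n, 1.0 / sample_rate)
    band = (omega >= max(lo, omega[1] / 2)) & (omega <= hi)
    m = int(band.sum())
    if m == 0:
        raise ValueError("no FFT bins fall inside the noise band; increase duration")

    rng = np.random.default_rng(seed)
    shared = (rng.standard_normal(m) + 1j * rng.standard_normal(m)) / np.sqrt(2.0)
    indep = (rng.standard_normal(m) + 1j * rng.standard_normal(m)) / np.sqrt(2.0)

    rho = spec.noise_correlation
    phase = np.exp(-1j * np.asarray(spec.noise_ipd_spectrum(omega[band]), dtype=float))
    left_band = shared
    right_band = rho * shared * phase + np.sqrt(max(0.0, 1.0 - rho * rho)) * indep

    scale = n / np.sqrt(2.0 * m)  # unit expected per-channel noise power
    spec_l = np.zeros_like(omega, dtype=complex)
    spec_r = np.zeros_like(omega, dtype=complex)
    spec_l[band] = left_band * scale
    spec_r[band] = right_band * scale
    left = np.fft.irfft(spec_l, n)
    right = np.fft.irfft(spec_r, n)

    if spec.tone_present and spec.snr > 0:
        t = np.arange(n) / sample_rate
        amp = np.sqrt(2.0 * spec.snr)  # tone power = snr (noise power is one)
        left = left + amp * np.cos(spec.center_frequency * t + spec.tone_ipd / 2.0)
        right = right + amp * np.cos(spec.center_frequency * t - spec.tone_ipd / 2.0)

    return TokenPair(left=left, right=right, sample_rate=sample_rate, seed=seed)


def _filter_magnitude(x: np.ndarray, sample_rate: float, filt: GammatoneSpec) -> np.ndarray:
    """Zero-phase application of the gammatone magnitude response.

    γ is invariant to any phase response common to both ears, so the filter
    phase is discarded: multiply the spectrum by |H(ω)| only.
    """
    spectrum = np.fft.rfft(x)
    omega = TWO_PI * np.fft.rfftfreq(len(x), 1.0 / sample_rate)
    spectrum *= np.sqrt(gammatone_power(filt, omega))
    return np.fft.irfft(spectrum, len(x))


def gamma_of_token(token: TokenPair, filt: GammatoneSpec | None = None) -> complex:
    """Empirical γ̂ of one token (optionally after peripheral filtering)."""
    left, right = token.left, token.right
    if filt is not None:
        left = _filter_magnitude(left, token.sample_rate, filt)
        right = _filter_magnitude(right, token.sample_rate, filt)
    la = hilbert(left)
    ra = hilbert(right)
    num = np.mean(la * np.conj(ra))
    den = np.sqrt(np.mean(np.abs(la) ** 2) * np.mean(np.abs(ra) ** 2))
    if den == 0:
        raise ValueError("degenerate token: zero energy")
    g = num / den
    if abs(g) > 1.0 + 1e-12:
        raise ValueError(f"per-token |gamma| = {abs(g)} exceeds 1")
    return complex(g)


def estimate_gamma(tokens: Sequence[TokenPair], filt: GammatoneSpec | None = None) -> EnsembleEstimate:
    """Ensemble estimate of γ: across-token mean and standard error."""
    if len(tokens) < 2:
        raise ValueError("estimate_gamma requires at least 2 tokens")
    g = np.array([gamma_of_token(tok, filt) for tok in tokens])
    mean = complex(g.mean())
    se = float(
        np.sqrt(
            (np.var(g.real, ddof=1) + np.var(g.imag, ddof=1)) / len(g)
        )
    )
    return EnsembleEstimate(gamma_hat=mean, n_tokens=len(g), standard_error=se)


def write_wav(path, token: TokenPair) -> None:
    """Export a token pair as a 2-channel float32 WAV (debug/listening aid)."""
    from scipy.io import wavfile

    data = np.stack([token.left, token.right], axis=1).astype(np.float32)
    peak = np.max(np.abs(data))
    if peak > 0:
        data = data / peak * 0.5
    wavfile.write(path, int(token.sample_rate), data)
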