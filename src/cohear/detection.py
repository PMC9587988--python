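"""Two-branch signal-detection model and threshold solvers.

The binaural branch measures the distance between reference and target in
the Fisher-z feature space, d'_bin = |z[ρ̂γ_ref] − z[ρ̂γ_tgt]| / σ_bin; the
monaural branch measures the energy increment the tone causes after
peripheral filtering, d'_mon = SNR_eff / σ_mon.  The two are combined as
independent cues, d' = sqrt(d'_bin² + d'_mon²), and a detection threshold is
the SNR at which d' reaches a criterion value (d_target, conventionally 1).

Closed-form corollaries of the same feature-space geometry give the
incoherence-detection threshold (smallest detectable correlation decrease)
and the IPD-discrimination threshold (chord length on the z-circle):

    Δσ_thr = 2·arcsin(d'·σ_bin / (2·arctanh ρ̂)).
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .coherence import (
    ComplexCoherence,
    GammatoneSpec,
    _filtered_integral,
    _integrate,
    fisher_z,
    gamma_from_cspd,
    gammatone_power,
)
from .stimuli import StimulusSpec, build_cspd

__all__ = [
    "ModelParams",
    "SensitivityBreakdown",
    "ThresholdKernel",
    "d_bin",
    "effective_snr",
    "d_mon",
    "d_total",
    "solve_threshold_snr",
    "incoherence_threshold",
    "ipd_discrimination_threshold",
    "ipd_threshold_as_itd",
]

# threshold search bracket, in log10(linear SNR)
_LOG_SNR_LO = -8.0
_LOG_SNR_HI = 4.0


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the detection model.

    ``rho_hat`` caps the usable coherence (internal decorrelation), the two
    σ set the sensitivity of the binaural and monaural branches, and
    ``d_target`` is the criterion sensitivity defining "threshold".
    ``sigma_mon`` may be None for tasks with no monaural pathway (pure
    incoherence detection).
    """

    rho_hat: float
    sigma_bin: float
    sigma_mon: float | None = None
    d_target: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.rho_hat < 1.0:
            raise ValueError(f"rho_hat must lie in (0, 1), got {self.rho_hat}")
        if self.sigma_bin <= 0:
            raise ValueError(f"sigma_bin must be > 0, got {self.sigma_bin}")
        if self.sigma_mon is not None and self.sigma_mon <= 0:
            raise ValueError(f"sigma_mon must be > 0 or None, got {self.sigma_mon}")
        if self.d_target <= 0:
            raise ValueError(f"d_target must be > 0, got {self.d_target}")


@dataclass(frozen=True)
class SensitivityBreakdown:
    d_bin: float
    d_mon: float

    @property
    def d_total(self) -> float:
        return math.hypot(self.d_bin, self.d_mon)


def d_bin(gamma_ref: ComplexCoherence, gamma_tgt: ComplexCoherence, params: ModelParams) -> float:
    """Binaural sensitivity: z-space distance between reference and target."""
    zr = fisher_z(gamma_ref, params.rho_hat).value
    zt = fisher_z(gamma_tgt, params.rho_hat).value
    return abs(zr - zt) / params.sigma_bin


def effective_snr(spec: StimulusSpec, filt: GammatoneSpec) -> float:
    """Tone-to-noise power ratio after peripheral filtering.

    Narrowband noise (Δω ≪ ERB) passes entirely, so SNR_eff → SNR; for wide
    bands the filter rejects noise energy and SNR_eff grows ∝ Δω.
    """
    if not spec.tone_present:
        raise ValueError("effective_snr requires a tone (tone_present=True)")
    dens = build_cspd(spec)
    noise_power = _filtered_integral(dens.auto_density_left, dens.band, filt, False)
    if noise_power <= 0:
        raise ValueError("degenerate stimulus: no noise energy passes the filter")
    return spec.snr * gammatone_power(filt, spec.center_frequency) / noise_power


def d_mon(spec: StimulusSpec, filt: GammatoneSpec, params: ModelParams) -> float:
    """Monaural sensitivity to the energy increment caused by the tone."""
    if params.sigma_mon is None:
        raise ValueError("sigma_mon is not set: the monaural pathway is unavailable")
    return effective_snr(spec, filt) / params.sigma_mon


def d_total(
    spec_ref: StimulusSpec,
    spec_tgt: StimulusSpec,
    filt: GammatoneSpec,
    params: ModelParams,
) -> SensitivityBreakdown:
    """Combined sensitivity for target (noise+tone) against reference noise."""
    if not spec_ref.same_noise_as(spec_tgt):
        raise ValueError("reference and target must differ only by the added tone")
    g_ref = gamma_from_cspd(build_cspd(spec_ref.without_tone()), filt)
    g_tgt = gamma_from_cspd(build_cspd(spec_tgt), filt)
    db = d_bin(g_ref, g_tgt, params)
    dm = d_mon(spec_tgt, filt, params) if spec_tgt.tone_present else 0.0
    return SensitivityBreakdown(d_bin=db, d_mon=dm)


class ThresholdKernel:
    """Precomputed spectral integrals for fast threshold solving.

    For a fixed noise stimulus and filter, γ of noise and of noise+tone are
    rational functions of the tone SNR:

        γ_tgt(s) = (I_cross + s·h0·e^{iΔψ}) / (I_auto + s·h0),

    with I_cross = ∫S_lr|H|²dω, I_auto = ∫S_ll|H|²dω and h0 = |H(ω0)|².
    The two quadratures are done once here; every d'(SNR) evaluation and
    model-parameter change afterwards is pure arithmetic, which makes
    repeated threshold solving (fitting) cheap.
    """

    def __init__(self, spec_noise: StimulusSpec, tone_ipd: float, filt: GammatoneSpec):
        dens = build_cspd(spec_noise.without_tone())
        self.i_cross = _filtered_integral(dens.cross_density, dens.band, filt, True)
        self.i_auto = _filtered_integral(dens.auto_density_left, dens.band, filt, False)
        if self.i_auto <= 0:
            raise ValueError("degenerate stimulus: no noise energy passes the filter")
        self.h0 = gammatone_power(filt, spec_noise.center_frequency)
        self.tone_ipd = float(tone_ipd)
        self.tone_phasor = cmath.exp(1j * self.tone_ipd)
        # tone power is SNR times the nominal unit noise power
        self.tone_ref = 1.0

    @classmethod
    def from_densities(
        cls, dens, tone_ipd: float, filt: GammatoneSpec, noise_power: float | None = None
    ) -> "ThresholdKernel":
        """Kernel from an explicit (noise-only) density set.

        Here SNR is interpreted relative to the noise power actually carried
        by the densities (``noise_power``, computed from them when not
        given), so an overall level scaling of the densities leaves every
        threshold unchanged.
        """
        self = cls.__new__(cls)
        self.i_cross = _filtered_integral(dens.cross_density, dens.band, filt, True)
        self.i_auto = _filtered_integral(dens.auto_density_left, dens.band, filt, False)
        if self.i_auto <= 0:
            raise ValueError("degenerate stimulus: no noise energy passes the filter")
        self.h0 = gammatone_power(filt, dens.line_frequency)
        self.tone_ipd = float(tone_ipd)
        self.tone_phasor = cmath.exp(1j * self.tone_ipd)
        if noise_power is None:
            noise_power = _integrate(
                lambda w: float(np.real(dens.auto_density_left(w))), *dens.band
            )
        if noise_power <= 0:
            raise ValueError("degenerate stimulus: densities carry no noise power")
        self.tone_ref = float(noise_power)
        return self

    def gamma_ref(self) -> ComplexCoherence:
        return ComplexCoherence(complex(self.i_cross / self.i_auto))

    def gamma_target(self, snr: float) -> ComplexCoherence:
        line = snr * self.tone_ref * self.h0
        v = (self.i_cross + line * self.tone_phasor) / (self.i_auto + line)
        if abs(v) > 1.0:
            v /= abs(v)
        return ComplexCoherence(complex(v))

    def effective_snr(self, snr: float) -> float:
        return snr * self.tone_ref * self.h0 / self.i_auto

    def sensitivity(self, snr: float, params: ModelParams) -> SensitivityBreakdown:
        db = d_bin(self.gamma_ref(), self.gamma_target(snr), params)
        dm = self.effective_snr(snr) / params.sigma_mon if params.sigma_mon is not None else 0.0
        return SensitivityBreakdown(d_bin=db, d_mon=dm)

    def threshold_snr(self, params: ModelParams) -> float:
        """Linear SNR at which d'(SNR) = d_target.

        d' is monotone non-decreasing in SNR for these stimuli, so the root
        is found by bracketed root-finding on log10(SNR), with a coarse scan
        to locate the sign change.
        """

        def resid(log_snr: float) -> float:
            return self.sensitivity(10.0 ** log_snr, params).d_total - params.d_target

        lo, hi = _LOG_SNR_LO, _LOG_SNR_HI
        r_lo, r_hi = resid(lo), resid(hi)
        if r_lo >= 0:
            raise ValueError(
                f"threshold below search bracket [1e{_LOG_SNR_LO:.0f}, 1e{_LOG_SNR_HI:.0f}]: "
                f"d'({10.0**lo:g}) = {r_lo + params.d_target:g} >= d_target"
            )
        if r_hi < 0:
            raise ValueError(
                f"no threshold in search bracket [1e{_LOG_SNR_LO:.0f}, 1e{_LOG_SNR_HI:.0f}]: "
                f"d'({10.0**hi:g}) = {r_hi + params.d_target:g} < d_target "
                "(stimulus carries no usable cue at this sensitivity)"
            )
        # coarse pre-scan so brentq gets a tight, sign-changing bracket
        grid = np.linspace(lo, hi, 49)
        vals = [resid(x) for x in grid]
        for a, b, ra, rb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
            if ra < 0 <= rb:
                lo, hi = a, b
                break
        root = brentq(resid, lo, hi, xtol=1e-13, rtol=8.9e-16)
        snr = 10.0 ** root
        # polish check: relative d' tolerance 1e-6
        assert abs(self.sensitivity(snr, params).d_total - params.d_target) <= 1e-6 * params.d_target
        return snr


def solve_threshold_snr(
    spec_noise: StimulusSpec,
    tone_ipd: float,
    filt: GammatoneSpec,
    params: ModelParams,
) -> float:
    """Threshold SNR (linear) for detecting a tone of IPD ``tone_ipd``."""
    return ThresholdKernel(spec_noise, tone_ipd, filt).threshold_snr(params)


def incoherence_threshold(rho_ref: float, params: ModelParams) -> float:
    """Smallest detectable decrease Δρ from a reference correlation.

    Solves |arctanh(ρ̂ρ_ref) − arctanh(ρ̂(ρ_ref − Δρ))| = d_target·σ_bin in
    closed form (the z-transform is invertible); errors if even full
    decorrelation to ρ = −1 cannot reach the criterion sensitivity.
    """
    if not -1.0 <= rho_ref <= 1.0:
        raise ValueError(f"rho_ref must lie in [-1, 1], got {rho_ref}")
    z_ref = math.atanh(params.rho_hat * rho_ref)
    z_tgt = z_ref - params.d_target * params.sigma_bin
    if z_tgt < math.atanh(-params.rho_hat):
        raise ValueError(
            f"d_target={params.d_target} unreachable from rho_ref={rho_ref}: "
            "even a fully anticorrelated target falls short of the criterion"
        )
    rho_tgt = math.tanh(z_tgt) / params.rho_hat
    return rho_ref - rho_tgt


def ipd_discrimination_threshold(params: ModelParams) -> float:
    """Just-discriminable IPD change (rad) between two fully coherent tones.

    Two unit-coherence stimuli whose mean IPDs differ by Δσ sit on the
    z-circle of radius arctanh(ρ̂); the chord between them is the binaural
    cue, giving Δσ_thr = 2·arcsin(d'·σ_bin / (2·arctanh ρ̂)).
    """
    x = params.d_target * params.sigma_bin / (2.0 * math.atanh(params.rho_hat))
    if x > 1.0:
        raise ValueError(
            "IPD threshold undefined: criterion sensitivity exceeds the "
            f"resolution of the coherence code (arcsin argument {x:.3f} > 1)"
        )
    return 2.0 * math.asin(x)


def ipd_threshold_as_itd(params: ModelParams, frequency_hz: float = 500.0) -> float:
    """IPD-discrimination threshold expressed as an ITD (seconds) at a tone
    frequency."""
    return ipd_discrimination_threshold(params) / (2.0 * math.pi * frequency_hz)
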