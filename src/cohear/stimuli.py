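"""Stimulus parameterizations and their interaural spectral densities.

Every stimulus used by the model is a band of Gaussian noise centered at
``center_frequency`` with rectangular spectrum of width ``noise_bandwidth``,
interaural correlation ``noise_correlation``, an interaural-phase spectrum
``noise_ipd_spectrum`` (IPD of the noise as a function of angular frequency),
and optionally a pure tone at the center frequency with interaural phase
``tone_ipd`` and power ``snr`` relative to the unit-power noise.

The second-order interaural statistics of such a stimulus are fully described
by its cross- and auto-spectral power densities.  The noise contributes a
continuous density (1/Δω over the band, so total noise power is one); the
tone contributes discrete spectral lines at the center frequency.  The two
parts are kept separate so that integrals over the densities are quadrature
plus an algebraic line term — never a delta function smeared onto a grid.

Sign convention: positive IPD means the left ear leads (the right-ear signal
is delayed), so a whole-waveform delay Δt applied to the right ear gives
``noise_ipd_spectrum(ω) = ω·Δt``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

TWO_PI = 2.0 * math.pi

__all__ = [
    "StimulusSpec",
    "SpectralDensitySet",
    "build_cspd",
    "make_experiment_spec",
    "STUDY_IDS",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of one binaural noise(+tone) stimulus.

    Angular quantities are radians; frequencies are angular (rad/s); ``snr``
    is a linear power ratio (dB conversion happens only at I/O boundaries).
    """

    noise_ipd_spectrum: Callable[[np.ndarray], np.ndarray]
    noise_correlation: float
    tone_ipd: float
    noise_bandwidth: float
    center_frequency: float = TWO_PI * 500.0
    tone_present: bool = False
    snr: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.noise_correlation <= 1.0:
            raise ValueError(
                f"noise_correlation must lie in [-1, 1], got {self.noise_correlation}"
            )
        if self.noise_bandwidth <= 0:
            raise ValueError(f"noise_bandwidth must be > 0, got {self.noise_bandwidth}")
        if self.center_frequency <= 0:
            raise ValueError(
                f"center_frequency must be > 0, got {self.center_frequency}"
            )
        if self.snr < 0:
            raise ValueError(f"snr must be >= 0, got {self.snr}")
        if not self.tone_present and self.snr != 0:
            raise ValueError("snr must be 0 when tone_present is False")

    @property
    def band(self) -> tuple[float, float]:
        """Noise-band edges in rad/s, truncated to positive frequencies.

        A nominal lower edge below zero (very wide bands) is clipped to 0;
        the spectral density level 1/Δω is preserved, i.e. the energy that
        would fall at non-positive frequencies is discarded.
        """
        lo = self.center_frequency - self.noise_bandwidth / 2.0
        hi = self.center_frequency + self.noise_bandwidth / 2.0
        return max(lo, 0.0), hi

    def with_tone(self, snr: float, tone_ipd: float | None = None) -> "StimulusSpec":
        """Return a copy with a tone of power ``snr`` added."""
        return dataclasses.replace(
            self,
            tone_present=True,
            snr=snr,
            tone_ipd=self.tone_ipd if tone_ipd is None else tone_ipd,
        )

    def without_tone(self) -> "StimulusSpec":
        return dataclasses.replace(self, tone_present=False, snr=0.0)

    def same_noise_as(self, other: "StimulusSpec", omega_probe=None) -> bool:
        """True if the two specs share all noise parameters (tone may differ)."""
        if omega_probe is None:
            lo, hi = self.band
            omega_probe = np.linspace(lo, hi, 7)
        return (
            self.noise_correlation == other.noise_correlation
            and self.noise_bandwidth == other.noise_bandwidth
            and self.center_frequency == other.center_frequency
            and np.allclose(
                np.asarray(self.noise_ipd_spectrum(omega_probe), dtype=float),
                np.asarray(other.noise_ipd_spectrum(omega_probe), dtype=float),
            )
        )


@dataclass(frozen=True)
class SpectralDensitySet:
    """Cross/auto spectral densities of a stimulus: continuous + line parts.

    ``cross_density`` and the auto densities are functions of angular
    frequency with units 1/(rad/s); the line terms are dimensionless powers
    located at ``line_frequency`` (the tone).
    """

    cross_density: Callable[[np.ndarray], np.ndarray]
    cross_line: complex
    auto_density_left: Callable[[np.ndarray], np.ndarray]
    auto_density_right: Callable[[np.ndarray], np.ndarray]
    auto_line_left: float
    auto_line_right: float
    band: tuple[float, float]
    line_frequency: float

    def scaled(self, k: float) -> "SpectralDensitySet":
        """All densities and lines scaled by ``k`` (an overall level change)."""
        if k <= 0:
            raise ValueError("scale factor must be > 0")
        return SpectralDensitySet(
            cross_density=lambda w: k * self.cross_density(w),
            cross_line=k * self.cross_line,
            auto_density_left=lambda w: k * self.auto_density_left(w),
            auto_density_right=lambda w: k * self.auto_density_right(w),
            auto_line_left=k * self.auto_line_left,
            auto_line_right=k * self.auto_line_right,
            band=self.band,
            line_frequency=self.line_frequency,
        )


def build_cspd(spec: StimulusSpec) -> SpectralDensitySet:
    """Interaural spectral densities of a noise(+tone) stimulus.

    The continuous cross density is (ρ_N/Δω)·e^{iΔφ(ω)} over the noise band
    (only interaurally coherent energy appears in the cross spectrum, hence
    the ρ_N scale); the auto densities are 1/Δω over the band on both sides
    (total noise power one).  A present tone adds a cross line SNR·e^{iΔψ}
    and auto lines SNR at the center frequency.
    """
    lo, hi = spec.band
    rho = spec.noise_correlation
    dw = spec.noise_bandwidth
    ipd = spec.noise_ipd_spectrum

    def cross_density(w):
        w = np.asarray(w, dtype=float)
        inside = (w >= lo) & (w <= hi)
        phase = np.where(inside, np.asarray(ipd(w), dtype=float), 0.0)
        return np.where(inside, (rho / dw) * np.exp(1j * phase), 0.0 + 0.0j)

    def auto_density(w):
        w = np.asarray(w, dtype=float)
        return np.where((w >= lo) & (w <= hi), 1.0 / dw, 0.0)

    if spec.tone_present:
        cross_line = spec.snr * np.exp(1j * spec.tone_ipd)
        auto_line = float(spec.snr)
    else:
        cross_line = 0.0 + 0.0j
        auto_line = 0.0

    return SpectralDensitySet(
        cross_density=cross_density,
        cross_line=complex(cross_line),
        auto_density_left=auto_density,
        auto_density_right=auto_density,
        auto_line_left=auto_line,
        auto_line_right=auto_line,
        band=(lo, hi),
        line_frequency=spec.center_frequency,
    )


# --------------------------------------------------------------------------
# Study battery: construction of the stimulus for each of the eight studies.
#
# Per-study free condition parameters (all optional keys have study defaults):
#   delta_t_ms     noise (or whole-stimulus) ITD in milliseconds
#   rho_n          noise interaural correlation
#   bandwidth_hz   noise bandwidth in Hz
#   tone_ipd_rad   tone IPD in radians
#   noise_ipd_rad  constant noise IPD in radians
#   center_frequency_hz  (all studies default to 500 Hz)
# --------------------------------------------------------------------------

STUDY_IDS = (
    "pollack1959",
    "robinson1963",
    "bernstein1996",
    "langford1964",
    "vanderheijden1999",
    "rabiner1966",
    "bernstein1985",
    "vandepar1999",
)

_ZERO_IPD = lambda w: np.zeros_like(np.asarray(w, dtype=float))  # noqa: E731


def _constant_ipd(value: float):
    def ipd(w):
        return np.full_like(np.asarray(w, dtype=float), value)

    return ipd


def _linear_ipd(delta_t_s: float):
    """Whole-waveform ITD: Δφ(ω) = ω·Δt."""

    def ipd(w):
        return np.asarray(w, dtype=float) * delta_t_s

    return ipd


def _envelope_ipd(delta_t_s: float, omega0: float):
    """Envelope-only ITD: Δφ(ω) = (ω − ω0)·Δt; the carrier IPD stays zero."""

    def ipd(w):
        return (np.asarray(w, dtype=float) - omega0) * delta_t_s

    return ipd


def _require_range(study: str, name: str, value: float, lo: float, hi: float) -> float:
    if not lo <= value <= hi:
        raise ValueError(
            f"{study}: condition parameter {name}={value} outside the study's "
            f"range [{lo}, {hi}]"
        )
    return float(value)


def make_experiment_spec(study_id: str, condition_params: Mapping | None = None) -> StimulusSpec:
    """Build the noise (reference) stimulus for one condition of one study.

    The returned spec carries ``tone_ipd`` of the study's target tone but has
    ``tone_present=False``; add the tone at a given SNR with
    :meth:`StimulusSpec.with_tone`.
    """
    p = dict(condition_params or {})
    if study_id not in STUDY_IDS:
        raise ValueError(f"unknown study_id {study_id!r}; expected one of {STUDY_IDS}")

    omega0 = TWO_PI * float(p.pop("center_frequency_hz", 500.0))

    def take(name, default):
        return p.pop(name, default)

    if study_id == "pollack1959":
        # Incoherence detection in 1-kHz-wide diotic-phase noise; no tone.
        rho = _require_range(study_id, "rho_n", take("rho_n", 1.0), -1.0, 1.0)
        bw = _require_range(study_id, "bandwidth_hz", take("bandwidth_hz", 1000.0), 5.0, 1000.0)
        spec = StimulusSpec(_ZERO_IPD, rho, 0.0, TWO_PI * bw, omega0)
    elif study_id == "robinson1963":
        rho = _require_range(study_id, "rho_n", take("rho_n", 1.0), -1.0, 1.0)
        bw = _require_range(study_id, "bandwidth_hz", take("bandwidth_hz", 900.0), 900.0, 900.0)
        psi = float(take("tone_ipd_rad", math.pi))
        spec = StimulusSpec(_ZERO_IPD, rho, psi, TWO_PI * bw, omega0)
    elif study_id == "bernstein1996":
        rho = _require_range(study_id, "rho_n", take("rho_n", 1.0), -1.0, 1.0)
        bw = _require_range(study_id, "bandwidth_hz", take("bandwidth_hz", 900.0), 25.0, 900.0)
        spec = StimulusSpec(_ZERO_IPD, rho, math.pi, TWO_PI * bw, omega0)
    elif study_id in ("langford1964", "vanderheijden1999"):
        dt = _require_range(study_id, "delta_t_ms", take("delta_t_ms", 0.0), 0.0, 12.0)
        psi = float(take("tone_ipd_rad", math.pi))
        bw = _require_range(study_id, "bandwidth_hz", take("bandwidth_hz", 900.0), 900.0, 900.0)
        spec = StimulusSpec(_linear_ipd(dt * 1e-3), 1.0, psi, TWO_PI * bw, omega0)
    elif study_id == "rabiner1966":
        dt = _require_range(study_id, "delta_t_ms", take("delta_t_ms", 0.0), 0.0, 12.0)
        bw = _require_range(study_id, "bandwidth_hz", take("bandwidth_hz", 1100.0), 1100.0, 1100.0)
        spec = StimulusSpec(_envelope_ipd(dt * 1e-3, omega0), 1.0, math.pi, TWO_PI * bw, omega0)
    elif study_id == "bernstein1985":
        # ITD on the whole stimulus (noise and tone): tone IPD = ω0·Δt + π.
        dt = _require_range(study_id, "delta_t_ms", take("delta_t_ms", 0.0), 0.0, 12.0)
        rho = _require_range(study_id, "rho_n", take("rho_n", 1.0), 0.498, 1.0)
        bw = _require_range(study_id, "bandwidth_hz", take("bandwidth_hz", 900.0), 100.0, 900.0)
        spec = StimulusSpec(
            _linear_ipd(dt * 1e-3), rho, omega0 * dt * 1e-3 + math.pi, TWO_PI * bw, omega0
        )
    elif study_id == "vandepar1999":
        phi = float(take("noise_ipd_rad", 0.0))
        psi = float(take("tone_ipd_rad", math.pi))
        bw = _require_range(study_id, "bandwidth_hz", take("bandwidth_hz", 1000.0), 5.0, 1000.0)
        spec = StimulusSpec(_constant_ipd(phi) if phi != 0.0 else _ZERO_IPD, 1.0, psi, TWO_PI * bw, omega0)
    else:  # pragma: no cover - guarded above
        raise AssertionError(study_id)

    if p:
        raise ValueError(f"{study_id}: unknown condition parameters {sorted(p)}")
    return spec
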