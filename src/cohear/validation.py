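"""Analytic-vs-Monte-Carlo cross-validation of the coherence computation.

The default suite spans 12 stimuli — correlations {0, 0.5, 1} × ITDs
{0, 1.5 ms} × tone {absent, SNR 0.25 anti-phasic} — and checks that the
exact spectral-density γ lies within 3 standard errors of the waveform
ensemble estimate for each.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .coherence import GammatoneSpec, gamma_from_cspd
from .stimuli import StimulusSpec, TWO_PI, build_cspd
from .waveform import estimate_gamma, generate_token_pair

__all__ = ["default_validation_suite", "run_validation"]


def default_validation_suite() -> list[StimulusSpec]:
    """12 spot-check stimuli spanning correlation, ITD and tone SNR."""
    suite = []
    for rho in (0.0, 0.5, 1.0):
        for dt_ms in (0.0, 1.5):
            dt = dt_ms * 1e-3

            def ipd(w, _dt=dt):
                return np.asarray(w, dtype=float) * _dt

            base = StimulusSpec(ipd, rho, math.pi, TWO_PI * 900.0)
            suite.append(base)
            suite.append(base.with_tone(0.25))
    return suite


def run_validation(
    seed: int = 0,
    n_tokens: int = 50,
    duration: float = 1.0,
    sample_rate: float = 16000.0,
    filt: GammatoneSpec | None = None,
    suite: list[StimulusSpec] | None = None,
) -> pd.DataFrame:
    """Run the analytic-vs-Monte-Carlo comparison; one row per stimulus.

    Columns report both γ estimates, the ensemble standard error, the
    discrepancy in SE units, and a 3-SE pass flag.  All randomness derives
    from ``seed``; per-token seeds are recorded implicitly as
    seed*100000 + stimulus_index*1000 + token_index.
    """
    filt = filt or GammatoneSpec()
    suite = default_validation_suite() if suite is None else suite
    rows = []
    for i, spec in enumerate(suite):
        analytic = gamma_from_cspd(build_cspd(spec), filt).value
        tokens = [
            generate_token_pair(
                spec, duration, sample_rate, seed=seed * 100000 + i * 1000 + k
            )
            for k in range(n_tokens)
        ]
        est = estimate_gamma(tokens, filt)
        err = abs(est.gamma_hat - analytic)
        n_se = err / est.standard_error if est.standard_error > 0 else np.inf
        rows.append(
            {
                "stimulus": i,
                "rho_n": spec.noise_correlation,
                "delta_t_ms": spec.noise_ipd_spectrum(np.array([1.0]))[0] * 1e3,
                "snr": spec.snr,
                "gamma_analytic_re": analytic.real,
                "gamma_analytic_im": analytic.imag,
                "gamma_mc_re": est.gamma_hat.real,
                "gamma_mc_im": est.gamma_hat.imag,
                "standard_error": est.standard_error,
                "n_tokens": est.n_tokens,
                "n_se": n_se,
                "pass_3se": bool(n_se < 3.0),
            }
        )
    return pd.DataFrame(rows)
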