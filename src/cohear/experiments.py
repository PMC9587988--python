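"""Eight-study battery: condition grids, threshold prediction, R² scoring.

Each study is identified by first author and year.  Seven are tone-in-noise
detection tasks whose predictions are threshold SNRs in dB; pollack1959 is
incoherence detection, predicted as a just-detectable correlation decrease
Δρ.  The per-study and joint model parameters of the published battery are
recorded here so predictions can be generated without any fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coherence import GammatoneSpec
from .detection import ModelParams, ThresholdKernel, incoherence_threshold
from .stimuli import STUDY_IDS, make_experiment_spec

__all__ = [
    "ExperimentConfig",
    "PUBLISHED_PARAMS",
    "JOINT_PARAMS",
    "published_model_params",
    "default_condition_grid",
    "default_config",
    "build_predictors",
    "predict_thresholds",
    "run_battery",
    "r_squared",
    "fit_parameters",
]

# Published per-study parameters (rho_hat, sigma_bin, sigma_mon) and the
# variance each parameterization explained.  pollack1959 has no monaural
# pathway (incoherence detection carries no energy cue).
PUBLISHED_PARAMS: dict[str, dict] = {
    "pollack1959": dict(rho_hat=0.92, sigma_bin=0.42, sigma_mon=None, r_squared=0.97),
    "robinson1963": dict(rho_hat=0.92, sigma_bin=0.31, sigma_mon=0.76, r_squared=0.98),
    "bernstein1996": dict(rho_hat=0.97, sigma_bin=0.54, sigma_mon=0.76, r_squared=0.97),
    "langford1964": dict(rho_hat=0.95, sigma_bin=0.33, sigma_mon=0.70, r_squared=0.96),
    "vanderheijden1999": dict(rho_hat=0.90, sigma_bin=0.19, sigma_mon=0.61, r_squared=0.95),
    "rabiner1966": dict(rho_hat=0.85, sigma_bin=0.24, sigma_mon=0.71, r_squared=0.95),
    "bernstein1985": dict(rho_hat=0.89, sigma_bin=0.52, sigma_mon=0.93, r_squared=0.96),
    "vandepar1999": dict(rho_hat=0.97, sigma_bin=0.38, sigma_mon=0.76, r_squared=0.91),
}

# One parameter set over all eight studies.
JOINT_PARAMS = dict(rho_hat=0.96, sigma_bin=0.40, sigma_mon=0.74, r_squared=0.93)

_RESULT_COLUMNS = {
    "threshold_db",
    "delta_rho",
    "predicted_db",
    "predicted_delta_rho",
    "study_id",
}


def published_model_params(study_id: str, d_target: float = 1.0) -> ModelParams:
    """The published parameter set of one study as :class:`ModelParams`."""
    if study_id == "joint":
        row = JOINT_PARAMS
    elif study_id in PUBLISHED_PARAMS:
        row = PUBLISHED_PARAMS[study_id]
    else:
        raise ValueError(f"unknown study_id {study_id!r}")
    return ModelParams(
        rho_hat=row["rho_hat"],
        sigma_bin=row["sigma_bin"],
        sigma_mon=row["sigma_mon"],
        d_target=d_target,
    )


def default_condition_grid(study_id: str) -> list[dict]:
    """Programmatic condition grid tracing each study's stimulus manipulation."""
    pi = math.pi
    if study_id == "pollack1959":
        return [{"rho_ref": round(r, 3)} for r in np.linspace(0.0, 1.0, 11)]
    if study_id == "robinson1963":
        return [
            {"rho_n": round(r, 3), "tone_ipd_rad": psi}
            for psi in (0.0, pi)
            for r in np.linspace(-1.0, 1.0, 9)
        ]
    if study_id == "bernstein1996":
        return [
            {"rho_n": r, "bandwidth_hz": bw}
            for bw in (25.0, 50.0, 100.0, 200.0, 400.0, 900.0)
            for r in (-1.0, -0.5, 0.0, 0.5, 0.8, 1.0)
        ]
    if study_id in ("langford1964", "vanderheijden1999"):
        step = 0.2 if study_id == "langford1964" else 0.1
        return [
            {"delta_t_ms": round(dt, 3), "tone_ipd_rad": psi}
            for psi in (0.0, pi)
            for dt in np.arange(0.0, 4.0 + step / 2, step)
        ]
    if study_id == "rabiner1966":
        return [{"delta_t_ms": round(dt, 3)} for dt in np.arange(0.0, 4.01, 0.1)]
    if study_id == "bernstein1985":
        return [
            {"delta_t_ms": round(dt, 3), "rho_n": r, "bandwidth_hz": bw}
            for bw in (100.0, 900.0)
            for r in (0.498, 0.8, 0.992, 1.0)
            for dt in np.arange(0.0, 4.01, 0.25)
        ]
    if study_id == "vandepar1999":
        bands = np.geomspace(5.0, 1000.0, 12)
        configs = [
            {"noise_ipd_rad": 0.0, "tone_ipd_rad": pi},  # N0Spi
            {"noise_ipd_rad": pi, "tone_ipd_rad": 0.0},  # NpiS0
            {"noise_ipd_rad": 0.0, "tone_ipd_rad": 0.0},  # N0S0 (monaural only)
        ]
        return [
            {**cfg, "bandwidth_hz": round(bw, 2)} for cfg in configs for bw in bands
        ]
    raise ValueError(f"unknown study_id {study_id!r}")


@dataclass(frozen=True)
class ExperimentConfig:
    """One study, its condition grid, model parameters, and filter."""

    study_id: str
    condition_grid: list = field(default_factory=list)
    model_params: ModelParams | None = None
    filt: GammatoneSpec = field(default_factory=GammatoneSpec)

    def __post_init__(self) -> None:
        if self.study_id not in STUDY_IDS:
            raise ValueError(f"unknown study_id {self.study_id!r}")
        if not self.condition_grid:
            raise ValueError("condition_grid must be non-empty")


def default_config(
    study_id: str,
    model_params: ModelParams | None = None,
    filt: GammatoneSpec | None = None,
) -> ExperimentConfig:
    return ExperimentConfig(
        study_id=study_id,
        condition_grid=default_condition_grid(study_id),
        model_params=model_params or published_model_params(study_id),
        filt=filt or GammatoneSpec(),
    )


def build_predictors(rows, filt: GammatoneSpec):
    """Compile (study_id, condition) rows into fast threshold predictors.

    Each returned callable maps :class:`ModelParams` to the predicted
    threshold (dB SNR, or Δρ for incoherence detection).  The spectral
    quadratures are done once per condition here, so repeatedly re-solving
    under different model parameters — the inner loop of fitting — costs
    only scalar root-finding.
    """
    predictors = []
    for study_id, cond in rows:
        if study_id == "pollack1959":
            rho_ref = float(cond.get("rho_ref", 1.0))

            def predict(params: ModelParams, _r=rho_ref) -> float:
                return incoherence_threshold(_r, params)

        else:
            spec = make_experiment_spec(study_id, cond)
            kernel = ThresholdKernel(spec, spec.tone_ipd, filt)

            def predict(params: ModelParams, _k=kernel) -> float:
                return 10.0 * math.log10(_k.threshold_snr(params))

        predictors.append(predict)
    return predictors


def _rows_from_frame(frame: pd.DataFrame) -> list[tuple[str, dict]]:
    cond_cols = [c for c in frame.columns if c not in _RESULT_COLUMNS]
    rows = []
    for _, row in frame.iterrows():
        cond = {c: row[c] for c in cond_cols if pd.notna(row[c])}
        rows.append((str(row["study_id"]), cond))
    return rows


def predict_thresholds(
    frame: pd.DataFrame,
    params: ModelParams,
    filt: GammatoneSpec | None = None,
    on_error: str = "raise",
) -> np.ndarray:
    """Predicted thresholds for a table of (study_id, condition) rows."""
    filt = filt or GammatoneSpec()
    out = np.empty(len(frame))
    for i, predictor in enumerate(build_predictors(_rows_from_frame(frame), filt)):
        try:
            out[i] = predictor(params)
        except ValueError:
            if on_error == "raise":
                raise
            out[i] = np.nan
    return out


def run_battery(config: ExperimentConfig, on_error: str = "raise") -> pd.DataFrame:
    """Predicted thresholds for every condition of one study.

    Returns one row per condition with the condition parameters and a
    ``predicted_db`` column (``predicted_delta_rho`` for pollack1959).
    Solver failures raise, annotated with the condition, unless
    ``on_error="nan"``.
    """
    params = config.model_params or published_model_params(config.study_id)
    table = pd.DataFrame(config.condition_grid)
    table.insert(0, "study_id", config.study_id)
    col = "predicted_delta_rho" if config.study_id == "pollack1959" else "predicted_db"
    values = np.empty(len(table))
    rows = [(config.study_id, dict(c)) for c in config.condition_grid]
    predictors = build_predictors(rows, config.filt)
    for i, (predictor, cond) in enumerate(zip(predictors, config.condition_grid)):
        try:
            values[i] = predictor(params)
        except ValueError as err:
            if on_error == "raise":
                raise ValueError(f"{config.study_id} condition {cond}: {err}") from err
            values[i] = np.nan
    table[col] = values
    return table


def _threshold_values(frame, prefer=("threshold_db", "delta_rho", "predicted_db", "predicted_delta_rho")):
    if isinstance(frame, pd.DataFrame):
        for col in prefer:
            if col in frame.columns:
                return np.asarray(frame[col], dtype=float)
        raise ValueError(f"no threshold column among {prefer} in {list(frame.columns)}")
    return np.asarray(frame, dtype=float)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 − Σ(y−f)²/Σ(y−ȳ)².

    Accepts threshold tables (DataFrames with a threshold column) or plain
    arrays; rows must correspond one-to-one.  May be negative for fits worse
    than the mean.  Errors on fewer than two observations or zero variance.
    """
    y = _threshold_values(observed)
    f = _threshold_values(predicted, prefer=("predicted_db", "predicted_delta_rho", "threshold_db", "delta_rho"))
    if len(y) != len(f):
        raise ValueError(f"row count mismatch: {len(y)} observed vs {len(f)} predicted")
    if len(y) < 2:
        raise ValueError("r_squared requires at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed thresholds have zero variance")
    return 1.0 - float(np.sum((y - f) ** 2)) / ss_tot


def fit_parameters(observed: pd.DataFrame, config: ExperimentConfig) -> ModelParams:
    """Fit (ρ̂, σ_bin, σ_mon) to observed thresholds of one study.

    Thin wrapper over :class:`cohear.model.BinauralDetectionModel`; residuals
    are taken in dB for tone-in-noise studies and in Δρ for incoherence
    detection.
    """
    from .model import BinauralDetectionModel  # local import: model builds on this module

    if len(observed) < 3:
        raise ValueError("fitting requires at least 3 observed thresholds")
    y = _threshold_values(observed)
    if np.ptp(y) == 0.0:
        raise ValueError("observed thresholds have zero variance; nothing to fit")
    X = observed.drop(columns=[c for c in ("threshold_db", "delta_rho") if c in observed.columns])
    if "study_id" not in X.columns:
        X = X.copy()
        X.insert(0, "study_id", config.study_id)
    d_target = config.model_params.d_target if config.model_params else 1.0
    est = BinauralDetectionModel(
        d_target=d_target,
        order=config.filt.order,
        erb_hz=config.filt.erb,
    )
    est.fit(X, y)
    return est.params_
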