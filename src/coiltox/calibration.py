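"""Exponential calibration of emissions against device scores.

Total carbonyls per gram of e-liquid are modelled as y = a * exp(b * x)
where x is a device score.  The exponential form mirrors the exponential
temperature dependence of solvent vaporization and degradation.  Fitting
is done either by ordinary least squares of ln y on x (a spreadsheet-style
"exponential trendline"; the default) or by nonlinear least squares on the
original scale initialized from the log-linear solution.  Goodness of fit
and predictive accuracy are both reported as a coefficient of
determination R² = 1 - SSres/SStot computed on the ORIGINAL scale, with
predictions taken as-is (identity line).  That convention can go negative
when a calibrated curve predicts worse than the mean of the observations —
a meaningful outcome when comparing candidate scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit

from coiltox.device_model import Aggregation, AtomizerDevice
from coiltox.emissions import DeviceEmissionSummary
from coiltox.scoring import MissingVariableError, ScoreModel, evaluate_score_model

__all__ = [
    "CalibrationFit",
    "PredictionEvaluation",
    "ModelResult",
    "FitConvergenceError",
    "fit_exponential",
    "predictive_r2",
    "train_predict_evaluate",
    "rank_models",
]

_METHODS = ("log_linear_ols", "nonlinear_ls")


class FitConvergenceError(RuntimeError):
    """Nonlinear refinement failed; carries the log-linear fallback fit."""

    def __init__(self, message: str, fallback: "CalibrationFit"):
        super().__init__(message)
        self.fallback = fallback


def _r_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    """1 - SSres/SStot; returns 1.0 for an exact fit to constant data."""
    ss_res = float(np.sum((observed - fitted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        # constant data: an (up to rounding) exact fit scores 1, anything else -inf
        exact = ss_res <= 1e-20 * max(1.0, float(np.sum(observed**2)))
        return 1.0 if exact else -np.inf
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class CalibrationFit:
    """Fitted exponential y = a * exp(b * x) with goodness-of-fit diagnostics.

    ``fit_r2`` is on the original emission scale; ``log_r2`` is the R² of
    the underlying ln y on x regression (what a spreadsheet trendline
    prints).  ``b_conf_int`` / ``log_a_conf_int`` are 95% intervals from
    the log-scale OLS.
    """

    a: float
    b: float
    method: str
    fit_r2: float
    log_r2: float
    residuals: np.ndarray = field(repr=False)
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    b_conf_int: tuple[float, float] = (np.nan, np.nan)
    log_a_conf_int: tuple[float, float] = (np.nan, np.nan)

    @property
    def n(self) -> int:
        return int(self.x.size)

    def predict(self, x) -> np.ndarray:
        return predict(self, x)


def fit_exponential(
    x: Sequence[float],
    y: Sequence[float],
    weights: Optional[Sequence[float]] = None,
    method: str = "log_linear_ols",
) -> CalibrationFit:
    """Fit y = a * exp(b * x).

    ``log_linear_ols`` regresses ln y on x (optionally weighted) and maps
    the intercept/slope back to (a, b).  ``nonlinear_ls`` minimizes the
    original-scale sum of squares starting from the log-linear solution and
    raises :class:`FitConvergenceError` carrying that fallback on failure.
    Requires n >= 3 points, non-constant x and, for the log route, all y > 0.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError(f"exponential fit needs >= 3 points, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all scores identical")
    if np.any(y <= 0):
        bad = int(np.flatnonzero(y <= 0)[0])
        raise ValueError(
            f"log-linear exponential fit requires y > 0; y[{bad}] = {y[bad]}"
        )
    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape or np.any(w <= 0):
            raise ValueError("weights must be positive and match x in length")

    design = sm.add_constant(x)
    log_y = np.log(y)
    model = sm.WLS(log_y, design, weights=w) if w is not None else sm.OLS(log_y, design)
    result = model.fit()
    log_a, b = result.params
    conf = result.conf_int(alpha=0.05)
    a = float(np.exp(log_a))
    b = float(b)
    log_r2 = _r_squared(log_y, result.fittedvalues)

    if method == "nonlinear_ls":
        fallback = _build_fit(
            a, b, "log_linear_ols", x, y, log_r2, tuple(conf[1]), tuple(conf[0])
        )
        try:
            (a, b), _ = curve_fit(
                lambda xx, aa, bb: aa * np.exp(bb * xx),
                x,
                y,
                p0=[a, b],
                sigma=None if w is None else 1.0 / np.sqrt(w),
                maxfev=10000,
            )
        except RuntimeError as exc:
            raise FitConvergenceError(
                f"nonlinear least squares failed to converge: {exc}", fallback
            ) from exc
        log_r2 = _r_squared(log_y, np.log(a) + b * x)

    return _build_fit(float(a), float(b), method, x, y, log_r2, tuple(conf[1]), tuple(conf[0]))


def _build_fit(a, b, method, x, y, log_r2, b_ci, log_a_ci) -> CalibrationFit:
    fitted = a * np.exp(b * x)
    return CalibrationFit(
        a=a,
        b=b,
        method=method,
        fit_r2=_r_squared(y, fitted),
        log_r2=log_r2,
        residuals=y - fitted,
        x=x,
        y=y,
        b_conf_int=(float(b_ci[0]), float(b_ci[1])),
        log_a_conf_int=(float(log_a_ci[0]), float(log_a_ci[1])),
    )


def predict(fit: CalibrationFit, x) -> np.ndarray:
    """Evaluate the fitted curve a * exp(b * x); always positive."""
    return fit.a * np.exp(fit.b * np.asarray(x, dtype=float))


def predictive_r2(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Out-of-sample R² = 1 - SSres/SStot with predictions taken as-is.

    Not a squared correlation: predictions worse than the observation mean
    give a negative value, and only exact prediction gives 1.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D arrays of equal length")
    if obs.size < 2:
        raise ValueError(f"predictive R² needs >= 2 pairs, got {obs.size}")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed values are all identical; R² undefined")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


@dataclass(frozen=True)
class PredictionEvaluation:
    """Observed/predicted pairs for an evaluation fleet and their R²."""

    predictive_r2: float
    pairs: tuple  # of (device_id, observed, predicted)
    train_ids: tuple
    eval_ids: tuple


def _scores_and_means(
    model: ScoreModel,
    fleet: Sequence[AtomizerDevice],
    summaries: dict[str, DeviceEmissionSummary],
    aggregation: Aggregation,
):
    ids, xs, ys, ws = [], [], [], []
    for device in fleet:
        if device.device_id not in summaries:
            raise ValueError(f"no emission summary for device '{device.device_id}'")
        summary = summaries[device.device_id]
        ids.append(device.device_id)
        xs.append(evaluate_score_model(model, device, aggregation))
        ys.append(summary.mean_emission)
        ws.append(summary.standard_error)
    return ids, np.array(xs), np.array(ys), np.array(ws)


def train_predict_evaluate(
    model: ScoreModel,
    train_fleet: Sequence[AtomizerDevice],
    train_summaries: dict[str, DeviceEmissionSummary],
    eval_fleet: Sequence[AtomizerDevice],
    eval_summaries: dict[str, DeviceEmissionSummary],
    method: str = "log_linear_ols",
    aggregation: Aggregation = Aggregation.SUM_WIRES,
    weights: str = "none",
) -> tuple[CalibrationFit, PredictionEvaluation]:
    """Calibrate on the training fleet, predict the evaluation fleet.

    The evaluation fleet may overlap the training fleet (the study design
    evaluates all devices with a subset in training); both id sets are
    recorded so a strict held-out evaluation is equally expressible.
    ``weights='inverse_variance'`` weights training devices by 1/SE².
    """
    if len(train_fleet) < 3:
        raise ValueError(f"training fleet needs >= 3 devices, got {len(train_fleet)}")
    if len(eval_fleet) < 2:
        raise ValueError(f"evaluation fleet needs >= 2 devices, got {len(eval_fleet)}")
    if weights not in ("none", "inverse_variance"):
        raise ValueError(f"weights must be 'none' or 'inverse_variance', got {weights!r}")
    train_ids, x_train, y_train, se_train = _scores_and_means(
        model, train_fleet, train_summaries, aggregation
    )
    w = None
    if weights == "inverse_variance":
        if np.any(se_train <= 0):
            raise ValueError("inverse-variance weighting requires positive standard errors")
        w = 1.0 / se_train**2
    fit = fit_exponential(x_train, y_train, weights=w, method=method)
    eval_ids, x_eval, y_eval, _ = _scores_and_means(
        model, eval_fleet, eval_summaries, aggregation
    )
    y_pred = predict(fit, x_eval)
    evaluation = PredictionEvaluation(
        predictive_r2=predictive_r2(y_eval, y_pred),
        pairs=tuple(zip(eval_ids, y_eval.tolist(), y_pred.tolist())),
        train_ids=tuple(train_ids),
        eval_ids=tuple(eval_ids),
    )
    return fit, evaluation


@dataclass(frozen=True)
class ModelResult:
    """Outcome of calibrating and evaluating one candidate score model."""

    model: ScoreModel
    fit_r2: Optional[float] = None
    predictive_r2: Optional[float] = None
    fit: Optional[CalibrationFit] = None
    evaluation: Optional[PredictionEvaluation] = None
    error: Optional[str] = None

    @property
    def failed(self) -> bool:
        return self.error is not None


def rank_models(
    models: Sequence[ScoreModel],
    train_fleet: Sequence[AtomizerDevice],
    train_summaries: dict[str, DeviceEmissionSummary],
    eval_fleet: Sequence[AtomizerDevice],
    eval_summaries: dict[str, DeviceEmissionSummary],
    method: str = "log_linear_ols",
    aggregation: Aggregation = Aggregation.SUM_WIRES,
) -> list[ModelResult]:
    """Evaluate every candidate score and sort by predictive R² (descending).

    Models that error on any device (e.g., a power model on a fleet without
    power settings) are reported as failed at the end of the ranking, never
    silently dropped.  Ties break lexicographically by model name.
    """
    if not models:
        raise ValueError("rank_models needs at least one candidate model")
    results: list[ModelResult] = []
    for model in models:
        try:
            fit, evaluation = train_predict_evaluate(
                model,
                train_fleet,
                train_summaries,
                eval_fleet,
                eval_summaries,
                method=method,
                aggregation=aggregation,
            )
        except (ValueError, MissingVariableError, FitConvergenceError) as exc:
            results.append(ModelResult(model=model, error=str(exc)))
            continue
        results.append(
            ModelResult(
                model=model,
                fit_r2=fit.fit_r2,
                predictive_r2=evaluation.predictive_r2,
                fit=fit,
                evaluation=evaluation,
            )
        )
    successes = [r for r in results if not r.failed]
    failures = [r for r in results if r.failed]
    successes.sort(key=lambda r: (-r.predictive_r2, r.model.name))
    failures.sort(key=lambda r: r.model.name)
    return successes + failures
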