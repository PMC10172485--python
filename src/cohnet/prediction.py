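"""Predicting clinical improvement from treatment-induced network change.

The outcome is the PANSS change ratio ``(pre - post) / pre`` (positive =
improvement).  Features are the per-patient changes (after minus before
treatment) in the four weighted network properties — dCLU, dLE, dGE, dL
— aggregated over the three tasks by default.  A multiple linear
regression with collinearity screening (VIF < 10, tolerance > 0.1) is
evaluated by leave-one-out cross-validation: each patient is predicted
by a model fit on the others, and performance is summarized by the
Pearson correlation between predicted and actual change ratios and the
root mean square error (reported in percentage points of the ratio).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .graph import NetworkMetrics

FEATURE_NAMES = ("delta_clu", "delta_le", "delta_ge", "delta_l")
_METRIC_KEYS = ("clu", "le", "ge", "path_length")


@dataclass
class RegressionModel:
    """Fitted OLS model with collinearity diagnostics and LOOCV evaluation."""

    intercept: float
    coefficients: np.ndarray
    feature_names: tuple[str, ...]
    vif: np.ndarray
    tolerance: np.ndarray
    collinearity_flags: np.ndarray
    loocv_predictions: np.ndarray
    r: float
    p: float
    rmse: float

    @property
    def rmse_percent(self) -> float:
        """RMSE in percentage points of the change-ratio scale."""
        return 100.0 * self.rmse

    def formula(self) -> str:
        terms = "".join(
            f" {'-' if c < 0 else '+'} {abs(c):.3f}*{name}"
            for c, name in zip(self.coefficients, self.feature_names)
        )
        return f"y = {self.intercept:.3f}{terms}"


def panss_change_ratio(pre: float, post: float) -> float:
    """``(pre - post) / pre``; negative values (worsening) are allowed."""
    if pre <= 0:
        raise ValueError("pre-treatment PANSS must be positive")
    if pre < 30 or post < 30:
        warnings.warn(
            "PANSS below the 30-item scale minimum of 30", stacklevel=2
        )
    return (pre - post) / pre


def build_features(
    before: dict[str, dict[str, NetworkMetrics]],
    after: dict[str, dict[str, NetworkMetrics]],
    aggregation: str = "mean_over_tasks",
) -> pd.DataFrame:
    """Per-subject change features from before/after network metrics.

    ``before``/``after`` map subject -> task -> metrics.  The change is
    after minus before per property; ``mean_over_tasks`` (default)
    averages it over tasks, ``per_task`` keeps 4 features per task.
    """
    if aggregation not in ("mean_over_tasks", "per_task"):
        raise ValueError("aggregation must be 'mean_over_tasks' or 'per_task'")
    rows = {}
    for sid, tasks_before in before.items():
        if sid not in after:
            raise KeyError(f"subject {sid} missing the after-treatment phase")
        tasks_after = after[sid]
        missing = set(tasks_before) ^ set(tasks_after)
        if missing:
            raise KeyError(f"subject {sid}: task(s) {sorted(missing)} lack both phases")
        deltas: dict[str, float] = {}
        per_task = {
            task: {
                name: getattr(tasks_after[task], key) - getattr(tasks_before[task], key)
                for name, key in zip(FEATURE_NAMES, _METRIC_KEYS)
            }
            for task in tasks_before
        }
        if aggregation == "mean_over_tasks":
            for name in FEATURE_NAMES:
                deltas[name] = float(np.mean([per_task[t][name] for t in per_task]))
        else:
            for task in sorted(per_task):
                for name in FEATURE_NAMES:
                    deltas[f"{name}_{task}"] = per_task[task][name]
        rows[sid] = deltas
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    if aggregation == "per_task" and len(table) < 3 * table.shape[1]:
        warnings.warn(
            f"per_task aggregation yields {table.shape[1]} features for "
            f"{len(table)} subjects; expect unstable fits",
            stacklevel=2,
        )
    if table.isna().any().any():
        raise ValueError("missing values in feature table")
    return table


def collinearity_diagnostics(
    x: np.ndarray, vif_limit: float = 10.0, tol_limit: float = 0.1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """VIF and tolerance per column, plus violation flags.

    ``VIF_k = 1 / (1 - R2_k)`` from regressing column k on the other
    columns (with intercept); ``tolerance = 1 / VIF``.  A perfectly
    collinear column gets infinite VIF and is flagged, not raised.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than feature columns ({p})")
    vif = np.empty(p)
    for k in range(p):
        yk = x[:, k]
        others = np.delete(x, k, axis=1)
        design = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(design, yk, rcond=None)
        resid = yk - design @ beta
        ss_tot = np.sum((yk - yk.mean()) ** 2)
        if ss_tot == 0:
            vif[k] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        vif[k] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    with np.errstate(divide="ignore"):
        tolerance = 1.0 / vif
    flags = (vif >= vif_limit) | (tolerance <= tol_limit)
    return vif, tolerance, flags


def fit_linear(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Ordinary least squares with intercept: returns (intercept, coefs)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1 and len(np.asarray(y)) == x.shape[1]:
        x = x.T
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in regression inputs")
    design = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(beta[0]), beta[1:]


def evaluate_prediction(
    predicted: np.ndarray, actual: np.ndarray
) -> tuple[float, float, float]:
    """(Pearson r, two-sided p, RMSE) of predictions against truth."""
    pred = np.asarray(predicted, dtype=float)
    act = np.asarray(actual, dtype=float)
    if len(pred) != len(act) or len(pred) < 3:
        raise ValueError("need equal lengths >= 3")
    if np.ptp(pred) == 0 or np.ptp(act) == 0:
        raise ValueError("zero variance in predictions or actuals")
    r, p = sps.pearsonr(pred, act)
    rmse = float(np.sqrt(np.mean((pred - act) ** 2)))
    return float(r), float(p), rmse


def loocv(
    x: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    feature_names: tuple[str, ...] | None = None,
) -> RegressionModel:
    """Leave-one-out cross-validated linear prediction.

    Each subject is predicted from a model fit on the other n-1; the
    final reported model is refit on all n.  Perfectly linear noiseless
    data yields r = 1 and RMSE = 0 exactly.
    """
    if isinstance(x, pd.DataFrame):
        feature_names = tuple(x.columns)
        x = x.to_numpy()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    if n < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    if feature_names is None:
        feature_names = tuple(f"x{k}" for k in range(p))

    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        intercept, coefs = fit_linear(x[mask], y[mask])
        preds[i] = intercept + x[i] @ coefs
    r, p_val, rmse = evaluate_prediction(preds, y)
    intercept, coefs = fit_linear(x, y)
    vif, tol, flags = (
        collinearity_diagnostics(x) if p > 1 else (np.ones(1), np.ones(1), np.zeros(1, bool))
    )
    return RegressionModel(
        intercept=intercept,
        coefficients=coefs,
        feature_names=feature_names,
        vif=vif,
        tolerance=tol,
        collinearity_flags=flags,
        loocv_predictions=preds,
        r=r,
        p=p_val,
        rmse=rmse,
    )


def backward_eliminate(
    x: pd.DataFrame, y: np.ndarray, p_threshold: float = 0.05
) -> list[str]:
    """Drop the least significant feature until all coefficient p < threshold.

    A simple reduction yielding a parsimonious model (often a single
    property); at least one feature is always retained.
    """
    cols = list(x.columns)
    y = np.asarray(y, dtype=float)
    while len(cols) > 1:
        xs = x[cols].to_numpy()
        n, p = xs.shape
        design = np.column_stack([np.ones(n), xs])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        dof = n - p - 1
        if dof <= 0:
            cols = cols[:-1]
            continue
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.inv(design.T @ design)
        se = np.sqrt(np.diag(cov))[1:]
        tvals = beta[1:] / se
        pvals = 2.0 * sps.t.sf(np.abs(tvals), dof)
        worst = int(np.argmax(pvals))
        if pvals[worst] < p_threshold:
            break
        cols.pop(worst)
    return cols


__all__ = [
    "FEATURE_NAMES",
    "RegressionModel",
    "panss_change_ratio",
    "build_features",
    "collinearity_diagnostics",
    "fit_linear",
    "evaluate_prediction",
    "loocv",
    "backward_eliminate",
]
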