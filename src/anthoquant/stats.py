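"""Index-vs-concentration calibration statistics.

Ordinary least squares relates each color index to the biochemically
measured anthocyanin concentration, optionally after natural-log transforms
of either variable.  Goodness of fit is the coefficient of determination r²;
prediction accuracy is the range-normalized RMSE (RMSE divided by the
observed max − min, in percent).  Family-wise error over the 14 indices of
one dataset is controlled with the Holm step-down ("sequential Bonferroni");
the plain Bonferroni α/k threshold is reported alongside.  A fitted model is
validated on independent samples by regressing observed on predicted values
and testing the slope against 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RegressionFit",
    "HolmResult",
    "ValidationReport",
    "fit_index_regression",
    "predict",
    "nrmse",
    "sequential_bonferroni",
    "validate_model",
    "rank_indices",
]

_TRANSFORMS = ("none", "ln")


def _apply_transform(values: np.ndarray, transform: str, label: str) -> np.ndarray:
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    if transform == "none":
        return values
    bad = np.flatnonzero(values <= 0)
    if bad.size:
        raise ValueError(
            f"ln transform of {label} requires strictly positive values; "
            f"non-positive at positions {bad.tolist()}"
        )
    return np.log(values)


@dataclass
class RegressionFit:
    """OLS fit of (possibly transformed) concentration on index value."""

    slope: float
    intercept: float
    transform_x: str
    transform_y: str
    r2: float
    p_value: float
    df: int
    n: int
    stderr_slope: float
    residuals: np.ndarray
    fitted: np.ndarray


def fit_index_regression(
    x,
    y,
    transform_x: str = "none",
    transform_y: str = "none",
) -> RegressionFit:
    """Least-squares line through (transformed) index/concentration pairs.

    Refuses to fit with n < 4 or zero variance in x; ln transforms require
    strictly positive inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 4:
        raise ValueError(f"refusing to fit a regression with n={n} < 4")
    xt = _apply_transform(x, transform_x, "x")
    yt = _apply_transform(y, transform_y, "y")
    if np.ptp(xt) == 0:
        raise ValueError("x has zero variance; regression undefined")
    res = sps.linregress(xt, yt)
    fitted = res.intercept + res.slope * xt
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        transform_x=transform_x,
        transform_y=transform_y,
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        df=n - 2,
        n=n,
        stderr_slope=float(res.stderr),
        residuals=yt - fitted,
        fitted=fitted,
    )


def predict(fit: RegressionFit, x_new) -> np.ndarray:
    """Predict on the *original* response scale (back-transforming ln fits)."""
    x_new = np.asarray(x_new, dtype=float)
    xt = _apply_transform(x_new, fit.transform_x, "x_new")
    yt = fit.intercept + fit.slope * xt
    if fit.transform_y == "ln":
        return np.exp(yt)
    return yt


def nrmse(observed, predicted) -> float:
    """Range-normalized RMSE in percent: ``100·RMSE/(max(obs) − min(obs))``."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-D arrays")
    if observed.size < 2:
        raise ValueError("need at least 2 observations")
    rng = float(observed.max() - observed.min())
    if rng == 0:
        raise ValueError("observed values have zero range; NRMSE undefined")
    rmse = float(np.sqrt(np.mean((observed - predicted) ** 2)))
    return 100.0 * rmse / rng


@dataclass
class HolmResult:
    """Holm step-down outcome plus the plain Bonferroni comparison."""

    holm_significant: np.ndarray  # bool, original order
    bonferroni_significant: np.ndarray
    adjusted_p: np.ndarray  # Holm-adjusted p-values
    alpha: float
    k: int
    bonferroni_threshold: float


def sequential_bonferroni(p_values, alpha: float = 0.05) -> HolmResult:
    """Holm step-down across ``k`` hypotheses.

    Sorted ascending, p_(i) is compared with α/(k−i+1); at the first failure
    that hypothesis and every later one are declared non-significant.  The
    plain Bonferroni decision (p < α/k) is reported alongside for the
    fixed-threshold reading of "sequential Bonferroni".
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("need a 1-D list of at least one p-value")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    order = np.argsort(p, kind="stable")
    holm = np.zeros(k, dtype=bool)
    for rank, idx in enumerate(order):  # rank 0 = smallest p
        if p[idx] < alpha / (k - rank):
            holm[idx] = True
        else:
            break
    # Holm-adjusted p-values: running max of (k - rank)·p_(rank), capped at 1
    adj = np.empty(k, dtype=float)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (k - rank) * p[idx]))
        adj[idx] = running
    bonf = p < alpha / k
    return HolmResult(holm, bonf, adj, alpha, k, alpha / k)


@dataclass
class ValidationReport:
    """Observed-vs-predicted regression on an independent sample."""

    slope: float
    intercept: float
    r2: float
    t_statistic: float  # H0: slope = 1
    df: int
    p_value: float
    nrmse_pct: float
    n: int


def validate_model(fit: RegressionFit, x_new, y_new) -> ValidationReport:
    """Validate a fitted calibration on independent data.

    Predictions are back-transformed to the original concentration scale;
    observed values are regressed on them, and the slope is tested against 1
    with t = (slope − 1)/SE on n − 2 df.
    """
    x_new = np.asarray(x_new, dtype=float)
    y_new = np.asarray(y_new, dtype=float)
    if x_new.shape != y_new.shape or x_new.ndim != 1:
        raise ValueError("x_new and y_new must be equal-length 1-D arrays")
    n = x_new.size
    if n < 4:
        raise ValueError(f"validation needs n >= 4, got {n}")
    preds = predict(fit, x_new)
    if np.ptp(preds) == 0:
        raise ValueError("predictions have zero variance; validation undefined")
    res = sps.linregress(preds, y_new)
    if res.stderr == 0.0:
        # exact fit: slope estimated without error
        t = 0.0 if np.isclose(res.slope, 1.0) else math.inf * np.sign(res.slope - 1.0)
    else:
        t = (res.slope - 1.0) / res.stderr
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return ValidationReport(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        t_statistic=float(t),
        df=n - 2,
        p_value=float(p),
        nrmse_pct=nrmse(y_new, preds),
        n=n,
    )


def _sig_code(p_adj: float) -> str:
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return "ns"


def rank_indices(
    indices: pd.DataFrame,
    concentrations: pd.Series,
    transform_policy: dict[str, tuple[str, str]] | None = None,
    alpha: float = 0.05,
    dataset: str = "",
) -> pd.DataFrame:
    """Fit every index column against concentration and rank by r².

    ``indices`` is a samples × indices frame aligned with ``concentrations``.
    Indices undefined (NaN) for more than half the samples are dropped with
    a warning; Holm runs across the surviving indices; the highest r² among
    Holm-significant fits gets the best flag (ties: all tied rows flagged).
    """
    transform_policy = transform_policy or {}
    conc = np.asarray(concentrations, dtype=float)
    if len(indices) != conc.size:
        raise ValueError("indices and concentrations must have equal length")
    if indices.shape[1] < 1:
        raise ValueError("need at least one index column")
    rows = []
    for name in indices.columns:
        values = indices[name].to_numpy(dtype=float)
        ok = np.isfinite(values) & np.isfinite(conc)
        if ok.sum() < len(values) / 2:
            warnings.warn(
                f"index {name!r} undefined for more than half the samples; dropped",
                stacklevel=2,
            )
            continue
        tx, ty = transform_policy.get(name, ("none", "none"))
        try:
            fit = fit_index_regression(values[ok], conc[ok], tx, ty)
        except ValueError as exc:
            warnings.warn(f"index {name!r} could not be fitted ({exc}); dropped",
                          stacklevel=2)
            continue
        rows.append(
            {
                "dataset": dataset,
                "index": name,
                "n": fit.n,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "transform_x": tx,
                "transform_y": ty,
                "r2": fit.r2,
                "p": fit.p_value,
            }
        )
    if not rows:
        raise ValueError("no index could be fitted")
    table = pd.DataFrame(rows)
    holm = sequential_bonferroni(table["p"].to_numpy(), alpha=alpha)
    table["p_holm"] = holm.adjusted_p
    table["holm_significant"] = holm.holm_significant
    table["bonferroni_significant"] = holm.bonferroni_significant
    table["sig_code"] = [_sig_code(p) for p in holm.adjusted_p]
    table["best"] = False
    sig = table[table["holm_significant"]]
    if not sig.empty:
        best_r2 = sig["r2"].max()
        table.loc[table["holm_significant"] & (table["r2"] == best_r2), "best"] = True
    return table.sort_values("r2", ascending=False).reset_index(drop=True)
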