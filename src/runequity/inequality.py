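"""Relative Index of Inequality (RII) and the model fits behind it.

The RII is a regression-based summary of a socioeconomic gradient: the ratio
of the model-predicted outcome in the least deprived area to that in the
most deprived area.  A value of 1 means no gradient; above 1 the less
deprived areas have the higher predicted outcome.  Deprivation scores run
from 0 (least deprived) upward, so "least deprived" is the observed minimum
score and "most deprived" the observed maximum.

Two outcomes are supported, following the study design:

* distance to the nearest event — simple linear regression of distance on
  deprivation score, RII = prediction at min score / prediction at max;
* participation — univariable Poisson regression of finisher counts on
  deprivation score with log population as offset; for a log link the
  predict-and-divide ratio collapses to ``exp(slope * (score_min - score_max))``.

The Poisson fitter is an offset-aware IRLS (iteratively reweighted least
squares) maximiser of the Poisson log-likelihood, with standard errors from
the inverse Fisher information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)


@dataclass
class GlmFit:
    """Result of a regression fit (OLS or Poisson GLM)."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    log_likelihood: float
    aic: float
    converged: bool
    n_iterations: int
    deviance: float = np.nan
    fitted_values: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.standard_errors = np.asarray(self.standard_errors, dtype=float)
        if self.coefficients.shape != self.standard_errors.shape:
            raise ValueError("coefficients and standard_errors differ in length")


@dataclass
class RiiResult:
    month: str
    outcome: str  # "distance" or "participation"
    rii: float
    model_intercept: float
    model_slope: float
    imd_min_used: float
    imd_max_used: float


def fit_ols(x, y) -> GlmFit:
    """Closed-form simple linear regression of ``y`` on ``x``.

    Standard errors use the classical homoskedastic formula; the AIC counts
    the two regression coefficients (``aic = 2*2 - 2*loglik``) with the
    Gaussian log-likelihood evaluated at the MLE variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")

    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    sxy = np.sum((x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar

    resid = y - intercept - slope * x
    rss = float(resid @ resid)
    sigma2 = rss / (n - 2)
    se_slope = np.sqrt(sigma2 / sxx)
    se_intercept = np.sqrt(sigma2 * (1.0 / n + xbar**2 / sxx))

    if rss > 0:
        sigma2_mle = rss / n
        loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2_mle) + 1.0)
    else:
        loglik = np.inf  # exact fit
    k = 2
    return GlmFit(
        coefficients=np.array([intercept, slope]),
        standard_errors=np.array([se_intercept, se_slope]),
        log_likelihood=float(loglik),
        aic=float(2 * k - 2 * loglik),
        converged=True,
        n_iterations=0,
        deviance=rss,
        fitted_values=intercept + slope * x,
    )


def fit_poisson_glm(
    design,
    y,
    offset=None,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GlmFit:
    """Offset-Poisson GLM with log link, fit by IRLS.

    Parameters
    ----------
    design : (n, p) covariate matrix including the intercept column.
    y : nonnegative integer counts.
    offset : fixed log-exposure term added to the linear predictor
        (e.g. log population); zeros if omitted.
    tol : convergence threshold on the relative change in deviance.
    max_iter : iteration cap; hitting it leaves ``converged=False``.

    Raises ``ValueError`` for a rank-deficient design or invalid inputs.
    Non-convergence is flagged on the result, never silently hidden.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be nonnegative integers")
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    if not np.all(np.isfinite(offset)):
        raise ValueError("offsets must be finite")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(p)
    eta = X @ beta + offset
    mu = np.exp(np.clip(eta, -700, 700))
    dev = _poisson_deviance(y, mu)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu
        z = (eta - offset) + (y - mu) / mu
        wx = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ wx, wx.T @ z)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        eta = X @ beta + offset
        mu = np.exp(np.clip(eta, -700, 700))
        dev_new = _poisson_deviance(y, mu)
        # a deviance underflowing to zero while coefficients still move by
        # O(1) per iteration signals a divergent MLE (e.g. all counts zero),
        # so convergence also requires the coefficient step to be small
        if abs(dev_new - dev) < tol * (abs(dev_new) + 0.1) and step < 1e-4 * (
            1.0 + np.max(np.abs(beta))
        ):
            dev = dev_new
            converged = True
            break
        dev = dev_new

    fisher = X.T @ (X * mu[:, None])
    try:
        cov = np.linalg.inv(fisher)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False

    loglik = float(np.sum(y * np.clip(eta, -700, 700) - mu - gammaln(y + 1.0)))
    return GlmFit(
        coefficients=beta,
        standard_errors=se,
        log_likelihood=loglik,
        aic=float(2 * p - 2 * loglik),
        converged=converged,
        n_iterations=it,
        deviance=float(dev),
        fitted_values=mu,
    )


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _month_slice(panel: pd.DataFrame, month: str, value_col: str) -> pd.DataFrame:
    sub = panel.loc[panel["month"] == str(month), ["area_id", value_col]]
    if sub.empty:
        raise ValueError(f"month {month} not covered by panel")
    return sub


def rii_distance(areas: pd.DataFrame, distance_panel: pd.DataFrame, month) -> RiiResult:
    """RII in distance to the nearest event for one month.

    Linear regression of distance on deprivation score; RII is the predicted
    distance at the observed minimum score divided by the prediction at the
    observed maximum.  Nonpositive predictions make the ratio uninterpretable
    and raise ``ValueError``.
    """
    month = str(month)
    sub = _month_slice(distance_panel, month, "distance_km")
    df = sub.merge(areas[["area_id", "imd_score"]], on="area_id")
    fit = fit_ols(df["imd_score"], df["distance_km"])
    intercept, slope = fit.coefficients
    lo, hi = float(df["imd_score"].min()), float(df["imd_score"].max())
    pred_lo = intercept + slope * lo
    pred_hi = intercept + slope * hi
    if pred_lo <= 0 or pred_hi <= 0:
        raise ValueError(
            f"nonpositive predicted distance in month {month}: "
            f"{pred_lo:.4g} at score {lo:.3g}, {pred_hi:.4g} at score {hi:.3g}"
        )
    return RiiResult(
        month=month,
        outcome="distance",
        rii=pred_lo / pred_hi,
        model_intercept=float(intercept),
        model_slope=float(slope),
        imd_min_used=lo,
        imd_max_used=hi,
    )


def rii_participation(areas: pd.DataFrame, finisher_panel: pd.DataFrame, month) -> RiiResult:
    """RII in participation for one month.

    Univariable offset-Poisson regression of finisher counts on deprivation
    score with log population as offset.  With a log link the ratio of
    predictions at the score extremes is ``exp(slope * (min - max))``, so a
    negative slope (participation falling with deprivation) gives RII > 1.
    Areas with zero population are excluded (offset undefined) with a logged
    count.
    """
    month = str(month)
    sub = _month_slice(finisher_panel, month, "count")
    df = sub.merge(areas[["area_id", "imd_score", "total_pop"]], on="area_id")
    n_zero_pop = int((df["total_pop"] <= 0).sum())
    if n_zero_pop:
        logger.warning("month %s: excluding %d zero-population areas", month, n_zero_pop)
        df = df[df["total_pop"] > 0]
    X = np.column_stack([np.ones(len(df)), df["imd_score"].to_numpy(float)])
    fit = fit_poisson_glm(X, df["count"].to_numpy(), offset=np.log(df["total_pop"].to_numpy(float)))
    if not fit.converged:
        raise RuntimeError(
            f"Poisson fit did not converge for month {month} "
            f"(iterations={fit.n_iterations}, deviance={fit.deviance:.4g})"
        )
    intercept, slope = fit.coefficients
    lo, hi = float(df["imd_score"].min()), float(df["imd_score"].max())
    return RiiResult(
        month=month,
        outcome="participation",
        rii=float(np.exp(slope * (lo - hi))),
        model_intercept=float(intercept),
        model_slope=float(slope),
        imd_min_used=lo,
        imd_max_used=hi,
    )


def rii_series(
    areas: pd.DataFrame,
    panel: pd.DataFrame,
    month_range,
    outcome: str,
) -> pd.DataFrame:
    """Monthly RII series for ``outcome`` in {"distance", "participation"}.

    Returns an ascending-month DataFrame (month, outcome, rii, model_slope,
    model_intercept, imd_min_used, imd_max_used).  Per-month failures are
    re-raised with the month in the message.
    """
    if outcome not in ("distance", "participation"):
        raise ValueError(f"unknown outcome {outcome!r}")
    fn = rii_distance if outcome == "distance" else rii_participation
    if isinstance(month_range, (tuple, list)) and len(month_range) == 2:
        months = pd.period_range(month_range[0], month_range[1], freq="M")
    else:
        months = pd.PeriodIndex(month_range, freq="M")
    rows = []
    for m in months:
        try:
            r = fn(areas, panel, str(m))
        except (ValueError, RuntimeError) as exc:
            raise type(exc)(f"month {m}: {exc}") from exc
        rows.append(r)
    return pd.DataFrame(
        {
            "month": [r.month for r in rows],
            "outcome": outcome,
            "rii": [r.rii for r in rows],
            "model_slope": [r.model_slope for r in rows],
            "model_intercept": [r.model_intercept for r in rows],
            "imd_min_used": [r.imd_min_used for r in rows],
            "imd_max_used": [r.imd_max_used for r in rows],
        }
    )
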