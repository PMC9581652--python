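"""Classical AR(p) baseline: least squares, order selection, point forecasts.

The model is

    y_t = alpha + sum_k beta_k * y_{t-k} + eps_t,    eps_t ~ N(0, sigma^2)

fitted by conditional least squares on the lag-trimmed sample (the first p
observations serve only as lags).  Lag order is chosen by minimizing

    AIC(p) = log(SSE_p / (T - p)) + (T - p + 2p) / (T - p)

over candidate orders, where T is the training length and SSE_p the residual
sum of squares at order p (natural log).  This is the criterion as used by the
forecasting procedure this package implements; note it differs from the
textbook ``T log(SSE/T) + 2p`` form.  An optional stationarity screen excludes
orders whose fitted coefficients imply characteristic-polynomial roots inside
or on the unit circle, mimicking classical AR tooling that refuses unstable
fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .timeseries_io import MonthlySeries

__all__ = [
    "ARFit",
    "build_design",
    "fit_least_squares",
    "aic",
    "select_order",
    "check_stationarity",
    "forecast_point",
]


@dataclass(frozen=True)
class ARFit:
    """Least-squares AR(p) estimate.

    ``alpha`` is the intercept (visits), ``betas`` the p lag coefficients,
    ``sigma2`` the residual variance ``sse / (T_used - p - 1)`` (residual
    degrees of freedom with intercept), ``residuals`` the T-p one-step
    residuals on the training sample.
    """

    alpha: float
    betas: np.ndarray
    sigma2: float
    sse: float
    residuals: np.ndarray
    T_used: int

    @property
    def order(self) -> int:
        return int(self.betas.size)


def _as_values(series) -> np.ndarray:
    if isinstance(series, MonthlySeries):
        return series.values
    return np.asarray(series, dtype=float)


def build_design(train, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Lag matrix and targets for an AR(p) regression.

    Row t of the lag matrix is ``(y_{t-1}, ..., y_{t-p})`` aligned with target
    ``y_t``; the first p observations appear only as lags.
    """
    y = _as_values(train)
    n = y.size
    if p < 1:
        raise ValueError(f"order must be >= 1, got {p}")
    if p >= n:
        raise ValueError(f"order {p} >= series length {n}")
    lags = np.column_stack([y[p - k - 1 : n - k - 1] for k in range(p)])
    targets = y[p:]
    return lags, targets


def fit_least_squares(train, p: int) -> ARFit:
    """Conditional least-squares fit of AR(p) with intercept."""
    lags, targets = build_design(train, p)
    X = np.column_stack([np.ones(targets.size), lags])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"degenerate design at order {p} (rank-deficient lag matrix)")
    coef, _, _, _ = np.linalg.lstsq(X, targets, rcond=None)
    resid = targets - X @ coef
    sse = float(resid @ resid)
    T_used = int(targets.size)
    dof = T_used - p - 1
    sigma2 = sse / dof if dof > 0 else float("nan")
    return ARFit(
        alpha=float(coef[0]),
        betas=coef[1:].copy(),
        sigma2=sigma2,
        sse=sse,
        residuals=resid,
        T_used=T_used,
    )


def aic(sse: float, T: int, p: int) -> float:
    """Order-selection criterion ``log(sse/(T-p)) + (T-p+2p)/(T-p)``.

    Natural log. ``sse == 0`` (a perfect fit) returns ``-inf`` so an exact
    recurrence dominates every noisy competitor.
    """
    if p < 1:
        raise ValueError(f"order must be >= 1, got {p}")
    if T <= p:
        raise ValueError(f"need T > p, got T={T}, p={p}")
    if sse < 0:
        raise ValueError(f"sse must be >= 0, got {sse}")
    penalty = (T - p + 2 * p) / (T - p)
    if sse == 0.0:
        return float("-inf")  # perfect fit
    return math.log(sse / (T - p)) + penalty


def check_stationarity(betas) -> bool:
    """True iff all roots of ``1 - beta_1 z - ... - beta_p z^p`` lie strictly
    outside the unit circle (a stable AR process)."""
    b = np.atleast_1d(np.asarray(betas, dtype=float))
    if b.size < 1:
        raise ValueError("need at least one coefficient")
    # trim trailing zeros so np.roots sees a nonzero leading coefficient
    nz = np.nonzero(b)[0]
    if nz.size == 0:
        return True  # white noise around the intercept
    b = b[: nz[-1] + 1]
    poly = np.concatenate([[-bb for bb in b[::-1]], [1.0]])  # highest degree first
    roots = np.roots(poly)
    return bool(np.all(np.abs(roots) > 1.0 + 1e-12))


def select_order(
    train,
    max_p: int | None = None,
    check_stationarity_flag: bool = True,
) -> tuple[int, np.ndarray]:
    """AIC-minimizing lag order over ``1..max_p``.

    ``max_p`` defaults to half the training length. With the stationarity
    screen on, orders whose fitted coefficients fail :func:`check_stationarity`
    are excluded from the argmin (their AIC still appears in the trace). Ties
    break toward the smaller order. Orders whose design is degenerate are
    skipped (NaN in the trace).
    """
    y = _as_values(train)
    T = y.size
    if max_p is None:
        max_p = T // 2
    if max_p < 1:
        raise ValueError(f"max_p must be >= 1, got {max_p}")
    trace = np.full(max_p, np.nan)
    best_p, best_aic = None, np.inf
    for p in range(1, max_p + 1):
        try:
            fit = fit_least_squares(y, p)
        except (ValueError, np.linalg.LinAlgError):
            continue
        val = aic(fit.sse, T, p)
        trace[p - 1] = val
        if check_stationarity_flag and not check_stationarity(fit.betas):
            continue
        if val < best_aic:  # strict: ties keep the smaller p
            best_p, best_aic = p, val
    if best_p is None:
        raise ValueError("no admissible order in 1..%d" % max_p)
    return best_p, trace


def forecast_point(fit: ARFit, seed_lags, horizon: int) -> np.ndarray:
    """Recursive plug-in forecast with the noise term set to zero.

    ``seed_lags`` are the last p training observations, most recent first;
    each step feeds its own prediction back as the newest lag.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    lags = np.asarray(seed_lags, dtype=float).copy()
    if lags.size != fit.order:
        raise ValueError(f"need {fit.order} seed lags, got {lags.size}")
    out = np.empty(horizon)
    for h in range(horizon):
        y_next = fit.alpha + fit.betas @ lags
        out[h] = y_next
        lags = np.concatenate([[y_next], lags[:-1]])
    return out
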