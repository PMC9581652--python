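"""Bayesian AR(p) by systematic-scan Gibbs sampling.

Writing the AR(p) model as a linear regression of ``y_t`` on an intercept and
the p lagged values, with Gaussian noise of variance ``sigma^2``, the priors
are independent ``N(coef_mean, coef_var)`` on the intercept and each lag
coefficient (defaults N(0, 1)) and inverse-gamma(shape 1/2, scale 1/20) on
``sigma^2``.  Both priors are conditionally conjugate, so every full
conditional is available in closed form:

* one coefficient given the rest and sigma^2 is Normal with
  ``precision = 1/v0 + (sum_t x_tj^2)/sigma^2`` and
  ``mean = variance * (m0/v0 + sum_t x_tj r_tj / sigma^2)``,
  where ``r_tj`` is the partial residual of target t with coefficient j's
  contribution removed (the intercept's column is all ones);
* sigma^2 given the coefficients is inverse-gamma with
  ``shape = a0 + n/2`` and ``scale = b0 + SSE/2`` (density
  proportional to ``x^{-shape-1} exp(-scale/x)``).

Each Gibbs iteration samples the intercept, then each lag coefficient in
order (always conditioning on the freshest values), then sigma^2.  The first
``burn_in`` iterations are discarded; the retained draws approximate the
joint posterior.  No stationarity constraint is imposed on the draws: the
Bayesian fit deliberately drops the stability screen so that high lag orders
(which capture 12-month seasonality) remain admissible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ar_baseline import aic, build_design, fit_least_squares
from .timeseries_io import MonthlySeries

__all__ = [
    "PriorSpec",
    "GibbsConfig",
    "PosteriorDraws",
    "coef_conditional",
    "var_conditional",
    "gibbs_sample",
    "chain_diagnostics",
    "ChainDiagnostics",
    "posterior_aic",
]


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters.

    ``coef_mean``/``coef_var``: Normal prior on the intercept and every lag
    coefficient. ``var_shape``/``var_scale``: inverse-gamma prior on the noise
    variance, density proportional to ``x^{-shape-1} exp(-scale/x)``.
    """

    coef_mean: float = 0.0
    coef_var: float = 1.0
    var_shape: float = 0.5
    var_scale: float = 1.0 / 20.0

    def __post_init__(self) -> None:
        for name in ("coef_var", "var_shape", "var_scale"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if not np.isfinite(self.coef_mean):
            raise ValueError("coef_mean must be finite")


@dataclass(frozen=True)
class GibbsConfig:
    """Sampler run length and reproducibility settings."""

    iterations: int = 20_000
    burn_in: int = 4_000
    seed: int = 0
    init: str = "least_squares"  # or "zeros"

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError(
                f"need 0 <= burn_in < iterations, got {self.burn_in}/{self.iterations}"
            )
        if self.init not in ("least_squares", "zeros"):
            raise ValueError(f"init must be 'least_squares' or 'zeros', got {self.init!r}")


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained Gibbs draws, one row per kept iteration.

    Columns are ordered ``(alpha, beta_1, ..., beta_p, sigma2)``.
    """

    draws: np.ndarray
    order: int
    config: GibbsConfig

    PARAM_PREFIX = ("alpha", "beta", "sigma2")

    def __post_init__(self) -> None:
        d = np.asarray(self.draws, dtype=float)
        if d.ndim != 2 or d.shape[1] != self.order + 2:
            raise ValueError(
                f"draws must be (rows x {self.order + 2}) for order {self.order}"
            )
        if np.any(d[:, -1] <= 0):
            raise ValueError("every sigma2 draw must be strictly positive")
        object.__setattr__(self, "draws", d)

    @property
    def param_names(self) -> list[str]:
        return ["alpha"] + [f"beta{k}" for k in range(1, self.order + 1)] + ["sigma2"]

    @property
    def n_retained(self) -> int:
        return int(self.draws.shape[0])

    def posterior_mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def posterior_sd(self) -> np.ndarray:
        return self.draws.std(axis=0, ddof=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=self.param_names)


def coef_conditional(
    j: int,
    state: np.ndarray,
    design: np.ndarray,
    targets: np.ndarray,
    prior: PriorSpec,
) -> tuple[float, float]:
    """Normal full conditional of coefficient ``j`` given the others and sigma2.

    ``state`` holds the current ``(theta_0..theta_p, sigma2)`` with ``theta_0``
    the intercept; ``design`` is the regression matrix whose first column is
    all ones.  With zero data rows the prior itself is returned.
    """
    design = np.asarray(design, dtype=float)
    targets = np.asarray(targets, dtype=float)
    state = np.asarray(state, dtype=float)
    sigma2 = state[-1]
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be > 0, got {sigma2}")
    if targets.size == 0:
        return prior.coef_mean, prior.coef_var
    theta = state[:-1]
    xj = design[:, j]
    # partial residual: target minus every other coefficient's contribution
    r = targets - design @ theta + xj * theta[j]
    precision = 1.0 / prior.coef_var + (xj @ xj) / sigma2
    variance = 1.0 / precision
    mean = variance * (prior.coef_mean / prior.coef_var + (xj @ r) / sigma2)
    return float(mean), float(variance)


def var_conditional(residuals, prior: PriorSpec) -> tuple[float, float]:
    """Inverse-gamma full conditional of sigma2 given the coefficients:
    ``(shape, scale) = (a0 + n/2, b0 + SSE/2)``."""
    r = np.asarray(residuals, dtype=float)
    sse = float(r @ r)
    return prior.var_shape + r.size / 2.0, prior.var_scale + sse / 2.0


def _initial_state(y: np.ndarray, p: int, config: GibbsConfig) -> np.ndarray:
    if config.init == "least_squares":
        try:
            fit = fit_least_squares(y, p)
            sigma2 = fit.sigma2 if np.isfinite(fit.sigma2) and fit.sigma2 > 0 else 1.0
            return np.concatenate([[fit.alpha], fit.betas, [sigma2]])
        except (ValueError, np.linalg.LinAlgError):
            pass  # degenerate design: fall through to zeros
    sigma2 = float(np.var(y)) or 1.0
    return np.concatenate([np.zeros(p + 1), [sigma2]])


def gibbs_sample(
    train,
    p: int,
    prior: PriorSpec | None = None,
    config: GibbsConfig | None = None,
    allow_high_order: bool = False,
    scan_order=None,
) -> PosteriorDraws:
    """Systematic-scan Gibbs sampler for the Bayesian AR(p) posterior.

    Per iteration: sample the intercept, then beta_1..beta_p (each from its
    Normal conditional given the freshest values of all the others), then
    sigma2 from its inverse-gamma conditional.  The first ``burn_in``
    iterations are discarded.  Output is a pure function of
    ``(data, prior, config)``; identical seeds give bit-identical draws.

    ``scan_order`` permutes the coefficient update sequence (indices into
    ``(intercept, beta_1, ..., beta_p)``); the stationary distribution is the
    same for every permutation, which validity tests exploit.
    """
    prior = prior or PriorSpec()
    config = config or GibbsConfig()
    y = train.values if isinstance(train, MonthlySeries) else np.asarray(train, float)
    if not allow_high_order and p >= y.size / 2:
        raise ValueError(
            f"order {p} >= half the training length {y.size}; "
            "pass allow_high_order=True to override"
        )
    lags, targets = build_design(y, p)
    X = np.column_stack([np.ones(targets.size), lags])
    ncoef = p + 1
    col_ss = np.einsum("ij,ij->j", X, X)  # per-column sum of squares
    cols = [np.ascontiguousarray(X[:, j]) for j in range(ncoef)]

    rng = np.random.default_rng(config.seed)
    state = _initial_state(y, p, config)
    theta = state[:-1].copy()
    sigma2 = float(state[-1])
    resid = targets - X @ theta

    m0, v0 = prior.coef_mean, prior.coef_var
    a0, b0 = prior.var_shape, prior.var_scale
    n = targets.size
    a_n = a0 + n / 2.0  # shape never changes across iterations

    scan = list(range(ncoef)) if scan_order is None else [int(j) for j in scan_order]
    if sorted(scan) != list(range(ncoef)):
        raise ValueError(f"scan_order must permute 0..{ncoef - 1}, got {scan_order}")

    kept = np.empty((config.iterations - config.burn_in, ncoef + 1))
    names = ["alpha"] + [f"beta{k}" for k in range(1, p + 1)] + ["sigma2"]
    for it in range(config.iterations):
        for j in scan:
            xj = cols[j]
            prec = 1.0 / v0 + col_ss[j] / sigma2
            var = 1.0 / prec
            # xj @ resid + col_ss[j]*theta[j] == xj @ (partial residual)
            mean = var * (m0 / v0 + (xj @ resid + col_ss[j] * theta[j]) / sigma2)
            new = rng.normal(mean, np.sqrt(var))
            resid -= xj * (new - theta[j])
            theta[j] = new
        b_n = b0 + 0.5 * (resid @ resid)
        sigma2 = b_n / rng.gamma(a_n)
        if not (np.isfinite(sigma2) and sigma2 > 0 and np.all(np.isfinite(theta))):
            bad = (
                "sigma2"
                if not (np.isfinite(sigma2) and sigma2 > 0)
                else names[int(np.argmax(~np.isfinite(theta)))]
            )
            raise RuntimeError(
                f"non-finite draw for {bad} at iteration {it}; "
                "the chain has diverged (check data scale and prior)"
            )
        if it >= config.burn_in:
            row = kept[it - config.burn_in]
            row[:ncoef] = theta
            row[ncoef] = sigma2
    return PosteriorDraws(draws=kept, order=p, config=config)


@dataclass(frozen=True)
class ChainDiagnostics:
    """Per-parameter convergence summary plus plotting exports."""

    summary: pd.DataFrame  # index param, columns mean/sd/split_gap/converged
    traces: pd.DataFrame  # one column per parameter, row per retained draw
    histograms: dict = field(repr=False, default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(self.summary["converged"].all())


def chain_diagnostics(draws: PosteriorDraws, gap_threshold: float = 0.5) -> ChainDiagnostics:
    """First-half vs second-half mean gap per parameter, in posterior-SD units.

    A gap above ``gap_threshold`` flags the parameter as non-converged.
    Also exports per-parameter histograms and the raw trace series.
    """
    if draws.n_retained < 200:
        raise ValueError(
            f"need >= 200 retained draws for diagnostics, got {draws.n_retained}"
        )
    d = draws.draws
    half = d.shape[0] // 2
    first, second = d[:half], d[half:]
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        gap = np.abs(first.mean(axis=0) - second.mean(axis=0)) / sd
    gap = np.where(sd == 0, 0.0, gap)
    summary = pd.DataFrame(
        {
            "mean": d.mean(axis=0),
            "sd": sd,
            "split_gap": gap,
            "converged": gap <= gap_threshold,
        },
        index=draws.param_names,
    )
    hists = {
        name: np.histogram(d[:, k], bins=50)
        for k, name in enumerate(draws.param_names)
    }
    return ChainDiagnostics(summary=summary, traces=draws.to_frame(), histograms=hists)


def posterior_aic(train, draws: PosteriorDraws) -> float:
    """Order-selection criterion evaluated at the posterior-mean parameters.

    Computes the one-step residual SSE of the posterior-mean ``(alpha, beta)``
    on the training sample, then applies the same AIC formula as the
    least-squares baseline, so order traces are comparable across the two
    fitting routes.
    """
    y = train.values if isinstance(train, MonthlySeries) else np.asarray(train, float)
    p = draws.order
    lags, targets = build_design(y, p)
    mean = draws.posterior_mean()
    alpha, betas = mean[0], mean[1 : p + 1]
    resid = targets - (alpha + lags @ betas)
    return aic(float(resid @ resid), y.size, p)
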