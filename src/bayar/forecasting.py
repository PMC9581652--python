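"""Posterior-predictive forecasting and multi-level prediction intervals.

Each retained posterior draw ``(alpha, beta, sigma2)`` is propagated through
the AR recurrence over the full horizon, feeding its own predictions back as
lags; with process noise enabled (the default) every step also adds a fresh
``N(0, sigma2)`` innovation, so the forecast sample reflects both parameter
and process uncertainty.  The per-month sample is summarized by its mean
(point forecast), SD (uncertainty), and a fan of 17 central prediction
intervals at levels 0.10, 0.15, ..., 0.90 built from empirical quantiles
(linear interpolation between order statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bayes_ar import GibbsConfig, PosteriorDraws, PriorSpec, gibbs_sample
from .synthetic_data import SyntheticSpec, generate_series

__all__ = [
    "INTERVAL_LEVELS",
    "ForecastDistribution",
    "PredictionIntervalSet",
    "posterior_forecast",
    "build_intervals",
    "coverage_experiment",
]

#: The 17 central-interval levels: 10% to 90% in 5% steps.
INTERVAL_LEVELS = np.round(np.arange(0.10, 0.90 + 1e-9, 0.05), 2)


@dataclass(frozen=True)
class PredictionIntervalSet:
    """Central prediction intervals at each level, per horizon month.

    ``lower``/``upper`` have shape (levels x horizon); intervals at higher
    levels contain those at lower levels.
    """

    levels: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def at_level(self, level: float) -> tuple[np.ndarray, np.ndarray]:
        idx = np.nonzero(np.isclose(self.levels, level))[0]
        if idx.size == 0:
            raise ValueError(f"level {level} not on the grid {self.levels}")
        return self.lower[idx[0]], self.upper[idx[0]]


@dataclass(frozen=True)
class ForecastDistribution:
    """Per-month forecast sample with point summary and interval fan."""

    horizon: int
    samples: np.ndarray  # (retained draws x horizon)
    point: np.ndarray
    sd: np.ndarray
    intervals: PredictionIntervalSet | None = None


def posterior_forecast(
    draws: PosteriorDraws,
    seed_lags,
    horizon: int,
    include_noise: bool = True,
    seed: int = 0,
) -> ForecastDistribution:
    """One forecast trajectory per retained posterior draw.

    ``seed_lags`` are the last p training observations, most recent first.
    Point forecast = columnwise mean, SD = columnwise SD; intervals are built
    automatically when at least 100 trajectories are available.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    p = draws.order
    lags0 = np.asarray(seed_lags, dtype=float)
    if lags0.size != p:
        raise ValueError(f"need {p} seed lags for an order-{p} draw set, got {lags0.size}")
    d = draws.draws
    R = d.shape[0]
    alpha = d[:, 0]
    betas = d[:, 1 : p + 1]
    sigma = np.sqrt(d[:, p + 1])
    rng = np.random.default_rng(seed)
    lags = np.tile(lags0, (R, 1))  # (R x p), most recent first
    samples = np.empty((R, horizon))
    for h in range(horizon):
        y_next = alpha + np.einsum("ij,ij->i", betas, lags)
        if include_noise:
            y_next = y_next + sigma * rng.standard_normal(R)
        samples[:, h] = y_next
        lags = np.column_stack([y_next, lags[:, :-1]])
    dist = ForecastDistribution(
        horizon=horizon,
        samples=samples,
        point=samples.mean(axis=0),
        sd=samples.std(axis=0, ddof=1),
    )
    if R >= 100:
        dist = replace(dist, intervals=build_intervals(dist))
    return dist


def build_intervals(dist: ForecastDistribution) -> PredictionIntervalSet:
    """Empirical central intervals at every level of :data:`INTERVAL_LEVELS`.

    Level ``l`` spans the ((1-l)/2, (1+l)/2) empirical quantiles of the
    per-month forecast sample (quantiles by linear interpolation between
    order statistics, the "type 7" convention).
    """
    if dist.samples.shape[0] < 100:
        raise ValueError(
            f"need >= 100 samples per month to build intervals, got {dist.samples.shape[0]}"
        )
    lo_q = (1.0 - INTERVAL_LEVELS) / 2.0
    hi_q = (1.0 + INTERVAL_LEVELS) / 2.0
    lower = np.quantile(dist.samples, lo_q, axis=0, method="linear")
    upper = np.quantile(dist.samples, hi_q, axis=0, method="linear")
    return PredictionIntervalSet(levels=INTERVAL_LEVELS.copy(), lower=lower, upper=upper)


def coverage_experiment(
    generator: SyntheticSpec,
    level: float,
    replicates: int,
    seed: int,
    order: int | None = None,
    prior: PriorSpec | None = None,
    config: GibbsConfig | None = None,
    quantile_pair: tuple | None = None,
) -> float:
    """Empirical 1-step coverage of the level-``level`` prediction interval.

    For each replicate: draw a series one month longer than the generator's
    ``length``, fit the Bayesian AR on the first ``length`` months, forecast
    one step with process noise, and record whether the held-out final month
    falls inside the interval.  ``level`` must be on the 17-level grid unless
    an explicit ``quantile_pair`` is given.
    """
    if replicates < 50:
        raise ValueError(f"need >= 50 replicates, got {replicates}")
    if quantile_pair is None and not np.any(np.isclose(INTERVAL_LEVELS, level)):
        raise ValueError(
            f"level {level} outside the 0.10-0.90 grid; pass quantile_pair explicitly"
        )
    p = order if order is not None else max(len(generator.ar_coefs), 1)
    config = config or GibbsConfig(iterations=2_000, burn_in=400)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(generator, length=generator.length + 1, seed=rep_seed)
        series = generate_series(spec)
        train, truth = series.values[:-1], series.values[-1]
        draws = gibbs_sample(
            train, p, prior=prior, config=replace(config, seed=rep_seed)
        )
        dist = posterior_forecast(
            draws, train[-p:][::-1], horizon=1, include_noise=True, seed=rep_seed
        )
        if quantile_pair is not None:
            lo, hi = np.quantile(dist.samples[:, 0], quantile_pair)
        else:
            lo_arr, hi_arr = dist.intervals.at_level(level)
            lo, hi = lo_arr[0], hi_arr[0]
        hits += int(lo <= truth <= hi)
    return hits / replicates
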