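"""Series characterization: moments, permutation entropy, STL, seasonal profile.

These diagnostics describe the shape and complexity of a monthly register
before any model is fitted: population-moment skewness and kurtosis
(non-excess, so a Gaussian sample sits near 3), permutation entropy as a
model-free complexity index, an additive STL decomposition into seasonal,
trend and remainder components, and a years-by-calendar-month reshape for
polar seasonal plots.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.seasonal import STL

from .timeseries_io import MonthlySeries

__all__ = [
    "SeriesDiagnostics",
    "moment_stats",
    "permutation_entropy",
    "stl_components",
    "seasonal_profile",
    "describe_series",
]


@dataclass(frozen=True)
class SeriesDiagnostics:
    kurtosis: float
    skewness: float
    permutation_entropy: float  # nats
    stl: tuple  # (seasonal, trend, remainder), each length of the series


def _values(series) -> np.ndarray:
    if isinstance(series, MonthlySeries):
        return series.values
    return np.asarray(series, dtype=float)


def moment_stats(series) -> tuple[float, float]:
    """(kurtosis, skewness) by population-moment definitions.

    skewness = m3 / m2^(3/2); kurtosis = m4 / m2^2 (non-excess: a normal
    sample gives about 3).
    """
    y = _values(series)
    if y.size < 4:
        raise ValueError(f"need at least 4 observations, got {y.size}")
    if np.var(y) == 0:
        raise ValueError("zero variance: moments undefined")
    kurt = float(stats.kurtosis(y, fisher=False, bias=True))
    skew = float(stats.skew(y, bias=True))
    return kurt, skew


def permutation_entropy(series, m: int = 4, tau: int = 1) -> float:
    """Shannon entropy (nats) of ordinal patterns in sliding windows.

    Each window of ``m`` points at spacing ``tau`` maps to the permutation
    that sorts it (ties broken by earlier position first); the entropy of the
    empirical pattern distribution measures series complexity, from 0 for a
    monotone series up to ``log(m!)`` for patternless data.
    """
    y = _values(series)
    if m < 2:
        raise ValueError(f"embedding dimension must be >= 2, got {m}")
    if tau < 1:
        raise ValueError(f"delay must be >= 1, got {tau}")
    span = (m - 1) * tau
    if y.size < m * tau + 10:
        raise ValueError(
            f"series too short for m={m}, tau={tau}: need >= {m * tau + 10}, got {y.size}"
        )
    n_windows = y.size - span
    counts = Counter()
    for start in range(n_windows):
        window = y[start : start + span + 1 : tau]
        pattern = tuple(np.argsort(window, kind="stable"))
        counts[pattern] += 1
    freqs = np.array(list(counts.values()), dtype=float) / n_windows
    return float(-np.sum(freqs * np.log(freqs)))


def stl_components(
    series, period: int = 12, robust: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Additive seasonal/trend/remainder decomposition by LOESS (STL).

    The components sum back to the input exactly; the seasonal component has
    the stated period (12 for an annual cycle on monthly data).
    """
    y = _values(series)
    if y.size < 2 * period:
        raise ValueError(
            f"need at least two full periods ({2 * period}), got {y.size}"
        )
    res = STL(y, period=period, robust=robust).fit()
    return res.seasonal, res.trend, res.resid


def seasonal_profile(series: MonthlySeries) -> pd.DataFrame:
    """Observations arranged as a (years x 12 calendar months) table.

    Months outside the observed range (partial first/last years) are NaN.
    Ready for polar/seasonal plotting: each row is one year's annual profile.
    """
    idx = series.period_index()
    frame = pd.DataFrame(
        {"year": idx.year, "month": idx.month, "value": series.values}
    )
    profile = frame.pivot(index="year", columns="month", values="value")
    return profile.reindex(columns=range(1, 13))


def describe_series(
    series: MonthlySeries, pe_dim: int = 4, pe_tau: int = 1, period: int = 12
) -> SeriesDiagnostics:
    """All scalar diagnostics plus the STL components in one pass."""
    kurt, skew = moment_stats(series)
    pe = permutation_entropy(series, m=pe_dim, tau=pe_tau)
    comps = stl_components(series, period=period)
    return SeriesDiagnostics(
        kurtosis=kurt, skewness=skew, permutation_entropy=pe, stl=comps
    )
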