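"""Monthly series container, CSV I/O, and chronological train/test splitting.

A :class:`MonthlySeries` is a gapless run of strictly positive monthly counts
(outpatient visits per month) anchored at a calendar month.  The on-disk
format is a two-column CSV ``month,visits`` with ISO ``YYYY-MM`` month stamps;
rows may arrive in any order and are sorted chronologically on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MonthlySeries",
    "SplitSpec",
    "read_series",
    "write_series",
    "split_series",
]


@dataclass(frozen=True)
class MonthlySeries:
    """Gapless univariate series of positive monthly counts.

    Parameters
    ----------
    values
        Visit counts, one per consecutive calendar month. All finite and > 0.
    start
        ``(year, month)`` of the first observation, month in 1..12.
    """

    values: np.ndarray
    start: tuple[int, int]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("series must be a one-dimensional array of length >= 1")
        if not np.all(np.isfinite(vals)):
            raise ValueError("series values must all be finite")
        if np.any(vals <= 0):
            bad = int(np.argmax(vals <= 0))
            raise ValueError(f"series values must be strictly positive (index {bad})")
        year, month = self.start
        if not (1 <= month <= 12):
            raise ValueError(f"start month must be in 1..12, got {month}")
        object.__setattr__(self, "start", (int(year), int(month)))

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def length(self) -> int:
        return len(self)

    def period_index(self) -> pd.PeriodIndex:
        """Calendar months covered by the series, as a monthly PeriodIndex."""
        first = pd.Period(year=self.start[0], month=self.start[1], freq="M")
        return pd.period_range(first, periods=len(self), freq="M")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"month": self.period_index().strftime("%Y-%m"), "visits": self.values}
        )

    def month_of_year(self) -> np.ndarray:
        """Calendar month (1..12) of each observation."""
        return np.asarray(self.period_index().month)


@dataclass(frozen=True)
class SplitSpec:
    """Chronological train/test split by training fraction.

    The training set is the anterior ``floor(train_fraction * length)`` months;
    the remainder is the test set. The floor rule guarantees the test share is
    never smaller than advertised.
    """

    train_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError(
                f"train_fraction must lie in (0, 1), got {self.train_fraction}"
            )


def read_series(
    path, month_col: str = "month", value_col: str = "visits"
) -> MonthlySeries:
    """Read a monthly count series from CSV, validating and sorting rows.

    The file must have a header with ``month_col`` (ISO ``YYYY-MM``) and
    ``value_col`` (strictly positive numbers). Rows may be in any order;
    duplicates and calendar gaps are rejected with the offending row named.
    """
    frame = pd.read_csv(path, dtype={month_col: str})
    for col in (month_col, value_col):
        if col not in frame.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    if frame[month_col].isna().any():
        row = int(frame.index[frame[month_col].isna()][0])
        raise ValueError(f"missing month stamp at row {row}")
    try:
        periods = pd.PeriodIndex(frame[month_col].str.strip(), freq="M")
    except Exception as exc:  # unparseable stamp: name the first bad row
        for row, stamp in enumerate(frame[month_col]):
            try:
                pd.Period(str(stamp).strip(), freq="M")
            except Exception:
                raise ValueError(
                    f"unparseable month stamp {stamp!r} at row {row}"
                ) from exc
        raise
    counts = pd.to_numeric(frame[value_col], errors="coerce")
    if counts.isna().any():
        row = int(frame.index[counts.isna()][0])
        raise ValueError(
            f"non-numeric count {frame[value_col].iloc[row]!r} at row {row}"
        )
    if (counts <= 0).any():
        row = int(frame.index[counts <= 0][0])
        raise ValueError(f"non-positive count {counts.iloc[row]} at row {row}")
    order = np.argsort(periods.asi8, kind="stable")
    periods = periods[order]
    counts = counts.to_numpy()[order]
    dup = pd.Series(periods.asi8).duplicated()
    if dup.any():
        stamp = periods[int(dup.idxmax())].strftime("%Y-%m")
        raise ValueError(f"duplicate month {stamp}")
    steps = np.diff(periods.asi8)
    if np.any(steps != 1):
        i = int(np.argmax(steps != 1))
        raise ValueError(
            "calendar gap between "
            f"{periods[i].strftime('%Y-%m')} and {periods[i + 1].strftime('%Y-%m')}"
        )
    first = periods[0]
    return MonthlySeries(values=counts, start=(first.year, first.month))


def write_series(series: MonthlySeries, path) -> None:
    """Write a series as ``month,visits`` CSV (inverse of :func:`read_series`)."""
    series.to_frame().to_csv(path, index=False)


def split_series(
    series: MonthlySeries, spec: SplitSpec
) -> tuple[MonthlySeries, MonthlySeries]:
    """Split chronologically: anterior ``floor(fraction*length)`` months train,
    the rest test. Concatenating the two halves reproduces the input.
    """
    n = len(series)
    if n < 5:
        raise ValueError(f"series too short to split (length {n} < 5)")
    n_train = math.floor(spec.train_fraction * n)
    if n_train < 4:
        raise ValueError(
            f"train_fraction {spec.train_fraction} leaves only {n_train} "
            "training months (minimum 4)"
        )
    if n_train >= n:
        raise ValueError(f"train_fraction {spec.train_fraction} leaves an empty test set")
    train = MonthlySeries(values=series.values[:n_train], start=series.start)
    test_start = series.period_index()[n_train]
    test = MonthlySeries(
        values=series.values[n_train:], start=(test_start.year, test_start.month)
    )
    return train, test
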