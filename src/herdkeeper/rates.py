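"""Inbreeding/kinship rates, period partitioning and effective population size.

Rates are expressed per generation or per year.  Over a period of n years with
mean inbreeding F_1 in the first year and F_n in the last, the generation-based
rate is

    dF = 1 - ((1 - F_n) / (1 - F_1)) ** (L / n)

with L the generation interval in years; the year-based rate replaces L by 1.
A regression estimate is obtained from the OLS slope of ln(1 - F_y) on year.
The realized effective population size is Ne = 1 / (2 dF) whenever dF > 0; a
zero or negative rate (possible when pedigrees are incomplete or outside
animals are brought in) leaves Ne undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "RateEstimate",
    "partition_periods",
    "delta_f_generation",
    "delta_f_year",
    "delta_f_regression",
    "sim_delta_f",
    "effective_size",
]


@dataclass
class RateEstimate:
    """Rates over one period, with the derived effective size (None = undefined)."""

    period: tuple[int, int]
    n: int
    L: float
    dF_generation: float
    dF_year: float
    dF_regression: float | None
    Ne: float | None

    @classmethod
    def from_series(
        cls,
        period: tuple[int, int],
        L: float,
        F_by_year: Mapping[int, float],
    ) -> "RateEstimate":
        first, last = period
        n = last - first
        F1, Fn = F_by_year.get(first, math.nan), F_by_year.get(last, math.nan)
        if n <= 0 or not (np.isfinite(F1) and np.isfinite(Fn)):
            dFg = dFy = math.nan
        else:
            dFg = delta_f_generation(F1, Fn, L, n)
            dFy = delta_f_year(F1, Fn, n)
        series = {
            y: f for y, f in F_by_year.items() if first <= y <= last and np.isfinite(f)
        }
        dFr = delta_f_regression(series) if len(series) >= 2 else None
        return cls(
            period=period, n=n, L=L, dF_generation=dFg, dF_year=dFy,
            dF_regression=dFr, Ne=effective_size(dFg),
        )


def partition_periods(first_year: int, last_year: int) -> list[tuple[int, int]]:
    """Split [first_year, last_year] into contiguous 5-6-year periods.

    The span counts year intervals (last - first).  Spans under 10 years get
    no sub-periods; otherwise there are floor(span / 5) periods of 5 years and
    the span-mod-5 excess years are distributed one each to the leading
    periods.  Consecutive periods share their boundary year, matching the
    convention that a period's rate runs from its first to its last year.
    """
    if last_year < first_year:
        raise ValueError("last_year must be >= first_year")
    span = last_year - first_year
    if span < 10:
        return []
    k, excess = divmod(span, 5)
    # spread the excess as equally as possible over the leading periods
    lengths = [
        5 + excess // k + (1 if i < excess % k else 0) for i in range(k)
    ]
    periods = []
    start = first_year
    for length in lengths:
        periods.append((start, start + length))
        start += length
    return periods


def _check_f(value: float, name: str) -> None:
    if value >= 1.0:
        raise ValueError(f"{name} must be below 1, got {value}")


def delta_f_generation(F_first: float, F_last: float, L: float, n: int) -> float:
    """Generation-based rate 1 - ((1-F_last)/(1-F_first))**(L/n)."""
    _check_f(F_first, "F_first")
    _check_f(F_last, "F_last")
    if L <= 0:
        raise ValueError("generation interval L must be positive")
    if n < 1:
        raise ValueError("period length n must be at least 1 year")
    return 1.0 - ((1.0 - F_last) / (1.0 - F_first)) ** (L / n)


def delta_f_year(F_first: float, F_last: float, n: int) -> float:
    """Year-based rate: the generation-based formula with L replaced by 1."""
    return delta_f_generation(F_first, F_last, 1.0, n)


def delta_f_regression(F_by_year: Mapping[int, float]) -> float | None:
    """Minus the OLS slope of ln(1 - F_y) on year; None with < 2 usable years."""
    pairs = [
        (y, f)
        for y, f in F_by_year.items()
        if f is not None and np.isfinite(f) and f < 1.0
    ]
    if len(pairs) < 2:
        return None
    years = np.array([p[0] for p in pairs], dtype=float)
    logs = np.log1p(-np.array([p[1] for p in pairs], dtype=float))
    slope = np.polyfit(years, logs, 1)[0]
    return -float(slope)


def sim_delta_f(F_last: float, L: float, n: int) -> float:
    """Rate from a simulation starting at F = 0: 1 - (1 - F_last)**(L/n).

    The same form serves for kinship rates with the mean kinship of the last
    year in place of F_last.
    """
    return delta_f_generation(0.0, F_last, L, n)


def effective_size(delta_f: float) -> float | None:
    """Ne = 1/(2 dF) for dF > 0; undefined (None) at zero or negative rates."""
    if delta_f is None or not np.isfinite(delta_f) or delta_f <= 0.0:
        return None
    return 1.0 / (2.0 * delta_f)
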