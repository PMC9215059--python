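"""Linear-trend projection of annual healthcare cost series.

Annual direct healthcare costs per cancer type and sex are projected to a
target year by ordinary least squares of cost on calendar year, with a
standard OLS prediction interval.  Monetary values recorded in local
currency are converted to international dollars by a purchasing power
parity (PPP) factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PPP_FACTOR_2019",
    "CostSeries",
    "CostProjection",
    "fit_and_project",
    "ppp_convert",
    "read_cost_series",
    "write_cost_series",
]

#: 2019 purchasing power parity conversion factor, R$ per international US$.
PPP_FACTOR_2019 = 2.281


@dataclass(frozen=True)
class CostSeries:
    """Annual costs for one cancer type and sex."""

    cancer: str
    sex: str
    years: tuple[int, ...]
    costs: tuple[float, ...]
    currency: str = "BRL"

    def __post_init__(self) -> None:
        if len(self.years) != len(self.costs):
            raise ValueError("years and costs length mismatch")
        if len(set(self.years)) < 2:
            raise ValueError("cost series needs at least 2 distinct years")
        if any(c < 0 for c in self.costs):
            raise ValueError("costs must be non-negative")


@dataclass(frozen=True)
class CostProjection:
    cancer: str
    sex: str
    target_year: int
    point: float
    low: float
    high: float
    intercept: float  # fitted cost at year 0 of the centered scale's origin year
    slope: float  # cost units per calendar year
    currency: str = "BRL"

    def __post_init__(self) -> None:
        if not (self.low <= self.point <= self.high):
            raise ValueError("prediction interval must bracket the point")


def fit_and_project(
    series: CostSeries, target_year: int, interval_level: float = 0.95
) -> CostProjection:
    """OLS of cost on calendar year, evaluated at ``target_year``.

    The year covariate is centered before fitting (numerically identical
    fit, better conditioning).  The interval is the standard t-based OLS
    prediction interval for a new observation; for an exactly linear,
    noiseless series its width is zero.  Negative projections are floored
    at zero with a warning.
    """
    if not 0 < interval_level < 1:
        raise ValueError("interval_level must be in (0, 1)")
    if target_year < max(series.years):
        raise ValueError("target_year must not precede the observed series")
    years = np.asarray(series.years, dtype=float)
    x = years - years.mean()
    X = sm.add_constant(x)
    fit = sm.OLS(np.asarray(series.costs, dtype=float), X).fit()
    pred = fit.get_prediction([1.0, target_year - years.mean()])
    frame = pred.summary_frame(alpha=1.0 - interval_level)
    point = float(frame["mean"].iloc[0])
    low = float(frame["obs_ci_lower"].iloc[0])
    high = float(frame["obs_ci_upper"].iloc[0])
    if point < 0 or low < 0:
        warnings.warn(
            f"projection for {series.cancer}/{series.sex} at {target_year} "
            "went negative; flooring at 0",
            stacklevel=2,
        )
        point, low, high = max(point, 0.0), max(low, 0.0), max(high, 0.0)
    slope = float(fit.params[1])
    intercept = float(fit.params[0] - slope * years.mean())  # back to calendar origin
    return CostProjection(
        cancer=series.cancer,
        sex=series.sex,
        target_year=target_year,
        point=point,
        low=low,
        high=high,
        intercept=intercept,
        slope=slope,
        currency=series.currency,
    )


def ppp_convert(amount: float, factor: float = PPP_FACTOR_2019) -> float:
    """Convert local currency to international dollars: ``amount / factor``."""
    if factor <= 0:
        raise ValueError("PPP conversion factor must be positive")
    return amount / factor


# ---------------------------------------------------------------------------
# CSV I/O: long format (cancer, sex, year, cost, currency)


def read_cost_series(path) -> dict[tuple[str, str], CostSeries]:
    df = pd.read_csv(path)
    needed = {"cancer", "sex", "year", "cost"}
    if not needed <= set(df.columns):
        raise ValueError(f"cost CSV missing columns: {sorted(needed - set(df.columns))}")
    out: dict[tuple[str, str], CostSeries] = {}
    for (cancer, sex), grp in df.groupby(["cancer", "sex"], sort=False):
        grp = grp.sort_values("year")
        out[(str(cancer), str(sex))] = CostSeries(
            cancer=str(cancer),
            sex=str(sex),
            years=tuple(grp["year"].astype(int)),
            costs=tuple(grp["cost"].astype(float)),
            currency=str(grp["currency"].iloc[0]) if "currency" in grp else "BRL",
        )
    return out


def write_cost_series(series: Iterable[CostSeries], path) -> None:
    rows = [
        {"cancer": s.cancer, "sex": s.sex, "year": y, "cost": c, "currency": s.currency}
        for s in series
        for y, c in zip(s.years, s.costs)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
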