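"""Dose-response relative risks of cancer per BMI increment.

Meta-analyses of BMI and cancer incidence usually report a relative risk
(RR) per increment of ``x`` kg/m² of BMI (most often x = 5) under a
log-linear dose-response model: ``log RR`` is proportional to the BMI
difference.  This module provides

* rescaling of an RR between increments, ``RR_1 = exp(log(RR_x) / x)``;
* expansion of a per-unit RR into a categorical profile over BMI strata,
  ``RR_c = RR_1 ** (M_c − ref)`` where ``M_c`` is the median BMI of a
  category and ``ref`` the value assigned to the reference (lowest-risk)
  category; and
* DerSimonian–Laird random-effects pooling of per-study log-RR estimates,
  used when a published pooled RR mixes incidence and mortality outcomes
  and must be re-pooled on incidence studies only.

All RR confidence bounds are carried through the same power transforms as
the point estimate, which on the log scale is an exact rescaling of the
confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Z_95",
    "RelativeRiskEstimate",
    "BMICategory",
    "BMICategorySchema",
    "CategoricalRRProfile",
    "StudyEstimate",
    "default_schema",
    "rescale_rr",
    "categorical_profile",
    "pool_random_effects",
    "read_rr_table",
    "write_rr_table",
    "read_study_table",
]

#: 97.5th percentile of the standard normal, kept at full precision rather
#: than the conventional 1.96 so CI <-> SE round trips are exact.
Z_95 = 1.959964


@dataclass(frozen=True)
class RelativeRiskEstimate:
    """A relative risk per ``increment`` kg/m² of BMI with a 95% CI."""

    cancer: str
    sex: str
    increment: float
    rr: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.increment <= 0:
            raise ValueError(f"increment must be positive, got {self.increment}")
        if min(self.rr, self.ci_low, self.ci_high) <= 0:
            raise ValueError("relative risks and CI bounds must be positive")
        if not (self.ci_low <= self.rr <= self.ci_high):
            raise ValueError(
                f"CI ({self.ci_low}, {self.ci_high}) does not bracket RR {self.rr}"
            )

    @property
    def log_se(self) -> float:
        """Standard error of log-RR implied by the 95% CI."""
        return (math.log(self.ci_high) - math.log(self.ci_low)) / (2.0 * Z_95)


@dataclass(frozen=True)
class BMICategory:
    """One BMI stratum: half-open interval [lower, upper) with a median."""

    label: str
    lower: float
    upper: float
    median: float
    reference: bool = False

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"category {self.label}: lower must be < upper")
        if not (self.lower <= self.median < self.upper):
            raise ValueError(
                f"category {self.label}: median {self.median} outside "
                f"[{self.lower}, {self.upper})"
            )


@dataclass(frozen=True)
class BMICategorySchema:
    """Ordered, non-overlapping BMI categories with exactly one reference."""

    categories: tuple[BMICategory, ...]

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise ValueError("schema needs at least two categories")
        for a, b in zip(self.categories, self.categories[1:]):
            if a.upper > b.lower:
                raise ValueError(f"categories {a.label} and {b.label} overlap")
        n_ref = sum(c.reference for c in self.categories)
        if n_ref != 1:
            raise ValueError(f"schema must have exactly one reference category, got {n_ref}")

    def __len__(self) -> int:
        return len(self.categories)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.categories)

    @property
    def medians(self) -> np.ndarray:
        return np.array([c.median for c in self.categories])

    @property
    def lowers(self) -> np.ndarray:
        return np.array([c.lower for c in self.categories])

    @property
    def reference_index(self) -> int:
        return next(i for i, c in enumerate(self.categories) if c.reference)

    @property
    def reference_median(self) -> float:
        return self.categories[self.reference_index].median

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown category {label!r}") from None


def default_schema(medians: Sequence[float] = (22.0, 27.0, 32.0, 37.0)) -> BMICategorySchema:
    """WHO-style four-category schema: <25 (reference), 25–<30, 30–<35, ≥35.

    Category medians are configurable because they depend on the survey
    population; the defaults are the interval midpoints (37 for the open
    top category).
    """
    m = tuple(medians)
    if len(m) != 4:
        raise ValueError("default schema expects exactly 4 medians")
    return BMICategorySchema(
        (
            BMICategory("<25", 0.0, 25.0, m[0], reference=True),
            BMICategory("25-30", 25.0, 30.0, m[1]),
            BMICategory("30-35", 30.0, 35.0, m[2]),
            BMICategory(">=35", 35.0, math.inf, m[3]),
        )
    )


@dataclass(frozen=True)
class CategoricalRRProfile:
    """Per-category relative risks for one cancer subtype and sex.

    ``rr`` is aligned with ``schema.categories``; the reference category
    carries RR = 1 exactly.
    """

    cancer: str
    sex: str
    schema: BMICategorySchema
    rr: tuple[float, ...]
    ci_low: Optional[tuple[float, ...]] = None
    ci_high: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if len(self.rr) != len(self.schema):
            raise ValueError("rr length does not match schema")
        if any(r <= 0 for r in self.rr):
            raise ValueError("categorical RRs must be positive")
        if self.rr[self.schema.reference_index] != 1.0:
            raise ValueError("reference category RR must equal 1 exactly")

    @property
    def values(self) -> np.ndarray:
        return np.array(self.rr)


def rescale_rr(estimate: RelativeRiskEstimate, target_increment: float) -> RelativeRiskEstimate:
    """Rescale an RR from its increment to ``target_increment`` kg/m².

    Under the log-linear model the point estimate and both CI bounds are
    raised to the power ``target_increment / increment``; rescaling to the
    same increment is the identity.
    """
    if target_increment <= 0:
        raise ValueError(f"target_increment must be positive, got {target_increment}")
    power = target_increment / estimate.increment
    return replace(
        estimate,
        increment=target_increment,
        rr=estimate.rr**power,
        ci_low=estimate.ci_low**power,
        ci_high=estimate.ci_high**power,
    )


def categorical_profile(
    rr_per_unit: RelativeRiskEstimate,
    schema: BMICategorySchema,
    ref_value: Optional[float] = None,
    medians: Optional[Sequence[float]] = None,
) -> CategoricalRRProfile:
    """Expand a per-1 kg/m² RR into per-category RRs ``RR_1 ** (M_c − ref)``.

    Parameters
    ----------
    rr_per_unit
        RR expressed per 1 kg/m² (rescale first if needed).
    schema
        BMI category schema supplying medians and the reference category.
    ref_value
        Value subtracted from each median in the exponent.  Defaults to the
        reference category's median, so the reference RR is exactly 1.
    medians
        Override of the schema medians (used for counterfactuals that shift
        category medians without changing the schema).
    """
    if rr_per_unit.increment != 1.0:
        raise ValueError("categorical_profile expects an RR per 1 kg/m²; rescale first")
    ref = schema.reference_median if ref_value is None else float(ref_value)
    m = schema.medians if medians is None else np.asarray(medians, dtype=float)
    if m.shape != (len(schema),):
        raise ValueError("medians override must match schema length")
    # Normalize by the (unshifted) reference category so its RR is 1 exactly;
    # the impact fraction is invariant to this common rescaling, which makes
    # the choice of `ref` immaterial downstream.
    expo = m - ref
    ref_expo = schema.medians[schema.reference_index] - ref
    rr = rr_per_unit.rr**expo / rr_per_unit.rr**ref_expo
    lo = rr_per_unit.ci_low**expo / rr_per_unit.ci_low**ref_expo
    hi = rr_per_unit.ci_high**expo / rr_per_unit.ci_high**ref_expo
    # a protective RR (rr1 < 1) flips the bounds when the exponent is positive
    ci_low = np.minimum(lo, hi)
    ci_high = np.maximum(lo, hi)
    if m[schema.reference_index] == schema.reference_median:
        rr[schema.reference_index] = 1.0  # zero exponent, made exact
    return CategoricalRRProfile(
        cancer=rr_per_unit.cancer,
        sex=rr_per_unit.sex,
        schema=schema,
        rr=tuple(rr),
        ci_low=tuple(ci_low),
        ci_high=tuple(ci_high),
    )


@dataclass(frozen=True)
class StudyEstimate:
    """One study's log relative risk with its standard error."""

    study: str
    log_rr: float
    se: float
    outcome: str = "incidence"  # "incidence" | "mortality"

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if self.outcome not in ("incidence", "mortality"):
            raise ValueError(f"unknown outcome {self.outcome!r}")


def pool_random_effects(
    studies: Iterable[StudyEstimate],
    outcome_filter: Optional[str] = None,
    cancer: str = "pooled",
    sex: str = "both",
    increment: float = 5.0,
) -> RelativeRiskEstimate:
    """DerSimonian–Laird random-effects pooling of per-study log-RRs.

    The between-study variance τ² is the moment estimator
    ``max(0, (Q − (k−1)) / (Σw − Σw²/Σw))`` with fixed-effect weights
    ``w = 1/se²``; the pooled estimate uses weights ``1/(se² + τ²)``.
    With τ² = 0 this reduces to fixed-effect inverse-variance pooling.
    """
    kept = [s for s in studies if outcome_filter is None or s.outcome == outcome_filter]
    if not kept:
        raise ValueError("no studies left after outcome filtering")
    y = np.array([s.log_rr for s in kept])
    v = np.array([s.se for s in kept]) ** 2
    k = len(kept)
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    if k == 1:
        mu, se = y[0], math.sqrt(v[0])
    else:
        q = float(np.sum(w * (y - mu_fe) ** 2))
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - (k - 1)) / c)
        w_re = 1.0 / (v + tau2)
        mu = float(np.sum(w_re * y) / np.sum(w_re))
        se = math.sqrt(1.0 / np.sum(w_re))
    return RelativeRiskEstimate(
        cancer=cancer,
        sex=sex,
        increment=increment,
        rr=math.exp(mu),
        ci_low=math.exp(mu - Z_95 * se),
        ci_high=math.exp(mu + Z_95 * se),
    )


# ---------------------------------------------------------------------------
# CSV I/O

RR_COLUMNS = ["cancer", "sex", "increment", "rr", "ci_low", "ci_high"]


def read_rr_table(path) -> list[RelativeRiskEstimate]:
    """Read a dose-response RR table (columns: cancer, sex, increment, rr, ci_low, ci_high)."""
    df = pd.read_csv(path)
    missing = set(RR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"RR table missing columns: {sorted(missing)}")
    return [
        RelativeRiskEstimate(
            cancer=str(r.cancer),
            sex=str(r.sex),
            increment=float(r.increment),
            rr=float(r.rr),
            ci_low=float(r.ci_low),
            ci_high=float(r.ci_high),
        )
        for r in df.itertuples()
    ]


def write_rr_table(estimates: Iterable[RelativeRiskEstimate], path) -> None:
    pd.DataFrame(
        [
            {
                "cancer": e.cancer,
                "sex": e.sex,
                "increment": e.increment,
                "rr": e.rr,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
            }
            for e in estimates
        ]
    ).to_csv(path, index=False)


def read_study_table(path) -> list[StudyEstimate]:
    """Read per-study estimates (columns: study, log_rr, se, outcome)."""
    df = pd.read_csv(path)
    return [
        StudyEstimate(
            study=str(r.study),
            log_rr=float(r.log_rr),
            se=float(r.se),
            outcome=str(r.outcome),
        )
        for r in df.itertuples()
    ]
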