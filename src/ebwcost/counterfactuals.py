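"""Baseline and counterfactual BMI prevalence distributions.

The comparative risk assessment contrasts the observed BMI category
distribution of a population with counterfactual (alternative)
distributions describing population-wide BMI reductions.  Four scenario
kinds are supported:

``target_distribution``
    Roll the distribution back to a supplied historical table (e.g. an
    earlier household survey).
``hold_reference``
    Freeze the distribution at a designated reference year, halting the
    rise in excess body weight.
``truncate_above``
    Eliminate the categories at or above a BMI threshold (by default
    obesity classes II and III, BMI ≥ 35), moving their mass to the
    adjacent category below the threshold.
``mean_shift``
    Lower mean BMI by a fixed amount (default 1 kg/m²) among people at or
    above an eligibility threshold (default BMI ≥ 25).  Because exposure is
    categorical this is realized as a shift of category medians when the
    counterfactual relative risks are computed; the prevalence vector
    itself is unchanged.

A linear per-category projection is provided for analyses that need a
future-year baseline distribution between or beyond two observed surveys.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .relative_risk import BMICategorySchema

__all__ = [
    "PrevalenceTable",
    "ScenarioSpec",
    "ScenarioResult",
    "apply_scenario",
    "project_prevalence",
    "read_prevalence_table",
    "write_prevalence_tables",
    "scenario_from_dict",
    "scenario_to_dict",
    "load_scenarios",
]

_SUM_TOL = 1e-9

SCENARIO_KINDS = ("target_distribution", "hold_reference", "truncate_above", "mean_shift")


@dataclass(frozen=True)
class PrevalenceTable:
    """BMI category proportions for one stratum (sex, optionally age group)."""

    sex: str
    categories: tuple[str, ...]
    proportions: tuple[float, ...]
    ci_low: Optional[tuple[float, ...]] = None
    ci_high: Optional[tuple[float, ...]] = None
    effective_n: Optional[int] = None
    year: Optional[int] = None

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if len(self.categories) != p.size:
            raise ValueError("categories and proportions length mismatch")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("proportions must lie in [0, 1]")
        if abs(p.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"proportions must sum to 1, got {p.sum():.12f}")
        if self.effective_n is not None and self.effective_n < 1:
            raise ValueError("effective_n must be >= 1")

    @property
    def values(self) -> np.ndarray:
        return np.array(self.proportions)

    def with_proportions(self, p, **changes) -> "PrevalenceTable":
        """Copy with new proportions (CIs dropped — they no longer apply)."""
        return replace(
            self, proportions=tuple(np.asarray(p, dtype=float)), ci_low=None, ci_high=None, **changes
        )


@dataclass(frozen=True)
class ScenarioSpec:
    """Definition of one counterfactual BMI scenario."""

    kind: str
    label: str = ""
    target: Optional[PrevalenceTable] = None
    reference: Optional[PrevalenceTable] = None
    threshold: float = 35.0
    shift: float = 1.0
    eligibility: float = 25.0
    reallocate_to: str = "below"  # "below" | "reference"

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.threshold <= 0 or self.shift <= 0:
            raise ValueError("threshold and shift must be positive")
        if self.reallocate_to not in ("below", "reference"):
            raise ValueError("reallocate_to must be 'below' or 'reference'")
        if self.kind == "target_distribution" and self.target is None:
            raise ValueError("target_distribution scenario requires a target table")


@dataclass(frozen=True)
class ScenarioResult:
    """Counterfactual prevalence plus an optional RR-side adjustment.

    ``counterfactual_medians`` is set only by mean-shift scenarios: the
    counterfactual categorical RRs must be evaluated at these medians while
    the prevalence vector stays at baseline.
    """

    table: PrevalenceTable
    counterfactual_medians: Optional[tuple[float, ...]] = None
    warning: Optional[str] = None


def _truncate_matrix(
    p: np.ndarray, schema: BMICategorySchema, threshold: float, reallocate_to: str
) -> tuple[np.ndarray, Optional[str]]:
    """Move all mass from categories with lower bound >= threshold downwards.

    Vectorized over rows so the Monte Carlo engine can reuse it.
    """
    lowers = schema.lowers
    eliminated = lowers >= threshold
    if not eliminated.any():
        return p.copy(), f"threshold {threshold} eliminates no category; no-op"
    keep = np.flatnonzero(~eliminated)
    if keep.size == 0:
        return p.copy(), f"threshold {threshold} would eliminate every category; no-op"
    dest = schema.reference_index if reallocate_to == "reference" else int(keep.max())
    out = p.copy()
    moved = out[..., eliminated].sum(axis=-1)
    out[..., eliminated] = 0.0
    out[..., dest] += moved
    return out, None


def shifted_medians(schema: BMICategorySchema, shift: float, eligibility: float) -> np.ndarray:
    """Medians with ``shift`` subtracted for categories at/above ``eligibility``."""
    m = schema.medians.copy()
    m[schema.lowers >= eligibility] -= shift
    return m


def apply_scenario(
    baseline: PrevalenceTable, spec: ScenarioSpec, schema: BMICategorySchema
) -> ScenarioResult:
    """Build the counterfactual distribution for ``spec`` from ``baseline``."""
    if baseline.categories != schema.labels:
        raise ValueError("baseline table categories do not match schema")
    if spec.kind == "target_distribution":
        assert spec.target is not None
        if spec.target.categories != schema.labels:
            raise ValueError("target table categories do not match schema")
        return ScenarioResult(table=spec.target)
    if spec.kind == "hold_reference":
        table = spec.reference if spec.reference is not None else baseline
        if table.categories != schema.labels:
            raise ValueError("reference table categories do not match schema")
        return ScenarioResult(table=table)
    if spec.kind == "truncate_above":
        out, warning = _truncate_matrix(baseline.values, schema, spec.threshold, spec.reallocate_to)
        return ScenarioResult(table=baseline.with_proportions(out), warning=warning)
    # mean_shift: prevalences untouched, RR medians adjusted
    m = shifted_medians(schema, spec.shift, spec.eligibility)
    return ScenarioResult(table=baseline, counterfactual_medians=tuple(m))


def project_prevalence(
    early: PrevalenceTable, late: PrevalenceTable, target_year: int
) -> PrevalenceTable:
    """Linear per-category extrapolation of proportions to ``target_year``.

    Proportions are extrapolated on the straight line through the two
    observed surveys, clipped to [0, 1], and renormalized to sum to 1.
    """
    if early.categories != late.categories or early.sex != late.sex:
        raise ValueError("prevalence tables must share schema and stratum")
    if early.year is None or late.year is None:
        raise ValueError("both tables need a reference year")
    if not (early.year < late.year <= target_year):
        raise ValueError("need early.year < late.year <= target_year")
    if target_year == late.year:
        return late
    rate = (late.values - early.values) / (late.year - early.year)
    p = late.values + rate * (target_year - late.year)
    p = np.clip(p, 0.0, 1.0)
    total = p.sum()
    if total <= 0:
        raise ValueError("projection collapsed to an empty distribution")
    return late.with_proportions(p / total, year=target_year)


# ---------------------------------------------------------------------------
# I/O: prevalence CSV (long format) and scenario YAML

PREVALENCE_COLUMNS = ["sex", "category", "proportion"]


def read_prevalence_table(path, schema: BMICategorySchema) -> dict[str, PrevalenceTable]:
    """Read per-sex prevalence tables from long-format CSV.

    Required columns: sex, category, proportion.  Optional: ci_low,
    ci_high, effective_n, year.
    """
    df = pd.read_csv(path)
    missing = set(PREVALENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"prevalence CSV missing columns: {sorted(missing)}")
    out: dict[str, PrevalenceTable] = {}
    for sex, grp in df.groupby("sex", sort=False):
        grp = grp.set_index("category").reindex(list(schema.labels))
        if grp["proportion"].isna().any():
            raise ValueError(f"stratum {sex!r} is missing categories of the schema")
        has_ci = "ci_low" in grp.columns and grp["ci_low"].notna().all()
        out[str(sex)] = PrevalenceTable(
            sex=str(sex),
            categories=schema.labels,
            proportions=tuple(grp["proportion"].astype(float)),
            ci_low=tuple(grp["ci_low"].astype(float)) if has_ci else None,
            ci_high=tuple(grp["ci_high"].astype(float)) if has_ci else None,
            effective_n=int(grp["effective_n"].iloc[0]) if "effective_n" in grp and grp["effective_n"].notna().all() else None,
            year=int(grp["year"].iloc[0]) if "year" in grp and grp["year"].notna().all() else None,
        )
    return out


def write_prevalence_tables(tables: dict[str, PrevalenceTable], path, scenario: str = "") -> None:
    rows = []
    for table in tables.values():
        for i, cat in enumerate(table.categories):
            rows.append(
                {
                    "sex": table.sex,
                    "category": cat,
                    "proportion": table.proportions[i],
                    "ci_low": table.ci_low[i] if table.ci_low else np.nan,
                    "ci_high": table.ci_high[i] if table.ci_high else np.nan,
                    "effective_n": table.effective_n,
                    "year": table.year,
                    "scenario": scenario,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def scenario_to_dict(spec: ScenarioSpec) -> dict:
    d: dict = {"kind": spec.kind, "label": spec.label}
    if spec.kind == "truncate_above":
        d.update(threshold=spec.threshold, reallocate_to=spec.reallocate_to)
    elif spec.kind == "mean_shift":
        d.update(shift=spec.shift, eligibility=spec.eligibility)
    return d


def scenario_from_dict(
    d: dict,
    target: Optional[PrevalenceTable] = None,
    reference: Optional[PrevalenceTable] = None,
) -> ScenarioSpec:
    kw = {k: d[k] for k in ("kind", "label", "threshold", "shift", "eligibility", "reallocate_to") if k in d}
    return ScenarioSpec(target=target, reference=reference, **kw)


def load_scenarios(path) -> list[dict]:
    """Load scenario dicts from YAML (tables are attached by the pipeline)."""
    with open(path) as fh:
        docs = yaml.safe_load(fh)
    if not isinstance(docs, list):
        raise ValueError("scenario YAML must contain a list of scenario mappings")
    return docs
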