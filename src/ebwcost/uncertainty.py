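"""Monte Carlo propagation of sampling uncertainty through the PIF.

Each iteration redraws the inputs and re-evaluates the impact fraction:

a) baseline prevalence — per-category binomial draws at the stratum's
   effective sample size, renormalized to the simplex (or a single
   multinomial partition, configurable);
b) the log relative risk per published increment — a normal draw with
   standard error back-calculated from the 95% CI, rescaled to per-unit
   and expanded to categorical RRs *within* the iteration, so all
   category RRs of a subtype share one dose-response draw.

Summaries are the 2.5th / 50th / 97.5th percentiles of the draws; the
median is the central estimate.  Negative PIF draws are truncated to zero
by default (a BMI reduction is assumed not to increase risk).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .counterfactuals import (
    PrevalenceTable,
    ScenarioSpec,
    _truncate_matrix,
    shifted_medians,
)
from .pif_engine import PIFEstimate
from .relative_risk import BMICategorySchema, RelativeRiskEstimate

__all__ = [
    "MonteCarloConfig",
    "draw_prevalence",
    "draw_log_rr",
    "simulate_pif",
    "log_rr_se",
]


@dataclass(frozen=True)
class MonteCarloConfig:
    n_iterations: int = 10_000
    seed: int = 0
    percentiles: tuple[float, float, float] = (2.5, 50.0, 97.5)
    truncate_negative: bool = True
    prevalence_resampling: str = "per_category_binomial_renormalized"  # | "multinomial"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        p = self.percentiles
        if not (0 < p[0] < p[1] < p[2] < 100):
            raise ValueError("percentiles must be strictly increasing within (0, 100)")
        if self.prevalence_resampling not in (
            "per_category_binomial_renormalized",
            "multinomial",
        ):
            raise ValueError(f"unknown resampling mode {self.prevalence_resampling!r}")


def log_rr_se(estimate: RelativeRiskEstimate) -> float:
    """SE of log-RR from the 95% CI: (ln hi − ln lo) / (2 × 1.959964)."""
    if estimate.ci_low > estimate.ci_high:
        raise ValueError("inverted CI bounds")
    return estimate.log_se


def _draw_prevalence_matrix(
    p: np.ndarray, effective_n: int, n_iter: int, rng: np.random.Generator, mode: str
) -> np.ndarray:
    """(n_iter, k) matrix of prevalence draws on the simplex."""
    if mode == "multinomial":
        counts = rng.multinomial(effective_n, p, size=n_iter)
        return counts / effective_n
    counts = rng.binomial(effective_n, p, size=(n_iter, p.size)).astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    # all-zero rows can only occur when every true proportion is tiny;
    # fall back to the point estimate for those rows
    bad = totals[:, 0] == 0
    if bad.any():
        counts[bad] = p * effective_n
        totals = counts.sum(axis=1, keepdims=True)
    return counts / totals


def draw_prevalence(
    table: PrevalenceTable, config: MonteCarloConfig, rng: np.random.Generator
) -> PrevalenceTable:
    """One resampled prevalence table (binomial-renormalized or multinomial)."""
    if table.effective_n is None:
        raise ValueError("prevalence table has no effective_n; cannot resample")
    row = _draw_prevalence_matrix(
        table.values, table.effective_n, 1, rng, config.prevalence_resampling
    )[0]
    return table.with_proportions(row)


def draw_log_rr(
    estimate: RelativeRiskEstimate, rng: np.random.Generator
) -> RelativeRiskEstimate:
    """One normal draw of the log-RR on its published increment scale."""
    se = log_rr_se(estimate)
    drawn = math.exp(rng.normal(math.log(estimate.rr), se))
    return replace(estimate, rr=drawn, ci_low=drawn, ci_high=drawn)


def _counterfactual_matrix(
    p_draws: np.ndarray, spec: ScenarioSpec, schema: BMICategorySchema
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Counterfactual prevalence per draw and optional shifted medians.

    Scenario semantics per kind: fixed external tables (historical target,
    frozen reference year) are held constant across iterations — only
    baseline prevalence and RR are stochastic; distribution-derived
    scenarios (truncation) are recomputed from each baseline draw; the
    mean shift leaves prevalence draws untouched and adjusts medians.
    """
    if spec.kind == "target_distribution":
        assert spec.target is not None
        return np.broadcast_to(spec.target.values, p_draws.shape), None
    if spec.kind == "hold_reference":
        if spec.reference is None:
            return p_draws, None  # counterfactual ≡ baseline, PIF ≡ 0
        return np.broadcast_to(spec.reference.values, p_draws.shape), None
    if spec.kind == "truncate_above":
        out, _ = _truncate_matrix(p_draws, schema, spec.threshold, spec.reallocate_to)
        return out, None
    return p_draws, shifted_medians(schema, spec.shift, spec.eligibility)


def simulate_pif(
    baseline: PrevalenceTable,
    scenario: ScenarioSpec,
    rr: RelativeRiskEstimate,
    schema: BMICategorySchema,
    config: MonteCarloConfig,
    rng: Optional[np.random.Generator] = None,
    return_draws: bool = False,
):
    """Monte Carlo PIF for one cancer subtype, stratum and scenario.

    Returns a :class:`PIFEstimate` whose point is the configured middle
    percentile (the median by default); with ``return_draws=True`` the raw
    draw vector is returned alongside for audit.
    """
    if baseline.categories != schema.labels:
        raise ValueError("baseline table categories do not match schema")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_iterations
    p_draws = _draw_prevalence_matrix(
        baseline.values, _require_n(baseline), n, rng, config.prevalence_resampling
    )
    pc_draws, cf_medians = _counterfactual_matrix(p_draws, scenario, schema)

    se = log_rr_se(rr)
    log_rr_draws = rng.normal(math.log(rr.rr), se, size=n)
    log_rr1 = log_rr_draws / rr.increment
    ref = schema.reference_median
    expo = schema.medians - ref
    rr_draws = np.exp(np.outer(log_rr1, expo))
    if cf_medians is None:
        rr_cf = rr_draws
    else:
        rr_cf = np.exp(np.outer(log_rr1, cf_medians - ref))

    base_sum = (p_draws * rr_draws).sum(axis=1)
    cf_sum = (pc_draws * rr_cf).sum(axis=1)
    pif = 1.0 - cf_sum / base_sum
    n_truncated = 0
    if config.truncate_negative:
        n_truncated = int((pif < 0).sum())
        pif = np.maximum(pif, 0.0)
    lo, mid, hi = np.percentile(pif, config.percentiles)
    est = PIFEstimate(
        cancer=rr.cancer,
        sex=baseline.sex,
        scenario=scenario.label or scenario.kind,
        point=float(mid),
        ci_low=float(lo),
        ci_high=float(hi),
        n_draws=n,
    )
    if return_draws:
        return est, pif
    return est


def _require_n(table: PrevalenceTable) -> int:
    if table.effective_n is None:
        raise ValueError(f"stratum {table.sex!r} has no effective_n; cannot resample")
    return table.effective_n
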