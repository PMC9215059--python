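"""Synthetic survey, relative-risk and cost-registry inputs with known truth.

Real runs of the attribution pipeline consume (i) a national health-survey
BMI prevalence table by sex, (ii) a dose-response RR table by cancer
subtype and sex, and (iii) registry series of annual direct healthcare
costs of cancer.  This module generates statistically faithful stand-ins
for all three so every downstream stage can be tested end to end, and it
evaluates the exact ground-truth impact fraction implied by the generating
parameters so parameter recovery can be verified.

The generator emulates: categorical prevalence as one multinomial draw at
a stated effective sample size (so proportions always partition the sample
and sum to one); binomial (Wilson) confidence intervals per category; and
linear-in-time annual costs with additive Gaussian noise floored at zero.
It deliberately does not emulate complex survey design (stratification,
clustering, weights) — effective sample size is the only sampling knob.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from statsmodels.stats.proportion import proportion_confint

from .counterfactuals import (
    PrevalenceTable,
    ScenarioSpec,
    apply_scenario,
    write_prevalence_tables,
)
from .cost_projection import CostSeries, write_cost_series
from .pif_engine import pif_subtype
from .relative_risk import (
    BMICategorySchema,
    RelativeRiskEstimate,
    categorical_profile,
    default_schema,
    rescale_rr,
    write_rr_table,
)

__all__ = [
    "SyntheticConfig",
    "default_config",
    "generate_prevalence",
    "generate_cost_series",
    "ground_truth_pif",
    "write_dataset",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters for one synthetic dataset.

    ``true_proportions`` maps stratum (sex) → category proportion vector;
    ``cost_trend`` maps (cancer, sex) → (intercept, slope per year, noise
    standard deviation), all in million R$.
    """

    seed: int
    schema: BMICategorySchema
    true_proportions: dict[str, tuple[float, ...]]
    effective_n: dict[str, int]
    rr_table: tuple[RelativeRiskEstimate, ...]
    cost_trend: dict[tuple[str, str], tuple[float, float, float]]
    years: tuple[int, int] = (2008, 2019)
    survey_year: int = 2019

    def __post_init__(self) -> None:
        for sex, p in self.true_proportions.items():
            arr = np.asarray(p, dtype=float)
            if arr.size != len(self.schema):
                raise ValueError(f"stratum {sex!r}: proportions do not match schema")
            if abs(arr.sum() - 1.0) > _SUM_TOL:
                raise ValueError(f"stratum {sex!r}: proportions must sum to 1")
            if np.any(arr < 0):
                raise ValueError(f"stratum {sex!r}: proportions must be non-negative")
            if self.effective_n.get(sex, 0) < 1:
                raise ValueError(f"stratum {sex!r}: effective_n must be >= 1")
        for key, (_, _, sd) in self.cost_trend.items():
            if sd < 0:
                raise ValueError(f"cost trend {key}: noise sd must be >= 0")
        if self.years[1] <= self.years[0]:
            raise ValueError("years must span at least 2 distinct years")


def default_config(seed: int = 0) -> SyntheticConfig:
    """A Brazil-2019-like default: ~60% of adults above the reference category.

    Category proportions approximate the national survey picture (excess
    body weight ≈ 60%, obesity ≈ 26%); effective n of 5,000 per stratum is
    a large-survey effective size.  Cost trends are modest upward lines in
    million R$ per year.
    """
    schema = default_schema()
    rr = (
        RelativeRiskEstimate("endometrium", "F", 5.0, 1.50, 1.42, 1.59),
        RelativeRiskEstimate("kidney", "F", 5.0, 1.30, 1.25, 1.36),
        RelativeRiskEstimate("kidney", "M", 5.0, 1.30, 1.25, 1.36),
        RelativeRiskEstimate("colorectal", "M", 5.0, 1.08, 1.04, 1.11),
    )
    props = (0.397, 0.344, 0.189, 0.070)
    return SyntheticConfig(
        seed=seed,
        schema=schema,
        true_proportions={"F": props, "M": props},
        effective_n={"F": 5000, "M": 5000},
        rr_table=rr,
        cost_trend={
            ("endometrium", "F"): (40.0, 3.0, 2.0),
            ("kidney", "F"): (10.0, 0.8, 0.5),
            ("kidney", "M"): (14.0, 1.2, 0.5),
            ("colorectal", "M"): (250.0, 20.0, 10.0),
        },
    )


def generate_prevalence(config: SyntheticConfig) -> dict[str, PrevalenceTable]:
    """Sample one survey-like prevalence table per stratum.

    Counts are a single multinomial partition of the stratum's effective n
    (so observed proportions sum to 1 exactly); per-category 95% CIs use
    the Wilson score interval for a binomial proportion.
    """
    rng = np.random.default_rng(config.seed)
    out: dict[str, PrevalenceTable] = {}
    for sex in sorted(config.true_proportions):
        p_true = np.asarray(config.true_proportions[sex], dtype=float)
        n = config.effective_n[sex]
        counts = rng.multinomial(n, p_true)
        lo, hi = proportion_confint(counts, n, alpha=0.05, method="wilson")
        out[sex] = PrevalenceTable(
            sex=sex,
            categories=config.schema.labels,
            proportions=tuple(counts / n),
            ci_low=tuple(np.atleast_1d(lo)),
            ci_high=tuple(np.atleast_1d(hi)),
            effective_n=n,
            year=config.survey_year,
        )
    return out


def generate_cost_series(config: SyntheticConfig) -> dict[tuple[str, str], CostSeries]:
    """Linear-in-time annual cost series with additive Gaussian noise, floored at 0."""
    rng = np.random.default_rng(config.seed + 1)
    first, last = config.years
    years = np.arange(first, last + 1)
    out: dict[tuple[str, str], CostSeries] = {}
    for (cancer, sex), (intercept, slope, sd) in sorted(config.cost_trend.items()):
        values = intercept + slope * (years - first)
        if sd > 0:
            values = values + rng.normal(0.0, sd, size=years.size)
        values = np.maximum(values, 0.0)
        out[(cancer, sex)] = CostSeries(
            cancer=cancer,
            sex=sex,
            years=tuple(int(y) for y in years),
            costs=tuple(values),
            currency="BRL",
        )
    return out


def ground_truth_pif(
    config: SyntheticConfig,
    scenario: ScenarioSpec,
    cancer: str,
    sex: str,
    ref_value: Optional[float] = None,
) -> float:
    """Deterministic PIF implied by the generating (noise-free) parameters."""
    match = [e for e in config.rr_table if e.cancer == cancer and e.sex == sex]
    if not match:
        raise KeyError(f"no RR for cancer={cancer!r}, sex={sex!r}")
    truth = PrevalenceTable(
        sex=sex,
        categories=config.schema.labels,
        proportions=tuple(config.true_proportions[sex]),
        year=config.survey_year,
    )
    result = apply_scenario(truth, scenario, config.schema)
    rr1 = rescale_rr(match[0], 1.0)
    profile = categorical_profile(rr1, config.schema, ref_value=ref_value)
    cf_rr = None
    if result.counterfactual_medians is not None:
        cf_rr = categorical_profile(
            rr1, config.schema, ref_value=ref_value, medians=result.counterfactual_medians
        )
    return pif_subtype(truth, result.table, profile, counterfactual_rr=cf_rr)


def write_dataset(config: SyntheticConfig, outdir) -> dict[str, str]:
    """Write prevalence/RR/cost CSVs, the config YAML, and a seed manifest.

    Returns the mapping of artifact name → path; the manifest records the
    seed and SHA-256 checksums of every written table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "prevalence": outdir / "prevalence.csv",
        "rr": outdir / "relative_risks.csv",
        "costs": outdir / "costs.csv",
        "config": outdir / "config.yaml",
    }
    write_prevalence_tables(generate_prevalence(config), paths["prevalence"])
    write_rr_table(config.rr_table, paths["rr"])
    write_cost_series(generate_cost_series(config).values(), paths["costs"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=True)
    manifest = {
        "seed": config.seed,
        "checksums": {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in paths.items()
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = manifest_path
    return {k: str(v) for k, v in paths.items()}


def _config_to_dict(config: SyntheticConfig) -> dict:
    return {
        "seed": config.seed,
        "years": list(config.years),
        "survey_year": config.survey_year,
        "categories": [
            {
                "label": c.label,
                "lower": c.lower,
                "upper": None if c.upper == float("inf") else c.upper,
                "median": c.median,
                "reference": c.reference,
            }
            for c in config.schema.categories
        ],
        "true_proportions": {s: [float(x) for x in p] for s, p in config.true_proportions.items()},
        "effective_n": dict(config.effective_n),
        "cost_trend": {
            f"{cancer}|{sex}": [float(v) for v in trend]
            for (cancer, sex), trend in config.cost_trend.items()
        },
    }
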