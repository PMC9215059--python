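"""End-to-end attribution and savings runs.

`run_attribution` produces the attribution analysis for one exposure year
and one cost year (default: exposure 2019, costs 2030, respecting the
10-year exposure–outcome lag): per-subtype impact fractions under the
theoretical-minimum-risk counterfactual (everyone below 25 kg/m²), per-site
attributable costs, and per-sex totals.

`run_savings` produces the scenario analysis for a later pair (default:
exposure 2030, costs 2040): for each counterfactual scenario, the cost
savings per cancer site, sex, and overall.

Both write CSV reports plus a manifest JSON recording the seed, a config
hash and input checksums, so a report is reproducible from the manifest
alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .counterfactuals import (
    PrevalenceTable,
    ScenarioSpec,
    apply_scenario,
    project_prevalence,
    read_prevalence_table,
)
from .cost_projection import (
    PPP_FACTOR_2019,
    fit_and_project,
    ppp_convert,
    read_cost_series,
)
from .pif_engine import PIFEstimate, attributable_cost, pif_site, pif_subtype
from .relative_risk import (
    BMICategorySchema,
    categorical_profile,
    default_schema,
    read_rr_table,
    rescale_rr,
)
from .uncertainty import MonteCarloConfig, simulate_pif

__all__ = ["RunConfig", "ScenarioEntry", "run_attribution", "run_savings", "config_from_yaml"]

log = logging.getLogger(__name__)

#: minimum assumed latency between exposure prevalence and the costs it
#: influences, in years
MIN_LAG = 10


@dataclass
class RunConfig:
    prevalence_csv: str
    rr_csv: str
    cost_csv: str
    outdir: str
    schema: BMICategorySchema = field(default_factory=default_schema)
    prevalence_year: int = 2019
    cost_year: int = 2030
    savings_prevalence_year: int = 2030
    savings_cost_year: int = 2040
    mc: Optional[MonteCarloConfig] = None
    ppp_factor: float = PPP_FACTOR_2019
    #: subtype → topographic site whose total cost the subtype PIF is respread over;
    #: subtypes absent from the map are their own site
    site_map: dict = field(default_factory=dict)
    scenarios: Sequence[ScenarioSpec] = ()
    #: optional earlier survey used to project the savings-year baseline
    prevalence_csv_early: Optional[str] = None
    allow_short_lag: bool = False

    def __post_init__(self) -> None:
        for pair in ((self.prevalence_year, self.cost_year), (self.savings_prevalence_year, self.savings_cost_year)):
            if pair[1] - pair[0] < MIN_LAG and not self.allow_short_lag:
                raise ValueError(
                    f"cost year {pair[1]} is less than {MIN_LAG} years after exposure "
                    f"year {pair[0]}; set allow_short_lag to override"
                )


@dataclass
class ScenarioEntry:
    """A scenario definition whose target/reference tables vary by stratum."""

    params: dict
    targets: Optional[dict[str, PrevalenceTable]] = None
    references: Optional[dict[str, PrevalenceTable]] = None

    def resolve(self, sex: str) -> ScenarioSpec:
        from .counterfactuals import scenario_from_dict

        return scenario_from_dict(
            dict(self.params),
            target=(self.targets or {}).get(sex),
            reference=(self.references or {}).get(sex),
        )

    @property
    def label(self) -> str:
        return self.params.get("label") or self.params["kind"]


def _resolve_scenario(entry, sex: str) -> ScenarioSpec:
    return entry.resolve(sex) if isinstance(entry, ScenarioEntry) else entry


def _reference_scenario(schema: BMICategorySchema, sex: str) -> ScenarioSpec:
    """Theoretical minimum risk: all mass in the reference category."""
    one_hot = np.zeros(len(schema))
    one_hot[schema.reference_index] = 1.0
    target = PrevalenceTable(sex=sex, categories=schema.labels, proportions=tuple(one_hot))
    return ScenarioSpec(kind="target_distribution", label="theoretical_minimum", target=target)


def _pif_for(
    baseline: PrevalenceTable,
    spec: ScenarioSpec,
    rr_est,
    schema: BMICategorySchema,
    mc: Optional[MonteCarloConfig],
    rng: Optional[np.random.Generator],
    scenario_label: str,
) -> PIFEstimate:
    if mc is not None:
        return simulate_pif(baseline, spec, rr_est, schema, mc, rng=rng)
    result = apply_scenario(baseline, spec, schema)
    rr1 = rescale_rr(rr_est, 1.0)
    profile = categorical_profile(rr1, schema)
    cf_rr = (
        categorical_profile(rr1, schema, medians=result.counterfactual_medians)
        if result.counterfactual_medians is not None
        else None
    )
    point = pif_subtype(baseline, result.table, profile, counterfactual_rr=cf_rr)
    return PIFEstimate(
        cancer=rr_est.cancer,
        sex=baseline.sex,
        scenario=scenario_label,
        point=point,
        ci_low=point,
        ci_high=point,
        n_draws=0,
    )


def _projected_cost_usd(series, year: int, ppp: float) -> float:
    proj = fit_and_project(series, year)
    return ppp_convert(proj.point, ppp)


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_manifest(config: RunConfig, outdir: Path, inputs: dict[str, str], name: str) -> None:
    cfg_repr = {
        "prevalence_year": config.prevalence_year,
        "cost_year": config.cost_year,
        "savings_prevalence_year": config.savings_prevalence_year,
        "savings_cost_year": config.savings_cost_year,
        "ppp_factor": config.ppp_factor,
        "mc": None
        if config.mc is None
        else {
            "n_iterations": config.mc.n_iterations,
            "seed": config.mc.seed,
            "truncate_negative": config.mc.truncate_negative,
            "prevalence_resampling": config.mc.prevalence_resampling,
        },
        "site_map": dict(config.site_map),
        "scenarios": [
            s.label if isinstance(s, ScenarioEntry) else (s.label or s.kind)
            for s in config.scenarios
        ],
    }
    manifest = {
        "config_hash": hashlib.sha256(
            yaml.safe_dump(cfg_repr, sort_keys=True).encode()
        ).hexdigest(),
        "seed": None if config.mc is None else config.mc.seed,
        "inputs": {k: _checksum(v) for k, v in inputs.items()},
        "config": cfg_repr,
    }
    (outdir / name).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_attribution(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Attribution analysis: PIF per subtype, attributable cost per site, totals.

    Writes ``subtype_report.csv`` (per-increment and per-unit RRs with the
    subtype PIF), ``attribution_report.csv`` (site-level PIF, projected
    cost and attributable cost with totals rows) and
    ``attribution_manifest.json`` into ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prevalence = read_prevalence_table(config.prevalence_csv, config.schema)
    rr_table = read_rr_table(config.rr_csv)
    costs = read_cost_series(config.cost_csv)
    rng = None if config.mc is None else np.random.default_rng(config.mc.seed)

    subtype_rows = []
    for est in rr_table:
        if est.sex not in prevalence:
            raise ValueError(f"missing prevalence stratum for sex {est.sex!r} ({est.cancer})")
        if (est.cancer, est.sex) not in costs:
            raise ValueError(f"missing cost series for ({est.cancer}, {est.sex})")
        baseline = prevalence[est.sex]
        spec = _reference_scenario(config.schema, est.sex)
        log.info("attribution: %s/%s", est.cancer, est.sex)
        pif = _pif_for(baseline, spec, est, config.schema, config.mc, rng, spec.label)
        cost_usd = _projected_cost_usd(costs[(est.cancer, est.sex)], config.cost_year, config.ppp_factor)
        attr = attributable_cost(pif, cost_usd)
        rr1 = rescale_rr(est, 1.0)
        subtype_rows.append(
            {
                "cancer": est.cancer,
                "sex": est.sex,
                "rr_per_increment": est.rr,
                "increment": est.increment,
                "rr_per_unit": rr1.rr,
                "pif": pif.point,
                "pif_low": pif.ci_low,
                "pif_high": pif.ci_high,
                "cost_musd": cost_usd,
                "attributable_musd": attr.attributable,
                "attributable_low_musd": attr.attributable_low,
                "attributable_high_musd": attr.attributable_high,
                "site": config.site_map.get(est.cancer, est.cancer),
            }
        )
    subtypes = pd.DataFrame(subtype_rows)

    site_rows = []
    for (site, sex), grp in subtypes.groupby(["site", "sex"], sort=True):
        if site in set(grp["cancer"]) and len(grp) == 1 and site == grp["cancer"].iloc[0]:
            site_cost = float(grp["cost_musd"].iloc[0])
        else:
            if (site, sex) not in costs:
                raise ValueError(f"missing total cost series for site ({site}, {sex})")
            site_cost = _projected_cost_usd(costs[(site, sex)], config.cost_year, config.ppp_factor)
        attr = float(grp["attributable_musd"].sum())
        site_rows.append(
            {
                "site": site,
                "sex": sex,
                "pif_pct": 100.0 * pif_site(min(attr, site_cost), site_cost),
                "pif_low_pct": 100.0 * min(grp["attributable_low_musd"].sum() / site_cost, 1.0),
                "pif_high_pct": 100.0 * min(grp["attributable_high_musd"].sum() / site_cost, 1.0),
                "cost_musd": site_cost,
                "attributable_musd": attr,
                "attributable_low_musd": float(grp["attributable_low_musd"].sum()),
                "attributable_high_musd": float(grp["attributable_high_musd"].sum()),
            }
        )
    sites = pd.DataFrame(site_rows)
    totals = totals_by_sex(sites)
    report = pd.concat([sites, totals], ignore_index=True)

    subtypes.to_csv(outdir / "subtype_report.csv", index=False)
    report.to_csv(outdir / "attribution_report.csv", index=False)
    _write_manifest(
        config,
        outdir,
        {"prevalence": config.prevalence_csv, "rr": config.rr_csv, "costs": config.cost_csv},
        "attribution_manifest.json",
    )
    return {"subtypes": subtypes, "sites": sites, "totals": totals}


def totals_by_sex(sites: pd.DataFrame, label: str = "ebw_associated") -> pd.DataFrame:
    """Per-sex and both-sex totals across site rows; pooled PIF = Σattr / Σcost."""
    rows = []
    per_sex = sites.groupby("sex", sort=True)
    sums = {c: per_sex[c].sum() for c in ("cost_musd", "attributable_musd", "attributable_low_musd", "attributable_high_musd")}
    for sex in sums["cost_musd"].index:
        rows.append(_total_row(label, sex, {k: v[sex] for k, v in sums.items()}))
    rows.append(_total_row(label, "T", {k: v.sum() for k, v in sums.items()}))
    return pd.DataFrame(rows)


def _total_row(label: str, sex: str, s: dict) -> dict:
    return {
        "site": label,
        "sex": sex,
        "pif_pct": 100.0 * s["attributable_musd"] / s["cost_musd"],
        "pif_low_pct": 100.0 * s["attributable_low_musd"] / s["cost_musd"],
        "pif_high_pct": 100.0 * s["attributable_high_musd"] / s["cost_musd"],
        "cost_musd": s["cost_musd"],
        "attributable_musd": s["attributable_musd"],
        "attributable_low_musd": s["attributable_low_musd"],
        "attributable_high_musd": s["attributable_high_musd"],
    }


def run_savings(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Scenario savings analysis at the later exposure/cost pair.

    The savings-year baseline prevalence is projected linearly per category
    from an earlier survey (``prevalence_csv_early``) and the main survey
    when the main survey predates the savings exposure year; otherwise the
    supplied table is used as-is.  Savings per subtype and scenario are
    PIF × projected cost; site and total rows aggregate them.
    """
    if not config.scenarios:
        raise ValueError("run_savings needs at least one scenario")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prevalence = read_prevalence_table(config.prevalence_csv, config.schema)
    rr_table = read_rr_table(config.rr_csv)
    costs = read_cost_series(config.cost_csv)
    rng = None if config.mc is None else np.random.default_rng(config.mc.seed)

    baselines: dict[str, PrevalenceTable] = {}
    early = (
        read_prevalence_table(config.prevalence_csv_early, config.schema)
        if config.prevalence_csv_early
        else None
    )
    for sex, table in prevalence.items():
        if table.year is not None and table.year < config.savings_prevalence_year:
            if early is None:
                raise ValueError(
                    "savings baseline predates the savings exposure year and no "
                    "earlier survey is given for projection"
                )
            projected = project_prevalence(early[sex], table, config.savings_prevalence_year)
            # keep resampling possible at the survey's effective size
            baselines[sex] = projected if projected.effective_n else projected.with_proportions(
                projected.values, effective_n=table.effective_n
            )
        else:
            baselines[sex] = table

    rows = []
    for est in rr_table:
        baseline = baselines[est.sex]
        cost_usd = _projected_cost_usd(
            costs[(est.cancer, est.sex)], config.savings_cost_year, config.ppp_factor
        )
        for entry in config.scenarios:
            spec = _resolve_scenario(entry, est.sex)
            label = spec.label or spec.kind
            pif = _pif_for(baseline, spec, est, config.schema, config.mc, rng, label)
            attr = attributable_cost(pif, cost_usd)
            rows.append(
                {
                    "cancer": est.cancer,
                    "sex": est.sex,
                    "site": config.site_map.get(est.cancer, est.cancer),
                    "scenario": label,
                    "projected_cost_musd": cost_usd,
                    "savings_musd": attr.attributable,
                    "savings_low_musd": attr.attributable_low,
                    "savings_high_musd": attr.attributable_high,
                }
            )
    subtypes = pd.DataFrame(rows)
    sites = (
        subtypes.groupby(["site", "sex", "scenario"], sort=True)[
            ["savings_musd", "savings_low_musd", "savings_high_musd"]
        ]
        .sum()
        .reset_index()
    )
    total_rows = []
    for (sex, scenario), grp in subtypes.groupby(["sex", "scenario"], sort=True):
        total_rows.append(
            {
                "site": "ebw_associated",
                "sex": sex,
                "scenario": scenario,
                "savings_musd": grp["savings_musd"].sum(),
                "savings_low_musd": grp["savings_low_musd"].sum(),
                "savings_high_musd": grp["savings_high_musd"].sum(),
            }
        )
    for scenario, grp in subtypes.groupby("scenario", sort=True):
        total_rows.append(
            {
                "site": "ebw_associated",
                "sex": "T",
                "scenario": scenario,
                "savings_musd": grp["savings_musd"].sum(),
                "savings_low_musd": grp["savings_low_musd"].sum(),
                "savings_high_musd": grp["savings_high_musd"].sum(),
            }
        )
    totals = pd.DataFrame(total_rows)
    report = pd.concat([sites, totals], ignore_index=True)
    report.to_csv(outdir / "savings_report.csv", index=False)
    _write_manifest(
        config,
        outdir,
        {"prevalence": config.prevalence_csv, "rr": config.rr_csv, "costs": config.cost_csv},
        "savings_manifest.json",
    )
    return {"subtypes": subtypes, "sites": sites, "totals": totals}


def config_from_yaml(path, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML mapping of the same field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update(overrides)
    mc = raw.pop("mc", None)
    if mc is not None:
        mc = MonteCarloConfig(**mc)
    medians = raw.pop("schema_medians", None)
    schema = default_schema(medians) if medians else default_schema()
    scenario_dicts = raw.pop("scenarios", [])
    scenarios = []
    for d in scenario_dicts:
        d = dict(d)
        targets = references = None
        if "target_csv" in d:
            targets = read_prevalence_table(d.pop("target_csv"), schema)
        if "reference_csv" in d:
            references = read_prevalence_table(d.pop("reference_csv"), schema)
        scenarios.append(ScenarioEntry(params=d, targets=targets, references=references))
    return RunConfig(mc=mc, schema=schema, scenarios=scenarios, **raw)
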