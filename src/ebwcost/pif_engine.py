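"""Potential impact fractions and attributable costs.

The potential impact fraction (PIF) is the proportional reduction in an
outcome — here, direct healthcare costs of cancer — obtained by moving the
exposure distribution from its observed baseline ``P`` to a counterfactual
``P'``::

    PIF = (Σ P_i RR_i − Σ P'_i RR_i) / Σ P_i RR_i

summed over BMI categories ``i``.  When the counterfactual puts everyone in
the reference (lowest-risk) category, the PIF equals the population
attributable fraction (PAF).  Attributable cost is the PIF multiplied by
the projected cost of the cancer; for cancer subtypes whose costs are
recorded at a wider topographic site (e.g. oesophageal adenocarcinoma
within all oesophageal cancer), a site-level PIF is recovered as
attributable subtype cost over total site cost.

Deterministic PIFs may be negative (a counterfactual worse than baseline);
truncation of negative values is the Monte Carlo layer's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .counterfactuals import PrevalenceTable
from .relative_risk import CategoricalRRProfile

__all__ = [
    "PIFEstimate",
    "AttributionResult",
    "pif_subtype",
    "pif_site",
    "attributable_cost",
]


@dataclass(frozen=True)
class PIFEstimate:
    """A PIF with its Monte Carlo percentile interval (n_draws=0 ⇒ deterministic)."""

    cancer: str
    sex: str
    scenario: str
    point: float
    ci_low: float
    ci_high: float
    n_draws: int = 0

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError("interval must bracket the point estimate")
        if self.point > 1 or self.ci_high > 1:
            raise ValueError("a PIF cannot exceed 1")


@dataclass(frozen=True)
class AttributionResult:
    """PIF applied to a cost: attributable cost with interval."""

    cancer: str
    sex: str
    scenario: str
    pif: PIFEstimate
    cost: float
    attributable: float
    attributable_low: float
    attributable_high: float


def _as_array(x, name: str) -> np.ndarray:
    a = np.asarray(
        x.values if isinstance(x, (PrevalenceTable, CategoricalRRProfile)) else x, dtype=float
    )
    if a.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return a


def pif_subtype(
    baseline,
    counterfactual,
    rr,
    counterfactual_rr=None,
) -> float:
    """Potential impact fraction for one cancer subtype and stratum.

    Parameters accept either the domain objects (:class:`PrevalenceTable`,
    :class:`CategoricalRRProfile`) or plain arrays aligned on the same
    category schema.  ``counterfactual_rr`` supports mean-shift scenarios
    where the counterfactual population sits at lowered category medians,
    so the second sum uses RRs evaluated at those medians.
    """
    p = _as_array(baseline, "baseline")
    pc = _as_array(counterfactual, "counterfactual")
    r = _as_array(rr, "rr")
    rc = r if counterfactual_rr is None else _as_array(counterfactual_rr, "counterfactual_rr")
    if not (p.shape == pc.shape == r.shape == rc.shape):
        raise ValueError("baseline, counterfactual and RR vectors must share one schema")
    denom = float(p @ r)
    if denom == 0.0:
        raise ZeroDivisionError("Σ P_i RR_i is zero")
    return (denom - float(pc @ rc)) / denom


def pif_site(attributable_cost_of_subtype: float, total_site_cost: float) -> float:
    """Site-level PIF: attributable subtype cost over total topographic-site cost."""
    if total_site_cost <= 0:
        raise ZeroDivisionError("total site cost must be positive")
    if attributable_cost_of_subtype < 0:
        raise ValueError("attributable cost cannot be negative")
    if attributable_cost_of_subtype > total_site_cost:
        raise ValueError("attributable cost cannot exceed the total site cost")
    return attributable_cost_of_subtype / total_site_cost


def attributable_cost(pif: PIFEstimate, cost: float) -> AttributionResult:
    """Multiply a PIF (point and interval bounds) by a fixed cost.

    The cost is held fixed across the interval: uncertainty in the
    attributable cost reflects PIF uncertainty only, matching a reporting
    convention in which cost-projection uncertainty is shown separately.
    """
    if cost < 0:
        raise ValueError("cost must be non-negative")
    return AttributionResult(
        cancer=pif.cancer,
        sex=pif.sex,
        scenario=pif.scenario,
        pif=pif,
        cost=cost,
        attributable=pif.point * cost,
        attributable_low=pif.ci_low * cost,
        attributable_high=pif.ci_high * cost,
    )
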