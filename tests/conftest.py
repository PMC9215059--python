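import numpy as np
import pytest

from ebwcost import (
    PrevalenceTable,
    RelativeRiskEstimate,
    ScenarioSpec,
    default_schema,
)


@pytest.fixture
def schema():
    return default_schema()


@pytest.fixture
def endometrium_rr():
    """Endometrial-cancer dose-response RR per 5 kg/m² with its 95% CI."""
    return RelativeRiskEstimate("endometrium", "F", 5.0, 1.50, 1.42, 1.59)


@pytest.fixture
def baseline_table(schema):
    """A survey-like baseline: ~60% of the population above the reference."""
    return PrevalenceTable(
        sex="F",
        categories=schema.labels,
        proportions=(0.397, 0.344, 0.189, 0.070),
        effective_n=5000,
        year=2019,
    )


@pytest.fixture
def paf_scenario(schema):
    """Theoretical minimum risk: everyone in the reference category."""
    one_hot = np.zeros(len(schema))
    one_hot[schema.reference_index] = 1.0
    target = PrevalenceTable(sex="F", categories=schema.labels, proportions=tuple(one_hot))
    return ScenarioSpec(kind="target_distribution", label="theoretical_minimum", target=target)
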