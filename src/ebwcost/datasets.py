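"""Packaged reference tables.

Two small tables from the published Brazilian analysis ship with the
package so the arithmetic of the method can be exercised on real printed
inputs without any download:

* ``load_rr_table()`` — sex-specific dose-response relative risks of
  cancer incidence per 5 kg/m² of BMI (WCRF/AICR meta-analyses), with 95%
  CIs, for the twelve cancer types with strong evidence of an association
  with excess body weight.
* ``load_attribution_2030()`` — published site-level point estimates for
  Brazil in 2030: impact fraction (%), projected direct healthcare cost
  and attributable cost (million international US$), by sex.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .relative_risk import RelativeRiskEstimate, read_rr_table

__all__ = ["load_rr_table", "load_attribution_2030"]


def _data_path(name: str):
    return resources.files("ebwcost.data").joinpath(name)


def load_rr_table() -> list[RelativeRiskEstimate]:
    """Dose-response RRs per 5 kg/m² of BMI by cancer subtype and sex."""
    with resources.as_file(_data_path("rr_dose_response.csv")) as path:
        return read_rr_table(path)


def load_attribution_2030() -> pd.DataFrame:
    """Published 2030 site-level PIFs and costs (sex: F, M, T = both)."""
    with resources.as_file(_data_path("attribution_2030.csv")) as path:
        return pd.read_csv(path)
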