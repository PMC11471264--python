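"""Bundled reference data from the Canadian colorectal-cancer validation study.

Two small tables ship with the package, transcribed from the published
validation of neighbourhood against household income quintiles in a cohort
of 21,560 Canadian colorectal-cancer patients (counts disclosure-rounded to
the nearest 5 by the data custodian):

* the observed-by-true quintile cross-tabulation stratified by 5-year
  mortality (12,435 survivors / 9,120 decedents as printed), and
* the covariate-adjusted predictive values with 95% CIs, usable directly as
  bias parameters in application mode.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .bias_parameters import PredictiveValueMatrix, read_pv_csv
from .cohort import CrossTab

__all__ = ["load_validation_crosstab", "load_published_predictive_values"]


def _data_path(name: str):
    return resources.files("income_qba.data").joinpath(name)


def load_validation_crosstab() -> CrossTab:
    """Observed-by-true quintile counts by 5-year mortality (as printed)."""
    with resources.as_file(_data_path("canada_crc_crosstab.csv")) as path:
        return CrossTab.from_csv(path)


def load_published_predictive_values() -> dict[int, PredictiveValueMatrix]:
    """Published covariate-adjusted predictive values with 95% CIs.

    Point estimates are renormalized row-wise (printed percentages carry
    rounding); interval bounds are kept as printed.
    """
    with resources.as_file(_data_path("canada_crc_predictive_values.csv")) as path:
        return read_pv_csv(path, renormalize=True, source="published-adjusted")
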