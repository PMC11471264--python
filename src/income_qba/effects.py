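"""Relative risks for 5-year mortality by income quintile.

The working effect model is the modified Poisson: a log-link Poisson fit to
the binary death indicator with quintile indicators (reference = quintile 5,
the highest income) and optional covariates, with the HC0 sandwich variance
giving valid relative-risk inference for a binary outcome.  For the
unadjusted model with a categorical exposure the maximum-likelihood fit
reproduces the stratum risks exactly, so the relative risk and its robust
standard error have closed forms; :func:`crude_rr` implements them and
serves as the independent oracle for :func:`fit_rr_model`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import QUINTILES, validate_cohort

__all__ = ["EffectEstimate", "fit_rr_model", "crude_rr"]

_Z95 = 1.959963984540054


class EffectModelError(ValueError):
    pass


@dataclass(frozen=True)
class EffectEstimate:
    """Relative risk for one quintile contrast (k vs 5) with 95% Wald CI."""

    contrast: str
    rr: float
    ci_lo: float
    ci_hi: float
    se_log_rr: float
    model: str = "unadjusted"
    exposure_source: str = "observed"

    def __post_init__(self) -> None:
        if not self.rr > 0:
            raise EffectModelError(f"relative risk must be positive, got {self.rr}")
        if not (self.ci_lo <= self.rr <= self.ci_hi):
            raise EffectModelError("CI must bracket the point estimate")


def crude_rr(deaths_1: int, n_1: int, deaths_0: int, n_0: int,
             contrast: str = "1 vs 0") -> EffectEstimate:
    """Closed-form crude risk ratio with the large-sample log-RR variance.

    rr = (d1/n1)/(d0/n0);  se(log rr) = sqrt((1-p1)/(n1 p1) + (1-p0)/(n0 p0)).
    No continuity correction: zero deaths in either group is an error.
    """
    if min(n_1, n_0) <= 0:
        raise EffectModelError("group sizes must be positive")
    if min(deaths_1, deaths_0) <= 0:
        raise EffectModelError(
            f"zero deaths in a group (d1={deaths_1}, d0={deaths_0}); "
            "risk ratio undefined without a continuity correction"
        )
    p1, p0 = deaths_1 / n_1, deaths_0 / n_0
    rr = p1 / p0
    se = np.sqrt((1 - p1) / (n_1 * p1) + (1 - p0) / (n_0 * p0))
    return EffectEstimate(
        contrast=contrast, rr=rr,
        ci_lo=rr * np.exp(-_Z95 * se), ci_hi=rr * np.exp(_Z95 * se),
        se_log_rr=float(se),
    )


def fit_rr_model(records: pd.DataFrame, exposure_field: str = "observed_q",
                 adjust: bool = False,
                 exposure_source: str | None = None) -> list[EffectEstimate]:
    """Modified Poisson relative risks for quintiles 1..4 vs 5.

    Fits a log-link Poisson model to ``died_5y`` with indicators for
    ``exposure_field`` quintiles 1..4 (reference quintile 5) and, when
    ``adjust``, centred age, sex and rural residence; variance by the HC0
    sandwich, Wald 95% CIs on the log scale.
    """
    validate_cohort(records, require_covariates=adjust)
    if exposure_field not in records.columns:
        raise EffectModelError(f"exposure column {exposure_field!r} absent")
    exp_vals = records[exposure_field]
    if exp_vals.isna().any():
        raise EffectModelError(f"exposure column {exposure_field!r} has missing values")
    empty = [k for k in QUINTILES if not (exp_vals == k).any()]
    if empty:
        raise EffectModelError(f"empty exposure categories: {empty}")

    n = len(records)
    cols = [np.ones(n)]
    names = ["const"]
    exp_arr = exp_vals.to_numpy()
    for k in (1, 2, 3, 4):
        cols.append((exp_arr == k).astype(float))
        names.append(f"q{k}")
    if adjust:
        cols.append(records["age"].to_numpy(dtype=float)
                    - float(records["age"].mean()))
        names.append("age_c")
        cols.append(records["sex"].to_numpy(dtype=float))
        names.append("sex")
        cols.append(records["rural"].to_numpy(dtype=float))
        names.append("rural")
    exog = np.column_stack(cols)
    endog = records["died_5y"].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(endog, exog, family=sm.families.Poisson()).fit(cov_type="HC0")
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    source = exposure_source or (
        "household" if exposure_field == "true_q"
        else "neighbourhood" if exposure_field == "observed_q" else exposure_field
    )
    out = []
    for i, k in enumerate((1, 2, 3, 4), start=1):
        log_rr, se = params[i], bse[i]
        out.append(EffectEstimate(
            contrast=f"Q{k} vs Q5",
            rr=float(np.exp(log_rr)),
            ci_lo=float(np.exp(log_rr - _Z95 * se)),
            ci_hi=float(np.exp(log_rr + _Z95 * se)),
            se_log_rr=float(se),
            model="adjusted" if adjust else "unadjusted",
            exposure_source=source,
        ))
    return out


def contrast_counts(records: pd.DataFrame, exposure_field: str,
                    k: int, reference: int = 5) -> tuple[int, int, int, int]:
    """(deaths_k, n_k, deaths_ref, n_ref) for a quintile contrast."""
    exp_arr = records[exposure_field].to_numpy()
    died = records["died_5y"].to_numpy()
    in_k = exp_arr == k
    in_ref = exp_arr == reference
    return (int(died[in_k].sum()), int(in_k.sum()),
            int(died[in_ref].sum()), int(in_ref.sum()))
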