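"""Bias parameters: outcome-stratified predictive values for a 5-level exposure.

The bias parameters of the misclassification model are the predictive values
Pr(true quintile = k | observed quintile = j, outcome stratum): the five
diagonal cells of each 5x5 matrix are positive predictive values (PPVs) and
the twenty off-diagonal cells negative predictive values (NPVs).  Because the
misclassification may be differential, the matrices are estimated separately
within survivors and decedents.

Two estimators are provided:

* crude — row proportions of the observed-by-true cross-tabulation with
  Wilson score intervals per cell;
* covariate-adjusted — multinomial logistic regression of the true quintile
  on observed-quintile indicators plus age, sex and rural residence, with the
  predicted probabilities evaluated while holding covariates at their
  (stratum-specific) means.  Interval bounds come from the delta method on
  the softmax transform by default, or from a parametric bootstrap of the
  coefficient vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

from .cohort import QUINTILES, CrossTab, validate_cohort

__all__ = [
    "PredictiveValueMatrix",
    "MultinomialFit",
    "CovariateProfile",
    "crude_predictive_values",
    "fit_multinomial",
    "adjusted_predictive_values",
    "stratum_covariate_means",
    "read_pv_csv",
    "write_pv_csv",
]


class BiasParameterError(ValueError):
    pass


@dataclass(frozen=True)
class CovariateProfile:
    """Covariate values at which adjusted predictive values are evaluated.

    Binary covariates may be fractional (e.g. sex = sample proportion male),
    matching the convention of holding covariates at their mean.
    """

    age: float
    sex: float
    rural: float

    def as_dict(self) -> dict[str, float]:
        return {"age": self.age, "sex": self.sex, "rural": self.rural}


@dataclass(frozen=True)
class PredictiveValueMatrix:
    """Row-stochastic 5x5 Pr(true=k | observed=j) with 95% interval bounds.

    ``p[j-1, k-1]`` is the predictive value for observed quintile ``j`` and
    true quintile ``k``; ``lo``/``hi`` are elementwise 95% bounds.
    """

    stratum: int
    p: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    source: str = "crude"
    covariate_profile: CovariateProfile | None = None

    def __post_init__(self) -> None:
        for name in ("p", "lo", "hi"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (5, 5):
                raise BiasParameterError(f"{name} must be 5x5, got {arr.shape}")
            object.__setattr__(self, name, arr)
        if not np.allclose(self.p.sum(axis=1), 1.0, atol=1e-9):
            raise BiasParameterError(
                f"rows of p must sum to 1 (got {self.p.sum(axis=1)})"
            )
        eps = 1e-9
        if ((self.lo > self.p + eps) | (self.p > self.hi + eps)
                | (self.lo < -eps) | (self.hi > 1 + eps)).any():
            raise BiasParameterError("need 0 <= lo <= p <= hi <= 1 elementwise")

    def row(self, observed_q: int) -> np.ndarray:
        return self.p[observed_q - 1]

    def to_frame(self) -> pd.DataFrame:
        j, k = np.meshgrid(QUINTILES, QUINTILES, indexing="ij")
        return pd.DataFrame({
            "stratum": self.stratum,
            "observed_q": j.ravel(),
            "true_q": k.ravel(),
            "estimate": self.p.ravel(),
            "lo": self.lo.ravel(),
            "hi": self.hi.ravel(),
        })


def write_pv_csv(matrices: dict[int, PredictiveValueMatrix], path: str | Path) -> None:
    """Serialize per-stratum matrices as a 50-row CSV (25 cells per stratum)."""
    pd.concat([m.to_frame() for _, m in sorted(matrices.items())]).to_csv(path, index=False)


def read_pv_csv(path: str | Path, renormalize: bool = True,
                source: str = "external") -> dict[int, PredictiveValueMatrix]:
    """Read per-stratum predictive-value matrices from CSV.

    Published tables print values to a few decimals, so rows may miss 1 by
    print rounding; ``renormalize`` rescales each row of the point estimates
    (interval bounds are left as printed).
    """
    df = pd.read_csv(path)
    out: dict[int, PredictiveValueMatrix] = {}
    for y, grp in df.groupby("stratum"):
        p = np.zeros((5, 5))
        lo = np.zeros((5, 5))
        hi = np.zeros((5, 5))
        for _, row in grp.iterrows():
            j, k = int(row["observed_q"]) - 1, int(row["true_q"]) - 1
            p[j, k] = row["estimate"]
            lo[j, k] = row["lo"]
            hi[j, k] = row["hi"]
        if renormalize:
            p = p / p.sum(axis=1, keepdims=True)
            lo = np.minimum(lo, p)
            hi = np.maximum(hi, p)
        out[int(y)] = PredictiveValueMatrix(int(y), p, lo, hi, source=source)
    return out


def crude_predictive_values(tab: CrossTab, stratum: int) -> PredictiveValueMatrix:
    """Crude predictive values: row proportions with Wilson score intervals."""
    counts = tab.stratum(stratum).astype(float)
    row_tot = counts.sum(axis=1)
    if (row_tot == 0).any():
        empty = [int(j) + 1 for j in np.flatnonzero(row_tot == 0)]
        raise BiasParameterError(
            f"observed quintile rows {empty} have zero total in stratum {stratum}"
        )
    p = counts / row_tot[:, None]
    lo, hi = proportion_confint(counts, row_tot[:, None], alpha=0.05, method="wilson")
    return PredictiveValueMatrix(stratum, p, np.asarray(lo), np.asarray(hi),
                                 source="crude")


# ---------------------------------------------------------------------------
# covariate-adjusted estimation via multinomial logit


# response coding: true quintile 5 is the reference category (code 0);
# quintiles 1..4 get codes 1..4.  Predicted probabilities are invariant to
# this choice; it affects only how coefficients are reported.
_TRUE_TO_CODE = {5: 0, 1: 1, 2: 2, 3: 3, 4: 4}
_CODE_TO_TRUE = {v: k for k, v in _TRUE_TO_CODE.items()}


@dataclass(frozen=True)
class MultinomialFit:
    """Fitted multinomial logit of true quintile on observed quintile (+ covariates).

    ``coefficients`` has one column per non-reference true-quintile code
    (1..4, i.e. true quintiles 1..4; reference true quintile 5) and one row
    per design column in ``exog_names``.  ``covariance`` is the covariance of
    the coefficient vector flattened column-major (equation by equation), the
    layout statsmodels uses.
    """

    stratum: int
    coefficients: np.ndarray
    covariance: np.ndarray
    exog_names: tuple[str, ...]
    age_center: float
    n_used: int
    with_covariates: bool
    reference_category: int = 5
    penalty: float = 0.0

    def design_row(self, observed_q: int, profile: CovariateProfile | None) -> np.ndarray:
        x = np.zeros(len(self.exog_names))
        cols = {name: i for i, name in enumerate(self.exog_names)}
        x[cols["const"]] = 1.0
        if observed_q != 5:
            x[cols[f"obs_{observed_q}"]] = 1.0
        if self.with_covariates:
            if profile is None:
                raise BiasParameterError("covariate profile required for this fit")
            x[cols["age_c"]] = profile.age - self.age_center
            x[cols["sex"]] = profile.sex
            x[cols["rural"]] = profile.rural
        return x

    def predict_row(self, observed_q: int,
                    profile: CovariateProfile | None = None) -> np.ndarray:
        """Predicted Pr(true=k | observed_q, profile) ordered by true quintile 1..5."""
        x = self.design_row(observed_q, profile)
        eta = np.concatenate([[0.0], x @ self.coefficients])  # code order 0..4
        eta -= eta.max()
        probs_code = np.exp(eta) / np.exp(eta).sum()
        return np.array([probs_code[_TRUE_TO_CODE[k]] for k in QUINTILES])


def _design(records: pd.DataFrame, age_center: float,
            with_covariates: bool) -> tuple[np.ndarray, tuple[str, ...]]:
    n = len(records)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["const"]
    for j in (1, 2, 3, 4):  # observed quintile 5 is the predictor reference
        cols.append((records["observed_q"].to_numpy() == j).astype(float))
        names.append(f"obs_{j}")
    if with_covariates:
        cols.append(records["age"].to_numpy(dtype=float) - age_center)
        names.append("age_c")
        cols.append(records["sex"].to_numpy(dtype=float))
        names.append("sex")
        cols.append(records["rural"].to_numpy(dtype=float))
        names.append("rural")
    return np.column_stack(cols), tuple(names)


def stratum_covariate_means(records: pd.DataFrame, stratum: int) -> CovariateProfile:
    """Covariate means within one outcome stratum (binary covariates as proportions)."""
    sub = records[records["died_5y"] == stratum]
    return CovariateProfile(
        age=float(sub["age"].mean()),
        sex=float(sub["sex"].mean()),
        rural=float(sub["rural"].mean()),
    )


def fit_multinomial(records: pd.DataFrame, stratum: int, *,
                    with_covariates: bool = True,
                    penalty: float = 0.0,
                    maxiter: int = 500) -> MultinomialFit:
    """Fit the outcome-stratified multinomial logit of true on observed quintile.

    The response is the true quintile (reference = quintile 5); predictors
    are indicators for observed quintiles 1..4 (reference = quintile 5) plus,
    when ``with_covariates``, centred age, sex and rural residence.  A small
    L2 ``penalty`` (per-parameter, on the log-likelihood scale) is available
    for separation in sparse strata; it is off by default.
    """
    validate_cohort(records, require_true=True,
                    require_covariates=with_covariates)
    sub = records[records["died_5y"] == stratum]
    if sub.empty:
        raise BiasParameterError(f"no records in stratum {stratum}")
    missing = [k for k in QUINTILES if not (sub["true_q"] == k).any()]
    if missing:
        raise BiasParameterError(
            f"true quintile categories {missing} unobserved in stratum {stratum}"
        )
    age_center = float(sub["age"].mean()) if with_covariates else 0.0
    exog, names = _design(sub, age_center, with_covariates)
    endog = sub["true_q"].map(_TRUE_TO_CODE).to_numpy(dtype=int)

    model = sm.MNLogit(endog, exog)
    if penalty > 0:
        params, cov = _fit_ridge(model, penalty, maxiter)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="newton", maxiter=maxiter, disp=False)
        params = np.asarray(res.params)
        if not res.mle_retvals.get("converged", True) \
                or not np.isfinite(params).all():
            raise BiasParameterError(
                "multinomial fit did not converge (possible separation); "
                "retry with penalty > 0 for a ridge-stabilized fit"
            )
        cov = np.asarray(res.cov_params())
    return MultinomialFit(
        stratum=stratum,
        coefficients=params,
        covariance=cov,
        exog_names=names,
        age_center=age_center,
        n_used=len(sub),
        with_covariates=with_covariates,
        penalty=penalty,
    )


def _fit_ridge(model: sm.MNLogit, penalty: float,
               maxiter: int) -> tuple[np.ndarray, np.ndarray]:
    """Newton solve of the L2-penalized multinomial likelihood.

    Maximizes loglike(theta) - penalty/2 * ||theta||^2; the covariance is the
    inverse of the penalized observed information.
    """
    k = model.exog.shape[1] * (model.J - 1)
    theta = np.zeros(k)
    for _ in range(maxiter):
        g = model.score(theta) - penalty * theta
        h = model.hessian(theta) - penalty * np.eye(k)
        step = np.linalg.solve(h, g)
        theta = theta - step
        if np.abs(step).max() < 1e-10:
            break
    else:
        raise BiasParameterError("penalized multinomial fit did not converge")
    cov = np.linalg.inv(-(model.hessian(theta) - penalty * np.eye(k)))
    params = theta.reshape(model.exog.shape[1], model.J - 1, order="F")
    return params, cov


def _softmax_and_grad(fit: MultinomialFit, observed_q: int,
                      profile: CovariateProfile | None) -> tuple[np.ndarray, np.ndarray]:
    """Predicted code-ordered probabilities and their gradient w.r.t. the
    flattened (column-major) coefficient vector."""
    x = fit.design_row(observed_q, profile)
    eta = np.concatenate([[0.0], x @ fit.coefficients])
    eta -= eta.max()
    p = np.exp(eta) / np.exp(eta).sum()  # length 5, code order
    n_exog, n_eq = fit.coefficients.shape
    grad = np.zeros((5, n_exog * n_eq))
    for c in range(5):
        for m in range(n_eq):  # equation m corresponds to code m+1
            dp = p[c] * ((1.0 if c == m + 1 else 0.0) - p[m + 1])
            grad[c, m * n_exog:(m + 1) * n_exog] = dp * x
    return p, grad


def adjusted_predictive_values(fit: MultinomialFit,
                               profile: CovariateProfile | None = None,
                               *, ci_method: str = "delta",
                               n_boot: int = 2000,
                               rng: np.random.Generator | None = None,
                               covariate_range: tuple[float, float] | None = None,
                               ) -> PredictiveValueMatrix:
    """Predicted predictive-value matrix at a covariate profile, with 95% CIs.

    For each observed quintile ``j`` the softmax of the fitted linear
    predictors at (observed = j, profile) gives row ``j``.  ``ci_method`` is
    ``"delta"`` (default; delta method on the softmax using the coefficient
    covariance) or ``"bootstrap"`` (parametric bootstrap: ``n_boot`` draws of
    the coefficient vector from its asymptotic normal).
    """
    if fit.with_covariates and profile is None:
        raise BiasParameterError("covariate-adjusted fit requires a profile")
    if covariate_range is not None and profile is not None:
        lo_a, hi_a = covariate_range
        if not (lo_a <= profile.age <= hi_a):
            warnings.warn(
                f"profile age {profile.age} outside fitted range [{lo_a}, {hi_a}]",
                stacklevel=2,
            )
    p = np.zeros((5, 5))
    lo = np.zeros((5, 5))
    hi = np.zeros((5, 5))
    z = 1.959963984540054
    if ci_method == "bootstrap":
        rng = rng if rng is not None else np.random.default_rng()
        flat = fit.coefficients.ravel(order="F")
        draws = rng.multivariate_normal(flat, fit.covariance, size=n_boot,
                                        method="cholesky")
    for j in QUINTILES:
        probs_code, grad = _softmax_and_grad(fit, j, profile)
        row = np.array([probs_code[_TRUE_TO_CODE[k]] for k in QUINTILES])
        p[j - 1] = row
        if ci_method == "delta":
            var = np.einsum("ck,kl,cl->c", grad, fit.covariance, grad)
            se_code = np.sqrt(np.maximum(var, 0.0))
            se = np.array([se_code[_TRUE_TO_CODE[k]] for k in QUINTILES])
            lo[j - 1] = np.clip(row - z * se, 0.0, 1.0)
            hi[j - 1] = np.clip(row + z * se, 0.0, 1.0)
        elif ci_method == "bootstrap":
            x = fit.design_row(j, profile)
            n_exog, n_eq = fit.coefficients.shape
            etas = np.zeros((n_boot, 5))
            for m in range(n_eq):
                etas[:, m + 1] = draws[:, m * n_exog:(m + 1) * n_exog] @ x
            etas -= etas.max(axis=1, keepdims=True)
            pc = np.exp(etas) / np.exp(etas).sum(axis=1, keepdims=True)
            qs = np.percentile(pc, [2.5, 97.5], axis=0)
            lo_code, hi_code = qs[0], qs[1]
            lo[j - 1] = np.minimum(
                [lo_code[_TRUE_TO_CODE[k]] for k in QUINTILES], row)
            hi[j - 1] = np.maximum(
                [hi_code[_TRUE_TO_CODE[k]] for k in QUINTILES], row)
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
    return PredictiveValueMatrix(fit.stratum, p, lo, hi, source="adjusted",
                                 covariate_profile=profile)
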