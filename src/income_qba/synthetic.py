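"""Synthetic cohorts with known misclassification and a known mortality gradient.

Real validation data pairing household (true) and neighbourhood (observed)
income quintiles are confidential, so every downstream stage is exercised on
generated cohorts instead.  The generator specifies the *forward*
misclassification direction Pr(observed = j | true = k) — predictive values
Pr(true | observed, outcome) depend on the exposure marginal and the outcome
model, so they cannot be primitives of a generative model — and the implied
predictive values are recovered analytically by Bayes' rule, giving an exact
oracle for parameter-recovery tests.

Defaults emulate the Canadian colorectal-cancer validation cohort: n =
21,560; uniform quintile marginals; age ~ 66 (SD 12.5) truncated to
[35, 100]; 55.3% male; 23.7% rural; ~42% five-year mortality; diagonal
observed-given-true agreement around 0.31 decaying geometrically with
|j - k|; and a household-income mortality gradient with RR(Q1 vs Q5) = 1.46.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .bias_parameters import PredictiveValueMatrix
from .cohort import QUINTILES, STRATA

__all__ = [
    "MisclassMechanism",
    "OutcomeModel",
    "CohortConfig",
    "default_config",
    "generate_cohort",
    "implied_predictive_values",
    "decay_matrix",
]

AGE_BOUNDS = (35.0, 100.0)


class SyntheticConfigError(ValueError):
    pass


def decay_matrix(diag_target: float = 0.31) -> np.ndarray:
    """Row-stochastic Pr(observed=j | true=k) proportional to r^|j-k|.

    ``r`` is chosen so the middle row's diagonal mass equals ``diag_target``;
    edge rows end up somewhat more concentrated, mirroring the greater
    agreement observed in the extreme quintiles of validation tables.
    """
    if not (0.2 < diag_target < 1.0):
        raise SyntheticConfigError("diagonal target must be in (0.2, 1)")
    # middle row mass: 1 + 2r + 2r^2; diagonal = 1 / that
    r = optimize.brentq(lambda r: 1.0 / (1 + 2 * r + 2 * r * r) - diag_target,
                        1e-9, 1.0 - 1e-9)
    k_idx = np.arange(5)
    mat = r ** np.abs(k_idx[:, None] - k_idx[None, :])
    return mat / mat.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class MisclassMechanism:
    """Forward misclassification model Pr(observed = j | true = k).

    ``base_matrix`` rows are indexed by the true quintile.  Optional
    ``covariate_shift`` entries (keys ``"sex"``/``"rural"``, or ``"age"``
    applied per year above the cohort mean) add a log-odds increment to the
    off-diagonal cells of a record's row, which is then renormalized — e.g.
    a positive rural shift makes rural residents more often misclassified.
    """

    base_matrix: np.ndarray
    covariate_shift: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        mat = np.asarray(self.base_matrix, dtype=float)
        if mat.shape != (5, 5):
            raise SyntheticConfigError("base_matrix must be 5x5")
        if (mat < 0).any() or (mat > 1).any():
            raise SyntheticConfigError("base_matrix entries must be in [0,1]")
        if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-12):
            raise SyntheticConfigError("base_matrix rows must sum to 1")
        object.__setattr__(self, "base_matrix", mat)
        unknown = set(self.covariate_shift) - {"age", "sex", "rural"}
        if unknown:
            raise SyntheticConfigError(f"unknown covariate_shift keys {unknown}")

    @property
    def is_covariate_free(self) -> bool:
        return not any(v != 0 for v in self.covariate_shift.values())

    def realized_rows(self, true_q: np.ndarray, age_c: np.ndarray,
                      sex: np.ndarray, rural: np.ndarray) -> np.ndarray:
        """Per-record misclassification row, shape (n, 5); rows sum to 1."""
        rows = self.base_matrix[true_q - 1].copy()
        if not self.is_covariate_free:
            shift = (self.covariate_shift.get("age", 0.0) * age_c
                     + self.covariate_shift.get("sex", 0.0) * sex
                     + self.covariate_shift.get("rural", 0.0) * rural)
            off_diag = np.ones((len(true_q), 5), dtype=bool)
            off_diag[np.arange(len(true_q)), true_q - 1] = False
            logit = np.log(np.clip(rows, 1e-300, None))
            logit[off_diag] += np.repeat(shift, 4)
            rows = np.exp(logit - logit.max(axis=1, keepdims=True))
            rows /= rows.sum(axis=1, keepdims=True)
        return rows


@dataclass(frozen=True)
class OutcomeModel:
    """Log-linear risk model for 5-year mortality.

    ``risk = baseline_risk * exp(log_rr[true_q] + age_coef*(age - age_center)
    + sex_coef*sex + rural_coef*rural)`` where ``log_rr`` is indexed by
    quintile with quintile 5 (highest income) as the reference (log RR 0).
    """

    baseline_risk: float
    log_rr: tuple[float, float, float, float, float]
    age_coef: float = 0.0
    sex_coef: float = 0.0
    rural_coef: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.baseline_risk < 1):
            raise SyntheticConfigError("baseline_risk must be in (0,1)")
        if len(self.log_rr) != 5 or self.log_rr[4] != 0.0:
            raise SyntheticConfigError(
                "log_rr must have 5 entries with quintile-5 reference (last = 0)"
            )

    def risk(self, true_q: np.ndarray, age_c: np.ndarray, sex: np.ndarray,
             rural: np.ndarray) -> np.ndarray:
        lr = np.asarray(self.log_rr)[np.asarray(true_q) - 1]
        return self.baseline_risk * np.exp(
            lr + self.age_coef * age_c + self.sex_coef * sex
            + self.rural_coef * rural
        )


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to draw one synthetic cohort reproducibly."""

    n: int
    quintile_probs: tuple[float, ...]
    age_mean: float
    age_sd: float
    p_male: float
    p_rural: float
    mechanism: MisclassMechanism
    outcome: OutcomeModel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SyntheticConfigError("n must be >= 1")
        probs = tuple(float(p) for p in self.quintile_probs)
        if len(probs) != 5 or not np.isclose(sum(probs), 1.0):
            raise SyntheticConfigError("quintile_probs must be 5 values summing to 1")
        object.__setattr__(self, "quintile_probs", probs)

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


# quintile relative risks implied by the validation cohort's household-income
# mortality gradient (RR vs the highest quintile)
_DEFAULT_QUINTILE_RR = (1.46, 1.374, 1.188, 1.118, 1.0)
_DEFAULT_MORTALITY = 0.423


def _truncnorm(age_mean: float, age_sd: float) -> stats.rv_continuous:
    a, b = (AGE_BOUNDS[0] - age_mean) / age_sd, (AGE_BOUNDS[1] - age_mean) / age_sd
    return stats.truncnorm(a, b, loc=age_mean, scale=age_sd)


def _mean_covariate_multiplier(cfg_like: "CohortConfig") -> float:
    """E[exp(age_coef*(age - mean) + sex_coef*sex + rural_coef*rural)]."""
    om = cfg_like.outcome
    dist = _truncnorm(cfg_like.age_mean, cfg_like.age_sd)
    if om.age_coef == 0.0:
        e_age = 1.0
    else:
        e_age, _ = integrate.quad(
            lambda a: np.exp(om.age_coef * (a - cfg_like.age_mean)) * dist.pdf(a),
            *AGE_BOUNDS)
    e_sex = 1 - cfg_like.p_male + cfg_like.p_male * np.exp(om.sex_coef)
    e_rural = 1 - cfg_like.p_rural + cfg_like.p_rural * np.exp(om.rural_coef)
    return float(e_age * e_sex * e_rural)


def default_config(n: int = 21_560, seed: int = 0,
                   overall_mortality: float = _DEFAULT_MORTALITY,
                   quintile_rr: tuple[float, ...] = _DEFAULT_QUINTILE_RR,
                   ) -> CohortConfig:
    """Study-condition defaults mirroring the validation cohort.

    The baseline risk (mortality in the highest quintile at reference
    covariates) is solved so the analytic overall mortality equals
    ``overall_mortality`` under the configured marginals.
    """
    mechanism = MisclassMechanism(base_matrix=decay_matrix(0.31))
    log_rr = tuple(float(np.log(r)) for r in quintile_rr)
    outcome = OutcomeModel(baseline_risk=0.5, log_rr=log_rr,
                           age_coef=0.015, sex_coef=0.10, rural_coef=0.05)
    cfg = CohortConfig(
        n=n, quintile_probs=(0.2,) * 5, age_mean=66.0, age_sd=12.5,
        p_male=0.553, p_rural=0.237, mechanism=mechanism, outcome=outcome,
        seed=seed,
    )
    mult = _mean_covariate_multiplier(cfg)
    mean_rr = float(np.mean([np.exp(l) for l in log_rr]))
    baseline = overall_mortality / (mean_rr * mult)
    if not (0 < baseline < 1):
        raise SyntheticConfigError("requested overall mortality unattainable")
    return replace(cfg, outcome=replace(outcome, baseline_risk=baseline))


def generate_cohort(cfg: CohortConfig) -> pd.DataFrame:
    """Draw one cohort; identical config (including seed) gives identical output."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    true_q = rng.choice(np.arange(1, 6), size=n, p=cfg.quintile_probs)
    age = _truncnorm(cfg.age_mean, cfg.age_sd).rvs(size=n, random_state=rng)
    sex = (rng.random(n) < cfg.p_male).astype(np.int64)
    rural = (rng.random(n) < cfg.p_rural).astype(np.int64)
    age_c = age - cfg.age_mean

    rows = cfg.mechanism.realized_rows(true_q, age_c, sex, rural)
    cum = np.cumsum(rows, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(n)
    observed_q = (u[:, None] < cum).argmax(axis=1) + 1

    risk = cfg.outcome.risk(true_q, age_c, sex, rural)
    bad = np.flatnonzero((risk <= 0) | (risk >= 1))
    if bad.size:
        i = bad[0]
        raise SyntheticConfigError(
            f"implied risk {risk[i]:.3f} outside (0,1) for true_q={true_q[i]}, "
            f"age={age[i]:.1f}, sex={sex[i]}, rural={rural[i]}"
        )
    died = (rng.random(n) < risk).astype(np.int64)

    return pd.DataFrame({
        "id": np.arange(n),
        "observed_q": observed_q.astype(np.int64),
        "true_q": true_q.astype(np.int64),
        "died_5y": died,
        "age": age,
        "sex": sex,
        "rural": rural,
        "region": None,
    })


def implied_predictive_values(cfg: CohortConfig,
                              interval_halfwidth: float = 0.0,
                              ) -> dict[int, PredictiveValueMatrix]:
    """Analytic Pr(true = k | observed = j, outcome) under the generator.

    Requires a covariate-free mechanism, so covariates integrate out of the
    outcome model exactly (the per-stratum probability of a (true, observed)
    pair factorizes through the mean covariate risk multiplier).  Bayes'
    rule then gives, with m = Pr(observed=j | true=k), q_k the quintile
    marginal and d_k = Pr(died | true=k) marginal over covariates::

        Pr(true=k | observed=j, died)     ∝ q_k · m[k, j] · d_k
        Pr(true=k | observed=j, survived) ∝ q_k · m[k, j] · (1 - d_k)

    ``interval_halfwidth`` > 0 attaches symmetric bounds (clipped to (0,1))
    so the matrices can feed the beta-sampling QBA machinery directly; with
    the default 0 the matrices carry zero-width (point) intervals.
    """
    if not cfg.mechanism.is_covariate_free:
        raise SyntheticConfigError(
            "analytic predictive values require a covariate-free mechanism; "
            "marginalize numerically via a large generated cohort instead"
        )
    mult = _mean_covariate_multiplier(cfg)
    q = np.asarray(cfg.quintile_probs)
    d = cfg.outcome.baseline_risk * np.exp(np.asarray(cfg.outcome.log_rr)) * mult
    if (d >= 1).any():
        raise SyntheticConfigError("marginal death probability >= 1")
    m = cfg.mechanism.base_matrix  # m[k-1, j-1] = Pr(obs=j | true=k)
    out: dict[int, PredictiveValueMatrix] = {}
    for y in STRATA:
        w = d if y == 1 else 1 - d
        joint = q[:, None] * m * w[:, None]  # (true, observed)
        obs_marg = joint.sum(axis=0)
        if (obs_marg == 0).any():
            raise SyntheticConfigError(
                f"observed quintiles {np.flatnonzero(obs_marg == 0) + 1} have "
                f"zero probability in stratum {y}; predictive row undefined"
            )
        p = (joint / obs_marg[None, :]).T  # (observed, true)
        if interval_halfwidth > 0:
            lo = np.clip(p - interval_halfwidth, 1e-6, 1.0)
            hi = np.clip(p + interval_halfwidth, 0.0, 1.0 - 1e-6)
            lo = np.minimum(lo, p)
            hi = np.maximum(hi, p)
        else:
            lo, hi = p.copy(), p.copy()
        out[y] = PredictiveValueMatrix(y, p, lo, hi, source="implied")
    return out
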