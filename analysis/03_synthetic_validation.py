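#!/usr/bin/env python
"""Full-method validation on a synthetic cohort with known truth.

Generates a cohort at the default study conditions (n = 21,560, uniform
quintiles, diagonal observed-given-true agreement ~0.31-0.38, true
RR(Q1 vs Q5) = 1.46), runs the complete pipeline in validation mode —
covariate-adjusted multinomial predictive values, probabilistic QBA,
three-way effect comparison — and checks that the bias-adjusted estimate
recovers the configured gradient that the naive estimate attenuates.

Writes results/tables/synthetic_validation_comparison.csv.
"""

from pathlib import Path

import numpy as np

from income_qba import (
    PipelineConfig,
    default_config,
    fit_rr_model,
    generate_cohort,
    run_pipeline,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "tables"
OUT.mkdir(parents=True, exist_ok=True)

N_ITER = 1000
SEED = 7


def main() -> None:
    cfg = default_config(seed=SEED)
    coh = generate_cohort(cfg)
    print(f"generated n = {len(coh)}: mortality {coh['died_5y'].mean():.3f}, "
          f"{coh['sex'].mean():.1%} male, {coh['rural'].mean():.1%} rural, "
          f"diagonal agreement {(coh['observed_q'] == coh['true_q']).mean():.1%}")
    true_rr = fit_rr_model(coh, "true_q")[0].rr
    naive_rr = fit_rr_model(coh, "observed_q")[0].rr
    print(f"true-exposure RR(Q1 vs Q5) {true_rr:.3f} (configured 1.46); "
          f"naive observed-exposure RR {naive_rr:.3f} (attenuated)")

    report = run_pipeline(coh, PipelineConfig(n_iter=N_ITER, seed=SEED))
    report.comparison.to_csv(OUT / "synthetic_validation_comparison.csv",
                             index=False, float_format="%.4f")

    c = report.qba_result.contrasts[1]
    print(f"\nbias-adjusted RR(Q1 vs Q5): {c.median_rr:.3f} "
          f"[{c.si_lo:.3f}, {c.si_hi:.3f}] ({N_ITER} iterations)")
    gap_naive = abs(np.log(naive_rr) - np.log(true_rr))
    gap_adj = abs(np.log(c.median_rr) - np.log(true_rr))
    print(f"log-scale distance to truth: naive {gap_naive:.3f} -> "
          f"bias-adjusted {gap_adj:.3f}")
    verdict = "recovers" if gap_adj < gap_naive else "does NOT recover"
    print(f"the bias adjustment {verdict} the true income-mortality gradient")


if __name__ == "__main__":
    main()
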