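#!/usr/bin/env python
"""Probabilistic QBA of the published cohort counts (application mode).

Runs the full bias analysis on records expanded from the printed counts,
using the published covariate-adjusted predictive values (with their 95%
CIs) as beta-distributed bias parameters: 2,000 iterations of
sample-reassign-estimate with random error, unadjusted modified-Poisson
contrasts against the highest income quintile.

Writes results/tables/qba_published_summary.csv and the three-way
comparison results/tables/qba_published_comparison.csv.
"""

from pathlib import Path

from income_qba import (
    PipelineConfig,
    expand_crosstab,
    load_published_predictive_values,
    load_validation_crosstab,
    render_tables,
    run_pipeline,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "tables"
OUT.mkdir(parents=True, exist_ok=True)

N_ITER = 2000
SEED = 20240913


def main() -> None:
    records = expand_crosstab(load_validation_crosstab())
    pvms = load_published_predictive_values()
    report = run_pipeline(records,
                          PipelineConfig(n_iter=N_ITER, seed=SEED),
                          pv_external=pvms)
    report.qba_result.summary().to_csv(OUT / "qba_published_summary.csv",
                                       index=False, float_format="%.4f")
    report.comparison.to_csv(OUT / "qba_published_comparison.csv",
                             index=False, float_format="%.4f")
    render_tables(report, OUT, prefix="qba_published")

    print(f"{N_ITER} iterations, {report.qba_result.n_failed} failed\n")
    print("bias-adjusted relative risks, median [95% simulation interval]:")
    for _, c in sorted(report.qba_result.contrasts.items()):
        print(f"  {c.contrast}: {c.median_rr:.3f} [{c.si_lo:.3f}, {c.si_hi:.3f}]")
    cmp_df = report.comparison
    q1 = cmp_df[(cmp_df["contrast"] == "Q1 vs Q5")
                & (cmp_df["model"] == "unadjusted")]
    print("\nthree-way comparison for the lowest-vs-highest contrast:")
    for _, r in q1.iterrows():
        print(f"  {r['exposure']:>14}: {r['rr']:.3f} [{r['lo']:.3f}, {r['hi']:.3f}]")
    print("\nthe bias-adjusted estimate moves the naive neighbourhood RR "
          "back to the household-income gradient, at the cost of a wider "
          "interval that carries the bias-parameter uncertainty")


if __name__ == "__main__":
    main()
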