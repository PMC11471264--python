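#!/usr/bin/env python
"""Reproduce the validation study's descriptive quantities from printed counts.

From the bundled observed-by-true quintile cross-tabulation (stratified by
5-year mortality) this script recomputes the crude predictive values with
Wilson intervals, compares their diagonals against the published
covariate-adjusted values, and recomputes the naive (neighbourhood) and
gold-standard (household) relative risks of 5-year mortality.

Writes results/tables/crude_predictive_values.csv and
results/tables/published_effects.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from income_qba import (
    crude_predictive_values,
    expand_crosstab,
    fit_rr_model,
    load_published_predictive_values,
    load_validation_crosstab,
    write_pv_csv,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "tables"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    tab = load_validation_crosstab()
    print(f"cohort cells: {tab.stratum(0).sum()} survived, "
          f"{tab.stratum(1).sum()} died within 5 years")

    crude = {y: crude_predictive_values(tab, y) for y in (0, 1)}
    write_pv_csv(crude, OUT / "crude_predictive_values.csv")

    published = load_published_predictive_values()
    print("\nPPV diagonals, crude vs published covariate-adjusted (%):")
    for y, label in ((0, "survived"), (1, "died")):
        cd = np.diag(crude[y].p) * 100
        ad = np.diag(published[y].p) * 100
        for k in range(5):
            print(f"  {label:>8} Q{k + 1}: crude {cd[k]:5.2f}  "
                  f"adjusted {ad[k]:5.2f}  (diff {cd[k] - ad[k]:+.2f} pp)")
    all_ppv = np.concatenate([np.diag(crude[y].p) for y in (0, 1)])
    print(f"\ncrude PPV range: {all_ppv.min() * 100:.1f}% to "
          f"{all_ppv.max() * 100:.1f}% — agreement between neighbourhood and "
          "household quintiles is poor")

    records = expand_crosstab(tab)
    rows = []
    for field, label in (("observed_q", "neighbourhood"), ("true_q", "household")):
        for est in fit_rr_model(records, field):
            rows.append({"exposure": label, "contrast": est.contrast,
                         "rr": est.rr, "lo": est.ci_lo, "hi": est.ci_hi})
    effects = pd.DataFrame(rows)
    effects.to_csv(OUT / "published_effects.csv", index=False,
                   float_format="%.4f")
    q1 = effects[effects["contrast"] == "Q1 vs Q5"]
    print("\nunadjusted RR(Q1 vs Q5), lowest vs highest income:")
    for _, r in q1.iterrows():
        print(f"  {r['exposure']:>13}: {r['rr']:.3f} "
              f"[{r['lo']:.3f}, {r['hi']:.3f}]")
    print("\nthe neighbourhood proxy attenuates the income-mortality "
          "gradient by roughly two-thirds on the log scale")


if __name__ == "__main__":
    main()
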