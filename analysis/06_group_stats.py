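#!/usr/bin/env python
"""Group statistics over the ROI means from 02/03.

Fits the linear mixed-effects model (group fixed effect, ROI random
intercept), the ROI intra-class correlation, and per-ROI OLS with 0.05
alpha, for the NOE_MTR table (and the pool-fit table if present).
"""

from pathlib import Path

import pandas as pd

from noemri.stats import run_stats

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    mtr_path = OUT / "noe_mtr_table.csv"
    if not mtr_path.exists():
        raise SystemExit("run analysis/02_noe_mtr.py first (missing noe_mtr_table.csv)")
    table = pd.read_csv(mtr_path)
    fit_path = OUT / "pool_fit_table.csv"
    if fit_path.exists():
        table = pd.concat([table, pd.read_csv(fit_path)], ignore_index=True)

    for metric in sorted(table["metric"].unique()):
        sub = table[table["metric"] == metric]
        if sub["roi"].nunique() < 2:
            print(f"=== {metric} === (single ROI; LMM/ICC not applicable)")
            continue
        rep = run_stats(table, metric)
        print(rep.to_text())
        rep.to_json(OUT / f"stats_{metric}.json")
        print()
    print(f"wrote stats_*.json under {OUT}")


if __name__ == "__main__":
    main()
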