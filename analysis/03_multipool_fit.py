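#!/usr/bin/env python
"""Five-pool Lorentzian fitting of the hippocampus in both cohorts.

Spectra are SVD-denoised (Casorati median criterion), B0-corrected and
fitted voxelwise; the hippocampal relayed-NOE, amide and amine pool
amplitudes are compared with the phantom ground truth.
"""

import warnings
from pathlib import Path

import pandas as pd

from noemri.phantom import GROUND_TRUTH
from noemri.workflows import cohort_contrast_tables

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tables = [cohort_contrast_tables("WT", seed=1, fit_roi="hippocampus"),
                  cohort_contrast_tables("AD", seed=2, fit_roi="hippocampus")]
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(OUT / "pool_fit_table.csv", index=False)

    print("hippocampal fitted pool amplitudes (%), recovered vs ground truth:")
    for metric in ("noe", "amide", "amine"):
        sub = table[(table["metric"] == metric) & (table["roi"] == "hippocampus")]
        means = sub.groupby("group")["value"].mean()
        print(f"  {metric:<6s} WT {means['WT']:5.2f} "
              f"(truth {GROUND_TRUTH['WT']['hippocampus'][metric]:4.1f})   "
              f"AD {means['AD']:5.2f} "
              f"(truth {GROUND_TRUTH['AD']['hippocampus'][metric]:4.1f})")
    print(f"wrote {OUT / 'pool_fit_table.csv'}")


if __name__ == "__main__":
    main()
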