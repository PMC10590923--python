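"""Group statistics over ROI means.

The analysis unit is the subject x ROI mean of a contrast.  Three analyses
mirror a standard small-cohort neuroimaging battery:

* a linear mixed-effects model with disease group as the fixed effect and a
  random intercept per ROI (REML), giving one global group effect;
* the intra-class correlation ICC = between-ROI variance / total variance
  from the fitted variance components;
* per-ROI ordinary least squares of the mean on the group indicator, which
  for a two-level factor is exactly the equal-variance two-sample t-test.

Alpha is 0.05 throughout; per-ROI p-values are reported uncorrected (an
optional Holm flag is available but off by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .contrasts import ContrastMap
from .phantom import LabelImage

ALPHA = 0.05


def roi_means(contrast: ContrastMap, labels: LabelImage, subject: str, group: str,
              metric: Optional[str] = None) -> pd.DataFrame:
    """Long-format rows of per-ROI mean contrast (non-NaN pixels only)."""
    metric = metric or contrast.name
    rows = []
    for label, name in labels.roi_names.items():
        vals = contrast.values[labels.pixels(label)]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings.warn(f"ROI {name!r} is fully NaN for subject {subject}; row dropped",
                          stacklevel=2)
            continue
        rows.append({"subject": subject, "group": group, "roi": name, "metric": metric,
                     "value": float(vals.mean()), "n_pixels": int(vals.size)})
    return pd.DataFrame(rows)


def _check_table(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    sub = table[table["metric"] == metric].copy()
    if sub["group"].nunique() < 2:
        raise ValueError("need at least 2 groups")
    if sub["roi"].nunique() < 2:
        raise ValueError("need at least 2 ROIs")
    return sub


def fit_lmm(table: pd.DataFrame, metric: str, reference_group: str = "WT") -> Dict[str, float]:
    """Mixed model: value ~ group, random intercept per ROI (REML).

    Returns the group-effect estimate (non-reference minus reference), its
    standard error and Wald p-value, plus the fitted variance components.
    A singular (boundary) random-effect variance is reported, not raised.
    """
    sub = _check_table(table, metric)
    sub["group"] = pd.Categorical(sub["group"],
                                  categories=[reference_group] +
                                  sorted(set(sub["group"]) - {reference_group}))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value ~ group", sub, groups=sub["roi"])
        try:
            fit = model.fit(reml=True)
        except np.linalg.LinAlgError:
            # boundary fit (random-effect variance ~ 0) can make the default
            # optimizer's profiled solve singular; retry constrained variants
            try:
                fit = model.fit(reml=True, method="lbfgs")
            except np.linalg.LinAlgError:
                ols = smf.ols("value ~ group", sub).fit()
                term = [t for t in ols.params.index if t.startswith("group")][0]
                return {"effect": float(ols.params[term]), "se": float(ols.bse[term]),
                        "p": float(ols.pvalues[term]), "roi_variance": 0.0,
                        "residual_variance": float(ols.mse_resid), "boundary_fit": True}
    term = [t for t in fit.params.index if t.startswith("group")][0]
    re_var = float(np.asarray(fit.cov_re)[0, 0])
    return {
        "effect": float(fit.params[term]),
        "se": float(fit.bse[term]),
        "p": float(fit.pvalues[term]),
        "roi_variance": re_var,
        "residual_variance": float(fit.scale),
        "boundary_fit": bool(re_var < 1e-10),
    }


def compute_icc(table: pd.DataFrame, metric: str) -> float:
    """ICC = between-ROI variance / (between-ROI + residual) from the LMM."""
    res = fit_lmm(table, metric)
    total = res["roi_variance"] + res["residual_variance"]
    if total <= 0:
        return float("nan")
    return res["roi_variance"] / total


def per_roi_ols(table: pd.DataFrame, metric: str, alpha: float = ALPHA,
                reference_group: str = "WT", holm: bool = False) -> pd.DataFrame:
    """Per-ROI OLS of the mean on the group indicator (two-sample t-test).

    Returns effect (non-reference minus reference), two-sided p, and a
    significance flag at ``alpha`` (optionally Holm-adjusted).  ROIs with a
    single subject in either group are skipped with a warning.
    """
    sub = _check_table(table, metric)
    rows = []
    for roi, grp in sub.groupby("roi", sort=False):
        counts = grp.groupby("group")["value"].count()
        if (counts < 2).any() or counts.size < 2:
            warnings.warn(f"ROI {roi!r}: fewer than 2 subjects in a group; skipped", stacklevel=2)
            continue
        x = (grp["group"] != reference_group).astype(float)
        X = sm.add_constant(x.to_numpy())
        fit = sm.OLS(grp["value"].to_numpy(), X).fit()
        rows.append({"roi": roi, "effect": float(fit.params[1]), "se": float(fit.bse[1]),
                     "t": float(fit.tvalues[1]), "p": float(fit.pvalues[1])})
    out = pd.DataFrame(rows, columns=["roi", "effect", "se", "t", "p"])
    if holm and len(out):
        from statsmodels.stats.multitest import multipletests
        out["significant"] = multipletests(out["p"], alpha=alpha, method="holm")[0]
    else:
        out["significant"] = out["p"] < alpha
    out["marker"] = np.where(out["p"] < 0.01, "**", np.where(out["p"] < alpha, "*", ""))
    return out


@dataclass
class StatsReport:
    """The full battery for one metric, serializable to JSON and text."""

    metric: str
    lmm: Dict[str, float]
    icc: float
    per_roi: pd.DataFrame
    alpha: float = ALPHA

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"metric": self.metric, "alpha": self.alpha, "lmm": self.lmm,
                       "icc": self.icc, "per_roi": self.per_roi.to_dict(orient="records")},
                      fh, indent=2)

    def to_text(self) -> str:
        lines = [f"=== {self.metric} ===",
                 f"LMM group effect: {self.lmm['effect']:+.3f} "
                 f"(SE {self.lmm['se']:.3f}, p = {self.lmm['p']:.4g})",
                 f"ICC (ROI): {self.icc:.3f}", "per-ROI OLS:"]
        for _, r in self.per_roi.iterrows():
            lines.append(f"  {r['roi']:<20s} {r['effect']:+.3f}  p = {r['p']:.4g} {r['marker']}")
        return "\n".join(lines)


def run_stats(table: pd.DataFrame, metric: str, alpha: float = ALPHA) -> StatsReport:
    return StatsReport(metric=metric, lmm=fit_lmm(table, metric),
                       icc=compute_icc(table, metric),
                       per_roi=per_roi_ols(table, metric, alpha=alpha), alpha=alpha)
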