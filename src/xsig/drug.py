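"""Signature score vs drug sensitivity across a cell-line panel.

Dose-response input is a tidy table with columns ``cell_line, compound,
ln_ic50, kras_status, braf_status`` (one row per cell line x compound).
IC50 values are handled exclusively on the natural-log scale; lower ln IC50
means greater sensitivity.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import ScoreVector

log = logging.getLogger(__name__)


def load_dose_response(df: pd.DataFrame, ic50_col: str = "ln_ic50") -> pd.DataFrame:
    """Validate (and if needed log-transform) a dose-response table."""
    required = {"cell_line", "compound", ic50_col}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dose-response table lacks columns: {sorted(missing)}")
    out = df.copy()
    if ic50_col == "ic50":
        if (out[ic50_col] <= 0).any():
            raise ValueError("raw IC50 values must be positive for log transform")
        out["ln_ic50"] = np.log(out[ic50_col])
        log.info("load_dose_response: raw IC50 transformed to natural log")
    if not np.isfinite(out["ln_ic50"]).all():
        raise ValueError("non-finite ln_ic50 values")
    return out


def correlate_score_ic50(s: ScoreVector, dose: pd.DataFrame,
                         compound: str) -> dict:
    """Least-squares fit of ln IC50 on signature score for one compound.

    Returns overall Pearson r, R^2 (= r^2), slope, intercept and two-sided
    slope p-value, plus the same statistics within each KRAS-mutation
    stratum with at least 3 lines.
    """
    sub = dose[dose["compound"] == compound].set_index("cell_line")
    shared = s.scores.index.intersection(sub.index)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} cell lines with both score and ln_ic50 "
            f"for {compound!r}; need >= 3")
    x = s.scores.loc[shared].values
    y = sub.loc[shared, "ln_ic50"].values
    fit = stats.linregress(x, y)
    res = {"compound": compound, "n": len(shared), "r": fit.rvalue,
           "r2": fit.rvalue**2, "slope": fit.slope,
           "intercept": fit.intercept, "p": fit.pvalue, "strata": {}}
    if "kras_status" in sub.columns:
        for status, grp in sub.loc[shared].groupby("kras_status"):
            if len(grp) < 3:
                continue
            sf = stats.linregress(s.scores.loc[grp.index].values,
                                  grp["ln_ic50"].values)
            res["strata"][str(status)] = {
                "n": len(grp), "r": sf.rvalue, "r2": sf.rvalue**2,
                "slope": sf.slope, "p": sf.pvalue}
    return res


def rank_lines_by_score(s: ScoreVector, k_high: int,
                        k_low: int) -> tuple[list[str], list[str]]:
    """Deterministic extreme cell lines by score (ties broken by id).

    Returns (high-score ids, low-score ids); an error is raised if the
    requested extremes would overlap.
    """
    n = len(s.scores)
    if k_high + k_low > n:
        raise ValueError(f"k_high + k_low = {k_high + k_low} exceeds n = {n}")
    df = pd.DataFrame({"score": s.scores}).sort_index()
    desc = df.sort_values("score", ascending=False, kind="mergesort")
    asc = df.sort_values("score", ascending=True, kind="mergesort")
    high = list(desc.index[:k_high])
    low = list(asc.index[:k_low])
    if set(high) & set(low):
        raise ValueError("tied scores force the high and low sets to overlap")
    return high, low
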