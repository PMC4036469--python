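"""Single-sample signature scoring, normalization and classification.

The signature score of a sample is the mean expression of the signature's
up-regulated genes minus the mean expression of its down-regulated genes,
computed on a per-gene median-centered / IQR-scaled matrix. Cohort scores
are themselves median-centered and IQR-scaled before thresholding; the
classifier rule is normalized score > 0 (strict), or > the median score of
a designated subpopulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import iqr


@dataclass
class ScoreVector:
    """Per-sample signature scores with provenance."""

    scores: pd.Series
    allele: str
    normalized: bool = False
    coverage: dict[str, float] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)


def score_samples(m: pd.DataFrame, sig, min_coverage: float = 0.5) -> ScoreVector:
    """Difference-of-means signature score for every sample of a cohort.

    Signature genes missing from the matrix are silently excluded as long
    as each arm retains at least ``min_coverage`` of its genes; otherwise
    an error reporting both coverages is raised.

    ``m`` should already be per-gene median-centered and IQR-scaled
    (see :func:`xsig.preprocess.median_center_iqr_normalize`); the score is
    a plain difference of arm means and inherits whatever scale ``m`` is on.
    """
    up = [g for g in sig.up_genes if g in m.index]
    down = [g for g in sig.down_genes if g in m.index]
    cov_up = len(up) / len(sig.up_genes) if sig.up_genes else 0.0
    cov_down = len(down) / len(sig.down_genes) if sig.down_genes else 0.0
    if cov_up < min_coverage or cov_down < min_coverage:
        raise ValueError(
            f"signature coverage below {min_coverage:.2f}: "
            f"up {len(up)}/{len(sig.up_genes)} ({cov_up:.2f}), "
            f"down {len(down)}/{len(sig.down_genes)} ({cov_down:.2f})")
    s = m.loc[up].mean(axis=0) - m.loc[down].mean(axis=0)
    s.name = f"{sig.allele}_score"
    return ScoreVector(scores=s, allele=sig.allele, normalized=False,
                       coverage={"up": cov_up, "down": cov_down})


def normalize_scores(s: ScoreVector) -> ScoreVector:
    """Median-center and IQR-scale a score vector across the cohort."""
    if len(s.scores) < 2:
        raise ValueError("score normalization requires at least 2 samples")
    spread = iqr(s.scores.values)
    if spread == 0:
        raise ValueError("degenerate score vector: IQR is zero")
    out = (s.scores - np.median(s.scores.values)) / spread
    return replace(s, scores=out, normalized=True)


def classify(s: ScoreVector, mode: str = "zero_threshold",
             subpop=None) -> pd.Series:
    """Allele-like / non-allele-like call per sample.

    ``zero_threshold``: allele-like iff normalized score > 0 (a score of
    exactly 0 is non-allele-like). ``subpop_median``: allele-like iff score
    strictly exceeds the median score of the designated subpopulation
    (``subpop``: iterable of sample ids).
    """
    if mode == "zero_threshold":
        if not s.normalized:
            raise ValueError("zero_threshold classification requires "
                             "normalized scores")
        threshold = 0.0
    elif mode == "subpop_median":
        if subpop is None:
            raise ValueError("subpop_median mode requires a designated "
                             "subpopulation of sample ids")
        sub = s.scores.loc[list(subpop)]
        if sub.empty:
            raise ValueError("designated subpopulation is empty")
        threshold = float(np.median(sub.values))
    else:
        raise ValueError(f"unknown classification mode {mode!r}")
    call = s.scores > threshold
    call.name = f"{s.allele}_like"
    return call


def compare_scores(s1: ScoreVector, s2: ScoreVector) -> dict[str, float]:
    """Pearson r, R^2 and least-squares line between two score vectors.

    Computed over the intersection of sample ids (>= 3 required); the fit
    regresses ``s2`` on ``s1``.
    """
    shared = s1.scores.index.intersection(s2.scores.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need >= 3")
    x = s1.scores.loc[shared].values
    y = s2.scores.loc[shared].values
    fit = stats.linregress(x, y)
    return {"r": fit.rvalue, "r2": fit.rvalue**2, "slope": fit.slope,
            "intercept": fit.intercept, "p": fit.pvalue, "n": len(shared)}


def score_by_group(s: ScoreVector, labels: pd.Series,
                   test_groups: tuple[str, str] | None = None) -> dict:
    """Per-group score summaries plus a two-sided rank-sum test.

    ``labels`` maps sample id -> group. The Wilcoxon rank-sum (Mann-Whitney)
    test compares ``test_groups`` if given, else the two groups present
    (error if the label set is not exactly two and no pair is designated).
    """
    labels = labels.loc[labels.index.intersection(s.scores.index)]
    groups = labels.groupby(labels).groups
    if any(len(ix) == 0 for ix in groups.values()) or not groups:
        raise ValueError("empty group in labels")
    rows = []
    for g, ix in groups.items():
        v = s.scores.loc[ix].values
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append({"group": g, "n": len(v), "mean": v.mean(),
                     "median": med, "q1": q1, "q3": q3})
    summary = pd.DataFrame(rows).set_index("group")

    if test_groups is None:
        if len(groups) != 2:
            raise ValueError("designate test_groups when more than two "
                             "groups are present")
        test_groups = tuple(groups)
    for g in test_groups:
        if g not in groups:
            raise ValueError(f"group {g!r} absent from labels")
    a = s.scores.loc[groups[test_groups[0]]].values
    b = s.scores.loc[groups[test_groups[1]]].values
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"summary": summary, "test_groups": test_groups,
            "statistic": float(stat), "p": float(p)}
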