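"""Paired one-tailed t-test comparison of two segmentation methods.

Scores from two methods are paired per individual image — the
(subject_id, energy) key, the finest unit the per-image metrics tables
support — separately for each class (ulna, radius) and each metric
(Dice, Jaccard). For differences d_i = a_i - b_i the statistic is

    t = mean(d) / (sd(d) / sqrt(n)),  df = n - 1,

with the one-tailed p-value P(T_df > t) under H1 "method A scores
higher". Significance is declared at p < 0.05; no multiple-testing
correction is applied. The direction must be stated explicitly by the
caller — a one-tailed test silently run the wrong way round is the
classic misuse.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


class DegenerateDifferencesError(ValueError):
    """All paired differences are identically zero; t is undefined."""


def paired_one_tailed_t(scores_a, scores_b):
    """One-tailed paired t-test of H1: mean(a - b) > 0.

    Returns (t statistic, degrees of freedom, p-value). Raises on
    length mismatch, n < 2, or identically-zero differences.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"paired score vectors must match: {a.shape} vs {b.shape}")
    n = len(a)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    if np.all(d == 0):
        raise DegenerateDifferencesError("all paired differences are zero; t statistic undefined")
    res = stats.ttest_rel(a, b, alternative="greater")
    return float(res.statistic), n - 1, float(res.pvalue)


def compare_methods(metrics_a: pd.DataFrame, metrics_b: pd.DataFrame,
                    direction: str = "a_gt_b") -> pd.DataFrame:
    """Cell-wise method comparison over 2 classes x 2 metrics.

    Both tables are long-form per-image metrics (columns subject_id,
    energy, class, dice, jaccard) and must share the same
    (subject_id, energy, class) keys. Returns one row per
    (metric, class) with t, df, p and the p < 0.05 significance flag.
    A degenerate cell (identical scores) is reported with NaN statistics
    and degenerate=True rather than aborting the other cells.
    """
    if direction != "a_gt_b":
        raise ValueError("direction must be 'a_gt_b'; swap the inputs to test the other way")
    key = ["subject_id", "energy", "class"]
    a = metrics_a.set_index(key).sort_index()
    b = metrics_b.set_index(key).sort_index()
    if not a.index.equals(b.index):
        only_a = a.index.difference(b.index).tolist()
        only_b = b.index.difference(a.index).tolist()
        raise ValueError(f"metric tables are not aligned; only in A: {only_a[:5]}, only in B: {only_b[:5]}")
    rows = []
    for metric in ("dice", "jaccard"):
        for cls in sorted(a.index.get_level_values("class").unique()):
            sa = a.xs(cls, level="class")[metric].to_numpy()
            sb = b.xs(cls, level="class")[metric].to_numpy()
            try:
                t, df, p = paired_one_tailed_t(sa, sb)
                rows.append({"metric": metric, "class": cls, "n": len(sa), "t": t,
                             "df": df, "p": p, "significant": p < ALPHA, "degenerate": False})
            except DegenerateDifferencesError:
                rows.append({"metric": metric, "class": cls, "n": len(sa), "t": np.nan,
                             "df": len(sa) - 1, "p": np.nan, "significant": False,
                             "degenerate": True})
    return pd.DataFrame(rows)
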