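"""Descriptive comparisons: prevalence and t tests on construct scores."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .qc import PairedScores


def prevalence(
    scores: pd.DataFrame, construct: str, cutoff: float
) -> float:
    """Fraction of respondents scoring at or above a screening cutoff.

    Cutoffs for caseness (e.g. PHQ-9 >= 10 for at least moderate
    depressive symptoms) vary by study and must be supplied explicitly.
    """
    col = scores[construct]
    if len(col) == 0:
        raise ValueError("empty score table")
    return float((col >= cutoff).mean())


def _t_frame(rows: dict[str, dict]) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "construct"
    return df


def compare_waves(paired: PairedScores) -> pd.DataFrame:
    """Paired t tests of T2 vs T1 per construct (two-sided, df = n-1).

    A zero-variance difference column cannot support a t statistic; it
    is reported with ``degenerate=True`` (t set to 0 when the mean
    difference is also 0, NaN otherwise).
    """
    if paired.n_matched < 2:
        raise ValueError("need at least 2 matched respondents")
    rows: dict[str, dict] = {}
    for construct in paired.t1.columns:
        d = (
            paired.t2[construct].to_numpy(float)
            - paired.t1[construct].to_numpy(float)
        )
        n = len(d)
        if np.std(d, ddof=1) == 0:
            t = 0.0 if d.mean() == 0 else float("nan")
            rows[construct] = {
                "t": t, "p": float("nan"), "df": n - 1,
                "mean_diff": float(d.mean()), "degenerate": True,
            }
            continue
        res = stats.ttest_rel(
            paired.t2[construct], paired.t1[construct]
        )
        rows[construct] = {
            "t": float(res.statistic), "p": float(res.pvalue),
            "df": n - 1, "mean_diff": float(d.mean()),
            "degenerate": False,
        }
    return _t_frame(rows)


def compare_samples(
    group_a: pd.DataFrame, group_b: pd.DataFrame
) -> pd.DataFrame:
    """Welch independent-samples t tests per construct (two-sided)."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 respondents")
    rows: dict[str, dict] = {}
    for construct in group_a.columns:
        a = group_a[construct].to_numpy(float)
        b = group_b[construct].to_numpy(float)
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            rows[construct] = {
                "t": 0.0 if a.mean() == b.mean() else float("nan"),
                "p": float("nan"), "df": float("nan"),
                "mean_diff": float(a.mean() - b.mean()),
                "degenerate": True,
            }
            continue
        res = stats.ttest_ind(a, b, equal_var=False)
        rows[construct] = {
            "t": float(res.statistic), "p": float(res.pvalue),
            "df": float(res.df), "mean_diff": float(a.mean() - b.mean()),
            "degenerate": False,
        }
    return _t_frame(rows)
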