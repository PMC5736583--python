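"""Two-tier summary statistics for chirality quantities.

Tier 1 (per trial): each experimental trial (one cell, one culture)
yields a large sample of voxel-, pixel- or step-wise values; the trial is
summarized as mean ± s.d. and tested against a zero median with the
two-sided Wilcoxon signed-rank test.

Tier 2 (across trials): the trial means are treated as the sample; the
summary is mean ± s.e.m. of the means and a two-sided one-sample t-test
against zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["trial_summary", "across_trial_test", "histogram_export",
           "summary_table"]


def trial_summary(values, label: str = "") -> dict:
    """Per-trial row: n, mean, s.d. (n−1), two-sided Wilcoxon p vs 0.

    Zero differences are dropped (Wilcoxon's original policy; scipy
    ``zero_method='wilcox'``); the normal approximation is used for
    n > 25.  All-zero samples have an undefined statistic and are
    reported with p = 1 and a flag.
    """
    x = np.asarray(values, float)
    if len(x) < 5:
        raise ValueError("need n >= 5 for the signed-rank test")
    row = {"label": label, "n": int(len(x)), "mean": float(x.mean()),
           "sd": float(x.std(ddof=1)), "degenerate": False}
    nonzero = x[x != 0]
    if len(nonzero) == 0:
        row.update({"wilcoxon_p": 1.0, "degenerate": True})
        return row
    method = "approx" if len(nonzero) > 25 else "auto"
    stat, p = sps.wilcoxon(x, zero_method="wilcox", alternative="two-sided",
                           method=method)
    row.update({"wilcoxon_stat": float(stat), "wilcoxon_p": float(p)})
    return row


def across_trial_test(trial_means, label: str = "") -> dict:
    """Across-trial row: one-sample two-sided t-test of trial means vs 0."""
    m = np.asarray(trial_means, float)
    if len(m) < 3:
        raise ValueError("need >= 3 trials")
    sd = m.std(ddof=1)
    sem = sd / np.sqrt(len(m))
    row = {"label": label, "n_trials": int(len(m)),
           "mean_of_means": float(m.mean()), "sem": float(sem),
           "zero_variance": False}
    if sd == 0:
        row.update({"t": float("inf") if m.mean() != 0 else 0.0,
                    "p": 0.0 if m.mean() != 0 else 1.0,
                    "zero_variance": True})
        return row
    t, p = sps.ttest_1samp(m, 0.0)
    row.update({"t": float(t), "p": float(p)})
    return row


def histogram_export(values, bins=32, range=None) -> pd.DataFrame:
    """Figure-ready histogram: counts (summing to n) and bin edges."""
    x = np.asarray(values, float)
    if len(x) == 0:
        raise ValueError("empty input")
    if np.isscalar(bins) and bins < 2:
        raise ValueError("bins must be >= 2")
    counts, edges = np.histogram(x, bins=bins, range=range)
    return pd.DataFrame({"left": edges[:-1], "right": edges[1:],
                         "count": counts})


def summary_table(trials: dict[str, np.ndarray], label: str = "",
                  units: str = "") -> pd.DataFrame:
    """Full two-tier table for one quantity over several trials."""
    rows = [trial_summary(v, label=k) for k, v in trials.items()]
    df = pd.DataFrame(rows)
    across = across_trial_test([r["mean"] for r in rows], label=label)
    df.attrs["across"] = across
    df.attrs["units"] = units
    return df
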