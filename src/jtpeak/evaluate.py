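"""Method-comparison statistics for paired interval measurements.

Two measurement methods (e.g. this delineator vs. a reference annotation, or
vs. generator ground truth) are compared on *single-deltas* -- the change of
an interval from the subject's pre-dose baseline at each time point -- using
Bland-Altman agreement, intra-time-point replicate variability and the
fraction of time points within fixed thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError


@dataclass(frozen=True)
class BlandAltman:
    """Mean/SD of paired differences with mean +/- 2 SD agreement limits."""

    mean_diff: float
    sd_diff: float
    lower_limit: float
    upper_limit: float
    n: int


def bland_altman(a, b):
    """Bland-Altman comparison of two equal-length paired series.

    The sign convention is ``a - b``; limits are the mean difference plus and
    minus twice the (n-1) standard deviation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigError("paired series must be equal-length 1-d arrays")
    if len(a) < 2:
        raise ConfigError("at least 2 pairs are required")
    diff = a - b
    mean = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return BlandAltman(mean, sd, mean - 2.0 * sd, mean + 2.0 * sd, len(a))


def single_deltas(df, value_col="value", baseline_col="baseline"):
    """Post - baseline change per subject and time point.

    ``df`` needs columns ``subject``, ``timepoint``, ``value_col`` and a
    boolean ``baseline_col`` marking the pre-dose rows; replicate values are
    averaged within each (subject, timepoint) before differencing.
    """
    mean = (
        df.groupby(["subject", "timepoint", baseline_col])[value_col]
        .mean()
        .reset_index()
    )
    base = mean[mean[baseline_col]].set_index("subject")[value_col]
    post = mean[~mean[baseline_col]]
    out = post.copy()
    out["delta"] = post[value_col] - post["subject"].map(base).to_numpy()
    return out[["subject", "timepoint", "delta"]]


@dataclass(frozen=True)
class IntraTimepointComparison:
    """Paired comparison of per-subject mean replicate SDs of two methods."""

    mean_sd_a: float
    mean_sd_b: float
    mean_difference: float
    p_value: float
    n_subjects: int


def intra_timepoint_sd(df, value_col="value"):
    """Replicate SD per (subject, timepoint), averaged per subject.

    Time points with a single replicate are dropped with a warning. Returns a
    Series indexed by subject.
    """
    counts = df.groupby(["subject", "timepoint"])[value_col].transform("count")
    if (counts < 2).any():
        warnings.warn("dropping time points with fewer than 2 replicates")
        df = df[counts >= 2]
    if df.empty:
        raise ConfigError("no time point has 2 or more replicates")
    sds = df.groupby(["subject", "timepoint"])[value_col].std(ddof=1)
    return sds.groupby("subject").mean()


def compare_intra_timepoint_sd(df_a, df_b, value_col="value"):
    """Paired t-test of per-subject mean intra-time-point SDs, two methods."""
    sd_a = intra_timepoint_sd(df_a, value_col)
    sd_b = intra_timepoint_sd(df_b, value_col)
    common = sd_a.index.intersection(sd_b.index)
    if len(common) < 2:
        raise ConfigError("need at least 2 common subjects for a paired test")
    a, b = sd_a[common].to_numpy(), sd_b[common].to_numpy()
    t = stats.ttest_rel(a, b)
    return IntraTimepointComparison(
        mean_sd_a=float(np.mean(a)),
        mean_sd_b=float(np.mean(b)),
        mean_difference=float(np.mean(a - b)),
        p_value=float(t.pvalue),
        n_subjects=len(common),
    )


def coverage_within(diffs, thresholds):
    """Fraction of |differences| strictly below each threshold."""
    diffs = np.abs(np.asarray(diffs, dtype=float))
    if diffs.size == 0:
        raise ConfigError("difference series must be nonempty")
    return tuple(float(np.mean(diffs < thr)) for thr in thresholds)
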