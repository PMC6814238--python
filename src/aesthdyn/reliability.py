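"""Test-retest reliability of continuous traces and overall-rating vectors.

Two complementary measures:

* Pearson r between the test and retest trace of the same (observer, clip) —
  sensitive to the global shape of the response;
* a scaled Euclidean-distance score, 1 - ||x - y|| / sqrt(n), which equals 1
  for identical vectors and -1 at the maximum possible distance (all +1 vs
  all -1) — sensitive to local differences and overall magnitude, and immune
  to the autocorrelation inflation that affects r on smooth time series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .timeseries import fisher_mean_ci

__all__ = ["pearson_reliability", "l2_reliability", "reliability_summary",
           "ReliabilitySummary"]


def pearson_reliability(x, y) -> float:
    """Pearson r between two equal-length traces; NaN if either is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("traces must have equal length")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:  # constant -> r undefined
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def l2_reliability(x, y) -> float:
    """Scaled Euclidean-distance reliability in [-1, 1].

    score = 1 - d / sqrt(n) with d the Euclidean distance between the two
    vectors; d = 0 gives 1 and the maximal d = 2 sqrt(n) gives -1.  Applies
    to both continuous traces and per-category overall-rating vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 1:
        raise ValueError("vectors must be non-empty")
    for v in (x, y):
        if np.any(np.abs(v) > 1.0 + 1e-12):
            raise ValueError("values must lie in [-1, 1]")
    d = float(np.linalg.norm(x - y))
    return 1.0 - d / np.sqrt(x.size)


@dataclass
class ReliabilitySummary:
    """Per-(participant, category) reliability summaries plus comparisons."""

    records: pd.DataFrame       # one row per (participant, category, stimulus)
    per_participant: pd.DataFrame  # one row per (participant, category)
    cross_measure: dict         # category -> Pearson r (overall L2 vs median continuous L2)
    wilcoxon: dict              # measure -> (statistic, p) across categories
    n_dropped_pearson: int


def _wilcoxon(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    diff = a - b
    if np.allclose(diff, 0):
        return 0.0, 1.0
    res = stats.wilcoxon(a, b)  # exact for small n without ties/zeros
    return float(res.statistic), float(res.pvalue)


def reliability_summary(dataset) -> ReliabilitySummary:
    """Reliability of the rate group's traces and both groups' overall ratings.

    Per participant x category: the Fisher-z mean of Pearson r over that
    participant's clips, the mean and median of the L2 scores, and the L2
    score between the test and retest overall-rating vectors.  Also reports,
    per category, the across-participant correlation between overall-vector
    L2 and median continuous L2, and Wilcoxon signed-rank comparisons of
    per-participant means across categories.
    """
    test = dataset.traces(groups=("rate",), sessions=("test",))
    retest = dataset.traces(groups=("rate",), sessions=("retest",))
    if len(test) == 0 or len(retest) == 0:
        raise ValueError("dataset lacks rate-group test or retest traces")

    records = []
    n_dropped = 0
    re_lookup = {
        (k[0], k[3], k[4]): retest.loc[k].to_numpy()
        for k in retest.index
    }  # (participant, category, stimulus) -> trace
    for key, row in zip(test.index, test.to_numpy()):
        pid, group, _sess, cat, stim = key
        y = re_lookup.get((pid, cat, stim))
        if y is None:
            raise ValueError(f"missing retest trace for {(pid, cat, stim)}")
        r = pearson_reliability(row, y)
        if np.isnan(r):
            n_dropped += 1
        records.append({
            "participant_id": pid, "category": cat, "stimulus_id": stim,
            "pearson": r, "l2": l2_reliability(row, y),
        })
    records = pd.DataFrame(records)

    overall = dataset.overall
    per_part_rows = []
    for (pid, cat), grp in records.groupby(["participant_id", "category"]):
        pe = grp["pearson"].to_numpy()
        mean_pearson = (float("nan") if np.all(np.isnan(pe))
                        else fisher_mean_ci(pe).mean_r)
        per_part_rows.append({
            "participant_id": pid, "category": cat,
            "mean_pearson": mean_pearson,
            "mean_l2": float(grp["l2"].mean()),
            "median_l2": float(grp["l2"].median()),
        })
    per_part = pd.DataFrame(per_part_rows)

    # overall-rating vector L2 per participant x category (both groups)
    ov_rows = []
    for (pid, cat), grp in overall.groupby(["participant_id", "category"]):
        wide = grp.pivot(index="stimulus_id", columns="session",
                         values="rating")
        if {"test", "retest"} - set(wide.columns):
            continue
        ov_rows.append({
            "participant_id": pid, "category": cat,
            "group": grp["group"].iloc[0],
            "overall_l2": l2_reliability(wide["test"].to_numpy(),
                                         wide["retest"].to_numpy()),
        })
    ov = pd.DataFrame(ov_rows)
    per_part = per_part.merge(ov, on=["participant_id", "category"],
                              how="left")

    cross = {}
    for cat, grp in per_part.dropna(subset=["overall_l2"]).groupby("category"):
        cross[cat] = pearson_reliability(grp["overall_l2"].to_numpy(),
                                         grp["median_l2"].to_numpy())

    wide_p = per_part.pivot(index="participant_id", columns="category",
                            values="mean_pearson").dropna()
    wide_l = per_part.pivot(index="participant_id", columns="category",
                            values="mean_l2").dropna()
    wilcoxon = {
        "pearson": _wilcoxon(wide_p["dance"].to_numpy(),
                             wide_p["landscape"].to_numpy()),
        "l2": _wilcoxon(wide_l["dance"].to_numpy(),
                        wide_l["landscape"].to_numpy()),
    }
    return ReliabilitySummary(records=records, per_participant=per_part,
                              cross_measure=cross, wilcoxon=wilcoxon,
                              n_dropped_pearson=n_dropped)
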