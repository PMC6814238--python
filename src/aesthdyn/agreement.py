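"""Across-observer agreement (mean-minus-one) and taste variance decomposition.

The mean-minus-one (MM1) statistic correlates one observer's ratings with the
mean ratings of all other observers: for overall judgments the vectors run
over stimuli within one (category, session, group) cell; for continuous
ratings the vectors are the rating time courses of one clip.  High MM1 means
the observer shares the group's taste.

The variance decomposition splits the total rating variance into a
non-repeatable part (test-retest noise) and a repeatable part, and the
repeatable part further into *shared* taste (common to all observers) and
*individual* taste (stable but idiosyncratic).  It is a moment estimator:

    sigma2_e = Var(test - retest) / 2                    (noise)
    m_ps     = (test + retest) / 2                       (cell means)
    V_rep    = Var(m_ps) - sigma2_e / 2                  (repeatable)
    V_shared = (P * Var_s(mean_p m_ps) - V_rep - sigma2_e / 2) / (P - 1)
    V_indiv  = V_rep - V_shared

where P is the number of observers; the shared term subtracts the
finite-sample inflation of the group-mean variance.  Negative estimates are
clipped at zero and counted.  Fractions are reported relative to the total
V_rep + sigma2_e and sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timeseries import FisherMean, fisher_mean_ci
from .reliability import pearson_reliability

__all__ = ["mm1_overall", "mm1_continuous", "mm1_tables",
           "variance_decomposition", "VarianceDecomposition"]


def _mm1(matrix: np.ndarray) -> np.ndarray:
    """Per-row correlation with the mean of all other rows; NaN if undefined."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("expected a 2-D participants x observations matrix")
    if np.isnan(matrix).any():
        raise ValueError("matrix contains missing cells")
    p, _ = matrix.shape
    if p < 3:
        raise ValueError("need at least 3 participants")
    total = matrix.sum(axis=0)
    out = np.empty(p)
    for i in range(p):
        others_mean = (total - matrix[i]) / (p - 1)
        out[i] = pearson_reliability(matrix[i], others_mean)
    return out


def mm1_overall(ratings: pd.DataFrame | np.ndarray) -> pd.Series | np.ndarray:
    """MM1 agreement for one participants x stimuli overall-rating matrix.

    Each participant's rating vector over stimuli is correlated with the
    element-wise mean vector of the other N-1 participants.  Constant vectors
    yield NaN (dropped, never imputed, by the aggregation step).
    """
    if isinstance(ratings, pd.DataFrame):
        if ratings.shape[1] < 3:
            raise ValueError("need at least 3 stimuli")
        return pd.Series(_mm1(ratings.to_numpy()), index=ratings.index,
                         name="mm1")
    arr = np.asarray(ratings, dtype=float)
    if arr.shape[1] < 3:
        raise ValueError("need at least 3 stimuli")
    return _mm1(arr)


def mm1_continuous(traces: pd.DataFrame | np.ndarray):
    """MM1 agreement for one clip's participants x time trace matrix."""
    if isinstance(traces, pd.DataFrame):
        return pd.Series(_mm1(traces.to_numpy()), index=traces.index,
                         name="mm1")
    return _mm1(np.asarray(traces, dtype=float))


def mm1_tables(dataset) -> dict[str, pd.DataFrame]:
    """All MM1 records plus Fisher-z condition summaries for one dataset.

    Returns ``overall`` (one row per participant x category x session x
    group), ``continuous`` (one row per participant x stimulus x session,
    rate group for both sessions, view group for retest only), and
    ``summary`` (condition-level Fisher-z means with 95% CIs).
    """
    from .synth import has_continuous_rating

    overall_rows = []
    for (group, session, cat), grp in dataset.overall.groupby(
            ["group", "session", "category"]):
        mat = grp.pivot(index="participant_id", columns="stimulus_id",
                        values="rating")
        scores = mm1_overall(mat)
        for pid, score in scores.items():
            overall_rows.append({
                "participant_id": pid, "group": group, "session": session,
                "category": cat, "stimulus_id": "", "mm1": score,
            })
    overall_df = pd.DataFrame(overall_rows)

    cont_rows = []
    traces = dataset.traces()
    tr = traces.reset_index()
    for (group, session, cat, stim), grp in tr.groupby(
            ["group", "session", "category", "stimulus_id"]):
        if not has_continuous_rating(group, session) or len(grp) < 3:
            continue
        mat = grp.set_index("participant_id").drop(
            columns=["group", "session", "category", "stimulus_id"])
        scores = mm1_continuous(mat)
        for pid, score in scores.items():
            cont_rows.append({
                "participant_id": pid, "group": group, "session": session,
                "category": cat, "stimulus_id": stim, "mm1": score,
            })
    cont_df = pd.DataFrame(cont_rows)

    summaries = []
    for (group, session, cat), grp in overall_df.groupby(
            ["group", "session", "category"]):
        summaries.append(_summary_row("overall", group, session, cat,
                                      grp["mm1"].to_numpy()))
    if len(cont_df):
        # aggregate over stimuli within participant by Fisher z first,
        # mirroring the overall-rating granularity
        per_part = []
        for (group, session, cat, pid), grp in cont_df.groupby(
                ["group", "session", "category", "participant_id"]):
            vals = grp["mm1"].to_numpy()
            if np.all(np.isnan(vals)):
                per_part.append((group, session, cat, np.nan))
            else:
                per_part.append((group, session, cat,
                                 fisher_mean_ci(vals).mean_r))
        pp = pd.DataFrame(per_part, columns=["group", "session", "category",
                                             "mm1"])
        for (group, session, cat), grp in pp.groupby(
                ["group", "session", "category"]):
            summaries.append(_summary_row("continuous", group, session, cat,
                                          grp["mm1"].to_numpy()))
    summary_df = pd.DataFrame(summaries)
    return {"overall": overall_df, "continuous": cont_df,
            "summary": summary_df}


def _summary_row(kind, group, session, cat, values) -> dict:
    fm: FisherMean = fisher_mean_ci(values)
    return {
        "kind": kind, "group": group, "session": session, "category": cat,
        "mean_mm1": fm.mean_r, "ci_low": fm.ci_low, "ci_high": fm.ci_high,
        "n_used": fm.n_used, "n_dropped": fm.n_dropped,
    }


@dataclass
class VarianceDecomposition:
    total_var: float
    nonrepeatable_frac: float
    shared_frac: float
    individual_frac: float
    components: dict[str, float] = field(default_factory=dict)
    n_clipped: int = 0

    def __post_init__(self) -> None:
        fracs = (self.nonrepeatable_frac, self.shared_frac,
                 self.individual_frac)
        if any(f < -1e-9 or f > 1 + 1e-9 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")


def variance_decomposition(overall_test, overall_retest) -> VarianceDecomposition:
    """Split overall-rating variance into non-repeatable / shared / individual.

    Both arguments are matched participants x stimuli matrices (same row and
    column order) from the test and retest sessions.
    """
    x1 = np.asarray(overall_test, dtype=float)
    x2 = np.asarray(overall_retest, dtype=float)
    if isinstance(overall_test, pd.DataFrame):
        x1 = overall_test.to_numpy(dtype=float)
    if isinstance(overall_retest, pd.DataFrame):
        x2 = overall_retest.to_numpy(dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("test and retest matrices must have the same shape")
    if np.isnan(x1).any() or np.isnan(x2).any():
        raise ValueError("matrices contain missing cells")
    p, s = x1.shape
    if p < 3 or s < 3:
        raise ValueError("need at least 3 participants and 3 stimuli")

    n_clipped = 0
    sigma2_e = float(np.var(x1 - x2)) / 2.0
    m = (x1 + x2) / 2.0
    v_rep = float(np.var(m)) - sigma2_e / 2.0
    if v_rep < 0:
        v_rep = 0.0
        n_clipped += 1
    group_mean = m.mean(axis=0)
    v_graw = float(np.var(group_mean))
    v_shared = (p * v_graw - v_rep - sigma2_e / 2.0) / (p - 1)
    if v_shared < 0:
        v_shared = 0.0
        n_clipped += 1
    v_shared = min(v_shared, v_rep)
    v_indiv = v_rep - v_shared

    total = v_rep + sigma2_e
    if total <= 0:
        raise ValueError("zero total variance: ratings are all identical")
    return VarianceDecomposition(
        total_var=total,
        nonrepeatable_frac=sigma2_e / total,
        shared_frac=v_shared / total,
        individual_frac=v_indiv / total,
        components={
            "sigma2_error": sigma2_e, "v_repeatable": v_rep,
            "v_group_mean_raw": v_graw, "v_shared": v_shared,
            "v_individual": v_indiv,
        },
        n_clipped=n_clipped,
    )
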