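"""Temporal variability of rating traces and response-style clustering.

The variability index is the root-mean-squared derivative (rmsd) of a trace:
the square root of the mean squared first difference, in rating units per
0.1-s sample.  The divisor is the number of difference terms (299 for a
300-sample trace), which keeps the constant-trace case well defined at 0.
For mixed-model analyses rmsd is log-transformed; zero-rmsd trials (no dial
movement at all) are excluded from the log scale and counted.

Observers separate into response styles — "fast responders" with large
moment-to-moment changes versus slower integrators — which are recovered by
k-means clustering of each observer's median rmsd per category, with the
cluster count selected by the mean silhouette score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = ["rmsd", "log_rmsd_table", "reference_rmsd_logarithmic",
           "cluster_response_styles", "ClusterResult", "variability_table"]

# below this silhouette the best clustering is flagged as degenerate; k-means
# on structureless (single-Gaussian) 2-D data already reaches ~0.35-0.40, so
# the flag sits just above that null range
_DEGENERATE_SILHOUETTE = 0.45


def rmsd(trace) -> float:
    """Root-mean-squared first difference of a trace (>= 0)."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ValueError("trace must have at least 2 samples")
    d = np.diff(trace)
    return float(np.sqrt(np.mean(d * d)))


def reference_rmsd_logarithmic(duration_s: float, sample_rate_hz: float,
                               ) -> float:
    """rmsd of a logarithmic monotonic rise spanning the full rating scale.

    The reference curve r(t) = 2 log10(1 + 9 t / T) - 1 rises from -1 at
    t = 0 to +1 at t = T and is sampled on the standard grid.  It anchors
    interpretation: observed rmsd values above it indicate more temporal
    change than a single smooth sweep across the scale.
    """
    if duration_s <= 0 or sample_rate_hz <= 0:
        raise ValueError("duration and rate must be positive")
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    r = 2.0 * np.log10(1.0 + 9.0 * t / duration_s) - 1.0
    return rmsd(r)


def variability_table(dataset, sessions: tuple[str, ...] | None = None,
                      ) -> pd.DataFrame:
    """One rmsd row per continuous trial: trial keys + rmsd + log_rmsd.

    ``log_rmsd`` is NaN for zero-rmsd trials (log undefined); downstream
    analyses drop and count those rows.
    """
    traces = dataset.traces(sessions=sessions)
    rows = []
    for key, row in zip(traces.index, traces.to_numpy()):
        pid, group, session, cat, stim = key
        val = rmsd(row)
        rows.append({
            "participant_id": pid, "group": group, "session": session,
            "category": cat, "stimulus_id": stim, "rmsd": val,
            "log_rmsd": np.log(val) if val > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def log_rmsd_table(var_table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop zero-rmsd trials for log-scale analyses; return (table, n_dropped)."""
    keep = var_table["log_rmsd"].notna()
    return var_table[keep].reset_index(drop=True), int((~keep).sum())


@dataclass
class ClusterResult:
    k: int
    labels: pd.Series                  # participant_id -> cluster id
    silhouette: float
    centers: np.ndarray                # k x n_features, rmsd units
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    degenerate: bool = False


def median_rmsd_features(var_table: pd.DataFrame) -> pd.DataFrame:
    """Participant x category table of median rmsd (clustering features)."""
    return (var_table.groupby(["participant_id", "category"])["rmsd"]
            .median().unstack("category"))


def cluster_response_styles(features: pd.DataFrame,
                            k_range=(2, 3, 4, 5),
                            rng_seed: int = 0) -> ClusterResult:
    """K-means over participants' median rmsd features, k by silhouette.

    Uses the squared-Euclidean k-means objective with 50 restarts per k and
    Euclidean silhouette scoring.  Labels are ordered so cluster 0 has the
    largest mean rmsd (the "fast responders").  If even the best silhouette
    is low the result is flagged degenerate (no real cluster structure).
    """
    x = features.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 participants to cluster")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate input: all feature rows identical")
    best = None
    sil_by_k = {}
    for k in k_range:
        if not 2 <= k <= x.shape[0] - 1:
            raise ValueError(f"k={k} outside [2, n_participants-1]")
        km = KMeans(n_clusters=k, n_init=50, random_state=rng_seed)
        labels = km.fit_predict(x)
        if len(np.unique(labels)) < 2:
            continue
        sil = float(silhouette_score(x, labels, metric="euclidean"))
        sil_by_k[k] = sil
        if best is None or sil > best[0]:
            best = (sil, k, labels, km.cluster_centers_)
    if best is None:
        raise ValueError("clustering failed for every k in k_range")
    sil, k, labels, centers = best
    # relabel so cluster 0 has the largest mean rmsd
    order = np.argsort(-centers.mean(axis=1))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[l] for l in labels])
    centers = centers[order]
    return ClusterResult(
        k=k,
        labels=pd.Series(labels, index=features.index, name="cluster"),
        silhouette=sil,
        centers=centers,
        silhouette_by_k=sil_by_k,
        degenerate=sil < _DEGENERATE_SILHOUETTE,
    )
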