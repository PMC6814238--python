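"""Event-log resampling and correlation aggregation.

Dial positions between updates are held constant (zero-order hold): the
physical cursor keeps its position until the observer moves it.  Traces are
sampled on the grid t_i = i / rate, i = 0..n-1 (t = 0 inclusive), which for a
30-s clip at 10 Hz yields exactly 300 samples.  Before the first event the
trace is 0.0 — the cursor starts at the neutral midpoint.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["events_to_trace", "traces_from_events", "scale_position",
           "fisher_mean_ci", "FisherMean"]

# correlations of +/-1 are clipped to this before atanh
_R_CLIP = 1.0 - 1e-7


def events_to_trace(t_sec: np.ndarray, position: np.ndarray,
                    duration_s: float, sample_rate_hz: float) -> np.ndarray:
    """Resample an event log to a fixed-rate trace by zero-order hold.

    Parameters
    ----------
    t_sec, position
        Event timestamps (strictly increasing, in [0, duration)) and the new
        dial position at each event.
    duration_s, sample_rate_hz
        Sampling grid: n = round(duration_s * sample_rate_hz) samples at
        t_i = i / sample_rate_hz.

    Returns
    -------
    ndarray of length n; sample i holds the position of the latest event with
    t_sec <= t_i, or 0.0 if there is none.
    """
    t_sec = np.asarray(t_sec, dtype=float)
    position = np.asarray(position, dtype=float)
    if t_sec.size and float(t_sec.max()) >= duration_s:
        raise ValueError(
            f"event at t={float(t_sec.max())} s lies beyond the clip "
            f"duration of {duration_s} s")
    n = int(round(duration_s * sample_rate_hz))
    grid = np.arange(n) / sample_rate_hz
    # index of the latest event with t <= t_i; 0 means "before first event"
    idx = np.searchsorted(t_sec, grid, side="right")
    trace = np.concatenate([[0.0], position])[idx]
    return trace


def traces_from_events(events: pd.DataFrame, trials: pd.DataFrame,
                       duration_s: float, sample_rate_hz: float) -> pd.DataFrame:
    """Zero-order-hold traces for every trial in ``trials``.

    ``trials`` lists the continuous trials that exist by design; trials with
    no events at all yield all-zero traces (the cursor never moved).
    Returns a wide DataFrame indexed by the trial keys.
    """
    keys = list(trials.columns)
    n = int(round(duration_s * sample_rate_hz))
    grouped = {k: g for k, g in events.groupby(keys, sort=False)}
    rows = []
    index = []
    for key_vals in trials.itertuples(index=False):
        key = tuple(key_vals)
        g = grouped.get(key)
        if g is None:
            rows.append(np.zeros(n))
        else:
            rows.append(events_to_trace(g["t_sec"].to_numpy(),
                                        g["position"].to_numpy(),
                                        duration_s, sample_rate_hz))
        index.append(key)
    out = pd.DataFrame(np.asarray(rows) if rows else np.empty((0, n)),
                       index=pd.MultiIndex.from_tuples(index, names=keys)
                       if index else None)
    return out


def scale_position(raw, device_min: float, device_max: float):
    """Affine map from device units onto the [-1, 1] rating scale.

    The device maximum codes as +1, the minimum as -1, the midpoint as 0.
    """
    if not device_max > device_min:
        raise ValueError("device_max must exceed device_min")
    raw_arr = np.asarray(raw, dtype=float)
    if np.any(raw_arr < device_min) or np.any(raw_arr > device_max):
        raise ValueError(
            f"raw position outside [{device_min}, {device_max}]")
    scaled = 2.0 * (raw_arr - device_min) / (device_max - device_min) - 1.0
    return scaled if scaled.ndim else float(scaled)


class FisherMean(NamedTuple):
    mean_r: float
    ci_low: float
    ci_high: float
    n_used: int
    n_dropped: int


def fisher_mean_ci(r_values, confidence: float = 0.95) -> FisherMean:
    """Average correlations on the Fisher-z scale with a normal-theory CI.

    NaN entries (undefined correlations from zero-variance inputs) are
    dropped and counted, never imputed.  r = +/-1 is clipped just inside the
    open interval before atanh.  A singleton list returns that value with a
    degenerate (zero-width) interval.
    """
    r = np.asarray(list(r_values), dtype=float)
    dropped = int(np.isnan(r).sum())
    r = r[~np.isnan(r)]
    if r.size == 0:
        raise ValueError("no defined correlations to average")
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    mean_z = float(z.mean())
    if r.size == 1:
        half = 0.0
    else:
        crit = stats.norm.ppf(0.5 + confidence / 2.0)
        half = crit * float(z.std(ddof=1)) / np.sqrt(r.size)
    return FisherMean(
        mean_r=float(np.tanh(mean_z)),
        ci_low=float(np.tanh(mean_z - half)),
        ci_high=float(np.tanh(mean_z + half)),
        n_used=int(r.size),
        n_dropped=dropped,
    )
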