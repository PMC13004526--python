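"""Movement and task-context labels: body speed, moving/stationary,
boundary proximity, detour-error performance tertiles, and trial halves."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .session import DEFAULT_ROOM, TimeSeries2D

MOVING_THRESHOLD_M_S = 0.2   # speed >= threshold counts as locomotion
BOUNDARY_THRESHOLD_M = 1.2


def body_speed(position: TimeSeries2D, smooth_window_s=0.25) -> np.ndarray:
    """Finite-difference speed (m/s), smoothed by a short moving average."""
    if len(position) < 2:
        raise ValueError("body_speed: fewer than 2 samples")
    dt = np.gradient(position.t)
    vx = np.gradient(position.x) / dt
    vy = np.gradient(position.y) / dt
    speed = np.hypot(vx, vy)
    w = max(1, int(round(smooth_window_s * position.rate)))
    if w > 1:
        pad = w // 2
        sp = np.pad(speed, pad, mode="edge")
        speed = np.convolve(sp, np.ones(w) / w, mode="same")[pad:pad + len(speed)]
    return speed


def moving_mask(speed, threshold=MOVING_THRESHOLD_M_S):
    return np.asarray(speed) >= threshold


def boundary_mask(position: TimeSeries2D, room=DEFAULT_ROOM,
                  threshold_m=BOUNDARY_THRESHOLD_M) -> np.ndarray:
    """True where the minimum distance to any of the four walls < threshold."""
    w, d = room
    if w <= 2 * threshold_m or d <= 2 * threshold_m:
        warnings.warn("room too small for the boundary threshold; inner region empty")
    dist = np.minimum.reduce([
        position.x, w - position.x, position.y, d - position.y,
    ])
    return dist < threshold_m


def detour_error(walked, straight) -> float:
    """Percent increase of walked distance over the straight-line path."""
    if straight <= 0:
        raise ValueError("straight distance must be > 0")
    return 100.0 * (walked - straight) / straight


def walked_distance(position: TimeSeries2D, t_start, t_end) -> float:
    """Path integral of the position trace within [t_start, t_end]."""
    m = (position.t >= t_start) & (position.t < t_end)
    if m.sum() < 2:
        return 0.0
    return float(np.hypot(np.diff(position.x[m]), np.diff(position.y[m])).sum())


def trial_detour_errors(trials: pd.DataFrame,
                        position: TimeSeries2D | None = None) -> pd.DataFrame:
    """Per-MC-trial detour errors (walked distance from the table, or the
    path integral of the trace when the table column is missing)."""
    mc = trials[trials["condition"] == "MC"].copy()
    if "walked_distance" in mc.columns and mc["walked_distance"].notna().all():
        walked = mc["walked_distance"].values
    else:
        walked = np.array([walked_distance(position, a, b)
                           for a, b in zip(mc["t_start"], mc["t_end"])])
    mc["detour_error"] = [detour_error(w, s)
                          for w, s in zip(walked, mc["straight_distance"])]
    return mc[["trial_id", "t_start", "t_end", "detour_error"]]


def performance_tertiles(mc_trials: pd.DataFrame) -> pd.DataFrame:
    """Equal-thirds split of MC trials by ascending detour error.

    HP = lowest third (best memory performance), MP middle, LP highest.
    Ties break by trial order; when the count is not divisible by 3 the
    remainder goes to HP first, then MP.
    """
    if len(mc_trials) < 3:
        raise ValueError("performance tertiles require at least 3 MC trials")
    df = mc_trials.copy().reset_index(drop=True)
    order = np.lexsort((df.index.values, df["detour_error"].values))
    n = len(df)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    tert = np.empty(n, dtype=object)
    start = 0
    for name, size in zip(("HP", "MP", "LP"), sizes):
        tert[order[start:start + size]] = name
        start += size
    df["tertile"] = tert
    return df


def trial_half_spans(trials: pd.DataFrame) -> pd.DataFrame:
    """First/second half spans of every trial, split at the temporal midpoint."""
    rows = []
    for _, r in trials.iterrows():
        mid = 0.5 * (r["t_start"] + r["t_end"])
        rows.append({"trial_id": r["trial_id"], "condition": r["condition"],
                     "half": "first", "t_start": r["t_start"], "t_end": mid})
        rows.append({"trial_id": r["trial_id"], "condition": r["condition"],
                     "half": "second", "t_start": mid, "t_end": r["t_end"]})
    return pd.DataFrame(rows)


def spans_to_mask(spans: pd.DataFrame, t: np.ndarray) -> np.ndarray:
    """Boolean per-sample mask of membership in any of the given spans."""
    m = np.zeros(len(t), dtype=bool)
    for a, b in zip(spans["t_start"].values, spans["t_end"].values):
        m |= (t >= a) & (t < b)
    return m
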