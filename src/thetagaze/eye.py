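"""Cluster-Fix-style saccade/fixation classification and scanpath metrics.

Every valid gaze sample is labeled ``saccade`` or ``fixation`` by k-means
clustering over kinematic features (speed, acceleration, angular change,
point-to-point displacement).  The cluster with the lowest combined speed and
acceleration seeds the fixation class; any other cluster whose centroid lies
within three standard deviations of that cluster's mean (on the combined
speed + acceleration axis) is absorbed into fixation, and all remaining
clusters are saccades.  Invalid samples stay ``invalid``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .session import TimeSeries2D

LABELS = ("fixation", "saccade", "invalid")


@dataclass
class KinematicFeatures:
    """Per-sample kinematics of a gaze trace (same length as the trace)."""

    speed: np.ndarray            # px/s
    accel: np.ndarray            # px/s^2 (magnitude)
    rotation: np.ndarray         # |angular change| of velocity direction, rad
    displacement: np.ndarray     # point-to-point step length, px
    valid: np.ndarray
    rate: float
    smooth_window_s: float = 0.02


@dataclass
class SampleLabels:
    """Per-sample oculomotor labels plus the derived event table."""

    t: np.ndarray
    label: np.ndarray            # object array of {"fixation","saccade","invalid"}
    events: pd.DataFrame = field(default=None)  # kind, onset_s, offset_s, duration_ms, displacement

    def __post_init__(self):
        if self.events is None:
            self.events = events_from_labels(self.t, self.label, None, None)


def _moving_average(x, w):
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    # reflect-pad so the centered average has no phase shift at the edges
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")[pad:pad + len(x)]
    return out


def compute_kinematics(gaze: TimeSeries2D, smooth_window_s=0.02) -> KinematicFeatures:
    """Speed, acceleration, angular change, and step displacement per sample.

    First differences of position over time give velocity; differences of the
    (smoothed) speed give acceleration.  A short (~20 ms) centered moving
    average suppresses sample-to-sample noise before differentiation-derived
    features enter the clustering.
    """
    if gaze.valid.sum() < 2:
        raise ValueError("compute_kinematics: fewer than 2 valid samples")
    n = len(gaze)
    dt = 1.0 / gaze.rate
    w = max(1, int(round(smooth_window_s * gaze.rate)))
    w += 1 - w % 2   # odd window: centered average, no half-sample shift
    xs = _moving_average(gaze.x, w)
    ys = _moving_average(gaze.y, w)

    vx = np.gradient(xs, dt)
    vy = np.gradient(ys, dt)
    speed = np.hypot(vx, vy)
    accel = np.abs(np.gradient(speed, dt))
    ang = np.arctan2(vy, vx)
    rotation = np.empty(n)
    rotation[1:] = np.abs(np.angle(np.exp(1j * np.diff(ang))))
    rotation[0] = rotation[1] if n > 1 else 0.0
    displacement = np.empty(n)
    displacement[1:] = np.hypot(np.diff(xs), np.diff(ys))
    displacement[0] = displacement[1] if n > 1 else 0.0

    for arr in (speed, accel, rotation, displacement):
        arr[~gaze.valid] = np.nan
    return KinematicFeatures(speed=speed, accel=accel, rotation=rotation,
                             displacement=displacement, valid=gaze.valid.copy(),
                             rate=gaze.rate, smooth_window_s=smooth_window_s)


def _standardize(col):
    sd = np.nanstd(col)
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(col)
    return (col - np.nanmean(col)) / sd


def classify_samples(features: KinematicFeatures, k_range=range(2, 6), seed=0,
                     min_event_samples=2) -> SampleLabels:
    """Label every sample saccade/fixation by k-means over the feature set.

    k is chosen from ``k_range`` by silhouette score (subsampled for speed,
    seeded).  Degenerate (constant) features yield all-fixation with a
    warning.  Events shorter than ``min_event_samples`` are merged into the
    flanking state to suppress single-sample flicker.
    """
    valid = features.valid
    n = len(valid)
    t = np.arange(n) / features.rate
    label = np.array(["invalid"] * n, dtype=object)

    # log-compress the heavy-tailed magnitude features so small saccades are
    # not crushed against the fixation cluster by a few very fast ones
    X = np.column_stack([
        _standardize(np.log1p(features.speed[valid])),
        _standardize(np.log1p(features.accel[valid])),
        _standardize(features.rotation[valid]),
        _standardize(np.log1p(features.displacement[valid])),
    ])
    if not np.isfinite(X).all():
        X = np.nan_to_num(X)
    if np.allclose(X.std(axis=0), 0):
        warnings.warn("degenerate kinematic features; labeling all samples fixation")
        label[valid] = "fixation"
        lab = SampleLabels(t=t, label=label)
        return lab

    rng = np.random.default_rng(seed)
    best = None
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=4, random_state=int(rng.integers(2**31)))
        assign = km.fit_predict(X)
        size = min(2000, len(X))
        try:
            score = silhouette_score(
                X, assign, sample_size=size,
                random_state=int(rng.integers(2**31)))
        except ValueError:
            continue
        if best is None or score > best[0]:
            best = (score, km, assign)
    _, km, assign = best

    # fixation seed cluster: lowest combined (standardized) speed + acceleration
    combo = X[:, 0] + X[:, 1]
    k_eff = km.n_clusters
    means = np.array([combo[assign == c].mean() for c in range(k_eff)])
    fix_c = int(np.argmin(means))
    fix_sd = combo[assign == fix_c].std()
    fixation_clusters = {c for c in range(k_eff)
                         if means[c] <= means[fix_c] + 3 * fix_sd}
    vl = np.where(np.isin(assign, list(fixation_clusters)), "fixation", "saccade")
    label[valid] = vl

    label = _refine_saccade_boundaries(label, features)
    label = _merge_short_events(label, min_event_samples)
    return SampleLabels(t=t, label=label)


def _refine_saccade_boundaries(label, features, max_extend_s=0.05):
    """Sharpen saccade onsets/offsets by local kinematic thresholds.

    The global clustering finds the high-velocity core of each saccade but
    misses the low-velocity tails.  Each detected saccade run is extended
    outward while the neighboring sample's speed or acceleration exceeds a
    robust fixation-level threshold (median + 3 MAD-scaled SD of
    fixation-labeled samples), up to ``max_extend_s`` per side.
    """
    from scipy.stats import median_abs_deviation

    fix = label == "fixation"
    if not fix.any() or not (label == "saccade").any():
        return label
    speed, accel = features.speed, features.accel
    sac = label == "saccade"
    # floor at a small fraction of the saccade-scale kinematics so noise-free
    # fixations (threshold would be 0) do not absorb smoothing leakage
    thr_s = max(np.nanmedian(speed[fix]) + 3 * median_abs_deviation(
        speed[fix], scale="normal", nan_policy="omit"),
        0.1 * np.nanmedian(speed[sac]))
    thr_a = max(np.nanmedian(accel[fix]) + 3 * median_abs_deviation(
        accel[fix], scale="normal", nan_policy="omit"),
        0.1 * np.nanmedian(accel[sac]))
    max_ext = max(1, int(round(max_extend_s * features.rate)))
    n = len(label)
    out = label.copy()
    starts, kinds = _runs(label)
    bounds = np.append(starts, n)

    def hot_onset(i):
        return (speed[i] > thr_s) or (accel[i] > thr_a)

    def hot_offset(i):
        # deceleration leaks one sample past the motion, so the trailing
        # edge extends on speed alone
        return speed[i] > thr_s

    for i, kind in enumerate(kinds):
        if kind != "saccade":
            continue
        a, b = bounds[i], bounds[i + 1]
        a1 = a
        while a1 > 0 and a - a1 < max_ext and label[a1 - 1] == "fixation" and hot_onset(a1 - 1):
            a1 -= 1
        b1 = b
        while b1 < n and b1 - b < max_ext and label[b1] == "fixation" and hot_offset(b1):
            b1 += 1
        out[a1:b1] = "saccade"
    return out


def _merge_short_events(label, min_samples):
    """Merge runs shorter than ``min_samples`` into the preceding state."""
    if min_samples <= 1:
        return label
    label = label.copy()
    starts, kinds = _runs(label)
    bounds = np.append(starts, len(label))
    for i in range(len(starts)):
        a, b = bounds[i], bounds[i + 1]
        if kinds[i] in ("fixation", "saccade") and (b - a) < min_samples:
            repl = kinds[i - 1] if i > 0 and kinds[i - 1] != "invalid" else (
                kinds[i + 1] if i + 1 < len(kinds) else kinds[i])
            if repl != "invalid":
                label[a:b] = repl
    return label


def _runs(label):
    """Start indices and values of maximal constant runs."""
    n = len(label)
    change = np.empty(n, dtype=bool)
    change[0] = True
    change[1:] = label[1:] != label[:-1]
    starts = np.flatnonzero(change)
    return starts, label[starts]


def events_from_labels(t, label, x=None, y=None) -> pd.DataFrame:
    """Event table of maximal saccade/fixation runs (regenerable from labels)."""
    starts, kinds = _runs(np.asarray(label, dtype=object))
    bounds = np.append(starts, len(label))
    dt = t[1] - t[0] if len(t) > 1 else 0.0
    rows = []
    for i, kind in enumerate(kinds):
        if kind == "invalid":
            continue
        a, b = bounds[i], bounds[i + 1]
        disp = np.nan
        if x is not None and b - a >= 2:
            disp = float(np.hypot(x[b - 1] - x[a], y[b - 1] - y[a]))
        rows.append({
            "event_id": len(rows) + 1, "kind": kind,
            "onset_s": t[a], "offset_s": t[b - 1] + dt,
            "duration_ms": (b - a) * dt * 1000.0,
            "displacement": disp,
            "i_start": int(a), "i_end": int(b),
        })
    return pd.DataFrame(rows, columns=["event_id", "kind", "onset_s", "offset_s",
                                       "duration_ms", "displacement",
                                       "i_start", "i_end"])


def labels_from_events(events: pd.DataFrame, n: int) -> np.ndarray:
    """Rebuild the per-sample label vector from an event table."""
    label = np.array(["invalid"] * n, dtype=object)
    for _, r in events.iterrows():
        label[int(r["i_start"]):int(r["i_end"])] = r["kind"]
    return label


def event_metrics(labels: SampleLabels, condition_mask=None, x=None, y=None) -> dict:
    """Saccade frequency/duration/displacement and fixation duration summary.

    ``condition_mask`` restricts to samples of one task condition; frequency
    is saccade onsets per second of condition time.
    """
    ev = labels.events
    if x is not None and ev["displacement"].isna().all():
        ev = events_from_labels(labels.t, labels.label, x, y)
    if condition_mask is not None:
        cond_time = condition_mask.sum() * (labels.t[1] - labels.t[0])
        onset_idx = ev["i_start"].values
        ev = ev[condition_mask[onset_idx]]
    else:
        cond_time = labels.t[-1] - labels.t[0] + (labels.t[1] - labels.t[0])
    if cond_time <= 0:
        raise ValueError("event_metrics: empty condition")
    sac = ev[ev["kind"] == "saccade"]
    fix = ev[ev["kind"] == "fixation"]
    return {
        "saccade_frequency_hz": len(sac) / cond_time,
        "saccade_duration_ms": float(sac["duration_ms"].mean()) if len(sac) else np.nan,
        "saccade_displacement": float(sac["displacement"].mean()) if len(sac) else np.nan,
        "fixation_duration_ms": float(fix["duration_ms"].mean()) if len(fix) else np.nan,
        "n_saccades": int(len(sac)),
        "n_fixations": int(len(fix)),
    }


def scanpath_entropy(gaze: TimeSeries2D, labels: SampleLabels | None = None,
                     grid=(30, 30), window_s=1.0, step_s=0.25,
                     frame=(192.0, 192.0)):
    """Shannon entropy (bits) of gaze occupancy over a spatial grid, per window.

    The frame is divided into ``grid`` bins; within each sliding window the
    occupancy distribution p over occupied bins gives H = -sum p log2 p.
    Windows with fewer than 2 valid samples are missing.  Returns
    ``(t_center, H_bits)``.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    t = gaze.t
    gx, gy = grid
    bx = np.clip((gaze.x / frame[0] * gx).astype(int), 0, gx - 1)
    by = np.clip((gaze.y / frame[1] * gy).astype(int), 0, gy - 1)
    bin_id = bx * gy + by
    valid = gaze.valid

    centers = np.arange(t[0] + window_s / 2, t[-1] - window_s / 2 + 1e-9, step_s)
    H = np.full(len(centers), np.nan)
    lo = np.searchsorted(t, centers - window_s / 2)
    hi = np.searchsorted(t, centers + window_s / 2)
    for i, (a, b) in enumerate(zip(lo, hi)):
        ids = bin_id[a:b][valid[a:b]]
        if len(ids) < 2:
            continue
        counts = np.bincount(ids)
        p = counts[counts > 0] / len(ids)
        H[i] = -np.sum(p * np.log2(p))
    return centers, H


def saccade_count_windows(labels: SampleLabels, window_s=1.0, step_s=0.004,
                          t_end=None):
    """Count saccade onsets within overlapping sliding windows.

    Windows are indexed by center time; default 1-s windows stepped at 4 ms.
    Returns ``(t_center, counts)``.
    """
    onsets = labels.events.loc[labels.events["kind"] == "saccade", "onset_s"].values
    t0 = labels.t[0]
    t1 = t_end if t_end is not None else labels.t[-1]
    centers = np.arange(t0 + window_s / 2, t1 - window_s / 2 + 1e-9, step_s)
    lo = np.searchsorted(onsets, centers - window_s / 2)
    hi = np.searchsorted(onsets, centers + window_s / 2)
    return centers, (hi - lo).astype(int)


def median_split(values, tie_low=True):
    """Boolean 'high' mask of a median split; ties go to the low group."""
    values = np.asarray(values, dtype=float)
    med = np.nanmedian(values)
    return values > med if tie_low else values >= med
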