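"""Shared data model for synchronized multi-rate behavioral/neural sessions.

A session bundles four streams recorded on one clock (seconds, t=0 at session
start): 2-D gaze in a normalized 192 x 192 reference frame (~200 Hz), 2-D body
position in meters (120 Hz), multichannel bipolar iEEG (250 Hz, recorded in
non-overlapping intervals of a few minutes), and a trial table alternating
memory-cued (MC) and visually-cued (VC) navigation.  Streams keep their native
timestamps; nothing is resampled implicitly.

The canonical interchange format is a directory of CSV files plus a YAML
manifest (see :func:`write_session` / :func:`read_session`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

GAZE_FRAME = 192.0          # gaze coordinates live in [0, 192]^2
DEFAULT_ROOM = (5.9, 5.2)   # meters (width, depth)

CONDITIONS = ("MC", "VC")


class SessionError(ValueError):
    """Invariant violation in a session bundle or its on-disk form."""


@dataclass
class TimeSeries2D:
    """A 2-D position trace with explicit per-sample timestamps.

    Parameters
    ----------
    t : array of seconds, strictly increasing.
    x, y : positions. Gaze: normalized frame units; body: meters.
    rate : nominal sampling rate in Hz.
    valid : per-sample validity (False for blinks / dropouts). Invalid
        samples are carried, never interpolated; downstream stages skip them.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    rate: float
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.t.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.valid)):
            raise SessionError("TimeSeries2D: stream arrays have unequal lengths")
        if self.rate <= 0:
            raise SessionError("TimeSeries2D: rate must be > 0")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            idx = int(np.argmax(dt <= 0))
            raise SessionError(f"TimeSeries2D: time not strictly increasing at index {idx + 1}")
        bad = self.valid & ~(np.isfinite(self.x) & np.isfinite(self.y))
        if np.any(bad):
            raise SessionError("TimeSeries2D: non-finite position on a valid sample")

    def __len__(self):
        return len(self.t)

    def __eq__(self, other):
        if not isinstance(other, TimeSeries2D):
            return NotImplemented
        return (
            np.array_equal(self.t, other.t)
            and np.allclose(self.x, other.x, equal_nan=True)
            and np.allclose(self.y, other.y, equal_nan=True)
            and self.rate == other.rate
            and np.array_equal(self.valid, other.valid)
        )


@dataclass
class IeegRecording:
    """Multichannel bipolar iEEG stored as channel x sample voltages.

    ``intervals`` lists the (start_s, end_s) of each recording segment; every
    sample belongs to exactly one interval and all per-interval statistics
    (z-scoring, IED baselines) are computed within segments.
    """

    channels: list
    data: np.ndarray          # (n_channels, n_samples)
    rate: float = 250.0
    intervals: list = field(default_factory=list)   # [(start_s, end_s), ...]
    t0: float = 0.0
    regions: dict = field(default_factory=dict)     # channel id -> region label

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.rate <= 0:
            raise SessionError("IeegRecording: rate must be > 0")
        if self.data.shape[0] != len(self.channels):
            raise SessionError("IeegRecording: channel list does not match data rows")
        if not self.intervals:
            dur = self.data.shape[1] / self.rate
            self.intervals = [(self.t0, self.t0 + dur)]
        self.intervals = [(float(a), float(b)) for a, b in self.intervals]
        prev_end = -np.inf
        for a, b in self.intervals:
            if b <= a:
                raise SessionError("IeegRecording: empty or inverted interval")
            if a < prev_end:
                raise SessionError("IeegRecording: overlapping recording intervals")
            prev_end = b
        n_expected = sum(int(round((b - a) * self.rate)) for a, b in self.intervals)
        if n_expected != self.data.shape[1]:
            raise SessionError(
                f"IeegRecording: interval table implies {n_expected} samples, "
                f"data has {self.data.shape[1]}"
            )

    @property
    def n_channels(self):
        return self.data.shape[0]

    @property
    def n_samples(self):
        return self.data.shape[1]

    @property
    def times(self):
        """Per-sample timestamps on the session clock (concatenated intervals)."""
        parts = []
        for (a, b), n in zip(self.intervals, self.interval_lengths()):
            parts.append(a + np.arange(n) / self.rate)
        return np.concatenate(parts) if parts else np.empty(0)

    def interval_lengths(self):
        """Number of samples in each recording interval."""
        return [int(round((b - a) * self.rate)) for a, b in self.intervals]

    def interval_slices(self):
        """Sample-index slice for each recording interval."""
        out, start = [], 0
        for n in self.interval_lengths():
            out.append(slice(start, start + n))
            start += n
        return out

    def interval_index(self):
        """Per-sample index of the owning recording interval."""
        idx = np.empty(self.n_samples, dtype=int)
        for i, sl in enumerate(self.interval_slices()):
            idx[sl] = i
        return idx

    def __eq__(self, other):
        if not isinstance(other, IeegRecording):
            return NotImplemented
        return (
            list(self.channels) == list(other.channels)
            and np.allclose(self.data, other.data)
            and self.rate == other.rate
            and np.allclose(np.asarray(self.intervals), np.asarray(other.intervals))
            and self.regions == other.regions
        )


TRIAL_COLUMNS = [
    "trial_id", "condition", "t_start", "t_end",
    "target_id", "walked_distance", "straight_distance",
]


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a trial table (non-overlap, distances, labels)."""
    trials = trials.copy()
    for col in TRIAL_COLUMNS:
        if col not in trials.columns:
            raise SessionError(f"trial table missing column {col!r}")
    for col in ("t_start", "t_end", "walked_distance", "straight_distance"):
        trials[col] = trials[col].astype(float)
    bad_cond = set(trials["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise SessionError(f"unknown condition labels: {sorted(bad_cond)}")
    if (trials["t_end"] <= trials["t_start"]).any():
        ids = trials.loc[trials["t_end"] <= trials["t_start"], "trial_id"].tolist()
        raise SessionError(f"trials with t_end <= t_start: {ids}")
    if (trials["walked_distance"] < 0).any() or (trials["straight_distance"] <= 0).any():
        raise SessionError("trial distances must be walked >= 0 and straight > 0")
    srt = trials.sort_values("t_start").reset_index(drop=True)
    overlap = srt["t_start"].values[1:] < srt["t_end"].values[:-1]
    if overlap.any():
        i = int(np.argmax(overlap))
        pair = (srt.loc[i, "trial_id"], srt.loc[i + 1, "trial_id"])
        raise SessionError(f"overlapping trials: {pair[0]} and {pair[1]}")
    return srt


@dataclass
class SessionBundle:
    """One participant-session: gaze + body + iEEG + trials on a shared clock."""

    gaze: TimeSeries2D
    body: TimeSeries2D
    ieeg: IeegRecording
    trials: pd.DataFrame
    participant_id: str = "P0"
    room: tuple = DEFAULT_ROOM

    def __post_init__(self):
        self.trials = validate_trials(self.trials)
        if self.room[0] <= 0 or self.room[1] <= 0:
            raise SessionError("room dimensions must be positive")

    def __eq__(self, other):
        if not isinstance(other, SessionBundle):
            return NotImplemented
        return (
            self.gaze == other.gaze
            and self.body == other.body
            and self.ieeg == other.ieeg
            and self.participant_id == other.participant_id
            and tuple(self.room) == tuple(other.room)
            and self.trials.reset_index(drop=True).equals(other.trials.reset_index(drop=True))
        )


# ---------------------------------------------------------------------------
# interchange: directory of CSVs + manifest.yaml
# ---------------------------------------------------------------------------

def write_session(bundle: SessionBundle, dir_path) -> dict:
    """Write a bundle as CSV files plus a YAML manifest; returns the manifest."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "t": bundle.gaze.t, "x": bundle.gaze.x, "y": bundle.gaze.y,
        "valid": bundle.gaze.valid.astype(int),
    }).to_csv(d / "gaze.csv", index=False, float_format="%.17g")
    pd.DataFrame({
        "t": bundle.body.t, "x": bundle.body.x, "y": bundle.body.y,
    }).to_csv(d / "position.csv", index=False, float_format="%.17g")
    ieeg_df = pd.DataFrame({"t": bundle.ieeg.times})
    for i, ch in enumerate(bundle.ieeg.channels):
        ieeg_df[str(ch)] = bundle.ieeg.data[i]
    ieeg_df.to_csv(d / "ieeg.csv", index=False, float_format="%.17g")
    bundle.trials[TRIAL_COLUMNS].to_csv(d / "trials.csv", index=False, float_format="%.17g")
    manifest = {
        "participant_id": bundle.participant_id,
        "room": [float(bundle.room[0]), float(bundle.room[1])],
        "streams": {
            "gaze": {"file": "gaze.csv", "rate_hz": float(bundle.gaze.rate),
                     "units": "frame_px_0_192"},
            "position": {"file": "position.csv", "rate_hz": float(bundle.body.rate),
                         "units": "m"},
            "ieeg": {"file": "ieeg.csv", "rate_hz": float(bundle.ieeg.rate),
                     "channels": [str(c) for c in bundle.ieeg.channels],
                     "regions": {str(k): v for k, v in bundle.ieeg.regions.items()},
                     "intervals": [[float(a), float(b)] for a, b in bundle.ieeg.intervals]},
            "trials": {"file": "trials.csv"},
        },
    }
    with open(d / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def read_session(dir_path, config: dict | None = None) -> SessionBundle:
    """Read a session directory written by :func:`write_session`.

    ``config`` overrides manifest entries (rates, room) if given.  Raises
    :class:`SessionError` naming the missing file or first offending sample
    when a stream violates an invariant.
    """
    d = Path(dir_path)
    mf_path = d / "manifest.yaml"
    if not mf_path.exists():
        raise SessionError(f"missing manifest: {mf_path}")
    with open(mf_path) as fh:
        manifest = yaml.safe_load(fh)
    if config:
        manifest = {**manifest, **config}
    streams = manifest["streams"]

    def _require(name):
        p = d / streams[name]["file"]
        if not p.exists():
            raise SessionError(f"missing stream file for {name!r}: {p}")
        return p

    gz = pd.read_csv(_require("gaze"), float_precision="round_trip")
    gaze = TimeSeries2D(gz["t"].values, gz["x"].values, gz["y"].values,
                        rate=float(streams["gaze"]["rate_hz"]),
                        valid=gz["valid"].values.astype(bool))
    ps = pd.read_csv(_require("position"), float_precision="round_trip")
    body = TimeSeries2D(ps["t"].values, ps["x"].values, ps["y"].values,
                        rate=float(streams["position"]["rate_hz"]))
    ie = pd.read_csv(_require("ieeg"), float_precision="round_trip")
    chans = [str(c) for c in streams["ieeg"]["channels"]]
    data = np.vstack([ie[c].values for c in chans])
    ieeg = IeegRecording(
        channels=chans, data=data, rate=float(streams["ieeg"]["rate_hz"]),
        intervals=[tuple(iv) for iv in streams["ieeg"]["intervals"]],
        regions=dict(streams["ieeg"].get("regions", {})),
    )
    trials = pd.read_csv(_require("trials"), float_precision="round_trip")
    if trials.empty:
        trials = pd.DataFrame(columns=TRIAL_COLUMNS)
    return SessionBundle(
        gaze=gaze, body=body, ieeg=ieeg, trials=trials,
        participant_id=str(manifest.get("participant_id", "P0")),
        room=tuple(manifest.get("room", DEFAULT_ROOM)),
    )


def slice_by_trials(bundle: SessionBundle, condition: str) -> dict:
    """Per-stream boolean masks marking samples inside trials of ``condition``.

    Samples outside all trials are False in both conditions' masks, so MC and
    VC masks are disjoint by construction.
    """
    if condition not in CONDITIONS:
        raise SessionError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    rows = bundle.trials[bundle.trials["condition"] == condition]
    spans = list(zip(rows["t_start"].values, rows["t_end"].values))

    def mask_for(t):
        m = np.zeros(len(t), dtype=bool)
        for a, b in spans:
            m |= (t >= a) & (t < b)
        return m

    return {
        "gaze": mask_for(bundle.gaze.t),
        "body": mask_for(bundle.body.t),
        "ieeg": mask_for(bundle.ieeg.times),
    }


def nearest_sample(t_query, t_stream):
    """Nearest-sample index lookup of query times into a stream's timestamps."""
    t_query = np.atleast_1d(np.asarray(t_query, dtype=float))
    idx = np.searchsorted(t_stream, t_query)
    idx = np.clip(idx, 1, len(t_stream) - 1)
    left = t_query - t_stream[idx - 1]
    right = t_stream[idx] - t_query
    out = np.where(left <= right, idx - 1, idx)
    return out if out.size > 1 else int(out[0])
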