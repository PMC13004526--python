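"""Synthetic session generator with known ground truth.

Emulates the four recorded streams of an ambulatory navigation session:

* gaze: alternating fixations (anchor + white noise) and minimum-jerk
  saccades with gamma-distributed durations anchored to the memory-cued
  condition means (saccade 89 ms, fixation 342 ms);
* iEEG: 1/f^alpha Gaussian background plus an ongoing theta oscillation whose
  amplitude can be multiplied by a gain in a window after each saccade onset
  (power locking, optionally restricted to one condition) and whose phase can
  be reset to a fixed angle at saccade onset (phase locking); interictal
  discharges injected as large biphasic transients with truth flags;
* body path: piecewise-linear walks between waypoints with controllable
  detour errors on memory-cued trials and a faster second half;
* trial table: alternating visually-cued / memory-cued trials.

Every generator is deterministic under its seed; one master seed expands to
per-stream child seeds via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import (
    DEFAULT_ROOM, GAZE_FRAME, IeegRecording, SessionBundle, TimeSeries2D,
)

# recording segments of the implant telemetry: ~3.5-4 min
SEGMENT_S = 225.0


@dataclass
class GazeGenParams:
    rate_hz: float = 200.0
    mean_fixation_ms: float = 342.0
    mean_saccade_ms: float = 89.0
    # gamma shape parameters for the two duration distributions (the source
    # distributions are not published; gamma keeps durations positive and
    # right-skewed, matching typical oculomotor statistics)
    fixation_shape: float = 4.0
    saccade_shape: float = 6.0
    min_duration_ms: float = 20.0
    amplitude_mean_px: float = 20.0
    amplitude_shape: float = 2.5
    amplitude_min_px: float = 5.0
    noise_sd_px: float = 0.3

    def __post_init__(self):
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be > 0")
        if min(self.mean_fixation_ms, self.mean_saccade_ms) <= 0:
            raise ValueError("durations must be positive")


@dataclass
class NeuralGenParams:
    rate_hz: float = 250.0
    background_slope: float = 1.0          # 1/f^alpha
    theta_freq_hz: float = 6.5
    theta_amp: float = 1.0                 # baseline theta amplitude (bg SD units)
    power_lock_gain: float = 1.0           # amplitude gain in post-saccade window
    power_lock_window_s: tuple = (0.0, 0.2)
    power_lock_condition: str | None = None  # None = all saccades; "MC"/"VC"
    phase_lock: bool = False
    phase_lock_angle: float = 0.0          # reset phase (rad) at saccade onset
    gamma_level: float = 0.0               # optional 60 Hz component amplitude
    ied_rate_hz: float = 0.05
    ied_amp_sd: float = 10.0               # IED amplitude in background-SD units
    noise_sd: float = 1.0                  # background SD

    def __post_init__(self):
        if self.power_lock_gain < 0 or self.gamma_level < 0:
            raise ValueError("gains must be >= 0")
        if not 0 <= self.ied_rate_hz:
            raise ValueError("ied_rate_hz must be >= 0")


@dataclass
class GroundTruth:
    """Per-stream truth labels for one synthetic session."""

    gaze_labels: np.ndarray = None          # per-gaze-sample {"fixation","saccade"}
    saccades: pd.DataFrame = None           # onset_s, offset_s, displacement_px
    ied_flags: np.ndarray = None            # (n_channels, n_ieeg_samples) bool
    trial_detour: pd.DataFrame = None       # trial_id, detour_error_pct
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# gaze
# ---------------------------------------------------------------------------

def _minimum_jerk(n):
    """Normalized minimum-jerk position profile on n samples (0 -> 1)."""
    tau = np.linspace(0.0, 1.0, n)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def gen_gaze(params: GazeGenParams, duration_s: float, seed=0):
    """Generate a gaze trace of alternating fixations and saccades.

    Returns ``(TimeSeries2D, GroundTruth)`` where the truth carries per-sample
    labels and the saccade event table (onset, offset, endpoint displacement).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = np.random.default_rng(seed)
    rate = params.rate_hz
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate

    x = np.empty(n)
    y = np.empty(n)
    labels = np.empty(n, dtype=object)
    events = []

    pos = np.array([GAZE_FRAME / 2, GAZE_FRAME / 2])
    lo, hi = params.amplitude_min_px, GAZE_FRAME - params.amplitude_min_px
    i = 0
    state = "fixation"
    while i < n:
        if state == "fixation":
            dur_ms = max(params.min_duration_ms,
                         rng.gamma(params.fixation_shape,
                                   params.mean_fixation_ms / params.fixation_shape))
            m = min(n - i, max(2, int(round(dur_ms / 1000 * rate))))
            x[i:i + m] = pos[0]
            y[i:i + m] = pos[1]
            labels[i:i + m] = "fixation"
            i += m
            state = "saccade"
        else:
            dur_ms = max(params.min_duration_ms,
                         rng.gamma(params.saccade_shape,
                                   params.mean_saccade_ms / params.saccade_shape))
            m = min(n - i, max(3, int(round(dur_ms / 1000 * rate))))
            amp = max(params.amplitude_min_px,
                      rng.gamma(params.amplitude_shape,
                                params.amplitude_mean_px / params.amplitude_shape))
            theta = rng.uniform(0, 2 * np.pi)
            target = pos + amp * np.array([np.cos(theta), np.sin(theta)])
            # reflect off the frame border so gaze stays in the frame
            target = np.where(target < lo, 2 * lo - target, target)
            target = np.where(target > hi, 2 * hi - target, target)
            prof = _minimum_jerk(m)
            x[i:i + m] = pos[0] + prof * (target[0] - pos[0])
            y[i:i + m] = pos[1] + prof * (target[1] - pos[1])
            labels[i:i + m] = "saccade"
            if i + m <= n:
                events.append({
                    "onset_s": t[i],
                    "offset_s": t[min(i + m, n) - 1] + 1 / rate,
                    "displacement_px": float(np.linalg.norm(target - pos)),
                })
            pos = target
            i += m
            state = "fixation"

    x += rng.normal(0, params.noise_sd_px, n)
    y += rng.normal(0, params.noise_sd_px, n)
    gaze = TimeSeries2D(t, x, y, rate=rate)
    truth = GroundTruth(
        gaze_labels=labels,
        saccades=pd.DataFrame(events, columns=["onset_s", "offset_s", "displacement_px"]),
        params={"gaze": params},
    )
    return gaze, truth


# ---------------------------------------------------------------------------
# iEEG
# ---------------------------------------------------------------------------

def powerlaw_noise(n, rate, alpha, rng, sd=1.0):
    """Gaussian noise with a 1/f^alpha power spectrum, unit variance * sd."""
    white = rng.standard_normal(n)
    if alpha == 0:
        return sd * white
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.ones_like(f)
    shaping[1:] = f[1:] ** (-alpha / 2.0)
    shaping[0] = 0.0
    shaped = np.fft.irfft(np.fft.rfft(white) * shaping, n)
    shaped /= shaped.std()
    return sd * shaped


def _ied_waveform(rate, dur_s=0.1):
    """Biphasic spike: derivative-of-Gaussian, unit peak amplitude."""
    m = int(round(dur_s * rate))
    tt = np.linspace(-1, 1, m)
    w = -tt * np.exp(-4 * tt**2)
    return w / np.abs(w).max()


def _segment_intervals(duration_s, segment_s=SEGMENT_S):
    """Split a session into recording intervals of at most ``segment_s``."""
    out, t0 = [], 0.0
    while duration_s - t0 > 1e-9:
        out.append((t0, min(t0 + segment_s, duration_s)))
        t0 += segment_s
    return out


def gen_ieeg(params: NeuralGenParams, gaze_truth: GroundTruth,
             trials: pd.DataFrame | None, n_channels: int, duration_s: float,
             seed=0):
    """Generate multichannel iEEG with saccade-locked theta structure.

    Each channel is an independent 1/f^alpha background plus one theta
    oscillator.  With ``power_lock_gain`` g, the theta amplitude is multiplied
    by g inside ``power_lock_window_s`` after every saccade onset (restricted
    to ``power_lock_condition`` trials when set).  With ``phase_lock``, the
    oscillator phase is reset to ``phase_lock_angle`` at every saccade onset.
    IEDs are injected as biphasic transients with truth flags.
    """
    rng = np.random.default_rng(seed)
    rate = params.rate_hz
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    onsets = (np.asarray(gaze_truth.saccades["onset_s"], dtype=float)
              if gaze_truth is not None and len(gaze_truth.saccades) else np.empty(0))
    onsets = onsets[onsets < duration_s]

    # which saccade onsets carry the power-locked gain
    lock_onsets = onsets
    if params.power_lock_condition is not None and trials is not None and len(trials):
        rows = trials[trials["condition"] == params.power_lock_condition]
        keep = np.zeros(len(onsets), dtype=bool)
        for a, b in zip(rows["t_start"].values, rows["t_end"].values):
            keep |= (onsets >= a) & (onsets < b)
        lock_onsets = onsets[keep]

    # theta amplitude envelope shared across channels
    envelope = np.full(n, params.theta_amp)
    w0, w1 = params.power_lock_window_s
    for on in lock_onsets:
        i0 = int(round((on + w0) * rate))
        i1 = int(round((on + w1) * rate))
        envelope[max(i0, 0):min(i1, n)] = params.theta_amp * params.power_lock_gain

    # theta phase: advances at 2*pi*f, reset at saccade onsets if phase-locked
    phase = 2 * np.pi * params.theta_freq_hz * t + rng.uniform(0, 2 * np.pi)
    if params.phase_lock and len(onsets):
        onset_idx = np.minimum((onsets * rate).round().astype(int), n - 1)
        seg_starts = np.concatenate([[0], onset_idx])
        base = 2 * np.pi * params.theta_freq_hz * t
        offs = np.empty(n)
        # piecewise-constant phase offset so phase(onset) == phase_lock_angle
        for s0, s1 in zip(seg_starts, np.concatenate([seg_starts[1:], [n]])):
            if s0 == 0 and s0 not in onset_idx:
                offs[s0:s1] = rng.uniform(0, 2 * np.pi)
            else:
                offs[s0:s1] = params.phase_lock_angle - base[s0]
        phase = base + offs

    ied_w = _ied_waveform(rate)
    data = np.empty((n_channels, n))
    flags = np.zeros((n_channels, n), dtype=bool)
    for c in range(n_channels):
        bg = powerlaw_noise(n, rate, params.background_slope, rng, sd=params.noise_sd)
        sig = bg + envelope * np.sin(phase)
        if params.gamma_level > 0:
            sig = sig + params.gamma_level * np.sin(
                2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))
        n_ied = rng.poisson(params.ied_rate_hz * duration_s)
        for _ in range(n_ied):
            i0 = rng.integers(0, max(1, n - len(ied_w)))
            amp = params.ied_amp_sd * params.noise_sd * rng.uniform(0.8, 1.2)
            sig[i0:i0 + len(ied_w)] += amp * ied_w * rng.choice([-1, 1])
            flags[c, i0:i0 + len(ied_w)] = True
        data[c] = sig

    rec = IeegRecording(
        channels=[f"ch{c + 1}" for c in range(n_channels)],
        data=data, rate=rate, intervals=_segment_intervals(duration_s),
        regions={f"ch{c + 1}": "HPP" for c in range(n_channels)},
    )
    truth = GroundTruth(ied_flags=flags, params={"neural": params})
    return rec, truth


# ---------------------------------------------------------------------------
# trials + body path
# ---------------------------------------------------------------------------

def _zigzag_waypoints(pos, target, walked, room, rng, margin=0.05):
    """Waypoints of a triangle-wave walk from pos to target of exact length.

    A zigzag of m peaks with lateral amplitude a = sqrt(walked^2 -
    straight^2) / (2 m) realizes the requested walked distance exactly; m is
    chosen so the peaks stay inside the room on the roomier side of the
    straight line.
    """
    pos, target = np.asarray(pos, float), np.asarray(target, float)
    straight = float(np.linalg.norm(target - pos))
    u = (target - pos) / straight
    perp = np.array([-u[1], u[0]])
    amp_total = np.sqrt(max(walked**2 - straight**2, 0.0))
    w, d = room

    def clearance(v):
        """Worst-case room clearance of the straight line in direction v."""
        best = np.inf
        for frac in np.linspace(0.1, 0.9, 9):
            p = pos + frac * straight * u
            step = np.inf
            for comp, lo, hi in ((0, margin, w - margin), (1, margin, d - margin)):
                if v[comp] > 1e-12:
                    step = min(step, (hi - p[comp]) / v[comp])
                elif v[comp] < -1e-12:
                    step = min(step, (lo - p[comp]) / v[comp])
            best = min(best, step)
        return max(best, 0.0)

    c_plus, c_minus = clearance(perp), clearance(-perp)
    side = perp if c_plus >= c_minus else -perp
    a_feas = max(c_plus, c_minus, 0.1)
    m = max(1, int(np.ceil(amp_total / (2 * 0.95 * a_feas))))
    a = amp_total / (2 * m)
    pts = [pos]
    for i in range(m):
        peak = pos + (i + 0.5) / m * straight * u + a * side
        pts.append(peak)
        pts.append(pos + (i + 1) / m * straight * u)
    pts[-1] = target
    return pts


def gen_trials_and_path(room=DEFAULT_ROOM, n_trials=10, detour_spec=None,
                        seed=0, rate_hz=120.0, trial_s=20.0, gap_s=1.0,
                        second_half_speedup=1.5):
    """Alternating VC/MC trials with piecewise-linear walks.

    ``detour_spec`` gives the true detour error (percent) of each MC trial;
    the walk inserts a lateral detour waypoint so that walked distance equals
    ``straight * (1 + e/100)`` exactly.  The second half of each trial is
    walked faster by ``second_half_speedup`` (speed ratio second/first half).
    """
    if n_trials % 2:
        raise ValueError("n_trials must be even (MC/VC alternation)")
    rng = np.random.default_rng(seed)
    n_mc = n_trials // 2
    if detour_spec is None:
        detour_spec = rng.gamma(2.0, 15.0, n_mc)      # mean 30% detour
    detour_spec = np.asarray(detour_spec, dtype=float)
    if len(detour_spec) != n_mc:
        raise ValueError("detour_spec must have one entry per MC trial")

    margin = 0.4
    w, d = room

    def rand_point():
        return np.array([rng.uniform(margin, w - margin),
                         rng.uniform(margin, d - margin)])

    rows, t_pieces, xy_pieces = [], [], []
    pos = rand_point()
    t_clock = 0.0
    mc_i = 0
    for k in range(n_trials):
        cond = "VC" if k % 2 == 0 else "MC"
        target = rand_point()
        while np.linalg.norm(target - pos) < 1.0:
            target = rand_point()
        straight = float(np.linalg.norm(target - pos))
        if cond == "MC":
            err = detour_spec[mc_i]
            mc_i += 1
            walked = straight * (1 + err / 100.0)
            if err > 0:
                waypoints = _zigzag_waypoints(pos, target, walked, (w, d), rng)
                walked = float(sum(np.linalg.norm(b - a) for a, b in
                                   zip(waypoints[:-1], waypoints[1:])))
            else:
                waypoints = [pos, target]
        else:
            walked = straight
            waypoints = [pos, target]

        # arc-length parameterization, then a two-speed time warp
        seglen = [np.linalg.norm(b - a) for a, b in zip(waypoints[:-1], waypoints[1:])]
        total = sum(seglen)
        n_samp = max(4, int(round(trial_s * rate_hz)))
        # fraction of path covered as a function of normalized time:
        # slower first half (u<0.5), faster second half, ratio = speedup
        u = np.arange(n_samp) / n_samp
        r = second_half_speedup
        frac = np.where(u < 0.5, u / (0.5 * (1 + r)) * 1.0,
                        (0.5 + (u - 0.5) * r) / (0.5 * (1 + r)))
        s = frac * total
        # map arc length to xy
        cum = np.concatenate([[0], np.cumsum(seglen)])
        xy = np.empty((n_samp, 2))
        for j in range(len(seglen)):
            m = (s >= cum[j]) & (s <= cum[j + 1] + 1e-12)
            if seglen[j] > 0:
                frac_seg = (s[m] - cum[j]) / seglen[j]
            else:
                frac_seg = np.zeros(m.sum())
            xy[m] = waypoints[j] + frac_seg[:, None] * (waypoints[j + 1] - waypoints[j])
        tt = t_clock + np.arange(n_samp) / rate_hz
        t_pieces.append(tt)
        xy_pieces.append(xy)
        rows.append({
            "trial_id": k + 1, "condition": cond,
            "t_start": t_clock, "t_end": t_clock + trial_s,
            "target_id": f"T{k % 3 + 1}" if cond == "MC" else f"sign{k % 20 + 1}",
            "walked_distance": walked, "straight_distance": straight,
        })
        pos = target
        t_clock += trial_s + gap_s
        # stand still during the inter-trial gap
        n_gap = int(round(gap_s * rate_hz))
        if n_gap and k < n_trials - 1:
            t_pieces.append(rows[-1]["t_end"] + np.arange(n_gap) / rate_hz)
            xy_pieces.append(np.tile(pos, (n_gap, 1)))

    t = np.concatenate(t_pieces)
    xy = np.vstack(xy_pieces)
    body = TimeSeries2D(t, xy[:, 0], xy[:, 1], rate=rate_hz)
    trials = pd.DataFrame(rows)
    return trials, body


# ---------------------------------------------------------------------------
# whole session
# ---------------------------------------------------------------------------

def gen_session(seed=0, duration_s=240.0, n_channels=3, n_trials=None,
                gaze_params: GazeGenParams | None = None,
                neural_params: NeuralGenParams | None = None,
                participant_id="P1", room=DEFAULT_ROOM,
                detour_spec=None):
    """Generate one complete SessionBundle plus its GroundTruth.

    The master seed expands to independent per-stream child seeds so streams
    can be regenerated in isolation.
    """
    ss = np.random.SeedSequence(seed)
    s_gaze, s_ieeg, s_path = [int(c.generate_state(1)[0] % 2**31)
                              for c in ss.spawn(3)]
    gaze_params = gaze_params or GazeGenParams()
    neural_params = neural_params or NeuralGenParams()

    trial_s, gap_s = 20.0, 1.0
    if n_trials is None:
        n_trials = max(2, 2 * int(duration_s // (2 * (trial_s + gap_s))))
    trials, body = gen_trials_and_path(room=room, n_trials=n_trials, seed=s_path,
                                       trial_s=trial_s, gap_s=gap_s,
                                       detour_spec=detour_spec)
    duration_s = max(duration_s, float(trials["t_end"].iloc[-1]))

    gaze, g_truth = gen_gaze(gaze_params, duration_s, seed=s_gaze)
    ieeg, n_truth = gen_ieeg(neural_params, g_truth, trials, n_channels,
                             duration_s, seed=s_ieeg)

    mc = trials[trials["condition"] == "MC"]
    detour = pd.DataFrame({
        "trial_id": mc["trial_id"].values,
        "detour_error_pct": 100 * (mc["walked_distance"].values
                                   - mc["straight_distance"].values)
                                  / mc["straight_distance"].values,
    })
    truth = GroundTruth(
        gaze_labels=g_truth.gaze_labels,
        saccades=g_truth.saccades,
        ied_flags=n_truth.ied_flags,
        trial_detour=detour,
        params={"gaze": gaze_params, "neural": neural_params, "seed": seed},
    )
    bundle = SessionBundle(gaze=gaze, body=body, ieeg=ieeg, trials=trials,
                           participant_id=participant_id, room=room)
    return bundle, truth
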