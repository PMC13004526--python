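"""Eye-movement classification, event bookkeeping, entropy, count windows."""

import numpy as np
import pytest

from thetagaze import eye, synth
from thetagaze.session import TimeSeries2D


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def test_linear_drift_constant_speed():
    rate = 200.0
    t = np.arange(400) / rate
    gaze = TimeSeries2D(t, 50 + 10 * t, np.full_like(t, 50.0), rate=rate)
    f = eye.compute_kinematics(gaze, smooth_window_s=0.0)
    core = slice(5, -5)
    assert np.allclose(f.speed[core], 10.0, atol=1e-9)
    assert np.allclose(f.accel[core], 0.0, atol=1e-6)


def test_stationary_gaze_zero_speed():
    rate = 200.0
    t = np.arange(200) / rate
    gaze = TimeSeries2D(t, np.full_like(t, 96.0), np.full_like(t, 96.0), rate=rate)
    f = eye.compute_kinematics(gaze)
    assert np.allclose(f.speed, 0.0)


def test_speed_peak_at_truth_saccade_midpoints():
    gp = synth.GazeGenParams(noise_sd_px=0.0)
    gaze, truth = synth.gen_gaze(gp, 20.0, seed=7)
    f = eye.compute_kinematics(gaze, smooth_window_s=0.0)
    hits = 0
    for _, r in truth.saccades.iterrows():
        i0 = int(round(r["onset_s"] * gp.rate_hz))
        i1 = int(round(r["offset_s"] * gp.rate_hz))
        mid = (i0 + i1) / 2
        peak = i0 + np.argmax(f.speed[i0:i1])
        hits += abs(peak - mid) <= 2
    assert hits / len(truth.saccades) > 0.9


def test_too_few_valid_samples():
    t = np.arange(10) / 200.0
    gaze = TimeSeries2D(t, np.zeros(10), np.zeros(10), rate=200.0,
                        valid=np.zeros(10, dtype=bool))
    with pytest.raises(ValueError):
        eye.compute_kinematics(gaze)


# ---------------------------------------------------------------------------
# classification against generator truth
# ---------------------------------------------------------------------------

def test_classification_accuracy_zero_noise():
    gp = synth.GazeGenParams(noise_sd_px=0.0)
    gaze, truth = synth.gen_gaze(gp, 60.0, seed=5)
    f = eye.compute_kinematics(gaze, smooth_window_s=0.0)
    labels = eye.classify_samples(f, seed=0)
    acc = np.mean(labels.label == truth.gaze_labels)
    # one sample per event boundary is kinematically ambiguous by
    # construction, which caps attainable accuracy just below 99%
    assert acc >= 0.98


def test_classification_accuracy_default_noise(default_session, classified):
    _, truth = default_session
    _, labels = classified
    acc = np.mean(labels.label == truth.gaze_labels)
    assert acc >= 0.95
    onsets_pred = labels.events.loc[labels.events["kind"] == "saccade",
                                    "onset_s"].values
    errs = [np.min(np.abs(onsets_pred - o))
            for o in truth.saccades["onset_s"].values]
    assert np.median(errs) * 200.0 <= 1.0 + 1e-9


def test_pure_fixation_trace():
    gp = synth.GazeGenParams(mean_fixation_ms=1e7)
    gaze, _ = synth.gen_gaze(gp, 30.0, seed=6)
    f = eye.compute_kinematics(gaze)
    labels = eye.classify_samples(f, seed=0)
    assert np.mean(labels.label == "fixation") >= 0.99


def test_scale_invariance_of_classification(default_session):
    """Uniformly rescaling gaze coordinates leaves labels unchanged
    (features are standardized)."""
    bundle, _ = default_session
    g = bundle.gaze
    scaled = TimeSeries2D(g.t, 3.0 * g.x, 3.0 * g.y, rate=g.rate, valid=g.valid)
    l1 = eye.classify_samples(eye.compute_kinematics(g), seed=0)
    l2 = eye.classify_samples(eye.compute_kinematics(scaled), seed=0)
    assert np.mean(l1.label == l2.label) > 0.999


def test_invalid_samples_stay_invalid(default_session):
    bundle, _ = default_session
    g = bundle.gaze
    valid = g.valid.copy()
    valid[1000:1200] = False
    g2 = TimeSeries2D(g.t, g.x, g.y, rate=g.rate, valid=valid)
    labels = eye.classify_samples(eye.compute_kinematics(g2), seed=0)
    assert (labels.label[1000:1200] == "invalid").all()


# ---------------------------------------------------------------------------
# event table duality and metrics
# ---------------------------------------------------------------------------

def test_label_event_duality(classified):
    _, labels = classified
    rebuilt = eye.labels_from_events(labels.events, len(labels.label))
    assert (rebuilt == labels.label).all()


def test_event_metrics_frequency_definition():
    """10 saccade onsets in 5 s of condition time -> 2.0 Hz."""
    rate = 200.0
    n = int(5 * rate)
    label = np.array(["fixation"] * n, dtype=object)
    for k in range(10):
        i = 50 + k * 95
        label[i:i + 10] = "saccade"
    t = np.arange(n) / rate
    labels = eye.SampleLabels(t=t, label=label)
    m = eye.event_metrics(labels, condition_mask=np.ones(n, dtype=bool))
    assert m["saccade_frequency_hz"] == pytest.approx(2.0)
    assert m["saccade_duration_ms"] == pytest.approx(50.0)


def test_event_metrics_recover_generator_means(default_session, classified):
    _, truth = default_session
    _, labels = classified
    m = eye.event_metrics(labels)
    # default generator anchors MC means: saccade 89 ms, fixation 342 ms
    assert m["saccade_duration_ms"] == pytest.approx(89.0, rel=0.25)
    assert m["fixation_duration_ms"] == pytest.approx(342.0, rel=0.25)


def test_event_metrics_all_fixation_missing_saccade_stats():
    t = np.arange(1000) / 200.0
    labels = eye.SampleLabels(t=t, label=np.array(["fixation"] * 1000, dtype=object))
    m = eye.event_metrics(labels)
    assert m["saccade_frequency_hz"] == 0.0
    assert np.isnan(m["saccade_duration_ms"])


# ---------------------------------------------------------------------------
# entropy + count windows
# ---------------------------------------------------------------------------

def test_entropy_closed_forms():
    rate = 200.0
    t = np.arange(int(2 * rate)) / rate
    # all samples in one bin -> 0 bits
    g0 = TimeSeries2D(t, np.full_like(t, 10.0), np.full_like(t, 10.0), rate=rate)
    _, H0 = eye.scanpath_entropy(g0, window_s=1.0, step_s=0.5)
    assert np.allclose(H0[np.isfinite(H0)], 0.0)
    # two bins with p=(.5,.5) -> 1 bit
    x = np.where(np.arange(len(t)) % 2 == 0, 10.0, 100.0)
    g1 = TimeSeries2D(t, x, np.full_like(t, 10.0), rate=rate)
    _, H1 = eye.scanpath_entropy(g1, window_s=1.0, step_s=0.5)
    assert np.allclose(H1[np.isfinite(H1)], 1.0)


def test_entropy_uniform_900_bins():
    """Uniform occupancy of all 30 x 30 bins -> log2(900) ~ 9.814 bits."""
    rate = 1000.0
    n = 2700
    t = np.arange(n) / rate
    # cycle through all 900 bin centers with period 900 samples, so any
    # interior 0.9 s window holds each bin exactly once
    gx, gy = np.meshgrid(np.arange(30), np.arange(30))
    cx = (gx.ravel() + 0.5) * (192.0 / 30)
    cy = (gy.ravel() + 0.5) * (192.0 / 30)
    x = np.tile(cx, 3)[:n]
    y = np.tile(cy, 3)[:n]
    g = TimeSeries2D(t, x, y, rate=rate)
    _, H = eye.scanpath_entropy(g, window_s=0.9, step_s=1.0)
    assert H[0] == pytest.approx(np.log2(900), abs=1e-6)


def test_entropy_rejects_bad_window(default_session):
    bundle, _ = default_session
    with pytest.raises(ValueError):
        eye.scanpath_entropy(bundle.gaze, window_s=0.0)


def test_saccade_count_windows_bookkeeping(classified):
    _, labels = classified
    centers, counts = eye.saccade_count_windows(labels, window_s=1.0, step_s=0.5)
    onsets = labels.events.loc[labels.events["kind"] == "saccade", "onset_s"]
    # non-overlapping windows (step == window) tile the count exactly
    c2, k2 = eye.saccade_count_windows(labels, window_s=1.0, step_s=1.0)
    inside = (onsets >= c2[0] - 0.5) & (onsets < c2[-1] + 0.5)
    assert k2.sum() == inside.sum()
    # single-saccade sanity
    t = np.arange(400) / 200.0
    lab = np.array(["fixation"] * 400, dtype=object)
    lab[100:110] = "saccade"
    sl = eye.SampleLabels(t=t, label=lab)
    c, k = eye.saccade_count_windows(sl, window_s=1.0, step_s=1.0)
    assert k.sum() == 1


def test_median_split_balance():
    rng = np.random.default_rng(3)
    v = rng.standard_normal(101)
    high = eye.median_split(v)
    assert abs(high.sum() - (~high).sum()) <= 1
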