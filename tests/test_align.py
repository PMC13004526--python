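"""Peri-saccade epoching rules, normalization, phase extraction, PPC."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import i0, i1

from thetagaze import align, synth
from thetagaze.session import IeegRecording

RATE = 250.0


def _events(rows):
    out = []
    for i, (kind, a, b) in enumerate(rows):
        out.append({"event_id": i + 1, "kind": kind, "onset_s": a, "offset_s": b,
                    "duration_ms": (b - a) * 1000, "displacement": 1.0,
                    "i_start": int(a * 200), "i_end": int(b * 200)})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# epoching rules
# ---------------------------------------------------------------------------

def test_isolated_saccade_full_epoch_76_points(rng):
    x = rng.standard_normal(int(10 * RATE))
    t = np.arange(len(x)) / RATE
    ev = _events([("fixation", 4.0, 5.0), ("saccade", 5.0, 5.2),
                  ("fixation", 5.2, 6.0)])
    tensor = align.epoch_power(x, t, ev, RATE)
    assert tensor.values.shape == (1, 76)          # -100..+200 ms at 4 ms
    assert tensor.validity.all()                   # 200 ms saccade: fully valid


def test_post_onset_validity_ends_at_offset(rng):
    """A 64 ms saccade (the real-data median duration) contributes no
    post-onset samples beyond +64 ms."""
    x = rng.standard_normal(int(10 * RATE))
    t = np.arange(len(x)) / RATE
    ev = _events([("fixation", 4.0, 5.0), ("saccade", 5.0, 5.064),
                  ("fixation", 5.064, 6.0)])
    tensor = align.epoch_power(x, t, ev, RATE)
    post = tensor.time_ms > 64.0 + 1e-9
    assert not tensor.validity[0, post].any()
    assert tensor.validity[0, (tensor.time_ms >= 0) & (tensor.time_ms <= 64)].all()


def test_prior_saccade_invalidates_pre_window(rng):
    """Two saccades 50 ms apart: the second epoch's -100..-50 ms is invalid."""
    x = rng.standard_normal(int(10 * RATE))
    t = np.arange(len(x)) / RATE
    ev = _events([("saccade", 4.90, 4.95), ("fixation", 4.95, 5.0),
                  ("saccade", 5.0, 5.2), ("fixation", 5.2, 6.0)])
    tensor = align.epoch_power(x, t, ev, RATE)
    second = tensor.validity[1]
    early = tensor.time_ms < -50.0
    mid = (tensor.time_ms >= -48.0) & (tensor.time_ms < 0)
    assert not second[early].any()
    assert second[mid].all()


def test_event_counts_nonincreasing_after_onset(default_session, classified):
    """Later post-onset time points aggregate fewer saccades (variable
    durations), matching the bookkeeping contract."""
    from thetagaze import eye, ied, spectral
    bundle, _ = default_session
    _, labels = classified
    m = ied.detect_ied(bundle.ieeg)
    stack = spectral.zscore_power(
        spectral.wavelet_power(bundle.ieeg, freqs=np.array([6.0, 6.5, 7.0])),
        mask=m.mask)
    theta = spectral.band_power(stack, (6.0, 7.0))
    tensor = align.epoch_power(theta[0], bundle.ieeg.times, labels.events,
                               RATE, mask=m.mask[0])
    counts = tensor.event_counts()
    post = counts[tensor.time_ms >= 0]
    assert (np.diff(post) <= 0).all()


def test_masked_epochs_dropped(rng):
    x = rng.standard_normal(int(10 * RATE))
    t = np.arange(len(x)) / RATE
    mask = np.zeros(len(x), dtype=bool)
    mask[int(5.05 * RATE)] = True
    ev = _events([("fixation", 4.0, 5.0), ("saccade", 5.0, 5.2),
                  ("fixation", 5.2, 6.0),
                  ("fixation", 7.0, 8.0), ("saccade", 8.0, 8.2)])
    tensor = align.epoch_power(x, t, ev, RATE, mask=mask, drop_masked="drop")
    assert tensor.n_events == 1                    # first epoch touches the mask


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_normalize_reference_and_shift_invariance(rng):
    x = rng.standard_normal(int(20 * RATE))
    t = np.arange(len(x)) / RATE
    ev = _events([("fixation", 4.0, 5.0), ("saccade", 5.0, 5.2),
                  ("fixation", 5.2, 6.0)])
    ref = align.pooled_reference(x)
    tensor = align.normalize_epochs(align.epoch_power(x, t, ev, RATE), ref)
    # applying the reference to the reference series itself centers it
    assert (x - ref[0]).mean() / ref[1] == pytest.approx(0.0, abs=1e-12)
    # adding a constant to the power leaves normalized epochs unchanged
    ref2 = align.pooled_reference(x + 3.0)
    tensor2 = align.normalize_epochs(
        align.epoch_power(x + 3.0, t, ev, RATE), ref2)
    assert np.allclose(tensor.values, tensor2.values, atol=1e-9)
    with pytest.raises(ValueError):
        align.normalize_epochs(tensor, (0.0, 0.0))


# ---------------------------------------------------------------------------
# phase
# ---------------------------------------------------------------------------

def test_phase_of_pure_sinusoid_advances_linearly():
    t = np.arange(int(40 * RATE)) / RATE
    x = np.sin(2 * np.pi * 6.0 * t)
    rec = IeegRecording(channels=["c"], data=x[None, :], rate=RATE)
    ph = align.theta_phase(rec)[0]
    un = np.unwrap(ph[2000:-2000])
    slope = np.polyfit(t[2000:-2000], un, 1)[0]
    assert slope == pytest.approx(2 * np.pi * 6.0, rel=1e-3)
    # sign flip shifts phase by pi
    ph2 = align.theta_phase(IeegRecording(channels=["c"], data=-x[None, :],
                                          rate=RATE))[0]
    d = np.angle(np.exp(1j * (ph2 - ph)))[2000:-2000]
    assert np.allclose(np.abs(d), np.pi, atol=1e-6)


def test_phase_band_validation():
    rec = IeegRecording(channels=["c"], data=np.zeros((1, 10000)), rate=RATE)
    with pytest.raises(ValueError):
        align.theta_phase(rec, band=(5.0, 200.0))


def test_phase_locked_sessions_have_concentrated_onset_phase():
    """The generator's phase at onset is exactly the reset angle (checked at
    construction level elsewhere); the *measured* band-passed phase blurs
    across the short inter-saccade segments, but the onset-phase distribution
    must remain strongly concentrated (resultant length far above chance)."""
    p = synth.NeuralGenParams(noise_sd=0.05, theta_amp=1.0, phase_lock=True,
                              phase_lock_angle=0.0, ied_rate_hz=0.0)
    gaze, gtruth = synth.gen_gaze(synth.GazeGenParams(), 60.0, seed=8)
    rec, _ = synth.gen_ieeg(p, gtruth, None, 1, 60.0, seed=9)
    ph = align.theta_phase(rec)[0]
    idx = np.round(gtruth.saccades["onset_s"].values * RATE).astype(int)
    idx = idx[(idx > 2000) & (idx < rec.n_samples - 2000)]
    R = np.abs(np.mean(np.exp(1j * ph[idx])))
    # chance level for n~130 uniform phases is R ~ 1/sqrt(n) ~ 0.09
    assert R > 0.5


# ---------------------------------------------------------------------------
# PPC
# ---------------------------------------------------------------------------

def test_ppc_closed_form_equals_pairwise_sum(rng):
    for n in (2, 3, 10, 101):
        ph = rng.uniform(0, 2 * np.pi, n)
        assert align.ppc(ph) == pytest.approx(align.ppc_pairwise(ph), abs=1e-12)


def test_ppc_extremes():
    assert align.ppc(np.full(7, 1.3)) == pytest.approx(1.0, abs=1e-12)
    assert align.ppc(np.array([0.0, np.pi])) == pytest.approx(-1.0, abs=1e-12)
    with pytest.raises(ValueError):
        align.ppc(np.array([0.1]))


def test_ppc_rotation_invariance(rng):
    ph = rng.uniform(0, 2 * np.pi, 50)
    assert align.ppc(ph) == pytest.approx(align.ppc(ph + 1.234), abs=1e-12)


def test_ppc_von_mises_expectation(rng):
    """E[PPC] under von Mises(kappa=1) equals (I1/I0)^2 ~ 0.199 (Bessel
    oracle); uniform phases give 0 in expectation."""
    kappa = 1.0
    expected = (i1(kappa) / i0(kappa)) ** 2
    vals = [align.ppc(rng.vonmises(0.0, kappa, 100)) for _ in range(300)]
    sem = np.std(vals) / np.sqrt(len(vals))
    assert np.mean(vals) == pytest.approx(expected, abs=4 * sem + 0.005)
    vals0 = [align.ppc(rng.uniform(0, 2 * np.pi, 100)) for _ in range(300)]
    sem0 = np.std(vals0) / np.sqrt(len(vals0))
    assert np.mean(vals0) == pytest.approx(0.0, abs=4 * sem0 + 0.003)


def test_ppc_timecourse_windows(default_session, classified):
    from thetagaze import ied
    bundle, _ = default_session
    _, labels = classified
    m = ied.detect_ied(bundle.ieeg)
    ph = align.theta_phase(bundle.ieeg)
    res = align.ppc_timecourse(ph[0], bundle.ieeg.times, labels.events, RATE,
                               mask=m.mask[0])
    # time axis covers -800..+208 ms at 4 ms steps
    assert res.time_ms[0] == -800 and res.time_ms[-1] == 208
    assert len(res.time_ms) == 253
    assert res.n_events >= 2
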