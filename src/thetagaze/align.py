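"""Peri-saccade epoching, baseline normalization, and saccade-locked theta
phase consistency (PPC).

Power epochs cover -100..+200 ms around saccade onset at 4 ms resolution
(one iEEG sample at 250 Hz).  Pre-onset samples overlapping an earlier
saccade and post-onset samples beyond the saccade's own offset (i.e. into
the following fixation) are invalidated, so later time points aggregate
fewer events.  Phase epochs cover -800..+208 ms; only IED-masked samples
invalidate them, because the -800..-550 ms baseline window necessarily
contains earlier fixations and saccades.

PPC is the unbiased pairwise estimator: the mean cosine of all pairwise
phase differences across events, computed via the closed form
(N^2 R^2 - N) / (N (N - 1)) with R the resultant length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .session import IeegRecording

POWER_WINDOW_MS = (-100, 200)
PHASE_WINDOW_MS = (-800, 208)
STEP_MS = 4
PPC_SACCADE_WINDOW_MS = (-50, 200)
PPC_BASELINE_WINDOW_MS = (-800, -550)


@dataclass
class PeriSaccadeTensor:
    """event x time values aligned to saccade onset, with a validity mask."""

    values: np.ndarray          # (n_events, n_times)
    validity: np.ndarray        # (n_events, n_times) bool
    time_ms: np.ndarray
    onsets_s: np.ndarray

    @property
    def n_events(self):
        return self.values.shape[0]

    def event_counts(self):
        """Number of valid events contributing at each time point."""
        return self.validity.sum(axis=0)

    def mean_trace(self):
        """Across-event mean at each time point (valid samples only)."""
        v = np.where(self.validity, self.values, np.nan)
        with np.errstate(invalid="ignore"):
            return np.nanmean(v, axis=0)


@dataclass
class PpcResult:
    time_ms: np.ndarray
    ppc: np.ndarray
    n_events: int
    saccade_window_mean: float
    baseline_window_mean: float


def _window_samples(window_ms, rate):
    step = int(round(rate * STEP_MS / 1000.0))
    lo = int(round(window_ms[0] / 1000.0 * rate))
    hi = int(round(window_ms[1] / 1000.0 * rate))
    offs = np.arange(lo, hi + 1, step)
    return offs, offs / rate * 1000.0


def epoch_power(band_series: np.ndarray, times: np.ndarray, events: pd.DataFrame,
                rate: float, mask: np.ndarray | None = None,
                window_ms=POWER_WINDOW_MS, drop_masked="drop") -> PeriSaccadeTensor:
    """Extract peri-saccade power epochs with overlap-exclusion rules.

    ``band_series`` is one channel's band-power series on ``times``;
    ``events`` is the full event table (saccades and fixations) from the eye
    classifier.  Exclusions: pre-onset samples inside any earlier saccade,
    post-onset samples after the event's own offset, and (``drop_masked`` =
    "drop") whole epochs touching an IED-masked sample; with "sample",
    masked samples are invalidated individually instead.
    """
    sac = events[events["kind"] == "saccade"].reset_index(drop=True)
    if sac.empty:
        raise ValueError("no saccade events to epoch")
    offs, time_ms = _window_samples(window_ms, rate)
    t0 = times[0]
    onset_idx = np.round((sac["onset_s"].values - t0) * rate).astype(int)
    n = len(band_series)
    in_range = (onset_idx + offs[0] >= 0) & (onset_idx + offs[-1] < n)
    sac = sac[in_range]
    onset_idx = onset_idx[in_range]
    if sac.empty:
        raise ValueError("all saccade events fall outside the recorded series")

    idx = onset_idx[:, None] + offs[None, :]
    values = band_series[idx]
    validity = np.ones(idx.shape, dtype=bool)

    # times (s) of each epoch sample relative to session clock
    samp_t = t0 + idx / rate
    onsets = sac["onset_s"].values
    offsets = sac["offset_s"].values

    # post-onset beyond the saccade's own offset -> into following fixation
    # (a sample at exactly the offset time still belongs to the saccade)
    validity &= ~((samp_t > offsets[:, None] + 1e-9) & (offs[None, :] > 0))

    # pre-onset samples overlapping any earlier saccade
    all_on = events.loc[events["kind"] == "saccade", "onset_s"].values
    all_off = events.loc[events["kind"] == "saccade", "offset_s"].values
    pre = offs[None, :] < 0
    flat_t = samp_t.ravel()
    inside_prior = np.zeros(flat_t.shape, dtype=bool)
    j = np.searchsorted(all_on, flat_t, side="right") - 1
    ok = j >= 0
    inside_prior[ok] = flat_t[ok] < all_off[j[ok]]
    inside_prior = inside_prior.reshape(samp_t.shape)
    own = (samp_t >= onsets[:, None]) & (samp_t < offsets[:, None])
    validity &= ~(pre & inside_prior & ~own)

    # NaN samples (masked power) invalidate
    validity &= np.isfinite(values)

    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        hit = mask[idx]
        if drop_masked == "drop":
            keep = ~hit.any(axis=1)
            values, validity = values[keep], validity[keep]
            onsets = onsets[keep]
        else:
            validity &= ~hit
    return PeriSaccadeTensor(values=values, validity=validity,
                             time_ms=time_ms, onsets_s=onsets)


def pooled_reference(band_series: np.ndarray, mask: np.ndarray | None = None):
    """Mean/SD of the band series over unmasked samples, pooled across both
    task conditions and oculomotor states (the epoch-normalization baseline)."""
    x = np.asarray(band_series, dtype=float)
    if mask is not None:
        x = x[~np.asarray(mask, dtype=bool)]
    x = x[np.isfinite(x)]
    mu, sd = x.mean(), x.std()
    if sd == 0:
        raise ValueError("zero pooled variance in normalization reference")
    return mu, sd


def normalize_epochs(tensor: PeriSaccadeTensor, reference) -> PeriSaccadeTensor:
    """Express epoch values relative to a pooled (mean, SD) reference."""
    mu, sd = reference
    if sd == 0:
        raise ValueError("zero pooled variance")
    return PeriSaccadeTensor(values=(tensor.values - mu) / sd,
                             validity=tensor.validity.copy(),
                             time_ms=tensor.time_ms, onsets_s=tensor.onsets_s)


def theta_phase(ieeg: IeegRecording, band=(5.0, 8.0), numtaps=501) -> np.ndarray:
    """Instantaneous theta phase (radians) per channel and sample.

    Zero-phase FIR band-pass followed by the analytic signal, computed per
    recording interval.  Raises if the band cannot be realized at the
    recording rate.
    """
    ny = ieeg.rate / 2.0
    if not 0 < band[0] < band[1] < ny:
        raise ValueError(f"band {band} not realizable at rate {ieeg.rate}")
    taps = signal.firwin(numtaps, [band[0], band[1]], pass_zero=False, fs=ieeg.rate)
    phase = np.empty_like(ieeg.data)
    for c in range(ieeg.n_channels):
        for sl in ieeg.interval_slices():
            seg = ieeg.data[c, sl]
            if len(seg) <= 3 * numtaps:
                raise ValueError("interval too short for the phase filter")
            filt = signal.filtfilt(taps, [1.0], seg)
            phase[c, sl] = np.angle(signal.hilbert(filt))
    return phase


def ppc(phases: np.ndarray) -> float:
    """Pairwise phase consistency of a set of phases (unbiased estimator).

    Closed form (N^2 R^2 - N) / (N (N-1)) with R the resultant length; equals
    the mean cosine of all pairwise phase differences.
    """
    phases = np.asarray(phases, dtype=float)
    n = len(phases)
    if n < 2:
        raise ValueError("PPC requires at least 2 events")
    R = np.abs(np.mean(np.exp(1j * phases)))
    return (n**2 * R**2 - n) / (n * (n - 1))


def ppc_pairwise(phases: np.ndarray) -> float:
    """Brute-force pairwise-sum PPC: (2 / N(N-1)) sum_{j<k} cos(th_j - th_k).

    Kept as an independent oracle for the closed form used by :func:`ppc`.
    """
    phases = np.asarray(phases, dtype=float)
    n = len(phases)
    if n < 2:
        raise ValueError("PPC requires at least 2 events")
    total = 0.0
    for j in range(n - 1):
        total += np.cos(phases[j] - phases[j + 1:]).sum()
    return 2.0 * total / (n * (n - 1))


def ppc_timecourse(phase_series: np.ndarray, times: np.ndarray,
                   events: pd.DataFrame, rate: float,
                   mask: np.ndarray | None = None,
                   window_ms=PHASE_WINDOW_MS) -> PpcResult:
    """PPC across saccade events at each peri-onset time point.

    Only IED-masked samples invalidate phase epochs (the baseline window
    predates onset by over half a second, so the power-epoch fixation-overlap
    rule cannot apply).  Window means are reported for the saccade window
    (-50..+200 ms) and the equal-duration baseline (-800..-550 ms).
    """
    sac = events[events["kind"] == "saccade"]
    offs, time_ms = _window_samples(window_ms, rate)
    t0 = times[0]
    onset_idx = np.round((sac["onset_s"].values - t0) * rate).astype(int)
    n = len(phase_series)
    in_range = (onset_idx + offs[0] >= 0) & (onset_idx + offs[-1] < n)
    onset_idx = onset_idx[in_range]
    if len(onset_idx) < 2:
        raise ValueError("PPC requires at least 2 in-range events")
    idx = onset_idx[:, None] + offs[None, :]
    ph = phase_series[idx]
    valid = np.ones(idx.shape, dtype=bool)
    if mask is not None:
        keep = ~np.asarray(mask, dtype=bool)[idx].any(axis=1)
        ph, valid = ph[keep], valid[keep]
        if len(ph) < 2:
            raise ValueError("fewer than 2 unmasked events")

    out = np.empty(len(offs))
    for k in range(len(offs)):
        out[k] = ppc(ph[valid[:, k], k])

    def wmean(win):
        sel = (time_ms >= win[0]) & (time_ms <= win[1])
        return float(out[sel].mean())

    return PpcResult(time_ms=time_ms, ppc=out, n_events=ph.shape[0],
                     saccade_window_mean=wmean(PPC_SACCADE_WINDOW_MS),
                     baseline_window_mean=wmean(PPC_BASELINE_WINDOW_MS))
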