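"""Interictal epileptiform discharge (IED) detection and exclusion masking.

A double-threshold detector flags samples where either (1) the envelope of
the unfiltered signal, or (2) the envelope of the 15-80 Hz band-passed
signal, exceeds six standard deviations above baseline.  Baseline statistics
are computed per recording interval with robust estimators (median /
MAD-scaled SD) so the IEDs themselves do not inflate the threshold.  The
binary detection vector is then smeared with a 0.05 s Gaussian and every
sample whose smoothed value exceeds 0.01 joins the exclusion mask, removing
the residual activity around each discharge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d
from scipy.stats import median_abs_deviation

from .session import IeegRecording


@dataclass
class IedParams:
    sd_threshold: float = 6.0
    band: tuple = (15.0, 80.0)
    smooth_window_s: float = 0.05
    smooth_cutoff: float = 0.01
    robust_baseline: bool = True


@dataclass
class IedMask:
    """Per-channel exclusion mask aligned to iEEG samples."""

    mask: np.ndarray                       # (n_channels, n_samples) bool
    detections: np.ndarray                 # raw (pre-smear) detections
    params: IedParams = field(default_factory=IedParams)

    @property
    def excluded_fraction(self):
        return self.mask.mean(axis=1)


def _envelope(x):
    """Magnitude of the analytic signal."""
    return np.abs(signal.hilbert(x))


def _bandpass(x, band, rate):
    ny = rate / 2.0
    hi = min(band[1], 0.99 * ny)
    sos = signal.butter(4, [band[0] / ny, hi / ny], btype="band", output="sos")
    return signal.sosfiltfilt(sos, x)


def _baseline_stats(env, robust):
    if robust:
        mu = np.median(env)
        sd = median_abs_deviation(env, scale="normal")
    else:
        mu, sd = env.mean(), env.std()
    return mu, sd


def detect_ied(ieeg: IeegRecording, params: IedParams | None = None) -> IedMask:
    """Detect IEDs per channel; returns the smeared exclusion mask.

    Thresholds are computed separately within each recording interval.  A
    zero-variance channel yields no detections with a warning.
    """
    params = params or IedParams()
    n_ch, n = ieeg.n_channels, ieeg.n_samples
    detections = np.zeros((n_ch, n), dtype=bool)
    for c in range(n_ch):
        x = ieeg.data[c]
        for sl in ieeg.interval_slices():
            seg = x[sl]
            if len(seg) < ieeg.rate:  # < 1 s of data
                continue
            if seg.std() == 0:
                warnings.warn(f"zero-variance channel {ieeg.channels[c]}; no detections")
                continue
            env_raw = _envelope(seg)
            env_band = _envelope(_bandpass(seg, params.band, ieeg.rate))
            det = np.zeros(len(seg), dtype=bool)
            for env in (env_raw, env_band):
                mu, sd = _baseline_stats(env, params.robust_baseline)
                det |= env > mu + params.sd_threshold * sd
            detections[c, sl] = det
    return smear_mask(detections, params, rate=ieeg.rate)


def smear_mask(detections: np.ndarray, params: IedParams | None = None,
               rate: float = 250.0) -> IedMask:
    """Gaussian-smear binary detections into the final exclusion mask.

    The kernel has total length ``smooth_window_s`` with sigma = window/5
    (unit-sum, truncated); output mask = detections OR (smoothed > cutoff),
    so every detected run is strictly contained in its smeared run.
    """
    params = params or IedParams()
    detections = np.atleast_2d(np.asarray(detections, dtype=bool))
    sigma = params.smooth_window_s / 5.0 * rate       # samples
    truncate = (params.smooth_window_s * rate / 2.0) / max(sigma, 1e-9)
    smoothed = gaussian_filter1d(detections.astype(float), sigma=sigma,
                                 axis=1, mode="constant", truncate=truncate)
    mask = detections | (smoothed > params.smooth_cutoff)
    return IedMask(mask=mask, detections=detections, params=params)


def gaussian_kernel(params: IedParams, rate: float) -> np.ndarray:
    """The exact smoothing kernel used by :func:`smear_mask` (for oracles)."""
    sigma = params.smooth_window_s / 5.0 * rate
    truncate = (params.smooth_window_s * rate / 2.0) / max(sigma, 1e-9)
    half = int(truncate * sigma + 0.5)
    xx = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (xx / sigma) ** 2)
    return k / k.sum()


def apply_mask(series: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace masked samples with NaN so they drop out of downstream averages.

    ``series`` may be 1-D (samples) or 2-D (channels x samples) and must be
    aligned with ``mask`` on the sample axis.
    """
    series = np.asarray(series, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if series.shape[-1] != mask.shape[-1]:
        raise ValueError(
            f"apply_mask: series length {series.shape[-1]} != mask length {mask.shape[-1]}")
    out = series.copy()
    if out.ndim == 1 and mask.ndim == 2:
        mask = mask.any(axis=0)
    if out.ndim == mask.ndim:
        out[mask] = np.nan
    else:
        out[:, mask] = np.nan
    return out


def drop_overlapping_epochs(onset_idx: np.ndarray, pre: int, post: int,
                            mask_1d: np.ndarray) -> np.ndarray:
    """Keep only epochs [onset-pre, onset+post] that touch no masked sample."""
    onset_idx = np.asarray(onset_idx, dtype=int)
    keep = np.ones(len(onset_idx), dtype=bool)
    cum = np.concatenate([[0], np.cumsum(mask_1d.astype(int))])
    n = len(mask_1d)
    a = np.clip(onset_idx - pre, 0, n)
    b = np.clip(onset_idx + post + 1, 0, n)
    keep = (cum[b] - cum[a]) == 0
    return keep
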