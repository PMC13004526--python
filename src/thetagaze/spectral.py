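"""Morlet wavelet time-frequency power, per-interval z-scoring, band power,
and BOSC-style oscillation-bout detection.

Power is estimated with complex Morlet wavelets of a fixed number of cycles
(default 6; a 3-cycle control trades frequency for temporal resolution) on a
frequency grid of 2-30 Hz in 0.25 Hz steps and 31-80 Hz in 1 Hz steps (163
frequencies).  Power is z-scored per frequency, per recording interval, per
channel over unmasked samples.  Bout detection fits a 1/f background to the
log-log mean spectrum (robust Theil-Sen fit), thresholds power at the 95th
percentile of a chi-square(2) distribution scaled to the fitted background
mean, and requires bouts to last at least two cycles; Pepisode(f) is the
fraction of unmasked samples inside bouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .session import IeegRecording

BANDS = {"theta": (5.0, 8.0), "lowfreq": (3.0, 15.0), "gamma": (45.0, 80.0)}


def default_grid() -> np.ndarray:
    """2-30 Hz in 0.25 Hz steps + 31-80 Hz in 1 Hz steps (163 frequencies)."""
    return np.concatenate([np.arange(2.0, 30.0 + 1e-9, 0.25),
                           np.arange(31.0, 80.0 + 1e-9, 1.0)])


@dataclass
class SpectralStack:
    """time x frequency x channel power (and z-scored power)."""

    freqs: np.ndarray
    power: np.ndarray               # (n_channels, n_freqs, n_samples) linear
    zpower: np.ndarray = None       # same shape; NaN where masked/edge
    cycles: float = 6.0
    rate: float = 250.0
    edge_invalid: np.ndarray = None  # (n_freqs, n_samples) True near interval edges
    intervals: list = field(default_factory=list)
    interval_slices: list = field(default_factory=list)


def morlet_kernel(freq, rate, cycles, n_sigmas=3.5):
    """Unit-energy complex Morlet wavelet, sigma_t = cycles / (2 pi f)."""
    sigma_t = cycles / (2 * np.pi * freq)
    half = int(np.ceil(n_sigmas * sigma_t * rate))
    tt = np.arange(-half, half + 1) / rate
    k = np.exp(2j * np.pi * freq * tt) * np.exp(-tt**2 / (2 * sigma_t**2))
    k /= np.sqrt(np.sum(np.abs(k) ** 2))
    return k


def wavelet_power(ieeg: IeegRecording, freqs=None, cycles=6.0) -> SpectralStack:
    """Continuous Morlet wavelet power per sample at every grid frequency.

    Computed independently within each recording interval; samples within one
    wavelet half-support of an interval boundary are flagged unreliable in
    ``edge_invalid``.  Raises if any interval is shorter than the longest
    wavelet.
    """
    freqs = np.asarray(default_grid() if freqs is None else freqs, dtype=float)
    rate = ieeg.rate
    slices = ieeg.interval_slices()
    kernels = [morlet_kernel(f, rate, cycles) for f in freqs]
    longest = max(len(k) for k in kernels)
    for sl, (a, b) in zip(slices, ieeg.intervals):
        if sl.stop - sl.start < longest:
            raise ValueError(
                f"interval ({a:.1f},{b:.1f}) shorter than the longest wavelet "
                f"({longest / rate:.1f} s)")

    n_ch, n = ieeg.n_channels, ieeg.n_samples
    power = np.empty((n_ch, len(freqs), n))
    edge = np.zeros((len(freqs), n), dtype=bool)
    for j, kern in enumerate(kernels):
        half = len(kern) // 2
        for sl in slices:
            edge[j, sl.start:min(sl.start + half, sl.stop)] = True
            edge[j, max(sl.stop - half, sl.start):sl.stop] = True
        for c in range(n_ch):
            for sl in slices:
                conv = signal.oaconvolve(ieeg.data[c, sl], kern, mode="same")
                power[c, j, sl] = np.abs(conv) ** 2
    return SpectralStack(freqs=freqs, power=power, cycles=cycles, rate=rate,
                         edge_invalid=edge, intervals=list(ieeg.intervals),
                         interval_slices=slices)


def zscore_power(stack: SpectralStack, mask=None, use_edge=True) -> SpectralStack:
    """Z-score power per frequency, per recording interval, per channel.

    Statistics use unmasked (and non-edge) samples only; masked samples carry
    NaN in ``zpower``.  A zero-variance (frequency, interval, channel) cell is
    degenerate and its interval is dropped (all NaN).
    """
    n_ch, n_f, n = stack.power.shape
    z = np.full_like(stack.power, np.nan)
    excl = np.zeros((n_ch, n), dtype=bool)
    if mask is not None:
        mask = np.atleast_2d(mask)
        excl |= mask if mask.shape[0] == n_ch else np.broadcast_to(mask, (n_ch, n))
    for c in range(n_ch):
        for sl in stack.interval_slices:
            for j in range(n_f):
                seg = stack.power[c, j, sl]
                ok = ~excl[c, sl]
                if use_edge and stack.edge_invalid is not None:
                    ok = ok & ~stack.edge_invalid[j, sl]
                if ok.sum() < 2:
                    continue
                mu = seg[ok].mean()
                sd = seg[ok].std()
                if sd == 0:
                    continue  # degenerate: interval left NaN at this frequency
                zseg = (seg - mu) / sd
                zseg[~ok] = np.nan
                z[c, j, sl] = zseg
    out = SpectralStack(freqs=stack.freqs, power=stack.power, zpower=z,
                        cycles=stack.cycles, rate=stack.rate,
                        edge_invalid=stack.edge_invalid,
                        intervals=stack.intervals,
                        interval_slices=stack.interval_slices)
    return out


def band_power(stack: SpectralStack, band) -> np.ndarray:
    """Mean z-power across band frequencies (inclusive endpoints).

    Returns a (n_channels, n_samples) series; NaN where all bins are masked.
    """
    if isinstance(band, str):
        band = BANDS[band]
    lo, hi = band
    sel = (stack.freqs >= lo - 1e-9) & (stack.freqs <= hi + 1e-9)
    if not sel.any():
        raise ValueError(f"empty band {band} on this grid")
    src = stack.zpower if stack.zpower is not None else stack.power
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(src[:, sel, :], axis=1)


def band_bin_count(freqs, band) -> int:
    if isinstance(band, str):
        band = BANDS[band]
    return int(((freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)).sum())


@dataclass
class BoscModel:
    """1/f background fit, power/duration thresholds, bout mask, Pepisode."""

    freqs: np.ndarray
    intercept: np.ndarray          # per channel, log10 power at log10 f = 0
    slope: np.ndarray              # per channel
    power_threshold: np.ndarray    # (n_channels, n_freqs)
    duration_cycles: float
    bout_mask: np.ndarray          # (n_channels, n_freqs, n_samples)
    pepisode: np.ndarray           # (n_channels, n_freqs)


def bosc_detect(stack: SpectralStack, percentile=95.0, duration_cycles=2.0,
                mask=None) -> BoscModel:
    """BOSC-style oscillation-bout detection.

    The background is a robust (Theil-Sen) linear fit of log10 mean power vs
    log10 frequency per channel.  The power threshold at f is the given
    percentile of a chi-square(2) distribution scaled so its mean equals the
    fitted background power at f; a bout requires the threshold to be
    exceeded continuously for at least ``duration_cycles / f`` seconds.
    """
    n_ch, n_f, n = stack.power.shape
    excl = np.zeros(n, dtype=bool)
    if mask is not None:
        m = np.atleast_2d(mask)
        excl = m.any(axis=0) if m.shape[0] > 1 else m[0]
    logf = np.log10(stack.freqs)
    intercept = np.empty(n_ch)
    slope = np.empty(n_ch)
    thr = np.empty((n_ch, n_f))
    bout = np.zeros((n_ch, n_f, n), dtype=bool)
    chi_factor = stats.chi2.ppf(percentile / 100.0, 2) / 2.0
    for c in range(n_ch):
        meanpow = stack.power[c][:, ~excl].mean(axis=1)
        if not np.all(np.isfinite(np.log10(meanpow))):
            raise ValueError("degenerate spectrum; background fit failed")
        if n_f < 2:   # single-frequency grid: flat background
            sl_, ic_ = 0.0, float(np.log10(meanpow[0]))
        else:
            sl_, ic_, *_ = stats.theilslopes(np.log10(meanpow), logf)
        slope[c], intercept[c] = sl_, ic_
        bg = 10 ** (ic_ + sl_ * logf)          # fitted mean background power
        thr[c] = chi_factor * bg               # mean of chi2(2)*bg/2 is bg
        for j in range(n_f):
            min_samp = int(np.ceil(duration_cycles / stack.freqs[j] * stack.rate))
            above = stack.power[c, j] > thr[c, j]
            bout[c, j] = _runs_at_least(above, min_samp)
    ok = ~excl
    pep = bout[:, :, ok].mean(axis=2)
    return BoscModel(freqs=stack.freqs, intercept=intercept, slope=slope,
                     power_threshold=thr, duration_cycles=duration_cycles,
                     bout_mask=bout, pepisode=pep)


def _runs_at_least(above: np.ndarray, min_samples: int) -> np.ndarray:
    """True where ``above`` is part of a run of at least ``min_samples``."""
    if not above.any():
        return np.zeros_like(above)
    padded = np.concatenate([[False], above, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    out = np.zeros_like(above)
    for a, b in zip(starts, ends):
        if b - a >= min_samples:
            out[a:b] = True
    return out
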