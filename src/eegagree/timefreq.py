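"""Morlet-wavelet time-frequency decomposition and theta-power extraction.

Power is computed per trial by convolution with complex Morlet wavelets
(sigma_t = n_cycles / (2 pi f), amplitude normalization
A = sigma_t^(-1/2) * pi^(-1/4)), averaged over trials per condition,
sampled on a coarse time grid, and decibel-corrected against a
pre-stimulus baseline.  The number of cycles grows linearly from 3 at the
lowest frequency to 10 at the highest, trading temporal precision at low
frequencies for spectral precision at high ones.

Default analysis grid: 1-18 Hz in 1 Hz bins, -1.2 to +1.2 s in 0.05 s
steps, dB baseline -0.6 to -0.3 s; theta is the mean over the 4-8 Hz bins
(inclusive) and 0.1-0.3 s (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.signal import fftconvolve

from .preprocess import EpochSet

DEFAULT_FREQS = np.arange(1.0, 19.0)  # 1..18 Hz
DEFAULT_TIMES = np.arange(-1.2, 1.2 + 1e-9, 0.05)
BASELINE = (-0.600, -0.300)
THETA_BAND = (4.0, 8.0)
THETA_WINDOW = (0.100, 0.300)


def n_cycles_schedule(freqs: np.ndarray, lo: float = 3.0, hi: float = 10.0) -> np.ndarray:
    """Linear cycle count from ``lo`` at the lowest to ``hi`` at the highest
    frequency (constant when a single frequency is given)."""
    freqs = np.asarray(freqs, float)
    if freqs.size == 1:
        return np.array([lo])
    f0, f1 = freqs.min(), freqs.max()
    return lo + (hi - lo) * (freqs - f0) / (f1 - f0)


def morlet_wavelet(freq: float, n_cycles: float, fs: float,
                   trunc_sigmas: float = 3.0) -> np.ndarray:
    """Complex Morlet wavelet truncated at +-``trunc_sigmas`` * sigma_t."""
    sigma_t = n_cycles / (2 * np.pi * freq)
    half = int(np.ceil(trunc_sigmas * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    A = sigma_t ** -0.5 * np.pi ** -0.25
    return A * np.exp(-(t**2) / (2 * sigma_t**2)) * np.exp(2j * np.pi * freq * t)


@dataclass
class TFRMap:
    """Trial-averaged power: channels x frequencies x times.

    ``valid`` flags time bins farther than one wavelet half-length from
    both epoch edges at each frequency; window statistics only use valid
    bins.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel_labels: list
    n_cycles: np.ndarray
    baseline_mode: str = "raw"  # or "dB"
    valid: Optional[np.ndarray] = None  # freqs x times boolean
    condition: str = ""
    n_trials: int = 0

    def channel(self, label: str) -> np.ndarray:
        return self.power[self.channel_labels.index(label)]


def morlet_tfr(epochs: EpochSet, condition: Optional[str] = None,
               freqs: np.ndarray = DEFAULT_FREQS,
               times: np.ndarray = DEFAULT_TIMES,
               n_cycles: Optional[np.ndarray] = None,
               trunc_sigmas: float = 3.0) -> TFRMap:
    """Trial-averaged Morlet power for one condition on a coarse grid.

    The epochs must be long enough to contain at least the central sample
    of the lowest-frequency wavelet; edge-contaminated time bins are kept
    in the array but flagged invalid.
    """
    freqs = np.asarray(freqs, float)
    if freqs.max() >= epochs.fs / 2:
        raise ValueError("frequency above Nyquist")
    n_cycles = n_cycles_schedule(freqs) if n_cycles is None else np.asarray(n_cycles, float)
    ep_times = epochs.times
    half_samp = 0.5 / epochs.fs
    if (times.min() < ep_times[0] - half_samp
            or times.max() > ep_times[-1] + half_samp):
        raise ValueError("requested time grid exceeds the epoch span")
    sel = epochs.kept_mask.copy()
    if condition is not None:
        conds = epochs.info["condition"].to_numpy()
        if condition == "deviant":
            sel &= np.isin(conds, ["deviant", "deviant_low", "deviant_high"])
        else:
            sel &= conds == condition
    if not sel.any():
        raise ValueError(f"no kept trials for condition {condition!r}")
    data = epochs.data[sel]

    # sample indices of the coarse grid within the epoch
    grid_idx = np.round((times - ep_times[0]) * epochs.fs).astype(int)
    grid_idx = np.clip(grid_idx, 0, data.shape[-1] - 1)
    n_ch = data.shape[1]
    power = np.empty((n_ch, freqs.size, times.size))
    valid = np.empty((freqs.size, times.size), dtype=bool)
    n_samp = data.shape[2]
    for i, (f, nc) in enumerate(zip(freqs, n_cycles)):
        w = morlet_wavelet(f, nc, epochs.fs, trunc_sigmas)
        if w.size > 2 * n_samp:
            raise ValueError(
                f"epoch too short for a {f} Hz wavelet of {nc:.1f} cycles")
        conv = fftconvolve(data, w[None, None, :], mode="same", axes=2)
        p = (np.abs(conv) ** 2).mean(axis=0)  # channels x samples
        power[:, i, :] = p[:, grid_idx]
        half_len = (w.size // 2) / epochs.fs
        valid[i] = ((times - ep_times[0] >= half_len)
                    & (ep_times[-1] - times >= half_len))
    return TFRMap(power=power, freqs=freqs, times=np.asarray(times, float),
                  channel_labels=list(epochs.channel_labels),
                  n_cycles=n_cycles, baseline_mode="raw", valid=valid,
                  condition=condition or "all", n_trials=int(sel.sum()))


def db_baseline(tfr: TFRMap, baseline: Tuple[float, float] = BASELINE) -> TFRMap:
    """Decibel baseline correction: 10*log10(P / mean baseline P), per
    channel and frequency."""
    if tfr.baseline_mode == "dB":
        raise ValueError("TFR is already dB-corrected")
    bmask = (tfr.times >= baseline[0]) & (tfr.times <= baseline[1])
    if not bmask.any():
        raise ValueError("baseline window outside the time grid")
    base = tfr.power[:, :, bmask].mean(axis=2, keepdims=True)
    if np.any(base <= 0):
        raise ValueError("baseline power must be strictly positive")
    out_power = 10.0 * np.log10(tfr.power / base)
    return TFRMap(power=out_power, freqs=tfr.freqs, times=tfr.times,
                  channel_labels=list(tfr.channel_labels),
                  n_cycles=tfr.n_cycles, baseline_mode="dB", valid=tfr.valid,
                  condition=tfr.condition, n_trials=tfr.n_trials)


def extract_theta(tfr_dev: TFRMap, tfr_std: TFRMap, channel: str,
                  band: Tuple[float, float] = THETA_BAND,
                  window: Tuple[float, float] = THETA_WINDOW,
                  ) -> Tuple[float, float, float]:
    """Mean dB theta power in the post-stimulus window for each condition.

    Returns ``(theta_dev, theta_std, theta_diff)`` with
    ``theta_diff = theta_dev - theta_std``.  Band and window bounds are
    inclusive at both ends; edge-contaminated bins are excluded.
    """
    if band[0] >= band[1] or window[0] >= window[1]:
        raise ValueError("band and window must be increasing (lo, hi) pairs")
    for tfr in (tfr_dev, tfr_std):
        if tfr.baseline_mode != "dB":
            raise ValueError("extract_theta expects dB-corrected TFRs")
        if channel not in tfr.channel_labels:
            raise ValueError(f"channel {channel!r} not in TFR")
    fmask = (tfr_dev.freqs >= band[0]) & (tfr_dev.freqs <= band[1])
    tmask = (tfr_dev.times >= window[0] - 1e-9) & (tfr_dev.times <= window[1] + 1e-9)
    if not fmask.any() or not tmask.any():
        raise ValueError("band or window outside the TFR grid")

    def _mean(tfr: TFRMap) -> float:
        ch = tfr.channel(channel)[np.ix_(fmask, tmask)]
        ok = tfr.valid[np.ix_(fmask, tmask)] if tfr.valid is not None else np.ones_like(ch, bool)
        if not ok.any():
            raise ValueError("no edge-clean bins in the requested window")
        return float(ch[ok].mean())

    theta_dev = _mean(tfr_dev)
    theta_std = _mean(tfr_std)
    return theta_dev, theta_std, theta_dev - theta_std


def plot_tfr(tfr: TFRMap, channel: str, ax=None, vlim: float = 3.0):
    """Spectrogram of one channel's (dB) time-frequency map."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    img = tfr.channel(channel)
    mesh = ax.pcolormesh(tfr.times, tfr.freqs, img, cmap="RdBu_r",
                         vmin=-vlim, vmax=vlim, shading="nearest")
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    unit = "dB" if tfr.baseline_mode == "dB" else "power"
    ax.figure.colorbar(mesh, ax=ax, label=unit)
    ax.set_title(f"{channel} ({tfr.condition}, n={tfr.n_trials})")
    return ax
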