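"""Event-related averages, mismatch-negativity metrics and plus-minus SNR.

The mismatch response is quantified at one fronto-central channel (FCz
for the wet system, 3Z for the dry system) as the deviant-minus-standard
difference wave: its mean amplitude over 100-150 ms after stimulus onset,
and the peak (most negative sample by default) amplitude and latency in
the same window.  SNR uses the plus-minus estimate: the noise reference
is the deviant average recomputed with every other trial polarity-
flipped, which cancels time-locked activity while preserving the noise
level of the average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .preprocess import EpochSet

MMN_WINDOW = (0.100, 0.150)


@dataclass
class Evoked:
    data: np.ndarray  # channels x samples, volts
    fs: float
    tmin: float
    n_trials: int
    condition: str
    channel_labels: list
    baseline_window: Tuple[float, float] = (-0.1, 0.0)

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[1]) / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]


@dataclass
class MMNResult:
    mean_amplitude: float  # volts, deviant - standard in the window
    peak_amplitude: float
    peak_latency: float
    channel: str
    n_trials_used: int
    snr: Optional[float] = None


def select_trials(epochs: EpochSet, seed: int = 0,
                  pool_deviants: bool = True,
                  n_max: Optional[int] = None) -> EpochSet:
    """Apply the averaging exclusions and equalize trial counts.

    Drops habituation standards and standards immediately following a
    deviant, pools the two deviant types into a single deviant condition
    (unless ``pool_deviants`` is False), and subsamples the larger
    condition uniformly without replacement (seeded) so standard and
    deviant counts match.  ``n_max`` additionally caps the common count,
    which is how counts are equalized across the two systems of one
    subject (pass the minimum over systems).
    """
    out = epochs.kept()
    cond = out.info["condition"].to_numpy().copy()
    is_dev = np.isin(cond, ["deviant_low", "deviant_high"])
    if pool_deviants:
        cond[is_dev] = "deviant"
    keep = ~(out.info["is_habituation"].to_numpy()
             | (out.info["follows_deviant"].to_numpy() & ~is_dev))
    out.data = out.data[keep]
    out.info = out.info[keep].reset_index(drop=True)
    out.info["condition"] = cond[keep]
    out.kept_mask = np.ones(out.data.shape[0], bool)

    groups = {"standard": np.flatnonzero(out.info["condition"] == "standard")}
    if pool_deviants:
        groups["deviant"] = np.flatnonzero(out.info["condition"] == "deviant")
    else:
        for c in ("deviant_low", "deviant_high"):
            groups[c] = np.flatnonzero(out.info["condition"] == c)
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError("a condition has zero trials after exclusions")

    n = min(len(v) for v in groups.values())
    if n_max is not None:
        n = min(n, int(n_max))
    rng = np.random.default_rng(seed)
    chosen = np.concatenate([
        np.sort(rng.choice(idx, size=n, replace=False)) for idx in groups.values()
    ])
    chosen = np.sort(chosen)
    out.data = out.data[chosen]
    out.info = out.info.iloc[chosen].reset_index(drop=True)
    out.kept_mask = np.ones(out.data.shape[0], bool)
    out.provenance.append(f"selected {n} trials per condition")
    return out


def average_and_baseline(epochs: EpochSet, condition: str,
                         baseline: Tuple[float, float] = (-0.1, 0.0)) -> Evoked:
    """Trial average for one condition with per-channel baseline correction."""
    sel = epochs.kept_mask & (epochs.info["condition"] == condition).to_numpy()
    if not sel.any():
        raise ValueError(f"no kept trials with condition {condition!r}")
    avg = epochs.data[sel].mean(axis=0)
    times = epochs.times
    bmask = (times >= baseline[0]) & (times < baseline[1])
    if bmask.any():
        avg = avg - avg[:, bmask].mean(axis=1, keepdims=True)
    return Evoked(data=avg, fs=epochs.fs, tmin=epochs.tmin,
                  n_trials=int(sel.sum()), condition=condition,
                  channel_labels=list(epochs.channel_labels),
                  baseline_window=baseline)


def mmn_metrics(evoked_dev: Evoked, evoked_std: Evoked, channel: str,
                window: Tuple[float, float] = MMN_WINDOW,
                peak_mode: str = "neg") -> MMNResult:
    """Difference-wave metrics at one channel.

    ``peak_mode='neg'`` (default) takes the most negative sample in the
    window, appropriate for a negativity; ``'abs'`` takes the sample of
    largest magnitude.  Ties resolve to the earliest sample.
    """
    if channel not in evoked_dev.channel_labels or channel not in evoked_std.channel_labels:
        raise ValueError(f"channel {channel!r} missing from an evoked")
    if evoked_dev.fs != evoked_std.fs or evoked_dev.tmin != evoked_std.tmin:
        raise ValueError("evokeds have mismatched sampling or time origin")
    diff = evoked_dev.channel(channel) - evoked_std.channel(channel)
    times = evoked_dev.times
    wmask = (times >= window[0]) & (times <= window[1])
    wdiff, wtimes = diff[wmask], times[wmask]
    if peak_mode == "neg":
        i = int(np.argmin(wdiff))
    elif peak_mode == "abs":
        i = int(np.argmax(np.abs(wdiff)))
    else:
        raise ValueError("peak_mode must be 'neg' or 'abs'")
    return MMNResult(
        mean_amplitude=float(wdiff.mean()),
        peak_amplitude=float(wdiff[i]),
        peak_latency=float(wtimes[i]),
        channel=channel,
        n_trials_used=min(evoked_dev.n_trials, evoked_std.n_trials),
    )


def plus_minus_snr(epochs_dev: EpochSet, channel: str,
                   window: Tuple[float, float] = MMN_WINDOW) -> float:
    """Plus-minus SNR of the deviant average at one channel.

    Signal: average of all kept deviant trials, restricted to the window.
    Noise: the same average after flipping the polarity of every other
    trial (the second, fourth, ... trial in kept chronological order), so
    time-locked components cancel.  Returns RMS(signal) / RMS(noise);
    a zero noise RMS yields ``inf`` with a warning.
    """
    kept = epochs_dev.kept()
    dev = np.isin(kept.info["condition"], ["deviant", "deviant_low", "deviant_high"])
    x = kept.data[dev][:, kept.idx(channel), :]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 kept deviant trials")
    times = kept.times
    wmask = (times >= window[0]) & (times <= window[1])
    x = x[:, wmask]
    signs = np.ones(x.shape[0])
    signs[0::2] = -1.0  # first, third, ... trial in kept order is flipped
    signal = x.mean(axis=0)
    noise = (signs[:, None] * x).mean(axis=0)
    rms_noise = np.sqrt(np.mean(noise**2))
    if rms_noise == 0:
        warnings.warn("plus-minus noise estimate is exactly zero; returning inf")
        return float("inf")
    return float(np.sqrt(np.mean(signal**2)) / rms_noise)


def analyze_mmn(erp_epochs: EpochSet, channel: Optional[str] = None,
                seed: int = 0, n_max: Optional[int] = None,
                window: Tuple[float, float] = MMN_WINDOW) -> MMNResult:
    """Full single-subject, single-system MMN analysis on clean epochs."""
    from .layouts import get_layout

    if channel is None:
        channel = get_layout(erp_epochs.layout_name).mmn_channel
    sel = select_trials(erp_epochs, seed=seed, n_max=n_max)
    ev_dev = average_and_baseline(sel, "deviant")
    ev_std = average_and_baseline(sel, "standard")
    res = mmn_metrics(ev_dev, ev_std, channel, window)
    res.snr = plus_minus_snr(sel, channel, window)
    return res
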