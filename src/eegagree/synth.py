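"""Paired wet/dry synthetic EEG with known ground truth.

The simulator emulates a two-system oddball session: pink (1/f) background
noise with a system-specific floor (the dry system is noisier), an N1-like
evoked response to every tone, an additional fronto-central negativity
(the mismatch response) plus a 4-8 Hz oscillatory burst on deviant trials,
seeded eye blinks propagated to frontal channels, and — for the dry system
— occasional step ("jump") artifacts.  Resting state is built from four
band-limited oscillators per channel with configurable constant phase lags
between chosen channel pairs so phase-based connectivity has a known
target.

All quantities are in volts; sampling rate is 1024 Hz before
preprocessing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .layouts import DEFAULT_LAYOUTS, Layout, get_layout
from .sequence import STANDARD, StimulusSequence

FS_RAW = 1024.0

#: resting-state band edges in Hz (delta, theta, alpha, low beta)
REST_BANDS: Dict[str, Tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 20.0),
}

# fraction of the broadband noise scale given to each resting oscillator
_BAND_WEIGHTS = {"delta": 0.5, "theta": 0.3, "alpha": 0.45, "beta": 0.2}

_SYSTEM_SALT = {"wet": 101, "dry": 202}


@dataclass
class GroundTruth:
    """Injected effect sizes, serialized alongside every generated dataset.

    ``resting_phase_lags`` maps band -> {(ch_a, ch_b): lag_radians};
    ``resting_coupling`` maps the same keys to a coupling strength in
    [0, 1] (1 = the lagged copy carries no independent noise).
    """

    mmn_amplitude: float = -3.5e-6
    mmn_latency: float = 0.125
    mmn_width: float = 0.050  # Gaussian sigma, seconds
    theta_burst_gain: float = 3.0  # dB
    noise_scale: Dict[str, float] = field(
        default_factory=lambda: {"wet": 8e-6, "dry": 16e-6}
    )
    resting_phase_lags: Dict[str, Dict[Tuple[str, str], float]] = field(
        default_factory=dict
    )
    resting_coupling: Dict[str, Dict[Tuple[str, str], float]] = field(
        default_factory=dict
    )
    blink_rate: float = 0.12  # blinks per second
    blink_amplitude: float = 100e-6
    blink_duration: float = 0.300
    blink_scalp_gain: float = 0.3
    saccade_rate: float = 0.25  # horizontal eye movements per second
    saccade_amplitude: float = 50e-6
    jump_rate: float = 1 / 120.0  # dry-system steps per second
    evoked_n1_amplitude: float = -2.0e-6
    evoked_p2_amplitude: float = 1.0e-6
    seed: int = 0

    def to_json(self, path) -> None:
        d = asdict(self)
        for key in ("resting_phase_lags", "resting_coupling"):
            d[key] = {
                band: {f"{a}|{b}": v for (a, b), v in pairs.items()}
                for band, pairs in d[key].items()
            }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("resting_phase_lags", "resting_coupling"):
            d[key] = {
                band: {tuple(k.split("|")): v for k, v in pairs.items()}
                for band, pairs in d[key].items()
            }
        return cls(**d)


@dataclass
class Recording:
    """Continuous multichannel recording (channels x samples, volts)."""

    data: np.ndarray
    fs: float
    channel_labels: List[str]
    system: str
    reference: str = "none"
    eog_channels: List[str] = field(default_factory=list)
    events: Optional[StimulusSequence] = None
    layout_name: Optional[str] = None
    bad_channels: List[str] = field(default_factory=list)

    def __post_init__(self):
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("channel_labels length must match data rows")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def idx(self, label: str) -> int:
        return self.channel_labels.index(label)

    def copy(self) -> "Recording":
        return Recording(
            data=self.data.copy(),
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            system=self.system,
            reference=self.reference,
            eog_channels=list(self.eog_channels),
            events=self.events,
            layout_name=self.layout_name,
            bad_channels=list(self.bad_channels),
        )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def pink_noise(n_channels: int, n_samples: int, rms: float,
               rng: np.random.Generator, exponent: float = 1.0,
               f_floor: float = 0.5, fs: float = FS_RAW,
               mixing: Optional[np.ndarray] = None) -> np.ndarray:
    """1/f^exponent (power) noise, shaped in the frequency domain.

    The amplitude spectrum is flat below ``f_floor`` to keep the variance
    finite; each channel is normalized to the requested RMS.  ``mixing``
    (channels x channels) spatially blends the independent channel
    processes, emulating the instantaneous smearing of background
    activity across the scalp; channel RMS is re-normalized afterwards.
    """
    if rms == 0:
        return np.zeros((n_channels, n_samples))
    from scipy.fft import irfft, next_fast_len

    n_fft = next_fast_len(n_samples, real=True)
    freqs = np.fft.rfftfreq(n_fft, 1.0 / fs)
    shape = 1.0 / np.maximum(freqs, f_floor) ** (exponent / 2.0)
    shape[0] = 0.0  # no DC
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size))) * shape
    x = irfft(spec, n=n_fft, axis=1)[:, :n_samples]
    if mixing is not None:
        x = mixing @ x
    x *= rms / np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x


def spatial_mixing(lay: Layout, labels: List[str], width: float = 0.6,
                   jitter: float = 1e-3) -> np.ndarray:
    """Cholesky factor of a smooth spatial correlation over the scalp.

    Neighbouring scalp electrodes share background activity (zero-lag, as
    volume conduction would produce); correlation falls off as a Gaussian
    of the 3-D inter-electrode distance.  This keeps the background's
    effective spatial rank low, as in real scalp recordings.  Periocular
    and mastoid channels keep independent background (their noise is
    dominated by local skin/muscle sources rather than cortex).
    """
    scalp_set = set(lay.scalp)
    idx = [i for i, l in enumerate(labels) if l in scalp_set]
    pos = np.array([lay.positions[labels[i]] for i in idx])
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    corr = np.exp(-((d / width) ** 2))
    block = np.linalg.cholesky(corr + jitter * np.eye(len(idx)))
    mix = np.eye(len(labels))
    mix[np.ix_(idx, idx)] = block
    return mix


def _gaussian(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def evoked_template(t: np.ndarray, truth: GroundTruth) -> np.ndarray:
    """Obligatory response to any tone: N1-like difference of Gaussians."""
    return (truth.evoked_n1_amplitude * _gaussian(t, 0.100, 0.030)
            + truth.evoked_p2_amplitude * _gaussian(t, 0.180, 0.040))


def mmn_template(t: np.ndarray, truth: GroundTruth) -> np.ndarray:
    """Extra deviant-only negativity: Gaussian of height ``mmn_amplitude``."""
    return truth.mmn_amplitude * _gaussian(t, truth.mmn_latency, truth.mmn_width)


def _spatial_gain(layout: Layout, center_label: str, width: float = 0.8) -> Dict[str, float]:
    c = layout.positions[center_label]
    gains = {}
    for lab in layout.scalp:
        d = np.linalg.norm(layout.positions[lab] - c)
        gains[lab] = float(np.exp(-((d / width) ** 2)))
    return gains


def _eye_gain(layout: Layout, scale: float) -> Dict[str, float]:
    eye = np.array([-0.2, 0.98, -0.15])
    eye /= np.linalg.norm(eye)
    gains = {}
    for lab in layout.scalp:
        d = np.linalg.norm(layout.positions[lab] - eye)
        gains[lab] = float(scale * np.exp(-((d / 0.7) ** 2)))
    return gains


def _theta_burst_amplitude(truth: GroundTruth, noise_rms: float) -> float:
    """Sinusoid amplitude giving ~``theta_burst_gain`` dB extra theta power.

    The 1/f background puts a fraction ln(8/4)/ln(f_hi/f_floor) of its
    variance into 4-8 Hz; the burst adds (10^(g/10) - 1) times that power.
    """
    if noise_rms == 0:
        return 0.0
    frac = np.log(8.0 / 4.0) / np.log((FS_RAW / 2) / 0.5)
    theta_rms = noise_rms * np.sqrt(frac)
    added_rms = theta_rms * np.sqrt(10 ** (truth.theta_burst_gain / 10.0) - 1.0)
    return float(np.sqrt(2.0) * added_rms)


def synthesize_task_recording(
    seq: StimulusSequence,
    truth: GroundTruth,
    layout: str | Layout = "wet61",
    system: str = "wet",
    duration_pad: float = 2.0,
    seed: Optional[int] = None,
    blinks: bool = True,
) -> Recording:
    """Simulate a continuous oddball-task recording for one system."""
    if system not in ("wet", "dry"):
        raise ValueError(f"unknown system {system!r}")
    lay = get_layout(layout) if isinstance(layout, str) else layout
    if len(lay.scalp) < 8:
        raise ValueError("layout must provide at least 8 scalp channels")
    if not seq.events:
        raise ValueError("stimulus sequence is empty")
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng([seed, _SYSTEM_SALT[system], 1])

    labels = lay.all_labels
    n_ch = len(labels)
    t_end = seq.events[-1].onset_time + max(duration_pad, 1.5)
    n_samp = int(round(t_end * FS_RAW))
    noise_rms = truth.noise_scale[system]
    data = pink_noise(n_ch, n_samp, noise_rms, rng,
                      mixing=spatial_mixing(lay, labels))

    # evoked components at fronto-central channels
    gain = _spatial_gain(lay, lay.mmn_channel)
    tmpl_t = np.arange(int(round(0.6 * FS_RAW))) / FS_RAW - 0.1  # -0.1..0.5 s
    base = evoked_template(tmpl_t, truth)
    mmn = mmn_template(tmpl_t, truth)
    burst_amp = _theta_burst_amplitude(truth, noise_rms)
    burst_env = _gaussian(tmpl_t, 0.200, 0.060)
    ch_gain = np.array([gain.get(l, 0.0) for l in labels])[:, None]

    for ev in seq.events:
        s0 = int(round(ev.onset_time * FS_RAW)) - int(round(0.1 * FS_RAW))
        sl = slice(s0, s0 + tmpl_t.size)
        if sl.start < 0 or sl.stop > n_samp:
            continue
        wave = base.copy()
        if ev.tone != STANDARD:
            wave = wave + mmn
            phase = rng.uniform(0, 2 * np.pi)
            wave = wave + burst_amp * burst_env * np.sin(
                2 * np.pi * 6.0 * tmpl_t + phase
            )
        data[:, sl] += ch_gain * wave[None, :]

    if blinks:
        _add_ocular(data, labels, lay, truth, n_samp, rng)

    if system == "dry" and truth.jump_rate > 0:
        _add_jumps(data, lay, labels, truth, n_samp, rng)

    return Recording(
        data=data,
        fs=FS_RAW,
        channel_labels=labels,
        system=system,
        reference="common (simulated)",
        eog_channels=list(lay.eog),
        events=seq,
        layout_name=lay.name,
    )


def _add_ocular(data, labels, lay, truth, n_samp, rng):
    if truth.blink_rate > 0:
        _add_blinks(data, labels, lay, truth, n_samp, rng)
    if truth.saccade_rate > 0:
        _add_saccades(data, labels, lay, truth, n_samp, rng)


def _add_blinks(data, labels, lay: Layout, truth: GroundTruth, n_samp, rng):
    n_blinks = rng.poisson(truth.blink_rate * n_samp / FS_RAW)
    blink_len = int(round(truth.blink_duration * FS_RAW))
    wave = truth.blink_amplitude * np.sin(np.pi * np.arange(blink_len) / blink_len)
    eye_gain = _eye_gain(lay, truth.blink_scalp_gain)
    g = np.zeros(len(labels))
    for i, lab in enumerate(labels):
        if lab in lay.eog:
            # vertical dipole: above-eye positive, below-eye negative;
            # lateral electrode sees ~30 % blink cross-talk
            g[i] = 0.5 if lab == "EOGa" else (-0.5 if lab == "EOGb" else 0.3)
        else:
            g[i] = eye_gain.get(lab, 0.0)
    onsets = rng.integers(0, max(1, n_samp - blink_len), size=n_blinks)
    for s0 in onsets:
        data[:, s0:s0 + blink_len] += g[:, None] * wave[None, :]


def _add_saccades(data, labels, lay: Layout, truth: GroundTruth, n_samp, rng):
    """Horizontal eye movements: ramp-plateau-ramp potentials, strongest on
    the lateral periocular electrode, weakly on lateral-frontal scalp."""
    n_sac = rng.poisson(truth.saccade_rate * n_samp / FS_RAW)
    lat_eye = np.array([-0.60, 0.80, -0.20])
    lat_eye /= np.linalg.norm(lat_eye)
    g = np.zeros(len(labels))
    for i, lab in enumerate(labels):
        if lab == "EOGl":
            g[i] = 1.0
        elif lab in lay.eog:
            g[i] = 0.2
        else:
            d = np.linalg.norm(lay.positions[lab] - lat_eye)
            g[i] = 0.15 * np.exp(-((d / 0.5) ** 2))
    ramp = int(0.05 * FS_RAW)
    for _ in range(n_sac):
        plateau = int(rng.uniform(0.2, 0.8) * FS_RAW)
        amp = rng.choice([-1, 1]) * truth.saccade_amplitude
        wave = np.concatenate([
            np.linspace(0, 1, ramp), np.ones(plateau), np.linspace(1, 0, ramp)
        ]) * amp
        s0 = int(rng.integers(0, max(1, n_samp - wave.size)))
        data[:, s0:s0 + wave.size] += g[:, None] * wave[None, :]


def _add_jumps(data, lay: Layout, labels, truth: GroundTruth, n_samp, rng):
    n_jumps = rng.poisson(truth.jump_rate * n_samp / FS_RAW)
    scalp_idx = [labels.index(l) for l in lay.scalp]
    for _ in range(n_jumps):
        ch = scalp_idx[int(rng.integers(len(scalp_idx)))]
        s0 = int(rng.integers(0, n_samp))
        dur = int(rng.uniform(0.5, 3.0) * FS_RAW)
        amp = rng.choice([-1, 1]) * rng.uniform(200e-6, 500e-6)
        data[ch, s0:min(n_samp, s0 + dur)] += amp


def phase_shift(x: np.ndarray, phi: float) -> np.ndarray:
    """Delay the analytic phase of ``x`` by ``phi`` radians (constant lag)."""
    return np.real(hilbert(x) * np.exp(-1j * phi))


def _narrowband(n_samp: int, band: Tuple[float, float], rms: float,
                rng: np.random.Generator) -> np.ndarray:
    sos = butter(4, band, btype="bandpass", fs=FS_RAW, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n_samp))
    return x * (rms / np.sqrt(np.mean(x**2)))


def synthesize_resting_recording(
    truth: GroundTruth,
    layout: str | Layout = "wet61",
    system: str = "wet",
    duration: float = 300.0,
    seed: Optional[int] = None,
) -> Recording:
    """Simulate eyes-open resting state from coupled band-limited oscillators.

    For every channel pair listed in ``truth.resting_phase_lags[band]`` the
    second channel's band component is the first channel's component with
    its instantaneous phase delayed by the stated lag, mixed with an
    independent component according to ``resting_coupling`` (so coupling 1
    gives a perfectly phase-locked pair and coupling 0 an independent one).
    """
    if system not in ("wet", "dry"):
        raise ValueError(f"unknown system {system!r}")
    if duration < 16.0:
        raise ValueError("resting duration must be at least 16 s (two 8 s epochs)")
    for band, pairs in truth.resting_phase_lags.items():
        for pair, lag in pairs.items():
            if not -np.pi < lag < np.pi:
                raise ValueError(f"phase lag {lag} for {pair} outside (-pi, pi)")
    lay = get_layout(layout) if isinstance(layout, str) else layout
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng([seed, _SYSTEM_SALT[system], 2])

    labels = lay.all_labels
    n_samp = int(round(duration * FS_RAW))
    noise_rms = truth.noise_scale[system]
    data = pink_noise(len(labels), n_samp, 0.25 * noise_rms, rng,
                      mixing=spatial_mixing(lay, labels))

    for band, (lo, hi) in REST_BANDS.items():
        band_rms = _BAND_WEIGHTS[band] * noise_rms
        scalp_set = set(lay.scalp)
        lags = {p: v for p, v in truth.resting_phase_lags.get(band, {}).items()
                if p[0] in scalp_set and p[1] in scalp_set}
        coupling = truth.resting_coupling.get(band, {})
        lagged = {b for (_, b) in lags}
        comps: Dict[str, np.ndarray] = {}
        for lab in lay.scalp:
            if lab not in lagged:
                comps[lab] = _narrowband(n_samp, (lo, hi), band_rms, rng)
        for (a, b), lag in lags.items():
            c = float(coupling.get((a, b), 1.0))
            if a not in comps:  # leader of a chained pair
                comps[a] = _narrowband(n_samp, (lo, hi), band_rms, rng)
            shifted = phase_shift(comps[a], lag)
            # the independent part is always drawn so that the RNG stream
            # (and hence every other channel) is invariant to the
            # coupling strength
            indep = _narrowband(n_samp, (lo, hi), band_rms, rng)
            comps[b] = c * shifted + (1.0 - c) * indep
        for i, lab in enumerate(labels):
            if lab in comps:
                data[i] += comps[lab]

    _add_ocular(data, labels, lay, truth, n_samp, rng)
    if system == "dry" and truth.jump_rate > 0:
        _add_jumps(data, lay, labels, truth, n_samp, rng)

    return Recording(
        data=data,
        fs=FS_RAW,
        channel_labels=labels,
        system=system,
        reference="common (simulated)",
        eog_channels=list(lay.eog),
        events=None,
        layout_name=lay.name,
    )
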