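"""EEG preprocessing: referencing, filtering, epoching, artifact removal.

The task pipeline applies, in order: mastoid-average re-referencing,
automated bad-channel detection, 0.1-25 Hz zero-phase band-pass filtering
of the continuous data, epoching (-0.1 to 0.5 s around tone onsets; 8 s
windows for resting state), resampling to 512 Hz, bipolar EOG derivation,
ICA-based ocular artifact rejection (15 components, |r| > 0.2 with either
EOG channel), spherical-spline interpolation of the previously detected
bad channels, and peak-to-peak trial rejection.  A subject's task data is
included only when more than 70 % of trials survive and the mismatch
response has SNR > 1.

Epoch sample convention is half-open [tmin, tmax): a -0.1 to 0.5 s epoch
at 1024 Hz has exactly 614 samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, firwin, oaconvolve, resample_poly

from .layouts import get_layout
from .sequence import StimulusSequence
from .synth import Recording


@dataclass
class PreprocConfig:
    """Every preprocessing threshold, mirrored into run configs."""

    band: Tuple[float, float] = (0.1, 25.0)
    low_transition: float = 0.1   # Hz, transition width at the high-pass edge
    high_transition: float = 6.0  # Hz, transition width at the low-pass edge
    task_tmin: float = -0.1
    task_tmax: float = 0.5
    rest_epoch_len: float = 8.0
    target_fs: float = 512.0
    flat_threshold: float = 1e-7  # volts RMS
    z_threshold: float = 5.0
    n_ica_components: int = 15
    eog_corr_threshold: float = 0.2
    ica_max_iter: int = 300
    ptp_threshold: float = 150e-3  # volts; 150e-6 is the microvolt preset
    min_fraction_retained: float = 0.7
    min_snr: float = 1.0
    interp_order: int = 4
    interp_degree: int = 7
    interp_lambda: float = 1e-5
    seed: int = 0


@dataclass
class PreprocReport:
    n_channels_rejected: int = 0
    n_components_rejected: int = 0
    n_trials_rejected: int = 0
    fraction_trials_retained: float = 1.0
    included: Optional[bool] = None
    snr: Optional[float] = None
    reasons: List[str] = field(default_factory=list)
    rejected_channels: List[str] = field(default_factory=list)

    def decide_inclusion(self, snr: float, min_fraction: float = 0.7,
                         min_snr: float = 1.0) -> bool:
        """Apply the inclusion rule: > 70 % trials retained and SNR > 1."""
        self.snr = float(snr)
        self.included = (self.fraction_trials_retained > min_fraction
                         and snr > min_snr)
        if self.fraction_trials_retained <= min_fraction:
            self.reasons.append(
                f"retained fraction {self.fraction_trials_retained:.3f} <= {min_fraction}")
        if snr <= min_snr:
            self.reasons.append(f"snr {snr:.3f} <= {min_snr}")
        return self.included

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EpochSet:
    """Epoched data: trials x channels x samples, with per-trial metadata."""

    data: np.ndarray
    fs: float
    tmin: float
    channel_labels: List[str]
    info: pd.DataFrame  # per-trial: condition, is_habituation, follows_deviant, onset_sample
    kept_mask: np.ndarray
    system: str = "wet"
    layout_name: Optional[str] = None
    eog_channels: List[str] = field(default_factory=list)
    mastoids: List[str] = field(default_factory=list)
    provenance: List[str] = field(default_factory=list)

    def __post_init__(self):
        if self.data.shape[0] != len(self.info):
            raise ValueError("info rows must match number of trials")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel_labels must match data channels")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.fs

    @property
    def scalp_channels(self) -> List[str]:
        excl = set(self.eog_channels) | set(self.mastoids)
        return [c for c in self.channel_labels if c not in excl]

    def idx(self, label: str) -> int:
        return self.channel_labels.index(label)

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(), fs=self.fs, tmin=self.tmin,
            channel_labels=list(self.channel_labels), info=self.info.copy(),
            kept_mask=self.kept_mask.copy(), system=self.system,
            layout_name=self.layout_name, eog_channels=list(self.eog_channels),
            mastoids=list(self.mastoids), provenance=list(self.provenance),
        )

    def kept(self) -> "EpochSet":
        """View restricted to kept trials (data copied)."""
        out = self.copy()
        out.data = out.data[self.kept_mask]
        out.info = out.info[self.kept_mask].reset_index(drop=True)
        out.kept_mask = np.ones(out.data.shape[0], bool)
        return out

    def drop_trials(self, bad_idx: np.ndarray, reason: str) -> None:
        """Monotone rejection: kept flags only ever flip True -> False."""
        self.kept_mask = self.kept_mask & ~bad_idx
        self.provenance.append(f"dropped {int(bad_idx.sum())} trials ({reason})")


# ---------------------------------------------------------------------------
# referencing and EOG derivation


def rereference_average_mastoids(rec: Recording, on_missing: str = "raise") -> Recording:
    """Subtract the mastoid average from every scalp channel.

    Mastoid channels themselves and EOG channels are left untouched;
    mastoids stay in the recording (flagged by label).  When mastoids are
    absent the behavior is configurable: ``raise`` or ``skip`` (returns
    the input unchanged with a warning).
    """
    mastoids = [c for c in ("M1", "M2") if c in rec.channel_labels]
    if len(mastoids) < 2:
        if on_missing == "skip":
            warnings.warn("mastoid channels missing; skipping re-reference")
            return rec.copy()
        raise ValueError("both mastoid channels (M1, M2) are required")
    out = rec.copy()
    ref = out.data[[out.idx(m) for m in mastoids]].mean(axis=0)
    # mastoids are re-referenced too (their new average is zero, which
    # makes the operation idempotent); EOG channels are left alone since
    # the bipolar derivations cancel any common reference
    skip = set(rec.eog_channels)
    for i, lab in enumerate(out.channel_labels):
        if lab not in skip:
            out.data[i] = out.data[i] - ref
    out.reference = "average mastoids"
    return out


def derive_bipolar_eog(obj, layout=None):
    """Replace raw periocular channels by bipolar vEOG and hEOG channels.

    The vertical EOG is the difference of the electrodes above and below
    the eye (wet) or below-eye minus a frontal scalp site (dry); the
    horizontal EOG is the lateral electrode minus its designated frontal
    reference.  Works on a continuous ``Recording`` or an ``EpochSet``.
    """
    lay = get_layout(layout or obj.layout_name)
    labels = obj.channel_labels
    for pair in (lay.veog_pair, lay.heog_pair):
        for ch in pair:
            if ch not in labels:
                raise ValueError(f"channel {ch!r} required for EOG derivation is missing")
    out = obj.copy()
    a, b = (labels.index(c) for c in lay.veog_pair)
    c_, d = (labels.index(c) for c in lay.heog_pair)
    veog = out.data[..., a, :] - out.data[..., b, :]
    heog = out.data[..., c_, :] - out.data[..., d, :]
    drop = [labels.index(ch) for ch in lay.eog if ch in labels]
    keep = [i for i in range(len(labels)) if i not in drop]
    new_labels = [labels[i] for i in keep] + ["vEOG", "hEOG"]
    out.data = np.concatenate(
        [out.data[..., keep, :], veog[..., None, :], heog[..., None, :]], axis=-2
    )
    out.channel_labels = new_labels
    out.eog_channels = ["vEOG", "hEOG"]
    if hasattr(out, "provenance"):
        out.provenance.append("derived bipolar vEOG/hEOG")
    return out


# ---------------------------------------------------------------------------
# filtering and resampling


def _fir_taps(fs: float, cutoff: float, transition: float, pass_zero: bool) -> np.ndarray:
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps += 1 - numtaps % 2  # odd -> type I linear phase
    return firwin(numtaps, cutoff, window="hamming", pass_zero=pass_zero, fs=fs)


def _zero_phase_fir(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR along the last axis with reflect padding.

    A type-I linear-phase FIR applied with 'same' alignment is zero-phase;
    odd-reflection padding of half the filter length limits edge
    transients.
    """
    half = len(taps) // 2
    pad = min(half, data.shape[-1] - 1)
    pre = 2 * data[..., :1] - data[..., 1:pad + 1][..., ::-1]
    post = 2 * data[..., -1:] - data[..., -pad - 1:-1][..., ::-1]
    padded = np.concatenate([pre, data, post], axis=-1)
    flat = padded.reshape(-1, padded.shape[-1])
    out = np.empty_like(flat)
    chunk = 8  # bounded memory for long recordings
    for i in range(0, flat.shape[0], chunk):
        out[i:i + chunk] = oaconvolve(flat[i:i + chunk], taps[None, :],
                                      mode="same", axes=-1)
    out = out.reshape(padded.shape)
    return out[..., pad:pad + data.shape[-1]]


def bandpass(obj, low: float = 0.1, high: float = 25.0,
             low_transition: float = 0.1, high_transition: float = 6.0):
    """Zero-phase FIR band-pass (Hamming), applied per channel.

    Implemented as a high-pass (narrow transition, so the 0.1 Hz edge is
    meaningful) followed by a low-pass (wide transition, short filter).
    Accepts a ``Recording`` or an ``EpochSet``.
    """
    fs = obj.fs
    if not 0 < low < high < fs / 2:
        raise ValueError(f"invalid band edges ({low}, {high}) at fs={fs}")
    hp = _fir_taps(fs, low, low_transition, pass_zero=False)
    lp = _fir_taps(fs, high, high_transition, pass_zero=True)
    # cascade the two symmetric kernels into one (still symmetric, so a
    # single centred convolution stays zero-phase)
    taps = fftconvolve(hp, lp)
    out = obj.copy()
    out.data = _zero_phase_fir(out.data, taps)
    if hasattr(out, "provenance"):
        out.provenance.append(f"bandpass {low}-{high} Hz")
    return out


def resample(epochs: EpochSet, target_fs: float) -> EpochSet:
    """Polyphase resampling along time; upsampling is not supported."""
    if target_fs > epochs.fs:
        raise ValueError("upsampling is not supported")
    out = epochs.copy()
    if target_fs == epochs.fs:
        return out
    from fractions import Fraction

    frac = Fraction(target_fs / epochs.fs).limit_denominator(1000)
    out.data = resample_poly(epochs.data, frac.numerator, frac.denominator, axis=-1)
    out.fs = float(target_fs)
    out.provenance.append(f"resampled to {target_fs} Hz")
    return out


# ---------------------------------------------------------------------------
# bad channels


def detect_and_mark_bad_channels(rec: Recording, flat_threshold: float = 1e-7,
                                 z_threshold: float = 5.0) -> List[str]:
    """Automated surrogate for visual bad-channel marking.

    A scalp channel is flagged when its RMS is below ``flat_threshold``
    (no signal) or when the robust z-score of its RMS across channels
    exceeds ``z_threshold``.  The MAD in the z-score is floored at 10 % of
    the median RMS so that near-identical channel amplitudes do not make
    the detector hypersensitive to benign spatial structure.
    """
    lay = get_layout(rec.layout_name) if rec.layout_name else None
    scalp = lay.scalp if lay else rec.channel_labels
    idx = [rec.idx(c) for c in scalp if c in rec.channel_labels]
    rms = np.sqrt(np.mean(rec.data[idx] ** 2, axis=1))
    med = np.median(rms)
    mad = np.median(np.abs(rms - med)) * 1.4826
    spread = max(mad, 0.1 * med)
    bads = []
    for i, ch_i in enumerate(idx):
        if rms[i] < flat_threshold or (rms[i] - med) / spread > z_threshold:
            bads.append(rec.channel_labels[ch_i])
    return bads


def interpolate_bads(epochs: EpochSet, bads: Sequence[str],
                     m: int = 4, degree: int = 7, lam: float = 1e-5) -> EpochSet:
    """Replace bad channels by spherical-spline estimates from good ones."""
    from .interpolate import interpolation_matrix

    out = epochs.copy()
    bads = [b for b in bads if b in epochs.channel_labels]
    if not bads:
        return out
    lay = get_layout(epochs.layout_name)
    good = [c for c in epochs.scalp_channels if c not in bads]
    if len(good) < 4:
        raise ValueError("fewer than 4 good scalp channels; cannot interpolate")
    W = interpolation_matrix(
        lay.position_array(good), lay.position_array(bads), m=m, degree=degree, lam=lam
    )
    gi = [epochs.idx(c) for c in good]
    bi = [epochs.idx(c) for c in bads]
    out.data[:, bi, :] = np.einsum("bg,tgs->tbs", W, epochs.data[:, gi, :])
    out.provenance.append(f"interpolated {len(bads)} channels: {bads}")
    return out


# ---------------------------------------------------------------------------
# epoching


def epoch(rec: Recording, events: Optional[StimulusSequence] = None,
          tmin: float = -0.1, tmax: float = 0.5,
          rest_len: float = 8.0) -> EpochSet:
    """Cut continuous data into stimulus-locked or resting epochs.

    Task mode (``events`` given): one epoch per tone event, half-open
    [tmin, tmax) so the sample count is round((tmax - tmin) * fs); events
    whose window exceeds the recording are dropped with a warning.
    Rest mode: consecutive non-overlapping windows of ``rest_len`` seconds
    from the start of the recording; the remainder is dropped.
    """
    fs = rec.fs
    lay = get_layout(rec.layout_name) if rec.layout_name else None
    mastoids = [m for m in (lay.mastoids if lay else ("M1", "M2"))
                if m in rec.channel_labels]
    common = dict(
        fs=fs, channel_labels=list(rec.channel_labels), system=rec.system,
        layout_name=rec.layout_name, eog_channels=list(rec.eog_channels),
        mastoids=mastoids,
    )
    if events is not None:
        n_samp = int(round((tmax - tmin) * fs))
        offset = int(round(tmin * fs))
        rows, slabs = [], []
        n_dropped = 0
        for ev in events.events:
            s0 = ev.onset_sample + offset
            if s0 < 0 or s0 + n_samp > rec.n_samples:
                n_dropped += 1
                continue
            slabs.append(rec.data[:, s0:s0 + n_samp])
            rows.append(dict(condition=ev.tone, is_habituation=ev.is_habituation,
                             follows_deviant=ev.follows_deviant,
                             onset_sample=ev.onset_sample))
        if n_dropped:
            warnings.warn(f"dropped {n_dropped} events outside recording bounds")
        if not rows:
            raise ValueError("no events fall inside the recording")
        data = np.stack(slabs)
        info = pd.DataFrame(rows)
        es = EpochSet(data=data, tmin=tmin, info=info,
                      kept_mask=np.ones(len(rows), bool), **common)
        es.provenance.append(f"epoched {len(rows)} task trials [{tmin}, {tmax}) s")
        return es

    n_samp = int(round(rest_len * fs))
    n_ep = rec.n_samples // n_samp
    if n_ep < 1:
        raise ValueError("recording shorter than one rest epoch")
    data = rec.data[:, :n_ep * n_samp].reshape(rec.data.shape[0], n_ep, n_samp)
    data = np.transpose(data, (1, 0, 2))
    info = pd.DataFrame(dict(condition=["rest"] * n_ep,
                             is_habituation=[False] * n_ep,
                             follows_deviant=[False] * n_ep,
                             onset_sample=np.arange(n_ep) * n_samp))
    es = EpochSet(data=data.copy(), tmin=0.0, info=info,
                  kept_mask=np.ones(n_ep, bool), **common)
    es.provenance.append(f"epoched {n_ep} rest epochs of {rest_len} s")
    return es


# ---------------------------------------------------------------------------
# ICA ocular rejection


class EogICA:
    """Extended-infomax ICA with EOG-correlation component rejection.

    Fitted on kept epochs' scalp channels concatenated in time (EOG and
    mastoid channels are excluded from the decomposition): the data is
    reduced to ``n_components`` principal components, whitened, and
    unmixed with the extended infomax algorithm — the standard choice
    for scalp EEG, able to isolate both super-Gaussian (blink, saccade)
    and sub-Gaussian sources.  Components whose activation time course
    correlates with either bipolar EOG channel above the threshold
    (absolute Pearson r) are removed; the fitted transform can be
    re-applied to differently epoched data from the same recording.
    """

    def __init__(self, n_components: int = 15, corr_threshold: float = 0.2,
                 seed: int = 0, max_iter: int = 300):
        self.n_components = n_components
        self.corr_threshold = corr_threshold
        self.seed = seed
        self.max_iter = max_iter
        self.rejected_: List[int] = []

    #: cap on time samples used to fit the unmixing (fitting on a strided
    #: subset of the heavily autocorrelated signal loses nothing; scoring
    #: and cleaning always use every sample)
    max_fit_samples: int = 40_000

    def _scalp_matrix(self, epochs: EpochSet) -> np.ndarray:
        si = [epochs.idx(c) for c in self.scalp_]
        return epochs.data[:, si, :].transpose(1, 0, 2).reshape(len(si), -1).T

    def fit(self, epochs: EpochSet) -> "EogICA":
        from mne.preprocessing import infomax

        eog = [c for c in ("vEOG", "hEOG") if c in epochs.channel_labels]
        if not eog:
            raise ValueError("no bipolar EOG channels; derive them before ICA")
        self.scalp_ = epochs.scalp_channels
        if self.n_components > len(self.scalp_):
            raise ValueError("n_components exceeds number of scalp channels")
        kept = epochs.kept()
        X = self._scalp_matrix(kept)
        self.mean_ = X.mean(axis=0)
        stride = max(1, X.shape[0] // self.max_fit_samples)
        sub = X[::stride] - self.mean_

        # PCA reduction + whitening
        _, sv, Vt = np.linalg.svd(sub, full_matrices=False)
        scale = sv[: self.n_components] / np.sqrt(sub.shape[0])
        if scale[-1] <= 0:
            raise ValueError("rank-deficient data; cannot whiten")
        white = Vt[: self.n_components] / scale[:, None]  # channels -> whitened

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            unmix = infomax(sub @ white.T, extended=True,
                            random_state=self.seed, max_iter=self.max_iter,
                            verbose="error")
        self.unmixing_ = unmix @ white                  # channels -> sources
        self.mixing_ = np.linalg.pinv(self.unmixing_)   # channels x sources

        S = (X - self.mean_) @ self.unmixing_.T
        eog_sig = {c: kept.data[:, kept.idx(c), :].reshape(-1) for c in eog}
        self.rejected_ = []
        self.corrs_ = np.zeros((self.n_components, len(eog)))
        for k in range(self.n_components):
            for j, c in enumerate(eog):
                self.corrs_[k, j] = np.corrcoef(S[:, k], eog_sig[c])[0, 1]
            if np.max(np.abs(self.corrs_[k])) > self.corr_threshold:
                self.rejected_.append(k)
        return self

    def clean(self, epochs: EpochSet) -> EpochSet:
        """Subtract the rejected components' contribution from all trials."""
        out = epochs.copy()
        if not self.rejected_:
            out.provenance.append("ICA: 0 components rejected")
            return out
        si = [out.idx(c) for c in self.scalp_]
        n_tr, _, n_s = out.data.shape
        X = out.data[:, si, :].transpose(1, 0, 2).reshape(len(si), -1).T
        rej = np.array(self.rejected_)
        S_rej = (X - self.mean_) @ self.unmixing_[rej].T
        X_rej = S_rej @ self.mixing_[:, rej].T
        cleaned = (X - X_rej).T.reshape(len(si), n_tr, n_s).transpose(1, 0, 2)
        out.data[:, si, :] = cleaned
        out.provenance.append(f"ICA: rejected components {self.rejected_}")
        return out


def ica_reject_eog(epochs: EpochSet, n_components: int = 15,
                   corr_threshold: float = 0.2, seed: int = 0,
                   report: Optional[PreprocReport] = None,
                   max_iter: int = 300,
                   ) -> Tuple[EpochSet, PreprocReport, EogICA]:
    """Fit EOG-targeted ICA on the epochs and reconstruct without ocular
    components; returns the cleaned epochs, an updated report and the
    fitted model (reusable on wider epochs of the same data)."""
    model = EogICA(n_components=n_components, corr_threshold=corr_threshold,
                   seed=seed, max_iter=max_iter).fit(epochs)
    cleaned = model.clean(epochs)
    report = report or PreprocReport()
    report.n_components_rejected = len(model.rejected_)
    return cleaned, report, model


# ---------------------------------------------------------------------------
# trial rejection and orchestration


def reject_trials_ptp(epochs: EpochSet, threshold: float = 150e-3,
                      report: Optional[PreprocReport] = None,
                      ) -> Tuple[EpochSet, PreprocReport]:
    """Reject trials whose max-over-scalp-channels peak-to-peak amplitude
    exceeds the threshold (in volts)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    out = epochs.copy()
    si = [out.idx(c) for c in out.scalp_channels]
    ptp = out.data[:, si, :].max(axis=2) - out.data[:, si, :].min(axis=2)
    bad = ptp.max(axis=1) > threshold if threshold > 0 else np.ones(out.n_trials, bool)
    out.drop_trials(bad & out.kept_mask, f"peak-to-peak > {threshold} V")
    report = report or PreprocReport()
    report.n_trials_rejected += int(bad.sum())
    report.fraction_trials_retained = float(out.kept_mask.mean())
    return out, report


def preprocess_task(rec: Recording, cfg: Optional[PreprocConfig] = None,
                    make_tfr_epochs: bool = True):
    """Run the full task preprocessing chain on a continuous recording.

    Returns ``(erp_epochs, tfr_epochs, report)``: narrow epochs for ERP
    analysis, wide (+-1.2 s) epochs for time-frequency analysis cleaned
    with the same ICA transform and sharing the trial-rejection mask by
    event identity, and the preprocessing report (inclusion still pending
    the SNR computed downstream).  ``tfr_epochs`` is None when
    ``make_tfr_epochs`` is False.
    """
    cfg = cfg or PreprocConfig()
    report = PreprocReport()

    rec = rereference_average_mastoids(rec)
    bads = detect_and_mark_bad_channels(rec, cfg.flat_threshold, cfg.z_threshold)
    report.rejected_channels = bads
    report.n_channels_rejected = len(bads)
    rec = bandpass(rec, *cfg.band, cfg.low_transition, cfg.high_transition)

    erp = epoch(rec, rec.events, cfg.task_tmin, cfg.task_tmax)
    erp = resample(erp, cfg.target_fs)
    erp = derive_bipolar_eog(erp)
    tfr = None
    if make_tfr_epochs:
        # slightly wider than the +-1.2 s analysis grid so the grid's
        # edge bins survive resampling
        tfr = epoch(rec, rec.events, -1.25, 1.25)
        tfr = resample(tfr, cfg.target_fs)
        tfr = derive_bipolar_eog(tfr)

    erp, report, model = ica_reject_eog(
        erp, cfg.n_ica_components, cfg.eog_corr_threshold, cfg.seed, report,
        cfg.ica_max_iter)
    erp = interpolate_bads(erp, bads, cfg.interp_order, cfg.interp_degree,
                           cfg.interp_lambda)
    erp, report = reject_trials_ptp(erp, cfg.ptp_threshold, report)

    if tfr is not None:
        tfr = model.clean(tfr)
        tfr = interpolate_bads(tfr, bads, cfg.interp_order, cfg.interp_degree,
                               cfg.interp_lambda)
        # reuse the rejection mask on the wide epochs by event identity
        kept_onsets = set(erp.info.loc[erp.kept_mask, "onset_sample"])
        tfr.drop_trials(~tfr.info["onset_sample"].isin(kept_onsets).to_numpy(),
                        "mask reused from ERP epochs")
    return erp, tfr, report


def preprocess_rest(rec: Recording, cfg: Optional[PreprocConfig] = None):
    """Preprocess a resting-state recording into clean 8 s epochs."""
    cfg = cfg or PreprocConfig()
    report = PreprocReport()
    rec = rereference_average_mastoids(rec)
    bads = detect_and_mark_bad_channels(rec, cfg.flat_threshold, cfg.z_threshold)
    report.rejected_channels = bads
    report.n_channels_rejected = len(bads)
    rec = bandpass(rec, *cfg.band, cfg.low_transition, cfg.high_transition)
    eps = epoch(rec, None, rest_len=cfg.rest_epoch_len)
    eps = resample(eps, cfg.target_fs)
    eps = derive_bipolar_eog(eps)
    eps, report, _ = ica_reject_eog(
        eps, cfg.n_ica_components, cfg.eog_corr_threshold, cfg.seed, report,
        cfg.ica_max_iter)
    eps = interpolate_bads(eps, bads, cfg.interp_order, cfg.interp_degree,
                           cfg.interp_lambda)
    return eps, report
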