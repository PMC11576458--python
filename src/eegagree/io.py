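"""On-disk formats for simulated datasets and results.

Recordings are stored in a documented NumPy ``.npz`` container (float64
volts, channels x samples) with metadata arrays; events go to a TSV with
columns onset_sample, onset_s, tone, is_habituation, follows_deviant;
ground truth to JSON.  These are the pipeline's native interchange
formats; all group-level results are plain CSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .sequence import StimulusSequence
from .synth import GroundTruth, Recording


def save_recording(rec: Recording, path) -> Path:
    """Write a recording to ``<path>.npz`` (+ ``<path>.events.tsv``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    base = path.with_suffix("")
    np.savez_compressed(
        base.with_suffix(".npz"),
        data=rec.data,
        fs=np.array([rec.fs]),
        channel_labels=np.array(rec.channel_labels),
        system=np.array([rec.system]),
        reference=np.array([rec.reference]),
        eog_channels=np.array(rec.eog_channels),
        layout_name=np.array([rec.layout_name or ""]),
        soa=np.array([rec.events.soa if rec.events else np.nan]),
    )
    if rec.events is not None:
        rec.events.to_tsv(base.with_suffix(".events.tsv"))
    return base.with_suffix(".npz")


def load_recording(path) -> Recording:
    path = Path(path)
    with np.load(path, allow_pickle=False) as z:
        events = None
        ev_path = path.with_suffix("").with_suffix(".events.tsv")
        soa = float(z["soa"][0])
        if ev_path.exists():
            events = StimulusSequence.from_tsv(ev_path, soa=soa)
        return Recording(
            data=z["data"],
            fs=float(z["fs"][0]),
            channel_labels=[str(c) for c in z["channel_labels"]],
            system=str(z["system"][0]),
            reference=str(z["reference"][0]),
            eog_channels=[str(c) for c in z["eog_channels"]],
            events=events,
            layout_name=str(z["layout_name"][0]) or None,
        )


def save_truth(truth: GroundTruth, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    truth.to_json(path)


def load_truth(path) -> GroundTruth:
    return GroundTruth.from_json(path)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
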