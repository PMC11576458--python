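"""Channel layouts for the two simulated acquisition systems.

Two fixture layouts are shipped:

* ``wet61`` — 61 scalp electrodes at standard 10-20/10-10 positions plus
  two mastoids (M1, M2) and three periocular EOG electrodes (above, below
  and lateral to the left eye).
* ``dry62`` — 62 scalp electrodes on an equidistant grid with numeric-row
  labels (1Z, 1L, 1LD, ..., 3Z, ...), two mastoids and two periocular EOG
  electrodes (below and lateral to the left eye).

Only labels and 3-D unit-sphere positions are provided; positions are used
for spherical-spline interpolation and for spatial gain profiles in the
simulator, not for volume-conduction modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List

import numpy as np

WET_SCALP_LABELS: List[str] = [
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
]

MASTOIDS = ["M1", "M2"]


@dataclass
class Layout:
    name: str
    system: str  # "wet" or "dry"
    scalp: List[str]
    mastoids: List[str]
    eog: List[str]
    positions: Dict[str, np.ndarray]  # unit-sphere xyz (y anterior, z superior)
    mmn_channel: str
    veog_pair: tuple  # (plus, minus) channels for bipolar vertical EOG
    heog_pair: tuple  # (plus, minus) channels for bipolar horizontal EOG

    @property
    def all_labels(self) -> List[str]:
        return self.scalp + self.mastoids + self.eog

    def position_array(self, labels) -> np.ndarray:
        return np.array([self.positions[l] for l in labels])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


@lru_cache(maxsize=1)
def _standard_positions() -> Dict[str, np.ndarray]:
    import mne

    import warnings

    for name in ("standard_1005", "colin27_1005"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FutureWarning)
                montage = mne.channels.make_standard_montage(name)
            break
        except Exception:
            continue
    pos = montage.get_positions()["ch_pos"]
    return {k: np.asarray(v, dtype=float) for k, v in pos.items()}


def _dry_grid() -> Dict[str, np.ndarray]:
    """62 near-equidistant upper-hemisphere positions with numeric labels.

    Rows run front (1) to back (9); within a row, Z is midline, L/R are
    lateral and LD/RD more lateral-inferior ("down"), loosely mirroring a
    multipin equidistant cap.
    """
    sides = ["Z", "L", "R", "LD", "RD", "LL", "RR"]
    labels = [f"{row}{side}" for row in range(1, 10) for side in sides][:62]
    # golden-angle spiral over the upper hemisphere, re-sorted front-to-back
    n = len(labels)
    idx = np.arange(n)
    z = 0.12 + 0.85 * idx / (n - 1)  # stay above the equator
    r = np.sqrt(1 - z**2)
    phi = idx * np.pi * (3 - np.sqrt(5))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    # anterior-posterior order: sort by decreasing y so row 1 is frontal,
    # and within blocks of 7 spread laterally by x
    order = np.lexsort((pts[:, 0], -pts[:, 1]))
    pts = pts[order]
    out = {}
    for lab, p in zip(labels, pts):
        out[lab] = _unit(p)
    return out


def _make_wet() -> Layout:
    std = _standard_positions()
    positions = {l: _unit(std[l]) for l in WET_SCALP_LABELS + MASTOIDS}
    # periocular electrodes: below/above/lateral to the left eye
    positions["EOGa"] = _unit(np.array([-0.35, 0.95, -0.05]))
    positions["EOGb"] = _unit(np.array([-0.35, 0.95, -0.35]))
    positions["EOGl"] = _unit(np.array([-0.60, 0.80, -0.20]))
    return Layout(
        name="wet61",
        system="wet",
        scalp=list(WET_SCALP_LABELS),
        mastoids=list(MASTOIDS),
        eog=["EOGa", "EOGb", "EOGl"],
        positions=positions,
        mmn_channel="FCz",
        veog_pair=("EOGa", "EOGb"),
        heog_pair=("EOGl", "F7"),
    )


def _make_dry() -> Layout:
    positions = _dry_grid()
    std = _standard_positions()
    positions["M1"] = _unit(std["M1"])
    positions["M2"] = _unit(std["M2"])
    positions["EOGb"] = _unit(np.array([-0.35, 0.95, -0.35]))
    positions["EOGl"] = _unit(np.array([-0.60, 0.80, -0.20]))
    scalp = [l for l in positions if l not in ("M1", "M2", "EOGb", "EOGl")]
    return Layout(
        name="dry62",
        system="dry",
        scalp=scalp,
        mastoids=list(MASTOIDS),
        eog=["EOGb", "EOGl"],
        positions=positions,
        mmn_channel="3Z",
        veog_pair=("EOGb", "1L"),
        heog_pair=("EOGl", "1LD"),
    )


_BUILDERS = {"wet61": _make_wet, "dry62": _make_dry}
DEFAULT_LAYOUTS = {"wet": "wet61", "dry": "dry62"}


def get_layout(name: str) -> Layout:
    """Return a shipped layout by name (``wet61`` or ``dry62``)."""
    if name not in _BUILDERS:
        raise KeyError(f"unknown layout {name!r}; available: {sorted(_BUILDERS)}")
    return _BUILDERS[name]()
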