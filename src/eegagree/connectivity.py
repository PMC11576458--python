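"""Sensor-level resting-state connectivity: PLI and MST diameter.

The phase lag index (PLI) between two signals is the absolute mean sign
of their Hilbert instantaneous phase difference: 0 when phase leads and
lags balance (including perfectly zero-lag coupling, which makes PLI
insensitive to volume-conduction-like mixing) and 1 for a consistently
one-sided lag.  Per subject and band: each 8 s epoch is average-
referenced, band-pass filtered, PLI is computed for every scalp channel
pair, pair values are averaged within an epoch and then across epochs.
PLI matrices are turned into distances and summarized by the minimum
spanning tree's normalized diameter D = d / M (longest within-tree path
in links over total links).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import networkx as nx
import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .preprocess import EpochSet

#: band edges in Hz; beta is restricted to 13-20 Hz to limit muscle artifact
BANDS: Dict[str, Tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 20.0),
}


@dataclass
class PLIMatrix:
    values: np.ndarray  # symmetric, zero diagonal, in [0, 1]
    labels: List[str]
    band: str
    n_epochs: int

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class MSTSummary:
    edges: List[Tuple[str, str, float]]
    d: int  # links on the longest within-tree path
    M: int  # total links = N - 1
    @property
    def D(self) -> float:
        return self.d / self.M


def average_reference(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean over scalp channels (EOG and
    mastoids excluded) from every scalp channel."""
    out = epochs.copy()
    si = [out.idx(c) for c in out.scalp_channels]
    if len(si) < 2:
        raise ValueError("need at least 2 scalp channels")
    mean = out.data[..., si, :].mean(axis=-2, keepdims=True)
    out.data[..., si, :] -= mean
    out.provenance.append("average reference")
    return out


def bandpass_butter(x: np.ndarray, band: Tuple[float, float], fs: float,
                    order: int = 4, pad_s: float = 1.0) -> np.ndarray:
    """Zero-phase Butterworth band-pass with reflection padding along the
    last axis, applied per epoch to limit edge effects."""
    sos = butter(order, band, btype="bandpass", fs=fs, output="sos")
    pad = min(int(pad_s * fs), x.shape[-1] - 1)
    return sosfiltfilt(sos, x, axis=-1, padtype="even", padlen=pad)


def pli_pair(x: np.ndarray, y: np.ndarray, trim: int = 0) -> float:
    """Phase lag index between two equal-length band-limited signals.

    PLI = | mean_t sign( phi_x(t) - phi_y(t) ) | with phases from the
    analytic signal and the phase difference wrapped to (-pi, pi]; exact
    zero (mod pi) differences contribute 0.  ``trim`` drops that many
    samples at each end before averaging (Hilbert edge effects).
    Symmetric in its arguments and invariant to amplitude scaling.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 64:
        raise ValueError("inputs must be equal-length with at least 64 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no defined phase")
    dphi = np.angle(hilbert(x) * np.conj(hilbert(y)))
    if trim:
        dphi = dphi[trim:-trim]
    return float(abs(np.mean(_phase_sign(dphi))))


def _phase_sign(dphi: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Sign of the phase difference; differences that are zero (mod pi) up
    to floating-point noise contribute 0, as an exactly balanced lead/lag."""
    s = np.sin(dphi)
    out = np.sign(s)
    out[np.abs(s) < tol] = 0.0
    return out


def _pli_matrix(data: np.ndarray, trim: int) -> np.ndarray:
    """All-pairs PLI for one epoch (channels x samples), vectorized."""
    phases = np.angle(hilbert(data, axis=-1))
    if trim:
        phases = phases[:, trim:-trim]
    n = data.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        d = phases[i][None, :] - phases[i + 1:]
        out[i, i + 1:] = np.abs(np.mean(_phase_sign(d), axis=-1))
    return out + out.T


def subject_pli(rest_epochs: EpochSet, band: str | Tuple[float, float],
                edge_trim_s: float = 0.5,
                reference: bool = True) -> Tuple[PLIMatrix, float]:
    """Band-specific PLI matrix and global mean PLI for one subject.

    Pair values are averaged over the upper triangle within each epoch,
    then across epochs (epoch-mean of pair-means); the matrix holds the
    per-pair epoch average.  The first and last ``edge_trim_s`` seconds of
    each epoch's phase series are excluded.
    """
    band_name, edges = (band, BANDS[band]) if isinstance(band, str) else ("custom", band)
    if edges[1] >= rest_epochs.fs / 2:
        raise ValueError("band extends beyond Nyquist")
    eps = rest_epochs.kept()
    if eps.n_trials < 1:
        raise ValueError("no kept rest epochs")
    if reference:
        eps = average_reference(eps)
    si = [eps.idx(c) for c in eps.scalp_channels]
    labels = eps.scalp_channels
    trim = int(edge_trim_s * eps.fs)
    mats = []
    for t in range(eps.n_trials):
        x = bandpass_butter(eps.data[t, si, :], edges, eps.fs)
        mats.append(_pli_matrix(x, trim))
    mats = np.array(mats)
    matrix = mats.mean(axis=0)
    iu = np.triu_indices(len(labels), 1)
    mean_pli = float(mats[:, iu[0], iu[1]].mean(axis=1).mean())
    return (PLIMatrix(values=matrix, labels=labels, band=band_name,
                      n_epochs=eps.n_trials), mean_pli)


def pli_to_distance(p: PLIMatrix | np.ndarray, transform: str = "one_minus") -> np.ndarray:
    """Turn a PLI (similarity) matrix into distances for MST algorithms.

    ``one_minus``: d = 1 - PLI (bounded, default); ``inverse``: d = 1/PLI
    with infinity for zero entries.  Both are strictly decreasing in PLI,
    so they yield the same MST whenever it is unique.
    """
    v = p.values if isinstance(p, PLIMatrix) else np.asarray(p, float)
    if transform == "one_minus":
        d = 1.0 - v
    elif transform == "inverse":
        with np.errstate(divide="ignore"):
            d = np.where(v > 0, 1.0 / np.maximum(v, 1e-300), np.inf)
    else:
        raise ValueError("transform must be 'one_minus' or 'inverse'")
    np.fill_diagonal(d, 0.0)
    return d


def mst_diameter(distances: np.ndarray, labels: List[str]) -> MSTSummary:
    """Kruskal MST of the complete weighted graph and its normalized
    diameter D = d / M.

    Ties are broken deterministically by lexicographic edge label order.
    The diameter in links is found by double breadth-first search (exact
    on trees).
    """
    distances = np.asarray(distances, float)
    n = len(labels)
    if distances.shape != (n, n):
        raise ValueError("distance matrix does not match labels")
    if not np.all(np.isfinite(distances[np.triu_indices(n, 1)])):
        raise ValueError("graph has non-finite edge weights (disconnected)")
    g = nx.Graph()
    g.add_nodes_from(labels)
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(labels[i], labels[j], weight=float(distances[i, j]))
    # stable tie-break: sort by (weight, labels) before Kruskal
    edges = sorted(g.edges(data=True),
                   key=lambda e: (e[2]["weight"], str(e[0]), str(e[1])))
    tree = nx.Graph()
    tree.add_nodes_from(labels)
    uf = nx.utils.UnionFind(labels)
    tree_edges = []
    for u, v, d_ in edges:
        if uf[u] != uf[v]:
            uf.union(u, v)
            tree.add_edge(u, v, weight=d_["weight"])
            tree_edges.append((u, v, d_["weight"]))
            if tree.number_of_edges() == n - 1:
                break
    # double-BFS diameter in links
    def farthest(src):
        lengths = nx.single_source_shortest_path_length(tree, src)
        node = max(lengths, key=lambda k: (lengths[k], str(k)))
        return node, lengths[node]

    a, _ = farthest(labels[0])
    _, d_links = farthest(a)
    return MSTSummary(edges=tree_edges, d=int(d_links), M=n - 1)


def write_mst_edges(mst: MSTSummary, path) -> None:
    """Export the tree's edge list as TSV (node_i, node_j, distance)."""
    import pandas as pd

    pd.DataFrame(mst.edges, columns=["node_i", "node_j", "distance"]).to_csv(
        path, sep="\t", index=False)


def analyze_connectivity(rest_epochs: EpochSet,
                         bands: Dict[str, Tuple[float, float]] = BANDS,
                         transform: str = "one_minus") -> Dict[str, dict]:
    """Per-band mean PLI and MST summary for one subject."""
    out = {}
    for name in bands:
        mat, mean_pli = subject_pli(rest_epochs, name)
        mst = mst_diameter(pli_to_distance(mat, transform), mat.labels)
        out[name] = dict(mean_pli=mean_pli, mst=mst, pli=mat,
                         d=mst.d, M=mst.M, diameter=mst.D)
    return out
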