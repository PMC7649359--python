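"""PLI-weighted electrode networks and their weighted graph metrics.

The functional network has one node per electrode and edge weights given by
the phase lag index (PLI) of the band-limited (8-26 Hz) signals: the
absolute time-average of the sign of the instantaneous phase difference.
PLI is insensitive to zero-lag (volume-conducted) coupling — a zero phase
difference contributes 0 to the sign average — and is bounded in [0, 1].

Networks are thresholded by sparsity (fraction of retained edges out of all
possible pairs, strongest first) and summarized by the weighted clustering
coefficient (wCC, Onnela geometric-mean triangle intensity; local
efficiency) and the weighted shortest path length (wsPL, Dijkstra on edge
lengths 1/w; global efficiency).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import signal
from scipy.sparse.csgraph import shortest_path

from .containers import EpochSet
from .spectral import bandpass

ALPHA_BETA_BAND: tuple[float, float] = (8.0, 26.0)
#: the studied sparsity grid: 0.10 to 0.20 in steps of 0.02
SPARSITY_GRID: tuple[float, ...] = (0.10, 0.12, 0.14, 0.16, 0.18, 0.20)


@dataclass
class ConnectivityGraph:
    """Symmetric PLI-weighted adjacency over electrodes (zero diagonal)."""

    labels: tuple[str, ...]
    weights: np.ndarray
    band: tuple[float, float] = ALPHA_BETA_BAND
    condition: str = ""
    sparsity: float | None = None  # set after thresholding

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.labels), len(self.labels)):
            raise ValueError("weight matrix shape does not match labels")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.abs(np.diag(w)).max(initial=0.0) != 0:
            raise ValueError("weight matrix must have a zero diagonal")
        if w.min(initial=0.0) < 0 or w.max(initial=0.0) > 1 + 1e-12:
            raise ValueError("PLI weights must lie in [0, 1]")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))


def compute_pli(
    epochs: EpochSet,
    band: tuple[float, float] = ALPHA_BETA_BAND,
    filter_order: int = 4,
    edge_s: float = 0.25,
) -> ConnectivityGraph:
    """PLI between every channel pair, per trial then averaged across trials.

    Instantaneous phase comes from the analytic signal of the band-passed
    epoch; the sign average runs over the embodiment window when one has
    been selected, otherwise over the epoch interior (trimmed by ``edge_s``
    on both sides to discard filter/Hilbert transients).
    """
    if len(epochs.ch_names) < 2:
        raise ValueError("PLI needs at least 2 channels")
    fs = epochs.fs
    x = bandpass(epochs.data, band, fs, order=filter_order)
    phase = np.angle(signal.hilbert(x, axis=-1))
    if epochs.analysis_start is not None and np.isfinite(epochs.analysis_dur):
        offs = np.rint((epochs.analysis_start - epochs.times[0]) * fs).astype(int)
        n_seg = int(round(epochs.analysis_dur * fs))
        idx = offs[:, None] + np.arange(n_seg)[None, :]
        phase = np.take_along_axis(phase, idx[:, None, :], axis=2)
    else:
        trim = int(round(edge_s * fs))
        if phase.shape[-1] <= 2 * trim + 8:
            raise ValueError("epoch too short for the filter transient allowance")
        if trim:
            phase = phase[..., trim:-trim]
    n_ch = phase.shape[1]
    w = np.zeros((n_ch, n_ch))
    for i in range(n_ch - 1):
        d = phase[:, i, None, :] - phase[:, i + 1:, :]
        pli = np.abs(np.sign(np.sin(d)).mean(axis=-1)).mean(axis=0)
        w[i, i + 1:] = pli
        w[i + 1:, i] = pli
    return ConnectivityGraph(labels=epochs.ch_names, weights=w, band=band,
                             condition=_condition_label(epochs))


def _condition_label(epochs: EpochSet) -> str:
    conds = epochs.info["condition"].unique()
    return conds[0] if len(conds) == 1 else "mixed"


def edge_count(n_nodes: int, sparsity: float) -> int:
    """Number of retained edges: round(sparsity * n(n-1)/2), half away from zero."""
    m = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(sparsity * m + 0.5))


def threshold_by_sparsity(graph: ConnectivityGraph, sparsity: float) -> ConnectivityGraph:
    """Keep the k strongest edges (k from the sparsity), zero the rest.

    Ties are broken by fixed lexicographic (i, j) node-pair order, which
    makes the edge sets nested across an increasing sparsity grid. Retained
    weights are unchanged.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must be in (0, 1]")
    k = edge_count(graph.n_nodes, sparsity)
    if k == 0:
        raise ValueError(f"sparsity {sparsity} retains no edges on {graph.n_nodes} nodes")
    iu, ju = np.triu_indices(graph.n_nodes, 1)
    w = graph.weights[iu, ju]
    order = np.argsort(-w, kind="stable")  # stable: lexicographic among ties
    keep = order[:k]
    new = np.zeros_like(graph.weights)
    new[iu[keep], ju[keep]] = w[keep]
    new += new.T
    return replace(graph, weights=new, sparsity=float(sparsity))


def weighted_clustering(graph: ConnectivityGraph, normalize: bool = True) -> float:
    """Network-level weighted clustering coefficient (Onnela form).

    Per node, the geometric-mean triangle intensity
    ``sum_{j,h} (w_ij w_ih w_jh)^(1/3) / (k_i (k_i - 1))`` over the
    binarized degree ``k_i``; weights are first normalized by the maximum
    retained weight (keeps the value in [0, 1] across sparsities). Nodes with
    fewer than two neighbors contribute 0; the network value is the mean
    over all nodes.
    """
    w = graph.weights
    if graph.n_edges == 0:
        raise ValueError("graph has no edges")
    if normalize:
        w = w / w.max()
    c = np.cbrt(w)
    num = np.diagonal(c @ c @ c).copy()  # 2 * sum of triangle intensities per node
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    per_node = np.where(denom > 0, num / np.where(denom > 0, denom, 1), 0.0)
    return float(per_node.mean())


class PathLength(NamedTuple):
    """wsPL result; ``disconnected`` flags that some node pairs were excluded."""

    value: float
    disconnected: bool


def weighted_shortest_path_length(graph: ConnectivityGraph) -> PathLength:
    """Network-level weighted shortest path length.

    Edge lengths are 1/w on retained edges; the value is the mean Dijkstra
    distance over all connected ordered node pairs. Disconnected pairs are
    excluded and flagged.
    """
    if graph.n_edges == 0:
        raise ValueError("graph has no edges")
    with np.errstate(divide="ignore"):
        lengths = np.where(graph.weights > 0, 1.0 / graph.weights, np.inf)
    d = shortest_path(lengths, method="D", directed=False)
    off = ~np.eye(graph.n_nodes, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise ValueError("no connected node pairs")
    return PathLength(float(d[finite].mean()), bool((~np.isfinite(d) & off).any()))


def metric_sweep(
    graph: ConnectivityGraph,
    sparsity_grid: tuple[float, ...] = SPARSITY_GRID,
    normalize: bool = True,
) -> pd.DataFrame:
    """wCC and wsPL across the sparsity grid.

    Returns a tidy frame (condition, sparsity, wcc, wspl, disconnected);
    edge sets are nested across increasing sparsity by construction.
    """
    rows = []
    for s in sparsity_grid:
        g = threshold_by_sparsity(graph, s)
        wspl = weighted_shortest_path_length(g)
        rows.append({
            "condition": graph.condition, "sparsity": float(s),
            "wcc": weighted_clustering(g, normalize=normalize),
            "wspl": wspl.value, "disconnected": wspl.disconnected,
        })
    return pd.DataFrame(rows)
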