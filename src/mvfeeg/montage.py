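"""Electrode montage geometry for the 32-channel extended 10/20 layout.

Positions come from MNE's idealized ``standard_1020`` montage. Everything the
rest of the package needs from the montage — 2-D scalp coordinates, homologous
left/right channel pairs, and small-Laplacian nearest-neighbor sets — is
derived here once and carried around as plain dictionaries so that downstream
results are reproducible regardless of upstream montage library changes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

#: Channel labels of the 32-channel extended 10/20 cap, in recording order.
CHANNELS_32: tuple[str, ...] = (
    "Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "PO4", "PO8", "Oz",
)

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(z|\d+)$")


def _standard_positions(channels: tuple[str, ...]) -> np.ndarray:
    """3-D head-frame positions (meters) for the requested labels."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        std = mne.channels.make_standard_montage("standard_1020")
    pos = std.get_positions()["ch_pos"]
    missing = [c for c in channels if c not in pos]
    if missing:
        raise KeyError(f"channels absent from standard_1020 montage: {missing}")
    return np.array([pos[c] for c in channels], dtype=float)


def azimuthal_projection(pos3d: np.ndarray) -> np.ndarray:
    """Project 3-D scalp positions to 2-D (azimuthal equidistant from vertex).

    Radius is the polar angle from the vertex, so Cz maps near the origin and
    the projection preserves along-scalp distance ordering well enough for
    neighbor selection and topographic display.
    """
    p = pos3d - pos3d.mean(axis=0, keepdims=True) * 0  # head frame already centered
    r = np.linalg.norm(p, axis=1)
    theta = np.arccos(np.clip(p[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(p[:, 1], p[:, 0])
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


def homologous_pair(label: str) -> str:
    """Mirror a 10/20 label across the midline (C3 -> C4, Fp2 -> Fp1, Cz -> Cz)."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"not a 10/20-style label: {label!r}")
    stem, idx = m.groups()
    if idx == "z":
        return label
    n = int(idx)
    return f"{stem}{n + 1 if n % 2 == 1 else n - 1}"


@dataclass(frozen=True)
class Montage:
    """Frozen scalp geometry: labels, positions, pairs, neighbor sets."""

    channels: tuple[str, ...]
    pos3d: np.ndarray
    pos2d: np.ndarray
    #: per-channel tuple of neighbor labels used by the small-Laplacian filter
    neighbors: dict[str, tuple[str, ...]] = field(repr=False)

    def __len__(self) -> int:
        return len(self.channels)

    def index(self, label: str) -> int:
        return self.channels.index(label)

    def homologous_pairs(self) -> list[tuple[str, str]]:
        """Left/right channel pairs (each pair listed once, left first)."""
        pairs = []
        for c in self.channels:
            mate = homologous_pair(c)
            if mate == c:
                continue
            if mate not in self.channels:
                raise ValueError(f"unpaired lateral channel {c!r} in montage")
            if (mate, c) not in [(a, b) for a, b in pairs] and (c, mate) not in pairs:
                if int(_LABEL_RE.match(c).group(2)) % 2 == 1:  # left hemisphere first
                    pairs.append((c, mate))
        return pairs


def neighbor_sets(
    channels: tuple[str, ...], pos3d: np.ndarray, k: int = 4
) -> dict[str, tuple[str, ...]]:
    """k nearest neighbors per channel by Euclidean scalp distance.

    Channels in reduced montages may end up with fewer than ``k`` neighbors
    only if the montage itself has fewer than ``k + 1`` channels.
    """
    n = len(channels)
    if n < 2:
        raise ValueError("montage must contain at least 2 channels")
    kk = min(k, n - 1)
    d = np.linalg.norm(pos3d[:, None, :] - pos3d[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    out = {}
    for i, c in enumerate(channels):
        idx = np.argsort(d[i], kind="stable")[:kk]
        out[c] = tuple(channels[j] for j in idx)
    return out


def make_montage(channels: tuple[str, ...] | list[str] = CHANNELS_32, n_neighbors: int = 4) -> Montage:
    """Build the frozen :class:`Montage` for a channel subset of extended 10/20."""
    channels = tuple(channels)
    pos3d = _standard_positions(channels)
    return Montage(
        channels=channels,
        pos3d=pos3d,
        pos2d=azimuthal_projection(pos3d),
        neighbors=neighbor_sets(channels, pos3d, k=n_neighbors),
    )
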