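"""In-memory containers shared across the pipeline.

A :class:`Recording` is one continuous run of multichannel EEG with its
montage; an :class:`EpochSet` is the trial-locked tensor cut from it, carrying
per-trial condition labels and pedal (embodiment-onset) times relative to the
go cue. Analysis windows are half-open ``[start, start + dur)`` in seconds,
with the go cue at t = 0 and 0-based sample indices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .montage import Montage

CONDITIONS: tuple[str, ...] = ("NV", "CV", "IV")


@dataclass
class Recording:
    """One continuous EEG run: channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    montage: Montage
    handedness: str = "right"  # {"left", "right"}
    subject: int = 0
    run_id: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be channels x samples")
        if self.data.shape[0] != len(self.montage):
            raise ValueError(
                f"channel count {self.data.shape[0]} does not match montage "
                f"size {len(self.montage)}"
            )
        if self.handedness not in ("left", "right"):
            raise ValueError(f"handedness must be 'left' or 'right', got {self.handedness!r}")

    @property
    def ch_names(self) -> tuple[str, ...]:
        return self.montage.channels

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy())


@dataclass
class EpochSet:
    """Trial-locked EEG tensor: trials x channels x samples.

    ``times`` is the common within-epoch time axis in seconds relative to the
    go cue. ``info`` holds one row per trial (subject, run, trial, condition,
    t_pedal_s where available). ``analysis_start`` is the per-trial start of
    the embodiment analysis window (seconds relative to go), NaN until
    :func:`mvfeeg.preprocess.select_embodiment_epochs` has run.
    """

    data: np.ndarray
    times: np.ndarray
    fs: float
    montage: Montage
    info: pd.DataFrame
    analysis_start: np.ndarray | None = None
    analysis_dur: float = float("nan")
    baseline: tuple[float, float] = (-0.9, -0.1)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be trials x channels x samples")
        if self.data.shape[2] != self.times.size:
            raise ValueError("times axis does not match data")
        if self.data.shape[1] != len(self.montage):
            raise ValueError("channel axis does not match montage")
        if len(self.info) != self.data.shape[0]:
            raise ValueError("info rows do not match trial count")
        bad = set(self.info["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if self.analysis_start is not None:
            self.analysis_start = np.asarray(self.analysis_start, dtype=float)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def ch_names(self) -> tuple[str, ...]:
        return self.montage.channels

    def channel_index(self, label: str) -> int:
        return self.montage.index(label)

    def subset(self, mask: np.ndarray) -> "EpochSet":
        """New EpochSet keeping trials where ``mask`` is True (order preserved)."""
        mask = np.asarray(mask, dtype=bool)
        return EpochSet(
            data=self.data[mask],
            times=self.times,
            fs=self.fs,
            montage=self.montage,
            info=self.info.loc[mask].reset_index(drop=True),
            analysis_start=None if self.analysis_start is None else self.analysis_start[mask],
            analysis_dur=self.analysis_dur,
            baseline=self.baseline,
        )

    def pick_condition(self, condition: str) -> "EpochSet":
        return self.subset((self.info["condition"] == condition).to_numpy())

    def time_slice(self, start: float, dur: float) -> slice:
        """Sample slice for the half-open window [start, start + dur)."""
        i0 = int(np.rint((start - self.times[0]) * self.fs))
        n = int(np.rint(dur * self.fs))
        if i0 < 0 or i0 + n > self.times.size:
            raise ValueError(f"window [{start}, {start + dur}) outside epoch")
        return slice(i0, i0 + n)
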