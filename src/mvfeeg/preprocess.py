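"""From continuous recordings to clean, spatially filtered, analysis-ready epochs.

The preprocessing chain mirrors how the embodiment paradigm is analyzed:
epochs are cut around the go cue, trials contaminated by large drifts or
electrode spikes are rejected by amplitude/slope criteria, left-handed
subjects' channels are mirrored so that C3 is always the dominant (static)
hemisphere, trials without a pedal press — or with less than the analysis
window remaining after it — are dropped, and a small-Laplacian spatial filter
(each channel minus the mean of its nearest neighbors) accentuates local
activity before any spectral estimate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import EpochSet, Recording
from .montage import Montage, homologous_pair


def epoch_recording(
    recording: Recording,
    events: pd.DataFrame,
    tmin: float = -1.5,
    tmax: float = 10.0,
) -> EpochSet:
    """Cut one epoch per event-log trial, time-locked to the go cue.

    ``tmin``/``tmax`` are seconds relative to go; the default window keeps
    the pre-go baseline and the full 10 s task. Channel order, sampling rate
    and labels are preserved.
    """
    ev = events[
        (events["subject"] == recording.subject) & (events["run"] == recording.run_id)
    ].reset_index(drop=True)
    if len(ev) == 0:
        raise ValueError(
            f"no events for subject {recording.subject} run {recording.run_id}"
        )
    fs = recording.fs
    n = int(np.rint((tmax - tmin) * fs))
    times = tmin + np.arange(n) / fs
    data = np.empty((len(ev), recording.data.shape[0], n))
    for t, go in enumerate(ev["t_go_s"].to_numpy()):
        i0 = int(np.rint((go + tmin) * fs))
        if i0 < 0 or i0 + n > recording.n_samples:
            raise ValueError(f"epoch window for trial {t} outside recording")
        data[t] = recording.data[:, i0:i0 + n]
    info = ev[["subject", "run", "trial", "condition"]].copy()
    info["t_pedal_s"] = (ev["t_pedal_s"] - ev["t_go_s"]).to_numpy()
    return EpochSet(data=data, times=times, fs=fs, montage=recording.montage, info=info)


def reject_artifact_trials(
    epochs: EpochSet,
    peak_to_peak_uv: float = 150.0,
    drift_uv_per_s: float = 20.0,
) -> tuple[EpochSet, pd.DataFrame]:
    """Drop trials whose any channel exceeds a peak-to-peak amplitude or a
    fitted linear drift slope criterion.

    Returns the surviving epochs (order preserved) and a per-trial report
    with columns (subject, run, trial, kept, reason). Raises if every trial
    is rejected.
    """
    if peak_to_peak_uv <= 0 or drift_uv_per_s <= 0:
        raise ValueError("rejection thresholds must be positive")
    x = epochs.data
    ptp = x.max(axis=2) - x.min(axis=2)  # trials x channels
    # least-squares slope of each trial/channel against time
    t = epochs.times - epochs.times.mean()
    slope = (x * t).mean(axis=2) / (t * t).mean()
    ptp_bad = (ptp > peak_to_peak_uv).any(axis=1)
    drift_bad = (np.abs(slope) > drift_uv_per_s).any(axis=1)
    keep = ~(ptp_bad | drift_bad)
    reasons = np.where(
        keep, "", np.where(ptp_bad & drift_bad, "peak_to_peak+drift",
                           np.where(ptp_bad, "peak_to_peak", "drift"))
    )
    report = epochs.info[["subject", "run", "trial"]].copy()
    report["kept"] = keep
    report["reason"] = reasons
    if not keep.any():
        raise ValueError("all trials rejected as artifactual")
    return epochs.subset(keep), report


def flip_left_handed(recording: Recording) -> Recording:
    """Mirror the montage of a left-handed subject's recording.

    Data of each homologous channel pair (C3<->C4, F3<->F4, ...) are swapped
    so that, across subjects, C4 is always the non-dominant (active) side and
    C3 the dominant (static) side. Midline channels map to themselves. The
    operation is an involution; right-handed recordings pass through
    unchanged.
    """
    if recording.handedness == "right":
        return recording
    rec = recording.copy()
    chans = rec.ch_names
    perm = np.arange(len(chans))
    for i, c in enumerate(chans):
        mate = homologous_pair(c)
        if mate == c:
            continue
        if mate not in chans:
            raise ValueError(f"unpaired lateral channel {c!r}: no {mate!r} in montage")
        perm[i] = chans.index(mate)
    rec.data = rec.data[perm]
    rec.handedness = "right"  # now in canonical orientation
    return rec


def select_embodiment_epochs(
    epochs: EpochSet, win_dur_s: float = 4.0, task_end_s: float = 10.0
) -> EpochSet:
    """Keep trials where embodiment lasted at least ``win_dur_s``.

    Trials with no pedal press, or with less than ``win_dur_s`` of task left
    after the press (the task ends at ``task_end_s`` relative to go), are
    dropped; survivors carry the analysis window
    [t_pedal, t_pedal + win_dur_s) relative to the go cue.
    """
    pedal = epochs.info["t_pedal_s"].to_numpy(dtype=float)
    task_end = min(task_end_s, float(epochs.times[-1]) + 1.0 / epochs.fs)
    keep = np.isfinite(pedal) & (pedal + win_dur_s <= task_end + 1e-9)
    if not keep.any():
        warnings.warn("no trials with sufficient embodiment duration", stacklevel=2)
    out = epochs.subset(keep)
    out.analysis_start = pedal[keep]
    out.analysis_dur = float(win_dur_s)
    return out


def small_laplacian(data: np.ndarray, montage: Montage) -> np.ndarray:
    """Small-Laplacian spatial filter: channel minus mean of its neighbors.

    ``data`` may be channels x samples or trials x channels x samples; the
    channel axis must match the montage, whose frozen nearest-neighbor sets
    define the filter. A spatially uniform field maps to exact zero when
    neighbor counts are powers of two (pairwise summation is then exact).
    """
    data = np.asarray(data, dtype=float)
    ch_axis = data.ndim - 2
    if data.shape[ch_axis] != len(montage):
        raise ValueError("channel axis does not match montage")
    out = np.empty_like(data)
    idx = [tuple(montage.index(n) for n in montage.neighbors[c]) for c in montage.channels]
    x = np.moveaxis(data, ch_axis, 0)
    o = np.moveaxis(out, ch_axis, 0)
    for i, nb in enumerate(idx):
        if len(nb) == 0:
            raise ValueError(f"channel {montage.channels[i]!r} has no neighbors")
        if len(nb) == 4:  # pairwise grouping: exact for identical values
            s = (x[nb[0]] + x[nb[1]]) + (x[nb[2]] + x[nb[3]])
        else:
            s = np.add.reduce([x[j] for j in nb])
        o[i] = x[i] - s / len(nb)
    return out


def laplacian_epochs(epochs: EpochSet) -> EpochSet:
    """Apply the small-Laplacian filter to every epoch, returning a new set."""
    out = EpochSet(
        data=small_laplacian(epochs.data, epochs.montage),
        times=epochs.times,
        fs=epochs.fs,
        montage=epochs.montage,
        info=epochs.info.copy(),
        analysis_start=None if epochs.analysis_start is None else epochs.analysis_start.copy(),
        analysis_dur=epochs.analysis_dur,
        baseline=epochs.baseline,
    )
    return out
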