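"""Baseline-referenced spectral measures: ERSP maps, ERD/ERS curves, topographies.

All three measures share the same parameterization: a 0.8 s sliding window
advanced in 4 ms steps across the first 4 s of embodiment (the per-trial
window starting at the pedal press), referenced to the -0.9..-0.1 s pre-go
baseline.

ERSP: each tapered segment is Fourier transformed; amplitude spectra are
divided by the trial-set mean baseline amplitude spectrum, averaged across
trials, and expressed as 20*log10 dB — negative values mean power loss
against baseline. Averaging the normalized amplitude across trials before
taking the log keeps the stationary-signal expectation at 0 dB (log-then-
average would carry a negative small-sample bias).

ERD/ERS: the band-passed signal is squared and averaged within each window;
the curve is 100 * (P(t) - P_base) / P_base in percent, so desynchronization
is negative and bounded below by -100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .containers import EpochSet

BANDS: dict[str, tuple[float, float]] = {"alpha": (8.0, 13.0), "beta": (13.0, 26.0)}


@dataclass(frozen=True)
class SpectralParams:
    """Sliding-window spectral parameters (defaults follow the paradigm)."""

    baseline: tuple[float, float] = (-0.9, -0.1)  # seconds relative to go
    win_dur_s: float = 0.8
    step_s: float = 0.004
    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(BANDS))
    taper: str = "hann"
    #: "amplitude" -> 20*log10 on amplitude ratios; "power" -> 10*log10 on power
    ersp_mode: str = "amplitude"
    filter_order: int = 4
    #: baseline pooling: trial-set mean baseline (stable at low trial counts)
    #: or per-trial baselines behind this flag
    per_trial_baseline: bool = False

    def validate(self, fs: float) -> None:
        if self.baseline[1] > 0:
            raise ValueError("baseline window must lie strictly before the go cue")
        if abs(self.win_dur_s * fs - round(self.win_dur_s * fs)) > 1e-9:
            raise ValueError("win_dur_s * fs must be an integer number of samples")
        if self.step_s < 1.0 / fs:
            raise ValueError("step_s must be at least one sample")

    def win_samples(self, fs: float) -> int:
        return int(round(self.win_dur_s * fs))

    def step_samples(self, fs: float) -> int:
        return max(1, int(round(self.step_s * fs)))


@dataclass
class ERSPMap:
    """Time-frequency map of dB change against baseline for one channel."""

    channel: str
    condition: str
    times: np.ndarray  # window-start offsets within the embodiment window (s)
    freqs: np.ndarray  # Hz
    values: np.ndarray  # times x freqs, dB (negative = power decrease)


@dataclass
class ERDCurve:
    """Band-limited ERD/ERS time course (percent change vs baseline)."""

    channel: str
    condition: str
    band: str
    times: np.ndarray
    values: np.ndarray  # percent; ERD negative, ERS positive, floor -100


@dataclass
class TopographyMap:
    """Per-channel ERD/ERS averaged over the embodiment window."""

    condition: str
    band: str
    channels: tuple[str, ...]
    values: np.ndarray


def bandpass(x: np.ndarray, band: tuple[float, float], fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass along the last axis."""
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def _analysis_offsets(epochs: EpochSet) -> tuple[np.ndarray, int]:
    """Per-trial sample offset of the embodiment window start, and its length.

    Falls back to a go-anchored window when embodiment selection has not run
    (analysis_start unset): window [0, 4) s for every trial.
    """
    if epochs.analysis_start is None or not np.isfinite(epochs.analysis_dur):
        starts = np.zeros(epochs.n_trials)
        dur = 4.0
    else:
        starts = epochs.analysis_start
        dur = epochs.analysis_dur
    offs = np.rint((starts - epochs.times[0]) * epochs.fs).astype(int)
    n_seg = int(round(dur * epochs.fs))
    if (offs < 0).any() or (offs + n_seg > epochs.times.size).any():
        raise ValueError("embodiment window extends outside the epoch")
    return offs, n_seg


def _segments(x: np.ndarray, offs: np.ndarray, n_seg: int) -> np.ndarray:
    """Gather the per-trial analysis segment: (trials, samples) -> (trials, n_seg)."""
    idx = offs[:, None] + np.arange(n_seg)[None, :]
    return np.take_along_axis(x, idx, axis=1)


def _condition_label(epochs: EpochSet) -> str:
    conds = epochs.info["condition"].unique()
    return conds[0] if len(conds) == 1 else "mixed"


def _sliding_mean(sq: np.ndarray, win: int, step: int) -> np.ndarray:
    """Mean over sliding windows along the last axis: (..., n) -> (..., n_pos)."""
    cs = np.cumsum(sq, axis=-1)
    cs = np.concatenate([np.zeros(sq.shape[:-1] + (1,)), cs], axis=-1)
    starts = np.arange(0, sq.shape[-1] - win + 1, step)
    return (cs[..., starts + win] - cs[..., starts]) / win


def baseline_power(
    epochs: EpochSet,
    params: SpectralParams,
    band: tuple[float, float],
    channel_indices: np.ndarray | list[int] | None = None,
) -> np.ndarray:
    """Trial-set mean band power in the baseline window, per channel.

    The pre-go baseline precedes any condition-specific stimulation, so a
    baseline pooled over all of a subject's trials may be shared across
    conditions (see :func:`erd_matrix`'s ``p_base`` argument); that keeps
    between-condition ERD contrasts free of independent baseline noise.
    """
    idx = np.arange(len(epochs.ch_names)) if channel_indices is None else np.asarray(channel_indices)
    x = bandpass(epochs.data[:, idx, :], band, epochs.fs, order=params.filter_order)
    b0, b1 = params.baseline
    bsl = epochs.time_slice(b0, b1 - b0)
    return (x[:, :, bsl] ** 2).mean(axis=(0, 2))


def erd_matrix(
    epochs: EpochSet,
    params: SpectralParams,
    band: tuple[float, float],
    channel_indices: np.ndarray | list[int] | None = None,
    p_base: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """ERD/ERS curves for many channels at once.

    Returns ``(times, values)`` with ``values`` of shape (channels, n_pos) in
    percent. This is the common core behind :func:`compute_erd` and
    :func:`compute_topography`, which guarantees that a topography value is
    exactly the time-mean of the corresponding curve. ``p_base`` overrides
    the per-trial-set baseline with an externally pooled one (one value per
    requested channel), e.g. pooled across conditions via
    :func:`baseline_power`.
    """
    params.validate(epochs.fs)
    if epochs.n_trials == 0:
        raise ValueError("empty trial set")
    fs = epochs.fs
    idx = np.arange(len(epochs.ch_names)) if channel_indices is None else np.asarray(channel_indices)
    x = bandpass(epochs.data[:, idx, :], band, fs, order=params.filter_order)
    sq = x * x
    b0, b1 = params.baseline
    bsl = epochs.time_slice(b0, b1 - b0)
    p_base_trials = sq[:, :, bsl].mean(axis=2)  # trials x channels
    offs, n_seg = _analysis_offsets(epochs)
    win, step = params.win_samples(fs), params.step_samples(fs)
    if win > n_seg:
        raise ValueError("sliding window longer than the analysis segment")
    n_pos = (n_seg - win) // step + 1
    seg = np.empty((epochs.n_trials, len(idx), n_seg))
    for c in range(len(idx)):
        seg[:, c, :] = _segments(sq[:, c, :], offs, n_seg)
    p_t = _sliding_mean(seg, win, step)  # trials x channels x n_pos
    if params.per_trial_baseline and p_base is None:
        denom = p_base_trials[:, :, None]
        if (denom == 0).any():
            raise ZeroDivisionError("zero baseline power in at least one trial")
        values = 100.0 * (p_t / denom - 1.0).mean(axis=0)
    else:
        pb = p_base_trials.mean(axis=0) if p_base is None else np.asarray(p_base, dtype=float)
        if (pb == 0).any():
            raise ZeroDivisionError("zero baseline power")
        values = 100.0 * (p_t.mean(axis=0) / pb[:, None] - 1.0)
    times = np.arange(n_pos) * step / fs
    return times, values


def compute_erd(
    epochs: EpochSet,
    params: SpectralParams,
    channel: str,
    band: str | tuple[float, float],
) -> ERDCurve:
    """Band-limited ERD/ERS curve for one channel, averaged across trials."""
    band_name, band_edges = _resolve_band(params, band)
    ci = epochs.channel_index(channel)
    times, values = erd_matrix(epochs, params, band_edges, [ci])
    return ERDCurve(
        channel=channel, condition=_condition_label(epochs),
        band=band_name, times=times, values=values[0],
    )


def compute_topography(
    epochs: EpochSet, params: SpectralParams, band: str | tuple[float, float]
) -> TopographyMap:
    """Per-channel ERD/ERS averaged over the full embodiment window."""
    band_name, band_edges = _resolve_band(params, band)
    _, values = erd_matrix(epochs, params, band_edges)
    return TopographyMap(
        condition=_condition_label(epochs), band=band_name,
        channels=epochs.ch_names, values=values.mean(axis=1),
    )


def _resolve_band(params: SpectralParams, band: str | tuple[float, float]):
    if isinstance(band, str):
        return band, params.bands[band]
    lo, hi = band
    return f"{lo:g}-{hi:g}Hz", (float(lo), float(hi))


def compute_ersp(
    epochs: EpochSet,
    params: SpectralParams,
    channel: str,
    fmax: float | None = None,
    chunk: int = 32,
) -> ERSPMap:
    """ERSP time-frequency map for one channel, averaged across trials.

    Per trial, tapered sliding windows over the embodiment segment are
    Fourier transformed; amplitude spectra are divided by the trial-set mean
    baseline amplitude spectrum, averaged across trials, and converted to dB.
    """
    params.validate(epochs.fs)
    if epochs.n_trials == 0:
        raise ValueError("empty trial set")
    fs = epochs.fs
    win, step = params.win_samples(fs), params.step_samples(fs)
    power = params.ersp_mode == "power"
    taper = signal.get_window(params.taper, win, fftbins=True)
    x = epochs.data[:, epochs.channel_index(channel), :]  # trials x samples

    b0, b1 = params.baseline
    n_bsl = int(round((b1 - b0) * fs))
    if n_bsl != win:
        raise ValueError(
            f"baseline window ({n_bsl} samples) must match the sliding window ({win})"
        )
    a_base = np.abs(np.fft.rfft(x[:, epochs.time_slice(b0, b1 - b0)] * taper, axis=-1))
    if power:
        a_base = a_base**2
    a_base = a_base.mean(axis=0)  # freqs
    if (a_base == 0).any():
        raise ZeroDivisionError("zero baseline spectrum")

    offs, n_seg = _analysis_offsets(epochs)
    if win > n_seg:
        raise ValueError("sliding window longer than the analysis segment")
    starts = np.arange(0, n_seg - win + 1, step)
    acc = 0.0
    for t0 in range(0, epochs.n_trials, chunk):
        seg = _segments(x[t0:t0 + chunk], offs[t0:t0 + chunk], n_seg)
        views = sliding_window_view(seg, win, axis=-1)[:, ::step, :]  # trials x pos x win
        a = np.abs(np.fft.rfft(views * taper, axis=-1))
        if power:
            a *= a
        acc = acc + a.sum(axis=0)
    ratio = acc / epochs.n_trials / a_base[None, :]
    values = (10.0 if power else 20.0) * np.log10(ratio)
    freqs = np.fft.rfftfreq(win, 1.0 / fs)
    if fmax is not None:
        sel = freqs <= fmax
        freqs, values = freqs[sel], values[:, sel]
    return ERSPMap(
        channel=channel, condition=_condition_label(epochs),
        times=np.arange(len(starts)) * step / fs, freqs=freqs, values=values,
    )
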