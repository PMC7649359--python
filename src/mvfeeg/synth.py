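"""Synthetic mirror-visual-feedback experiment generator.

Emulates the study design end to end: 32-channel extended-10/20 EEG at
250 Hz, six runs of 30 trials (10 per condition NV/CV/IV, randomized order),
a per-trial timeline of ready at -5 s, go at 0 s, a 10 s motor task and 5 s
rest, mu (8-13 Hz) and beta (13-26 Hz) oscillatory activity whose amplitude
is attenuated channel- and condition-dependently from the moment embodiment
is reached (operationalized as the pedal press) to the end of the task,
phase-lagged narrowband coupling between chosen channel pairs, stochastic
pedal latencies with a no-pedal probability, and Likert questionnaire
responses.

The oscillatory sources are band-limited filtered Gaussian noise carriers —
non-phase-locked activity, which is what baseline-relative ERD/ERS methods
assume — on top of broadband pink noise. Pure amplitude attenuation by a
factor ``a`` therefore yields an analytic ground-truth ERD of
``(a**2 - 1) * 100`` percent, which parameter-recovery tests use as oracle.

Left-handed subjects are simulated as montage mirrors of right-handed ones
(attenuation planted at the homologous channel), exercising the downstream
channel-flipping step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .containers import CONDITIONS, Recording
from .montage import CHANNELS_32, Montage, homologous_pair, make_montage

EQ_STATEMENTS: tuple[str, ...] = ("L-1", "L-2", "O-1", "O-2", "A-1", "A-2", "D-1", "D-2")
EQ_SUBSCALES: dict[str, str] = {
    "L-1": "location", "L-2": "location",
    "O-1": "ownership", "O-2": "ownership",
    "A-1": "agency", "A-2": "agency",
    "D-1": "deafference", "D-2": "deafference",
}

BANDS: dict[str, tuple[float, float]] = {"alpha": (8.0, 13.0), "beta": (13.0, 26.0)}


@dataclass(frozen=True)
class TrialTimeline:
    """Within-trial event times in seconds; the go cue is t = 0."""

    ready_s: float = -5.0
    go_s: float = 0.0
    task_dur_s: float = 10.0
    rest_dur_s: float = 5.0

    @property
    def trial_dur_s(self) -> float:
        return (self.go_s - self.ready_s) + self.task_dur_s + self.rest_dur_s


@dataclass(frozen=True)
class LatencyModel:
    """Per-condition pedal latency: truncated normal on (0, task_dur] plus a
    no-pedal probability."""

    mean_s: float
    sd_s: float
    p_no_pedal: float


def default_latency_models() -> dict[str, LatencyModel]:
    """Latency models matching the reported group behavior: mean +- SD of
    4.4 +- 2.0, 3.7 +- 2.0 and 3.6 +- 2.1 s, with no-pedal rates of
    10.1/60, 7/60 and 7.1/60 trials for NV, CV and IV respectively."""
    return {
        "NV": LatencyModel(4.4, 2.0, 10.1 / 60),
        "CV": LatencyModel(3.7, 2.0, 7.0 / 60),
        "IV": LatencyModel(3.6, 2.1, 7.1 / 60),
    }


@dataclass(frozen=True)
class Coupling:
    """A phase-lagged shared narrowband component between two channels."""

    ch_i: str
    ch_j: str
    phase_lag_rad: float
    strength_uv: float
    band: tuple[float, float] = BANDS["alpha"]


def default_erd_depths() -> dict[tuple[str, str, str], float]:
    """Amplitude attenuation factors a (power change a**2 - 1) per
    (condition, channel, band), calibrated to the reported topography:
    ~30% alpha power drop at C3/F3 without vibration vs ~40% with, ~40% at
    C4 under all conditions, ~22-25% beta drops, and parieto-occipital
    alpha ERD that is weaker under intermittent vibration. Channels not
    listed are unattenuated (a = 1)."""
    a30, a40 = math.sqrt(0.70), math.sqrt(0.60)  # -30%, -40% power
    a22, a25 = math.sqrt(0.78), math.sqrt(0.75)
    a20, a10 = math.sqrt(0.80), math.sqrt(0.90)
    depths: dict[tuple[str, str, str], float] = {}
    for ch in ("C3", "F3"):
        depths[("NV", ch, "alpha")] = a30
        depths[("CV", ch, "alpha")] = a40
        depths[("IV", ch, "alpha")] = a40
    for cond in CONDITIONS:
        depths[(cond, "C4", "alpha")] = a40
        depths[(cond, "F4", "alpha")] = a30
        depths[(cond, "C4", "beta")] = a25
    depths[("NV", "C3", "beta")] = a22
    depths[("CV", "C3", "beta")] = a25
    depths[("IV", "C3", "beta")] = a25
    for ch in ("PO4", "PO3", "Oz"):
        depths[("NV", ch, "alpha")] = a20
        depths[("CV", ch, "alpha")] = a20
        depths[("IV", ch, "alpha")] = a10
    return depths


def default_eq_model() -> dict[tuple[str, str], tuple[float, float]]:
    """Per-(condition, statement) Likert mean and SD on the -5..+5 scale.

    Ordered so that vibration raises location/ownership and first-agency
    ratings relative to no vibration (intermittent slightly above
    continuous), with the second agency statement near ceiling and
    deafference low under every condition."""
    base = {
        "NV": {"L-1": 1.0, "L-2": 1.0, "O-1": 0.5, "O-2": 0.5,
               "A-1": 1.0, "A-2": 3.5, "D-1": -1.0, "D-2": 0.0},
        "CV": {"L-1": 1.8, "L-2": 2.2, "O-1": 1.8, "O-2": 1.8,
               "A-1": 1.8, "A-2": 3.5, "D-1": -0.8, "D-2": 0.2},
        "IV": {"L-1": 2.3, "L-2": 2.4, "O-1": 2.2, "O-2": 2.0,
               "A-1": 2.2, "A-2": 3.5, "D-1": -0.6, "D-2": 0.3},
    }
    return {(c, s): (m, 1.5) for c, sts in base.items() for s, m in sts.items()}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment, defaulting to the study design."""

    n_subjects: int = 12
    n_runs: int = 6
    trials_per_run: int = 30
    fs: float = 250.0
    channels: tuple[str, ...] = CHANNELS_32
    timeline: TrialTimeline = field(default_factory=TrialTimeline)
    conditions: tuple[str, ...] = CONDITIONS
    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(BANDS))
    band_amp_uv: dict[str, float] = field(default_factory=lambda: {"alpha": 10.0, "beta": 5.0})
    erd_depth: dict[tuple[str, str, str], float] = field(default_factory=default_erd_depths)
    latency: dict[str, LatencyModel] = field(default_factory=default_latency_models)
    coupling: tuple[Coupling, ...] = ()
    pink_noise_uv: float = 4.0
    sensor_noise_uv: float = 1.0
    artifact_rate: float = 0.0
    eq_model: dict[tuple[str, str], tuple[float, float]] = field(default_factory=default_eq_model)
    eq_subject_sd: float = 1.0
    n_left_handed: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_runs < 1 or self.trials_per_run < 1:
            raise ValueError("degenerate configuration: zero subjects, runs, or trials")
        if self.trials_per_run % len(self.conditions) != 0:
            raise ValueError(
                f"trials_per_run={self.trials_per_run} not divisible by "
                f"{len(self.conditions)} conditions"
            )
        fmax = max(hi for _, hi in self.bands.values())
        if self.fs <= 2 * fmax:
            raise ValueError(f"fs={self.fs} too low for simulated band up to {fmax} Hz")
        for key, a in self.erd_depth.items():
            if not 0 < a <= 1:
                raise ValueError(f"attenuation factor {a} for {key} outside (0, 1]")
        for cond, lm in self.latency.items():
            if not 0 < lm.mean_s < self.timeline.task_dur_s:
                raise ValueError(f"latency mean for {cond} outside (0, task duration)")
            if not 0 <= lm.p_no_pedal <= 1:
                raise ValueError("no-pedal probability outside [0, 1]")
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact rate outside [0, 1]")
        if not 0 <= self.n_left_handed <= self.n_subjects:
            raise ValueError(
                f"n_left_handed={self.n_left_handed} outside [0, {self.n_subjects}]"
            )

    @property
    def trials_per_condition(self) -> int:
        return self.trials_per_run // len(self.conditions)

    def handedness(self, subject: int) -> str:
        """Last ``n_left_handed`` subjects are left-handed."""
        return "left" if subject >= self.n_subjects - self.n_left_handed else "right"


@dataclass
class GroundTruth:
    """What the generator actually planted, for parameter-recovery tests."""

    erd_percent: pd.DataFrame  # condition, channel, band, erd_pct
    onsets: pd.DataFrame  # subject, run, trial, condition, t_pedal_s (rel. go)
    coupling_strength: np.ndarray  # n_ch x n_ch, microvolts
    coupling_lag: np.ndarray  # n_ch x n_ch, radians
    artifact_trials: pd.DataFrame  # subject, run, trial, kind


@dataclass
class Experiment:
    """A full synthetic dataset: recordings keyed by (subject, run), the
    event log, the questionnaire table, and the generator's ground truth."""

    config: SimulationConfig
    recordings: dict[tuple[int, int], Recording]
    events: pd.DataFrame
    eq: pd.DataFrame
    ground_truth: GroundTruth


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Unit-variance 1/f noise per row (FFT-shaped white noise)."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n=n, axis=-1)
    out /= out.std(axis=-1, keepdims=True)
    return out


def _band_carrier(
    rng: np.random.Generator, shape: tuple[int, int], band: tuple[float, float], fs: float
) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise per row."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x


def _draw_latencies(
    rng: np.random.Generator, model: LatencyModel, n: int, task_dur: float
) -> np.ndarray:
    """Latencies in seconds; NaN where the subject never pedals."""
    lt = np.full(n, np.nan)
    pedal = rng.random(n) >= model.p_no_pedal
    k = int(pedal.sum())
    draws = rng.normal(model.mean_s, model.sd_s, size=k)
    bad = (draws <= 0) | (draws > task_dur)
    while bad.any():  # resample outside (0, task_dur] — keeps the normal shape
        draws[bad] = rng.normal(model.mean_s, model.sd_s, size=int(bad.sum()))
        bad = (draws <= 0) | (draws > task_dur)
    lt[pedal] = draws
    return lt


def _depth_vector(
    config: SimulationConfig, cond: str, band: str, mirror: bool
) -> np.ndarray:
    """Per-channel attenuation for one condition and band; the montage is
    mirrored for left-handed subjects."""
    out = np.ones(len(config.channels))
    for i, ch in enumerate(config.channels):
        key_ch = homologous_pair(ch) if mirror else ch
        out[i] = config.erd_depth.get((cond, key_ch, band), 1.0)
    return out


def _generate_run(
    config: SimulationConfig,
    montage: Montage,
    subject: int,
    run: int,
    rng: np.random.Generator,
) -> tuple[Recording, pd.DataFrame]:
    tl = config.timeline
    fs = config.fs
    n_ch = len(config.channels)
    spt = int(round(tl.trial_dur_s * fs))
    n_tr = config.trials_per_run
    n_samp = n_tr * spt
    mirror = config.handedness(subject) == "left"

    conds = np.repeat(np.array(config.conditions), config.trials_per_condition)
    rng.shuffle(conds)
    lat = np.full(n_tr, np.nan)
    for cond in config.conditions:
        m = conds == cond
        lat[m] = _draw_latencies(rng, config.latency[cond], int(m.sum()), tl.task_dur_s)

    data = config.pink_noise_uv * _pink_noise(rng, (n_ch, n_samp))
    if config.sensor_noise_uv > 0:
        data += config.sensor_noise_uv * rng.standard_normal((n_ch, n_samp))

    go_offset = int(round((tl.go_s - tl.ready_s) * fs))  # samples from trial start to go
    task_end = go_offset + int(round(tl.task_dur_s * fs))
    for band_name, band in config.bands.items():
        carrier = config.band_amp_uv[band_name] * _band_carrier(rng, (n_ch, n_samp), band, fs)
        env = np.ones((n_ch, n_samp))
        depth = {c: _depth_vector(config, c, band_name, mirror) for c in config.conditions}
        for t in range(n_tr):
            if np.isnan(lat[t]):
                continue
            on = t * spt + go_offset + int(round(lat[t] * fs))
            off = t * spt + task_end
            env[:, on:off] = depth[conds[t]][:, None]
        data += carrier * env

    for cp in config.coupling:
        if cp.ch_i not in config.channels or cp.ch_j not in config.channels:
            continue
        src = _band_carrier(rng, (1, n_samp), cp.band, fs)[0]
        z = signal.hilbert(src)
        data[montage.index(cp.ch_i)] += cp.strength_uv * src
        data[montage.index(cp.ch_j)] += cp.strength_uv * np.real(z * np.exp(-1j * cp.phase_lag_rad))

    rec = Recording(
        data=data, fs=fs, montage=montage,
        handedness=config.handedness(subject), subject=subject, run_id=run,
    )
    t_go = np.arange(n_tr) * tl.trial_dur_s + (tl.go_s - tl.ready_s)
    events = pd.DataFrame({
        "subject": subject, "run": run, "trial": np.arange(n_tr),
        "condition": conds, "t_go_s": t_go, "t_pedal_s": t_go + lat,
    })
    return rec, events


def generate_dataset(config: SimulationConfig | None = None) -> Experiment:
    """Generate the full synthetic experiment.

    Returns an :class:`Experiment` whose recordings are continuous per-run
    EEG assembled from per-trial segments, with mu/beta carriers attenuated
    from each trial's pedal time to the end of the task, coupled channel
    pairs sharing a phase-lagged narrowband component, pedal events drawn
    from the latency model (or omitted), and Likert questionnaire responses.
    The same seed reproduces the dataset bit for bit.
    """
    config = config or SimulationConfig()
    config.validate()
    montage = make_montage(config.channels)
    root = np.random.SeedSequence(config.seed)
    subj_seeds = root.spawn(config.n_subjects + 1)
    eq_rng = np.random.default_rng(subj_seeds[-1])

    recordings: dict[tuple[int, int], Recording] = {}
    ev_frames = []
    art_rows = []
    for s in range(config.n_subjects):
        run_seeds = subj_seeds[s].spawn(config.n_runs)
        for r in range(config.n_runs):
            rng = np.random.default_rng(run_seeds[r])
            rec, ev = _generate_run(config, montage, s, r, rng)
            if config.artifact_rate > 0:
                rec, arts = inject_artifacts(rec, ev, config.artifact_rate, rng,
                                             timeline=config.timeline)
                art_rows.append(arts)
            recordings[(s, r)] = rec
            ev_frames.append(ev)
    events = pd.concat(ev_frames, ignore_index=True)

    eq = _generate_eq(config, eq_rng)

    n_ch = len(config.channels)
    cs = np.zeros((n_ch, n_ch))
    cl = np.zeros((n_ch, n_ch))
    for cp in config.coupling:
        if cp.ch_i in config.channels and cp.ch_j in config.channels:
            i, j = montage.index(cp.ch_i), montage.index(cp.ch_j)
            cs[i, j] = cs[j, i] = cp.strength_uv
            cl[i, j] = cp.phase_lag_rad
            cl[j, i] = -cp.phase_lag_rad

    erd_rows = [
        {"condition": c, "channel": ch, "band": b, "erd_pct": (a * a - 1.0) * 100.0}
        for (c, ch, b), a in sorted(config.erd_depth.items())
        if ch in config.channels
    ]
    onsets = events[["subject", "run", "trial", "condition"]].copy()
    onsets["t_pedal_s"] = events["t_pedal_s"] - events["t_go_s"]
    gt = GroundTruth(
        erd_percent=pd.DataFrame(erd_rows, columns=["condition", "channel", "band", "erd_pct"]),
        onsets=onsets,
        coupling_strength=cs,
        coupling_lag=cl,
        artifact_trials=(
            pd.concat(art_rows, ignore_index=True) if art_rows
            else pd.DataFrame(columns=["subject", "run", "trial", "kind"])
        ),
    )
    return Experiment(config=config, recordings=recordings, events=events, eq=eq, ground_truth=gt)


def _generate_eq(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Likert ratings: discretized, clipped normal on the integer grid -5..+5,
    with a per-subject intercept shared across conditions and statements."""
    rows = []
    for s in range(config.n_subjects):
        intercept = rng.normal(0.0, config.eq_subject_sd)
        for cond in config.conditions:
            for st in EQ_STATEMENTS:
                mean, sd = config.eq_model[(cond, st)]
                r = int(np.clip(round(rng.normal(mean + intercept, sd)), -5, 5))
                rows.append({"subject": s, "condition": cond, "statement_id": st, "rating": r})
    return pd.DataFrame(rows)


def inject_artifacts(
    recording: Recording,
    events: pd.DataFrame,
    rate: float,
    rng: np.random.Generator | int,
    timeline: TrialTimeline | None = None,
    spike_uv: float = 300.0,
    drift_uv_per_s: float = 60.0,
) -> tuple[Recording, pd.DataFrame]:
    """Contaminate a fraction of trials with a large drift or electrode spike.

    Each selected trial gets, on one random channel, either a linear drift of
    ``drift_uv_per_s`` across the whole trial or a short spike of
    ``spike_uv`` during the task — both exceeding the default rejection
    thresholds by construction. Returns the contaminated copy and a table of
    (subject, run, trial, kind).
    """
    if not 0 <= rate <= 1:
        raise ValueError("artifact rate outside [0, 1]")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    tl = timeline or TrialTimeline()
    rec = recording.copy()
    fs = rec.fs
    spt = int(round(tl.trial_dur_s * fs))
    rows = []
    if rate > 0:
        for _, ev in events.iterrows():
            if rng.random() >= rate:
                continue
            t = int(ev["trial"])
            a, b = t * spt, (t + 1) * spt
            ch = rng.integers(0, rec.data.shape[0])
            if rng.random() < 0.5:
                rec.data[ch, a:b] += drift_uv_per_s * np.arange(b - a) / fs
                kind = "drift"
            else:
                at = rng.integers(a + spt // 4, b - spt // 4)
                rec.data[ch, at:at + 3] += spike_uv * np.array([0.5, 1.0, 0.5])
                kind = "spike"
            rows.append({"subject": rec.subject, "run": rec.run_id, "trial": t, "kind": kind})
    report = pd.DataFrame(rows, columns=["subject", "run", "trial", "kind"])
    return rec, report
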