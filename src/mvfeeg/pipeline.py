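"""Pipeline orchestration: simulate -> preprocess -> analyze -> stats -> report.

A :class:`PipelineConfig` aggregates every parameter of the experiment and
analysis with the paradigm's defaults (250 Hz, 0.8 s window / 0.004 s step,
-0.9..-0.1 s baseline, 8-13 / 13-26 Hz bands, 8-26 Hz network band, sparsity
0.10:0.02:0.20, alpha = 0.05) and round-trips through a flat TOML file.
Every output table carries the config hash and seed in its provenance
header; the same seed and config reproduce every table byte for byte.

Stages pass their products through a :class:`PipelineState`; requesting a
stage whose inputs are missing raises :class:`DependencyError` naming the
missing artifact.
"""

from __future__ import annotations

import hashlib
import json
import re
import tomllib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import network as net
from . import stats as st
from .containers import EpochSet
from .io import write_tsv
from .preprocess import (
    epoch_recording,
    flip_left_handed,
    laplacian_epochs,
    reject_artifact_trials,
    select_embodiment_epochs,
)
from .spectral import SpectralParams, baseline_power, compute_ersp, erd_matrix
from .synth import (
    Coupling,
    EQ_STATEMENTS,
    Experiment,
    LatencyModel,
    SimulationConfig,
    TrialTimeline,
    generate_dataset,
)

STAGES: tuple[str, ...] = (
    "simulate", "preprocess", "behavior", "erd", "ersp",
    "topography", "network", "stats", "report",
)

_DEPS: dict[str, tuple[str, ...]] = {
    "simulate": (),
    "preprocess": ("simulate",),
    "behavior": ("simulate",),
    "erd": ("preprocess",),
    "ersp": ("preprocess",),
    "topography": ("preprocess",),
    "network": ("preprocess",),
    "stats": ("behavior", "erd", "topography", "network"),
    "report": ("stats",),
}


class DependencyError(RuntimeError):
    """A requested stage is missing an upstream artifact."""


@dataclass
class PipelineConfig:
    """Aggregated parameters for the whole pipeline."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    spectral: SpectralParams = field(default_factory=SpectralParams)
    epoch_tmin_s: float = -1.5
    epoch_tmax_s: float = 10.0
    peak_to_peak_uv: float = 150.0
    drift_uv_per_s: float = 20.0
    embodiment_win_s: float = 4.0
    analysis_channels: tuple[str, ...] = ("C3", "C4")
    network_band: tuple[float, float] = net.ALPHA_BETA_BAND
    sparsity_grid: tuple[float, ...] = net.SPARSITY_GRID
    network_filter_order: int = 4
    alpha: float = 0.05
    erd_time_decim: int = 10
    seed: int = 0

    def config_hash(self) -> str:
        return hashlib.sha1(dumps_config(self).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# TOML round-trip

_BARE_KEY = re.compile(r"^[A-Za-z0-9_-]+$")


def _fmt_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_fmt_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)}")


def _fmt_key(k: str) -> str:
    return k if _BARE_KEY.match(k) else json.dumps(k)


def _emit(d: dict, prefix: str, lines: list[str]) -> None:
    scalars = {k: v for k, v in d.items() if not isinstance(v, dict)
               and not (isinstance(v, list) and v and isinstance(v[0], dict))}
    tables = {k: v for k, v in d.items() if isinstance(v, dict)}
    arrays = {k: v for k, v in d.items()
              if isinstance(v, list) and v and isinstance(v[0], dict)}
    if prefix and (scalars or not (tables or arrays)):
        lines.append(f"[{prefix}]")
    for k, v in scalars.items():
        lines.append(f"{_fmt_key(k)} = {_fmt_value(v)}")
    if scalars:
        lines.append("")
    for k, v in tables.items():
        _emit(v, f"{prefix}.{_fmt_key(k)}" if prefix else _fmt_key(k), lines)
    for k, items in arrays.items():
        name = f"{prefix}.{_fmt_key(k)}" if prefix else _fmt_key(k)
        for item in items:
            lines.append(f"[[{name}]]")
            for kk, vv in item.items():
                lines.append(f"{_fmt_key(kk)} = {_fmt_value(vv)}")
            lines.append("")


def _config_to_dict(config: PipelineConfig) -> dict:
    sim = config.simulation
    d = {
        "seed": config.seed,
        "epoch_tmin_s": config.epoch_tmin_s,
        "epoch_tmax_s": config.epoch_tmax_s,
        "peak_to_peak_uv": config.peak_to_peak_uv,
        "drift_uv_per_s": config.drift_uv_per_s,
        "embodiment_win_s": config.embodiment_win_s,
        "analysis_channels": list(config.analysis_channels),
        "network_band": list(config.network_band),
        "sparsity_grid": list(config.sparsity_grid),
        "network_filter_order": config.network_filter_order,
        "alpha": config.alpha,
        "erd_time_decim": config.erd_time_decim,
        "simulation": {
            "n_subjects": sim.n_subjects, "n_runs": sim.n_runs,
            "trials_per_run": sim.trials_per_run, "fs": sim.fs,
            "channels": list(sim.channels), "conditions": list(sim.conditions),
            "pink_noise_uv": sim.pink_noise_uv, "sensor_noise_uv": sim.sensor_noise_uv,
            "artifact_rate": sim.artifact_rate, "eq_subject_sd": sim.eq_subject_sd,
            "n_left_handed": sim.n_left_handed, "seed": sim.seed,
            "timeline": asdict(sim.timeline),
            "bands": {k: list(v) for k, v in sim.bands.items()},
            "band_amp_uv": dict(sim.band_amp_uv),
            "erd_depth": {f"{c}/{ch}/{b}": a for (c, ch, b), a in sim.erd_depth.items()},
            "latency": {c: asdict(m) for c, m in sim.latency.items()},
            "eq_model": {f"{c}/{s}": list(ms) for (c, s), ms in sim.eq_model.items()},
            "coupling": [asdict(cp) | {"band": list(cp.band)} for cp in sim.coupling],
        },
        "spectral": {
            "baseline": list(config.spectral.baseline),
            "win_dur_s": config.spectral.win_dur_s,
            "step_s": config.spectral.step_s,
            "bands": {k: list(v) for k, v in config.spectral.bands.items()},
            "taper": config.spectral.taper,
            "ersp_mode": config.spectral.ersp_mode,
            "filter_order": config.spectral.filter_order,
            "per_trial_baseline": config.spectral.per_trial_baseline,
        },
    }
    return d


def dumps_config(config: PipelineConfig) -> str:
    lines: list[str] = []
    _emit(_config_to_dict(config), "", lines)
    return "\n".join(lines).rstrip() + "\n"


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(dumps_config(config))


def _config_from_dict(d: dict) -> PipelineConfig:
    s = d["simulation"]
    sim = SimulationConfig(
        n_subjects=s["n_subjects"], n_runs=s["n_runs"],
        trials_per_run=s["trials_per_run"], fs=s["fs"],
        channels=tuple(s["channels"]), conditions=tuple(s["conditions"]),
        timeline=TrialTimeline(**s["timeline"]),
        bands={k: tuple(v) for k, v in s["bands"].items()},
        band_amp_uv=dict(s["band_amp_uv"]),
        erd_depth={tuple(k.split("/")): a for k, a in s["erd_depth"].items()},
        latency={c: LatencyModel(**m) for c, m in s["latency"].items()},
        coupling=tuple(Coupling(**(cp | {"band": tuple(cp["band"])}))
                       for cp in s.get("coupling", [])),
        pink_noise_uv=s["pink_noise_uv"], sensor_noise_uv=s["sensor_noise_uv"],
        artifact_rate=s["artifact_rate"], eq_subject_sd=s["eq_subject_sd"],
        n_left_handed=s["n_left_handed"], seed=s["seed"],
    )
    sp = d["spectral"]
    spectral = SpectralParams(
        baseline=tuple(sp["baseline"]), win_dur_s=sp["win_dur_s"], step_s=sp["step_s"],
        bands={k: tuple(v) for k, v in sp["bands"].items()},
        taper=sp["taper"], ersp_mode=sp["ersp_mode"],
        filter_order=sp["filter_order"], per_trial_baseline=sp["per_trial_baseline"],
    )
    return PipelineConfig(
        simulation=sim, spectral=spectral,
        epoch_tmin_s=d["epoch_tmin_s"], epoch_tmax_s=d["epoch_tmax_s"],
        peak_to_peak_uv=d["peak_to_peak_uv"], drift_uv_per_s=d["drift_uv_per_s"],
        embodiment_win_s=d["embodiment_win_s"],
        analysis_channels=tuple(d["analysis_channels"]),
        network_band=tuple(d["network_band"]),
        sparsity_grid=tuple(d["sparsity_grid"]),
        network_filter_order=d["network_filter_order"],
        alpha=d["alpha"], erd_time_decim=d["erd_time_decim"], seed=d["seed"],
    )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, "rb") as fh:
        return _config_from_dict(tomllib.load(fh))


# ---------------------------------------------------------------------------
# stages

@dataclass
class PipelineState:
    """Artifacts handed from stage to stage."""

    experiment: Experiment | None = None
    epochs: dict[int, EpochSet] | None = None  # per subject, analysis-ready
    counts: pd.DataFrame | None = None
    behavior: pd.DataFrame | None = None
    lt_summary: pd.DataFrame | None = None
    eq_summary: pd.DataFrame | None = None
    erd_curves: dict[tuple[str, str], np.ndarray] | None = None  # (ch, band) -> subj x cond x t
    erd_times: np.ndarray | None = None
    erd_values: pd.DataFrame | None = None
    topography: pd.DataFrame | None = None
    network_metrics: pd.DataFrame | None = None
    tests: pd.DataFrame | None = None
    report: dict | None = None


def concat_epochs(parts: list[EpochSet]) -> EpochSet:
    """Stack epochs from several runs of one subject (same grid and montage)."""
    first = parts[0]
    for p in parts[1:]:
        if p.times.shape != first.times.shape or p.ch_names != first.ch_names:
            raise ValueError("epoch sets are not compatible")
    return EpochSet(
        data=np.concatenate([p.data for p in parts], axis=0),
        times=first.times, fs=first.fs, montage=first.montage,
        info=pd.concat([p.info for p in parts], ignore_index=True),
        baseline=first.baseline,
    )


def _require(state: PipelineState, stage: str) -> None:
    artifacts = {
        "simulate": state.experiment, "preprocess": state.epochs,
        "behavior": state.behavior, "erd": state.erd_curves,
        "ersp": True, "topography": state.topography,
        "network": state.network_metrics, "stats": state.tests,
        "report": state.report,
    }
    for dep in _DEPS[stage]:
        if artifacts[dep] is None:
            raise DependencyError(
                f"stage {stage!r} requires the {dep!r} stage output "
                f"({_ARTIFACT_NAMES[dep]}), which is missing"
            )


_ARTIFACT_NAMES = {
    "simulate": "synthetic experiment", "preprocess": "analysis-ready epochs",
    "behavior": "behavior table", "erd": "ERD curves", "ersp": "ERSP maps",
    "topography": "topography values", "network": "network metrics",
    "stats": "test results", "report": "report bundle",
}


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    stages: tuple[str, ...] | list[str] | None = None,
    state: PipelineState | None = None,
) -> PipelineState:
    """Run the requested stages (default: all, in order) and write their
    outputs under ``outdir``. Returns the updated state so that later calls
    can continue from it."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = state or PipelineState()
    requested = list(STAGES) if stages is None else list(stages)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    prov = {"config_hash": config.config_hash(), "seed": config.seed}
    for stage in STAGES:
        if stage in requested:
            _require(state, stage)
            _STAGE_FN[stage](config, state, outdir, prov)
    return state


def _stage_simulate(config: PipelineConfig, state: PipelineState, outdir: Path, prov: dict):
    sim = replace(config.simulation, seed=config.seed)
    state.experiment = generate_dataset(sim)
    write_tsv(state.experiment.events, outdir / "events.tsv", prov)
    write_tsv(state.experiment.eq, outdir / "eq.tsv", prov)
    write_tsv(state.experiment.ground_truth.erd_percent, outdir / "ground_truth_erd.tsv", prov)


def _stage_preprocess(config: PipelineConfig, state: PipelineState, outdir: Path, prov: dict):
    exp = state.experiment
    sim = exp.config
    epochs: dict[int, EpochSet] = {}
    reports, count_rows = [], []
    for s in range(sim.n_subjects):
        parts = []
        for r in range(sim.n_runs):
            rec = flip_left_handed(exp.recordings[(s, r)])
            parts.append(epoch_recording(rec, exp.events,
                                         tmin=config.epoch_tmin_s, tmax=config.epoch_tmax_s))
        ep = concat_epochs(parts)
        n_total = ep.n_trials
        ep, report = reject_artifact_trials(ep, config.peak_to_peak_uv, config.drift_uv_per_s)
        n_clean = ep.n_trials
        ep = select_embodiment_epochs(ep, config.embodiment_win_s,
                                      task_end_s=sim.timeline.task_dur_s)
        ep = laplacian_epochs(ep)
        epochs[s] = ep
        reports.append(report)
        row = {"subject": s, "n_trials": n_total, "n_artifact": n_total - n_clean,
               "n_short_or_no_pedal": n_clean - ep.n_trials, "n_analyzed": ep.n_trials}
        for c in sim.conditions:
            row[f"n_{c}"] = int((ep.info["condition"] == c).sum())
        count_rows.append(row)
    state.epochs = epochs
    state.counts = pd.DataFrame(count_rows)
    write_tsv(pd.concat(reports, ignore_index=True), outdir / "rejection_report.tsv", prov)
    write_tsv(state.counts, outdir / "trial_counts.tsv", prov)


def _stage_behavior(config: PipelineConfig, state: PipelineState, outdir: Path, prov: dict):
    exp = state.experiment
    state.behavior = beh.compute_latency(exp.events, task_dur_s=exp.config.timeline.task_dur_s)
    state.lt_summary = beh.summarize_latency(state.behavior)
    state.eq_summary = beh.score_eq(exp.eq)
    write_tsv(state.behavior, outdir / "behavior.tsv", prov)
    write_tsv(state.lt_summary, outdir / "lt_summary.tsv", prov)
    write_tsv(state.eq_summary, outdir / "eq_summary.tsv", prov)


def _stage_erd(config: PipelineConfig, state: PipelineState, outdir: Path, prov: dict):
    sim = state.experiment.config
    params = config.spectral
    chans = [c for c in config.analysis_channels if c in sim.channels]
    curves: dict[tuple[str, str], np.ndarray] = {}
    times = None
    val_rows, tidy = [], []
    for ch in chans:
        for band in params.bands:
            per_subj = []
            for s in sorted(state.epochs):
                # baseline pooled over the subject's full trial set: the pre-go
                # baseline precedes stimulation, so it is condition-independent
                ci = [state.epochs[s].channel_index(ch)]
                pb = baseline_power(state.epochs[s], params, params.bands[band], ci)
                per_cond = []
                for cond in sim.conditions:
                    ep = state.epochs[s].pick_condition(cond)
                    t, v = erd_matrix(ep, params, params.bands[band], ci, p_base=pb)
                    per_cond.append(v[0])
                    times = t
                    val_rows.append({"subject": s, "channel": ch, "band": band,
                                     "condition": cond, "erd_pct": float(v[0].mean())})
                per_subj.append(per_cond)
            curves[(ch, band)] = np.array(per_subj)  # subj x cond x time
    state.erd_curves = curves
    state.erd_times = times
    state.erd_values = pd.DataFrame(val_rows)
    dec = config.erd_time_decim
    for (ch, band), arr in curves.items():
        mean = arr.mean(axis=0)  # cond x time
        for ci, cond in enumerate(sim.conditions):
            for ti in range(0, arr.shape[2], dec):
                tidy.append({"channel": ch, "band": band, "condition": cond,
                             "time_s": float(times[ti]), "erd_pct": float(mean[ci, ti])})
    write_tsv(pd.DataFrame(tidy), outdir / "erd_curves.tsv", prov)
    write_tsv(state.erd_values, outdir / "erd_values.tsv", prov)


def _stage_ersp(config: PipelineConfig, state: PipelineState, outdir: Path, prov: dict):
    sim = state.experiment.config
    params = config.spectral
    chans = [c for c in config.analysis_channels if c in sim.channels]
    dec = config.erd_time_decim
    rows = []
    for ch in chans:
        for cond in sim.conditions:
            acc, n = 0.0, 0
            times = freqs = None
            for s in sorted(state.epochs):
                m = compute_ersp(state.epochs[s].pick_condition(cond), params, ch, fmax=40.0)
                acc, n = acc + m.values, n + 1
                times, freqs = m.times, m.freqs
            mean = acc / n
            for ti in range(0, len(times), dec):
                for fi, f in enumerate(freqs):
                    rows.append({"channel": ch, "condition": cond,
                                 "time_s": float(times[ti]), "freq_hz": float(f),
                                 "ersp_db": float(mean[ti, fi])})
    write_tsv(pd.DataFrame(rows), outdir / "ersp_maps.tsv", prov)


def _stage_topography(config: PipelineConfig, state: PipelineState, outdir: Path, prov: dict):
    sim = state.experiment.config
    params = config.spectral
    rows = []
    for band, edges in params.bands.items():
        for s in sorted(state.epochs):
            pb = baseline_power(state.epochs[s], params, edges)
            for cond in sim.conditions:
                ep = state.epochs[s].pick_condition(cond)
                _, v = erd_matrix(ep, params, edges, p_base=pb)
                for ch, val in zip(ep.ch_names, v.mean(axis=1)):
                    rows.append({"subject": s, "band": band, "condition": cond,
                                 "channel": ch, "erd_pct": float(val)})
    state.topography = pd.DataFrame(rows)
    group = (state.topography
             .groupby(["band", "condition", "channel"], sort=False)["erd_pct"]
             .mean().reset_index())
    write_tsv(group, outdir / "topography.tsv", prov)
    write_tsv(state.topography, outdir / "topography_by_subject.tsv", prov)


def _stage_network(config: PipelineConfig, state: PipelineState, outdir: Path, prov: dict):
    sim = state.experiment.config
    frames = []
    for s in sorted(state.epochs):
        for cond in sim.conditions:
            g = net.compute_pli(state.epochs[s].pick_condition(cond),
                                band=config.network_band,
                                filter_order=config.network_filter_order)
            sweep = net.metric_sweep(g, config.sparsity_grid)
            sweep.insert(0, "subject", s)
            frames.append(sweep)
    state.network_metrics = pd.concat(frames, ignore_index=True)
    write_tsv(state.network_metrics, outdir / "network_metrics.tsv", prov)


def _stage_stats(config: PipelineConfig, state: PipelineState, outdir: Path, prov: dict):
    sim = state.experiment.config
    conds = sim.conditions
    rows: list[dict] = []

    def add(domain: str, where: str, results: list[st.TestResult]):
        for r in results:
            rows.append({"domain": domain, "where": where, "test": r.test,
                         "contrast": r.contrast, "statistic": r.statistic,
                         "df": "x".join(str(d) for d in (r.df or ())),
                         "p": r.p, "p_adj": r.p_adj if r.p_adj is not None else ""})

    lt = beh.latency_matrix(state.behavior, conds)
    add("latency", "LT", st.check_assumptions({c: lt[:, i] for i, c in enumerate(conds)}))
    add("latency", "LT", [st.rm_anova(lt, conds)])
    add("latency", "LT", st.paired_posthoc(lt, conds))

    for (ch, band), arr in state.erd_curves.items():
        vals = arr.mean(axis=2)  # subj x cond window means
        add("erd", f"{ch}/{band}", [st.rm_anova(vals, conds)])
        add("erd", f"{ch}/{band}", st.paired_posthoc(vals, conds))
        pmap = st.pointwise_map(arr, conds, state.erd_times, alpha=config.alpha)
        dec = config.erd_time_decim
        prows = []
        for label, p in pmap.contrasts.items():
            for ti in range(0, len(pmap.times), dec):
                prows.append({"channel": ch, "band": band, "contrast": label,
                              "time_s": float(pmap.times[ti]), "p_adj": float(p[ti])})
        write_tsv(pd.DataFrame(prows), outdir / f"pointwise_{ch}_{band}.tsv", prov)

    topo = state.topography
    for band in sorted(topo["band"].unique()):
        for ch in sim.channels:
            sub = topo[(topo["band"] == band) & (topo["channel"] == ch)]
            vals = sub.pivot(index="subject", columns="condition",
                             values="erd_pct")[list(conds)].to_numpy()
            add("topography", f"{ch}/{band}", st.paired_posthoc(vals, conds))

    for st_id in EQ_STATEMENTS:
        eqm = beh.eq_matrix(state.experiment.eq, st_id, conds)
        add("eq", st_id, [st.friedman(eqm, conds)])
        try:
            add("eq", st_id, st.wilcoxon_posthoc(eqm, conds))
        except ValueError:
            pass  # a contrast with all-zero differences has no evidence either way

    nm = state.network_metrics
    for metric in ("wcc", "wspl"):
        for sp in config.sparsity_grid:
            sub = nm[np.isclose(nm["sparsity"], sp)]
            vals = sub.pivot(index="subject", columns="condition",
                             values=metric)[list(conds)].to_numpy()
            add("network", f"{metric}@{sp:g}", [st.rm_anova(vals, conds)])

    state.tests = pd.DataFrame(rows)
    write_tsv(state.tests, outdir / "tests.tsv", prov)


def _stage_report(config: PipelineConfig, state: PipelineState, outdir: Path, prov: dict):
    sim = state.experiment.config
    tests = state.tests
    sig = tests[(tests["test"].isin(["paired-t", "wilcoxon-exact", "wilcoxon-approx"]))
                & (pd.to_numeric(tests["p_adj"], errors="coerce") < config.alpha)]
    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": sim.n_subjects,
        "trials_per_subject": sim.n_runs * sim.trials_per_run,
        "trial_counts": state.counts.to_dict(orient="records"),
        "lt_summary": state.lt_summary.to_dict(orient="records"),
        "erd_window_means": state.erd_values
        .groupby(["channel", "band", "condition"], sort=False)["erd_pct"]
        .mean().reset_index().to_dict(orient="records"),
        "significant_contrasts": sig[["domain", "where", "test", "contrast", "p_adj"]]
        .to_dict(orient="records"),
    }
    state.report = report
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))


_STAGE_FN = {
    "simulate": _stage_simulate, "preprocess": _stage_preprocess,
    "behavior": _stage_behavior, "erd": _stage_erd, "ersp": _stage_ersp,
    "topography": _stage_topography, "network": _stage_network,
    "stats": _stage_stats, "report": _stage_report,
}
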