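import numpy as np
import pandas as pd
import pytest

from mvfeeg import Recording, make_montage
from mvfeeg.preprocess import (
    epoch_recording,
    flip_left_handed,
    laplacian_epochs,
    reject_artifact_trials,
    select_embodiment_epochs,
    small_laplacian,
)

from conftest import TEN_CHANNELS


def _epochs(exp, subject=0):
    parts = [epoch_recording(exp.recordings[(subject, r)], exp.events)
             for r in range(exp.config.n_runs)]
    from mvfeeg.pipeline import concat_epochs
    return concat_epochs(parts)


def test_epoching_preserves_grid_and_labels(small_experiment):
    ep = _epochs(small_experiment)
    cfg = small_experiment.config
    assert ep.n_trials == cfg.n_runs * cfg.trials_per_run
    assert ep.ch_names == cfg.channels
    assert ep.fs == cfg.fs
    assert ep.times[0] == pytest.approx(-1.5)
    assert set(ep.info["condition"]) <= {"NV", "CV", "IV"}


def test_epoch_values_match_recording_slice(small_experiment):
    rec = small_experiment.recordings[(0, 0)]
    ev = small_experiment.events
    ep = epoch_recording(rec, ev)
    go = ev[(ev.subject == 0) & (ev.run == 0)].iloc[3]["t_go_s"]
    i0 = int(round((go - 1.5) * rec.fs))
    assert np.array_equal(ep.data[3], rec.data[:, i0:i0 + ep.times.size])


def test_rejection_identity_at_infinite_threshold(small_experiment):
    ep = _epochs(small_experiment)
    kept, report = reject_artifact_trials(ep, np.inf, np.inf)
    assert kept.n_trials == ep.n_trials
    assert report["kept"].all()
    assert np.array_equal(kept.data, ep.data)


def test_rejection_reports_reason_and_preserves_order(small_experiment):
    ep = _epochs(small_experiment)
    dirty = ep.subset(np.ones(ep.n_trials, dtype=bool))
    dirty.data[5, 0, 100] += 500.0  # spike on one channel
    n = dirty.data.shape[2]
    dirty.data[9, 2] += np.linspace(0, 40.0 * (n / dirty.fs), n)  # 40 uV/s drift
    kept, report = reject_artifact_trials(dirty)
    assert not report.loc[5, "kept"] and "peak_to_peak" in report.loc[5, "reason"]
    assert not report.loc[9, "kept"] and "drift" in report.loc[9, "reason"]
    assert kept.n_trials == ep.n_trials - 2
    # surviving order preserved
    surviving = report[report["kept"]].index.to_numpy()
    assert np.array_equal(kept.info.index.to_numpy(), np.arange(len(surviving)))
    assert np.array_equal(kept.data[0], dirty.data[0])


def test_flip_right_handed_is_identity(small_experiment):
    rec = small_experiment.recordings[(0, 0)]
    assert rec.handedness == "right"
    assert flip_left_handed(rec) is rec


def test_flip_is_involution():
    m = make_montage(TEN_CHANNELS)
    rng = np.random.default_rng(0)
    rec = Recording(rng.standard_normal((len(m), 100)), 250.0, m, handedness="left")
    once = flip_left_handed(rec)
    once.handedness = "left"  # force a second mirror of the same data
    twice = flip_left_handed(once)
    assert np.array_equal(twice.data, rec.data)
    assert not np.array_equal(once.data, rec.data)


def test_flip_swaps_homologous_channels():
    m = make_montage(TEN_CHANNELS)
    data = np.arange(len(m) * 4, dtype=float).reshape(len(m), 4)
    rec = Recording(data.copy(), 250.0, m, handedness="left")
    out = flip_left_handed(rec)
    assert np.array_equal(out.data[m.index("C3")], data[m.index("C4")])
    assert np.array_equal(out.data[m.index("FC5")], data[m.index("FC6")])


def test_select_embodiment_window_rules(small_experiment):
    ep = _epochs(small_experiment)
    ep.info["t_pedal_s"] = np.nan
    ep.info.loc[0, "t_pedal_s"] = 7.0   # only 3 s of task remain -> dropped
    ep.info.loc[1, "t_pedal_s"] = 2.0   # window [2, 6) -> retained
    ep.info.loc[2, "t_pedal_s"] = 6.0   # window [6, 10) -> exactly fits
    out = select_embodiment_epochs(ep, 4.0)
    assert out.n_trials == 2
    assert list(out.analysis_start) == [2.0, 6.0]
    assert out.analysis_dur == 4.0


def test_select_warns_when_nothing_survives(small_experiment):
    ep = _epochs(small_experiment)
    ep.info["t_pedal_s"] = np.nan
    with pytest.warns(UserWarning):
        out = select_embodiment_epochs(ep, 4.0)
    assert out.n_trials == 0


def test_survivor_counts_match_latency_model(small_experiment):
    # generator expectation: pedal present AND t_pedal <= 6 s
    ep = _epochs(small_experiment)
    pedal = ep.info["t_pedal_s"].to_numpy(dtype=float)
    expected = int((np.isfinite(pedal) & (pedal <= 6.0)).sum())
    out = select_embodiment_epochs(ep, 4.0)
    assert out.n_trials == expected


def test_laplacian_of_uniform_field_is_exact_zero():
    m = make_montage()  # full 32-channel montage, 4 neighbors everywhere
    data = np.full((len(m), 50), 0.1)
    out = small_laplacian(data, m)
    assert np.all(out == 0.0)


def test_laplacian_center_recovers_isolated_value():
    m = make_montage()
    data = np.zeros((len(m), 3))
    data[m.index("C3")] = 2.5
    out = small_laplacian(data, m)
    assert np.allclose(out[m.index("C3")], 2.5)


def test_laplacian_matches_per_sample_loop_oracle(rng):
    m = make_montage(TEN_CHANNELS)
    data = rng.standard_normal((len(m), 20))
    out = small_laplacian(data, m)
    for i, ch in enumerate(m.channels):
        nb = [m.index(c) for c in m.neighbors[ch]]
        for t in range(20):
            expect = data[i, t] - sum(data[j, t] for j in nb) / len(nb)
            assert out[i, t] == pytest.approx(expect, rel=1e-12)


def test_laplacian_epochs_keeps_metadata(small_experiment):
    ep = select_embodiment_epochs(_epochs(small_experiment))
    out = laplacian_epochs(ep)
    assert out.n_trials == ep.n_trials
    assert np.array_equal(out.analysis_start, ep.analysis_start)
    pd.testing.assert_frame_equal(out.info, ep.info)
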