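import numpy as np
import pytest

from mvfeeg import LatencyModel, SimulationConfig, generate_dataset
from mvfeeg.preprocess import epoch_recording, select_embodiment_epochs
from mvfeeg.spectral import (
    SpectralParams,
    baseline_power,
    compute_erd,
    compute_ersp,
    compute_topography,
    erd_matrix,
)
from mvfeeg.studies import band_noise_epochs

from conftest import CONDS


def test_sliding_window_count_matches_parameters():
    ep = band_noise_epochs(5, seed=0)
    curve = compute_erd(ep, SpectralParams(), "C3", "alpha")
    assert len(curve.times) == int((4.0 - 0.8) / 0.004) + 1 == 801
    assert curve.times[0] == 0.0
    assert curve.times[-1] == pytest.approx(3.2)


def test_erd_of_unattenuated_signal_is_near_zero():
    ep = band_noise_epochs(800, attenuation=1.0, seed=1)
    curve = compute_erd(ep, SpectralParams(), "C3", "alpha")
    assert abs(curve.values.mean()) < 5.0


def test_erd_recovers_planted_attenuation_via_generator_ground_truth():
    # variance attenuation factor 0.6 -> -40% ERD, compared against the
    # generator's analytic ground-truth table
    a = np.sqrt(0.6)
    cfg = SimulationConfig(
        n_subjects=1, n_runs=1, trials_per_run=240, n_left_handed=0,
        channels=("C3", "C4"),
        erd_depth={(c, "C3", "alpha"): a for c in CONDS},
        latency={c: LatencyModel(2.0, 0.001, 0.0) for c in CONDS},
        pink_noise_uv=0.0, sensor_noise_uv=0.0, seed=21,
    )
    exp = generate_dataset(cfg)
    truth = exp.ground_truth.erd_percent
    expected = truth[(truth.channel == "C3") & (truth.band == "alpha")]["erd_pct"].iloc[0]
    ep = select_embodiment_epochs(epoch_recording(exp.recordings[(0, 0)], exp.events))
    curve = compute_erd(ep, SpectralParams(), "C3", "alpha")
    assert curve.values.mean() == pytest.approx(expected, abs=3.0)


def test_erd_never_below_minus_hundred():
    ep = band_noise_epochs(50, attenuation=0.01, seed=2)
    curve = compute_erd(ep, SpectralParams(), "C3", "alpha")
    assert (curve.values >= -100.0).all()
    assert curve.values.mean() < -95.0


def test_gain_change_leaves_erd_and_ersp_unchanged():
    ep = band_noise_epochs(40, attenuation=0.7, seed=3)
    params = SpectralParams()
    c1 = compute_erd(ep, params, "C3", "alpha")
    m1 = compute_ersp(ep, params, "C3")
    ep.data *= 2.0
    c2 = compute_erd(ep, params, "C3", "alpha")
    m2 = compute_ersp(ep, params, "C3")
    assert np.allclose(c1.values, c2.values)
    assert np.allclose(m1.values, m2.values)


def test_topography_value_equals_curve_time_mean():
    ep = band_noise_epochs(30, attenuation=0.8, seed=4)
    params = SpectralParams()
    topo = compute_topography(ep, params, "alpha")
    curve = compute_erd(ep, params, "C3", "alpha")
    i = topo.channels.index("C3")
    assert topo.values[i] == pytest.approx(curve.values.mean(), rel=1e-12)


def test_topography_minimum_at_planted_channel():
    a = 0.5
    cfg = SimulationConfig(
        n_subjects=1, n_runs=1, trials_per_run=120, n_left_handed=0,
        channels=("C3", "C4", "FC1", "FC2", "CP1", "CP2"),
        erd_depth={(c, "C3", "alpha"): a for c in CONDS},
        latency={c: LatencyModel(2.0, 0.001, 0.0) for c in CONDS},
        seed=22,
    )
    exp = generate_dataset(cfg)
    ep = select_embodiment_epochs(epoch_recording(exp.recordings[(0, 0)], exp.events))
    topo = compute_topography(ep, SpectralParams(), "alpha")
    i = topo.channels.index("C3")
    assert np.argmin(topo.values) == i
    others = np.delete(topo.values, i)
    assert topo.values[i] < -50 and (others > -20).all()


def test_ersp_and_erd_agree_in_sign():
    ep = band_noise_epochs(200, attenuation=0.6, seed=5)
    params = SpectralParams()
    curve = compute_erd(ep, params, "C3", "alpha")
    m = compute_ersp(ep, params, "C3")
    band_sel = (m.freqs >= 8) & (m.freqs <= 13)
    assert curve.values.mean() < 0
    assert m.values[:, band_sel].mean() < 0


def test_ersp_localizes_single_band_attenuation():
    # attenuate only 8-13 Hz of a broadband signal: the dB dip should sit in
    # the alpha rows, not in distant frequencies
    rng = np.random.default_rng(6)
    ep = band_noise_epochs(300, band=None, seed=6)
    from mvfeeg.spectral import bandpass
    alpha = bandpass(ep.data, (8.0, 13.0), ep.fs)
    on = int(round((1.0 - ep.times[0]) * ep.fs))
    a = 0.5
    ep.data[:, :, on:] -= (1 - a) * alpha[:, :, on:]
    m = compute_ersp(ep, SpectralParams(), "C3")
    in_band = m.values[:, (m.freqs >= 9) & (m.freqs <= 12)].mean()
    out_band = m.values[:, (m.freqs >= 30) & (m.freqs <= 60)].mean()
    assert in_band < -3.0
    assert abs(out_band) < 1.0


def test_pooled_baseline_matches_trialset_baseline_in_expectation():
    ep = band_noise_epochs(400, attenuation=1.0, seed=7)
    params = SpectralParams()
    pb = baseline_power(ep, params, (8.0, 13.0), [0])
    _, v_own = erd_matrix(ep, params, (8.0, 13.0), [0])
    _, v_pooled = erd_matrix(ep, params, (8.0, 13.0), [0], p_base=pb)
    assert np.allclose(v_own, v_pooled)  # same trial set -> identical baseline


def test_per_trial_baseline_mode_is_shallower_than_pooled():
    # dividing by each trial's own short noisy baseline is upward-biased
    # (Jensen's inequality on 1/P); the trial-set-mean baseline is the
    # default for exactly this reason
    ep = band_noise_epochs(300, attenuation=0.6, seed=8)
    per_trial = compute_erd(ep, SpectralParams(per_trial_baseline=True), "C3", "alpha")
    pooled = compute_erd(ep, SpectralParams(), "C3", "alpha")
    assert pooled.values.mean() < 0 and per_trial.values.mean() < 0
    assert per_trial.values.mean() > pooled.values.mean()


def test_parameter_validation():
    ep = band_noise_epochs(5, seed=9)
    with pytest.raises(ValueError):
        SpectralParams(baseline=(-0.5, 0.1)).validate(250.0)  # baseline after go
    with pytest.raises(ValueError):
        SpectralParams(step_s=0.001).validate(250.0)  # below one sample
    with pytest.raises(ValueError):
        compute_erd(ep.subset(np.zeros(5, bool)), SpectralParams(), "C3", "alpha")
    with pytest.raises(ValueError):
        compute_ersp(ep, SpectralParams(win_dur_s=8.0, baseline=(-0.9, 7.1)), "C3")
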