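"""Generator properties: determinism, fractal calibration, trends, counts."""

import numpy as np
import pandas as pd
import pytest

from runfatigue.hr_dynamics import DFA_A1_RANGE, RrSeries, dfa, detect_qrs, resample_linear
from runfatigue.synthetic_data import (
    SimConfig, fractional_gaussian_noise, gait_cycle_truth,
    generate_gait_recording, generate_gnss_track, generate_rof_schedule,
    generate_rr_series, generate_subject, inject_rr_artifacts, synthesize_ecg,
)
from runfatigue.ingest_sync import cumulative_distance_m

from conftest import scaled_config


# ---------------------------------------------------------------------------
# configuration validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kwargs", [
    dict(rr_baseline=0.25),
    dict(artifact_rate=0.6),
    dict(cadence=0.0),
    dict(n_subjects=0),
    dict(slope_sections=((100.0, 300.0, 6.0), (200.0, 100.0, 6.0))),
])
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ValueError):
        SimConfig(**kwargs)


def test_non_positive_duration_rejected():
    cfg = SimConfig(race_times_min=(0.0,) * 13)
    with pytest.raises(ValueError):
        cfg.race_duration(0)


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------

def test_same_seed_bit_identical():
    cfg = scaled_config(seed=5)
    a = generate_subject(cfg, 2)
    b = generate_subject(SimConfig(**{**cfg.__dict__}), 2)
    np.testing.assert_array_equal(a.rr_observed.rr, b.rr_observed.rr)
    np.testing.assert_array_equal(a.foot.acc, b.foot.acc)
    np.testing.assert_array_equal(a.chest.gyro, b.chest.gyro)
    pd.testing.assert_frame_equal(a.gait_truth, b.gait_truth)
    pd.testing.assert_frame_equal(a.rof_log, b.rof_log)


def test_different_seed_differs():
    a = generate_subject(scaled_config(seed=5), 0)
    b = generate_subject(scaled_config(seed=6), 0)
    assert not np.array_equal(a.rr_observed.rr, b.rr_observed.rr)


# ---------------------------------------------------------------------------
# RR series: degenerate cases, drift sign, fractal calibration
# ---------------------------------------------------------------------------

def test_noise_free_rr_is_constant():
    cfg = scaled_config(rr_noise_sd=0.0, lf_amp=0.0, hf_amp=0.0,
                        rr_drift_slope=0.0)
    rr, _ = generate_rr_series(cfg, 0)
    np.testing.assert_allclose(rr.rr, cfg.rr_baseline, rtol=1e-12)


def test_negative_drift_lowers_late_rr():
    cfg = scaled_config(rr_drift_slope=-0.05)
    rr, _ = generate_rr_series(cfg, 0)
    n = len(rr)
    assert rr.rr[-n // 10:].mean() < rr.rr[:n // 10].mean()


def test_beat_times_strictly_increasing_and_cumulative():
    rr, truth = generate_rr_series(scaled_config(), 3)
    assert np.all(np.diff(rr.beat_time) > 0)
    np.testing.assert_allclose(np.diff(rr.beat_time), rr.rr, rtol=1e-12)
    np.testing.assert_array_equal(truth.beat_times, rr.beat_time)
    assert np.all(rr.rr > 0.25 - 1e-12)


@pytest.mark.parametrize("alpha,tol", [(0.5, 0.05), (0.75, 0.07), (1.0, 0.07)])
def test_fgn_dfa_calibration(alpha, tol):
    """Spectral fGn synthesis hits its target DFA exponent on average."""
    vals = []
    for seed in range(40):
        x = fractional_gaussian_noise(1000, alpha, np.random.default_rng(seed))
        vals.append(dfa(x, DFA_A1_RANGE))
    assert abs(np.mean(vals) - alpha) < tol


def test_rr_white_noise_dfa_half():
    """With no drift/oscillations, RR noise at target 0.5 measures DFA 0.5."""
    vals = []
    for seed in range(30):
        cfg = scaled_config(hurst_alpha_target=0.5, lf_amp=0.0, hf_amp=0.0,
                            rr_drift_slope=0.0, seed=seed)
        rr, _ = generate_rr_series(cfg, 0)
        vals.append(dfa(rr.rr[:1000], DFA_A1_RANGE))
    assert abs(np.mean(vals) - 0.5) < 0.05


# ---------------------------------------------------------------------------
# ECG synthesis
# ---------------------------------------------------------------------------

def test_ecg_peaks_at_metronome_beats():
    rr = RrSeries.from_beat_times(np.arange(60, dtype=float))
    ecg = synthesize_ecg(rr, fs=250.0, snr_db=None)
    span = rr.beat_time[-1] - rr.beat_time[0] + 1.0   # incl. edge lead-in/out
    assert len(ecg.mv) == int(np.ceil(span * 250))
    beats = detect_qrs(resample_linear(ecg))
    found = [b for b in beats if np.min(np.abs(rr.beat_time - b)) < 1.0 / 250.0]
    assert len(found) >= 58


def test_empty_rr_gives_empty_stream():
    rr = RrSeries(beat_time=np.array([]), rr=np.array([]),
                  artifact=np.array([], dtype=bool))
    assert len(synthesize_ecg(rr).mv) == 0


def test_bad_sampling_rate_rejected():
    rr = RrSeries.from_beat_times(np.arange(10, dtype=float))
    with pytest.raises(ValueError):
        synthesize_ecg(rr, fs=0.0)


# ---------------------------------------------------------------------------
# gait recording
# ---------------------------------------------------------------------------

def test_cycle_count_matches_cadence():
    cfg = scaled_config(race_times_min=(1.0,) * 13, race_distance_m=240.0,
                        cadence=90.0, rof_interval_s=7.0)
    truth = gait_cycle_truth(cfg, 0)
    assert abs(len(truth) - 89) <= 1
    # conservation: cycle times tile the race within one cycle
    assert abs(len(truth) * 60.0 / cfg.cadence - 60.0) <= 2 * 60.0 / cfg.cadence


def test_zero_trend_zero_noise_cycles_identical():
    cfg = scaled_config(trends={}, gait_noise_frac=0.0)
    truth = gait_cycle_truth(cfg, 0)
    for col in ("t_c", "t_f", "FSA", "omega_s"):
        assert truth[col].nunique() == 1


def test_destructive_trend_rejected():
    cfg = scaled_config(trends={"t_c": -1.5}, gait_noise_frac=0.0)
    with pytest.raises(ValueError):
        gait_cycle_truth(cfg, 0)


def test_gait_streams_cover_recording():
    cfg = scaled_config(race_times_min=(2.0,) * 13, race_distance_m=480.0,
                        rof_interval_s=14.0)
    truth, foot, chest = generate_gait_recording(cfg, 0)
    total = cfg.pre_duration + cfg.race_duration(0) + cfg.post_duration
    assert abs((foot.time[-1] - foot.time[0]) - total) < 1.0
    assert foot.time[0] == pytest.approx(cfg.sync_lag)   # offset clock
    assert chest.time[0] == 0.0


# ---------------------------------------------------------------------------
# GNSS track
# ---------------------------------------------------------------------------

def test_flat_track_has_no_grade():
    cfg = scaled_config(slope_sections=())
    track = generate_gnss_track(cfg, 0)
    dist = cumulative_distance_m(track)
    # steepest 100 m window
    j = np.searchsorted(dist, dist + 100.0)
    ok = j < len(dist)
    grade = np.abs(track.ele[j[ok]] - track.ele[np.nonzero(ok)[0]]) / 100.0
    assert np.max(grade) < 0.01
    assert abs(dist[-1] - cfg.race_distance_m) / cfg.race_distance_m < 0.01


def test_slope_section_elevation_gain():
    cfg = scaled_config(slope_sections=((1000.0, 200.0, 8.0),))
    track = generate_gnss_track(cfg, 0)
    assert track.ele[-1] == pytest.approx(16.0, abs=0.5)   # 8% over 200 m


def test_zero_speed_track_rejected():
    cfg = scaled_config(race_distance_m=0.0)
    with pytest.raises(ValueError):
        generate_gnss_track(cfg, 0)


# ---------------------------------------------------------------------------
# ROF schedule
# ---------------------------------------------------------------------------

def test_rof_prompt_count_100min_race():
    cfg = SimConfig(race_times_min=(100.0,) * 13)
    log = generate_rof_schedule(cfg, 0)
    assert len(log) == 10
    assert log["rof"].is_monotonic_increasing or np.all(np.diff(log["rof"]) >= 0)
    assert log["rof"].between(1, 10).all()


def test_rof_every_segment_occupied():
    cfg = scaled_config()
    for s in range(cfg.n_subjects):
        log = generate_rof_schedule(cfg, s)
        duration = cfg.race_duration(s)
        seg = np.floor((log["time_s"] - cfg.pre_duration) / (duration / 8.0))
        assert set(range(8)) <= set(seg.astype(int))


def test_rof_explicit_trajectory_endpoints():
    cfg = scaled_config(rof_start=(3,) * 13, rof_end=(9,) * 13)
    log = generate_rof_schedule(cfg, 0)
    assert log["rof"].iloc[0] >= 3
    assert log["rof"].iloc[-1] == 9


def test_short_race_warns():
    cfg = scaled_config(race_times_min=(5.0,) * 13, race_distance_m=1200.0)
    with pytest.warns(UserWarning):
        generate_rof_schedule(cfg, 0)


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------

def test_zero_rate_is_identity():
    rr, _ = generate_rr_series(scaled_config(), 0)
    out, idx = inject_rr_artifacts(rr, 0.0)
    np.testing.assert_array_equal(out.rr, rr.rr)
    assert idx.size == 0


def test_injection_halves_or_doubles():
    rr, _ = generate_rr_series(scaled_config(), 0)
    out, idx = inject_rr_artifacts(rr, 0.02, np.random.default_rng(3))
    assert idx.size == round(0.02 * len(rr))
    ratio = out.rr[idx] / rr.rr[idx]
    assert np.all(np.isin(np.round(ratio, 6), [0.5, 2.0]))
    untouched = np.setdiff1d(np.arange(len(rr)), idx)
    np.testing.assert_array_equal(out.rr[untouched], rr.rr[untouched])
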