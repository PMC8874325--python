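"""Heart-rate dynamics: QRS detection, RR correction, HRV/HRC metrics."""

import math

import numpy as np
import pytest

from runfatigue.hr_dynamics import (
    DFA_A1_RANGE, DFA_A2_RANGE, EcgStream, RrSeries, cardiac_cost,
    compute_hr_features, correct_rr, detect_qrs, dfa, frequency_domain,
    poincare, resample_linear, time_domain, validate_window, window_stream,
)
from runfatigue.synthetic_data import (
    fractional_gaussian_noise, generate_rr_series, inject_rr_artifacts,
    synthesize_ecg,
)

from conftest import scaled_config


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("duration,expected", [(600.0, 49), (120.0, 1),
                                               (1000.0, 89)])
def test_window_count(duration, expected):
    wins = window_stream(duration)
    assert len(wins) == expected
    steps = np.diff([a for a, _ in wins])
    assert np.allclose(steps, 10.0)


def test_short_signal_warns_no_windows():
    with pytest.warns(UserWarning):
        assert window_stream(119.0) == []


def test_bad_overlap_rejected():
    with pytest.raises(ValueError):
        window_stream(600.0, length=120.0, overlap=120.0)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def test_resample_identity_and_ramp():
    t = np.arange(0.0, 2.0, 1.0 / 250.0)
    ramp = EcgStream(time=t, mv=3.0 * t, fs=250.0)
    up = resample_linear(ramp, 1000.0)
    np.testing.assert_allclose(up.mv, 3.0 * up.time, atol=1e-12)
    same = resample_linear(ramp, 250.0)
    np.testing.assert_allclose(same.mv, ramp.mv, atol=1e-12)


def test_resample_sinusoid_accuracy():
    """Linear-interpolation error stays below the analytic chord bound
    (2πf/fs)²/8 of the amplitude."""
    t = np.arange(0.0, 1.0, 1.0 / 250.0)
    ecg = EcgStream(time=t, mv=np.sin(2 * np.pi * 10.0 * t), fs=250.0)
    up = resample_linear(ecg, 1000.0)
    err = np.max(np.abs(up.mv - np.sin(2 * np.pi * 10.0 * up.time)))
    bound = (2 * np.pi * 10.0 / 250.0) ** 2 / 8.0
    assert err < bound * 1.01


def test_downsample_rejected():
    t = np.arange(0.0, 1.0, 1.0 / 250.0)
    with pytest.raises(ValueError):
        resample_linear(EcgStream(time=t, mv=t, fs=250.0), 100.0)


# ---------------------------------------------------------------------------
# QRS detection
# ---------------------------------------------------------------------------

def test_qrs_clean_metronome():
    rr = RrSeries.from_beat_times(np.arange(0.5, 60.5, 1.0))
    ecg = resample_linear(synthesize_ecg(rr, snr_db=None))
    beats = detect_qrs(ecg)
    matched = sum(1 for b in rr.beat_time
                  if np.min(np.abs(beats - b)) <= 0.005)
    assert matched >= 0.99 * len(rr.beat_time)


def test_qrs_flat_signal_empty():
    t = np.arange(0.0, 10.0, 0.001)
    assert len(detect_qrs(EcgStream(time=t, mv=np.zeros_like(t), fs=1000.0))) == 0


def test_qrs_noisy_fast_rate():
    """Sensitivity and precision ≥ 0.99 at SNR 10 dB and 150 bpm."""
    beat_times = np.cumsum(np.full(300, 0.4))
    rr = RrSeries.from_beat_times(np.concatenate([[0.0], beat_times]))
    ecg = synthesize_ecg(rr, fs=250.0, snr_db=10.0,
                         rng=np.random.default_rng(7))
    beats = detect_qrs(resample_linear(ecg))
    tol = 0.010
    tp = sum(1 for b in rr.beat_time if np.min(np.abs(beats - b)) <= tol)
    sens = tp / len(rr.beat_time)
    prec = sum(1 for b in beats
               if np.min(np.abs(rr.beat_time - b)) <= tol) / len(beats)
    assert sens >= 0.99
    assert prec >= 0.99


# ---------------------------------------------------------------------------
# RR correction and window validity
# ---------------------------------------------------------------------------

def test_correct_rr_clean_identity():
    rr = RrSeries.from_rr(np.full(200, 0.8))
    out, rate = correct_rr(rr)
    assert rate == 0.0
    np.testing.assert_array_equal(out.rr, rr.rr)


def test_correct_rr_single_double():
    rng = np.random.default_rng(5)
    vals = 0.8 + 0.02 * rng.standard_normal(1000)
    vals[500] *= 2.0
    out, rate = correct_rr(RrSeries.from_rr(vals))
    assert out.artifact[500]
    neighbors = np.concatenate([vals[490:500], vals[501:511]])
    assert abs(out.rr[500] - neighbors.mean()) / neighbors.mean() < 0.05


def test_correct_rr_recall_on_injected():
    """≥ 90% of injected 2% artifacts are flagged."""
    cfg = scaled_config(artifact_rate=0.0)
    rr, _ = generate_rr_series(cfg, 0)
    perturbed, idx = inject_rr_artifacts(rr, 0.02, np.random.default_rng(9))
    out, rate = correct_rr(perturbed)
    recall = out.artifact[idx].mean()
    assert recall >= 0.90
    assert rate >= 0.015


@pytest.mark.parametrize("rate,expected", [(0.0, True), (0.049, True),
                                           (0.05, False), (0.2, False)])
def test_window_validity_strict_boundary(rate, expected):
    assert validate_window(rate) is expected


def test_validity_rejects_non_fraction():
    with pytest.raises(ValueError):
        validate_window(1.5)


# ---------------------------------------------------------------------------
# time-domain metrics
# ---------------------------------------------------------------------------

def test_time_domain_constant():
    bpm, sdnn, rmssd = time_domain(np.full(100, 1.0))
    assert bpm == pytest.approx(60.0)
    assert sdnn == pytest.approx(0.0)
    assert rmssd == pytest.approx(0.0)


def test_time_domain_alternating():
    rr = np.tile([0.9, 1.1], 50)
    bpm, sdnn, rmssd = time_domain(rr)
    assert bpm == pytest.approx(60.0)
    assert rmssd == pytest.approx(200.0)
    assert sdnn == pytest.approx(100.0, rel=0.01)


def test_time_domain_matches_textbook_formulas():
    """Dual implementation with plain python loops, 1e-9 relative."""
    rr = 0.8 + 0.05 * fractional_gaussian_noise(
        500, 0.75, np.random.default_rng(1))
    bpm, sdnn, rmssd = time_domain(rr)
    n = len(rr)
    mean = sum(rr) / n
    var = sum((x - mean) ** 2 for x in rr) / (n - 1)
    ss = sum((rr[i + 1] - rr[i]) ** 2 for i in range(n - 1)) / (n - 1)
    assert bpm == pytest.approx(60.0 / mean, rel=1e-9)
    assert sdnn == pytest.approx(math.sqrt(var) * 1000, rel=1e-9)
    assert rmssd == pytest.approx(math.sqrt(ss) * 1000, rel=1e-9)


def test_time_domain_needs_two_intervals():
    with pytest.raises(ValueError):
        time_domain(np.array([0.8]))


# ---------------------------------------------------------------------------
# frequency-domain metrics
# ---------------------------------------------------------------------------

def _modulated_rr(freq, duration=300.0, amp=0.05, base=1.0):
    beats = [0.0]
    while beats[-1] < duration:
        t = beats[-1]
        beats.append(t + base + amp * np.sin(2 * np.pi * freq * t))
    bt = np.asarray(beats)
    return np.diff(bt), bt


def test_hf_modulation_lands_in_hf_band():
    rr, bt = _modulated_rr(0.30)
    lf, hf, plf, phf, _ = frequency_domain(rr, bt)
    assert phf >= 0.95


def test_lf_modulation_lands_in_lf_band():
    rr, bt = _modulated_rr(0.10)
    lf, hf, plf, phf, lfhf = frequency_domain(rr, bt)
    assert plf >= 0.95
    assert lfhf > 1.0


def test_fractions_sum_to_one_and_dc_invariance():
    rng = np.random.default_rng(3)
    rr = 0.9 + 0.03 * fractional_gaussian_noise(400, 0.9, rng)
    bt = np.concatenate([[0.0], np.cumsum(rr)])
    lf, hf, plf, phf, _ = frequency_domain(rr, bt)
    assert plf + phf == pytest.approx(1.0, abs=1e-9)
    lf2, hf2, plf2, phf2, _ = frequency_domain(rr + 0.2,
                                               np.concatenate([[0.0], np.cumsum(rr + 0.2)]))
    assert plf2 == pytest.approx(plf, abs=0.1)   # detrending removes DC


# ---------------------------------------------------------------------------
# Poincaré
# ---------------------------------------------------------------------------

def test_sd1_is_rmssd_over_sqrt2():
    rng = np.random.default_rng(4)
    for seed in range(5):
        rr = 0.8 + 0.04 * fractional_gaussian_noise(
            300, 0.8, np.random.default_rng(seed))
        sd1, sd2, ratio = poincare(rr)
        _, _, rmssd = time_domain(rr)
        assert sd1 == pytest.approx(rmssd / math.sqrt(2.0), rel=1e-9)


def test_poincare_constant_degenerate():
    sd1, sd2, ratio = poincare(np.full(10, 0.8))
    assert sd1 == 0.0
    assert sd2 == 0.0
    assert np.isnan(ratio)


def test_poincare_matches_projection_quadratic_form():
    """Axes equal quadratic forms of the lag-1 point cloud's moments."""
    rr = 0.8 + 0.04 * fractional_gaussian_noise(
        500, 0.9, np.random.default_rng(8)) * 1.0
    sd1, sd2, _ = poincare(rr)
    x, y = rr[:-1] * 1000, rr[1:] * 1000
    w1 = np.array([-1.0, 1.0]) / math.sqrt(2.0)     # transverse direction
    w2 = np.array([1.0, 1.0]) / math.sqrt(2.0)      # line of identity
    raw = np.stack([x, y])
    second = raw @ raw.T / len(x)                    # raw second moments
    centered = np.cov(raw, ddof=0)
    sd1_oracle = math.sqrt(w1 @ second @ w1)
    sd2_oracle = math.sqrt(w2 @ centered @ w2)
    assert sd1 == pytest.approx(sd1_oracle, rel=1e-9)
    assert sd2 == pytest.approx(sd2_oracle, rel=1e-9)


# ---------------------------------------------------------------------------
# DFA
# ---------------------------------------------------------------------------

def test_dfa_white_noise():
    vals = [dfa(fractional_gaussian_noise(1000, 0.5, np.random.default_rng(s)),
                DFA_A1_RANGE) for s in range(50)]
    assert abs(np.mean(vals) - 0.5) < 0.05


def test_dfa_pink_noise():
    vals = [dfa(fractional_gaussian_noise(1000, 1.0, np.random.default_rng(s)),
                DFA_A1_RANGE) for s in range(50)]
    assert abs(np.mean(vals) - 1.0) < 0.07


def test_dfa_long_range_scales():
    vals = [dfa(fractional_gaussian_noise(1000, 0.5, np.random.default_rng(s)),
                DFA_A2_RANGE) for s in range(30)]
    assert abs(np.mean(vals) - 0.5) < 0.05


def test_dfa_degenerate_and_affine_invariance():
    assert np.isnan(dfa(np.full(500, 0.8), DFA_A1_RANGE))
    x = fractional_gaussian_noise(800, 0.75, np.random.default_rng(2))
    a = dfa(x, DFA_A1_RANGE)
    b = dfa(3.5 * x + 10.0, DFA_A1_RANGE)
    assert a == pytest.approx(b, abs=1e-9)


def test_dfa_needs_enough_beats():
    assert np.isnan(dfa(np.random.default_rng(0).standard_normal(50),
                        DFA_A2_RANGE))


# ---------------------------------------------------------------------------
# cardiac cost and the window driver
# ---------------------------------------------------------------------------

def test_cardiac_cost_arithmetic_and_homogeneity():
    assert cardiac_cost(180.0, 3.0) == pytest.approx(60.0)
    assert cardiac_cost(150.0, 2.5) == pytest.approx(60.0)
    assert cardiac_cost(150.0, 1.25) == pytest.approx(2 * cardiac_cost(150.0, 2.5))
    assert np.isnan(cardiac_cost(150.0, 0.0))


def test_feature_rows_every_ten_seconds():
    cfg = scaled_config(race_times_min=(10.0,) * 13, race_distance_m=2400.0,
                        rof_interval_s=70.0)
    rr, _ = generate_rr_series(cfg, 0)
    feats = compute_hr_features(rr)
    duration = rr.beat_time[-1] - rr.beat_time[0]
    assert len(feats) == int((duration - 120.0) / 10.0) + 1
    np.testing.assert_allclose(np.diff(feats["window_center"]), 10.0)
    valid = feats[feats["valid"]]
    assert (valid["pLF"] + valid["pHF"]).sub(1.0).abs().max() < 1e-9


def test_invalid_windows_propagate_missing():
    rng = np.random.default_rng(11)
    base = 0.8 + 0.01 * rng.standard_normal(400)
    rr, idx = inject_rr_artifacts(RrSeries.from_rr(base), 0.10, rng)
    feats = compute_hr_features(rr)
    bad = feats[~feats["valid"]]
    assert len(bad) > 0
    assert bad["BPM"].isna().all()
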