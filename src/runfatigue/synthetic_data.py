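"""Synthetic multi-sensor race recordings with known ground truth.

Emulates the study conditions of a 13-runner half-marathon: an RR-interval
series with controllable drift, 0.1 / 0.3 Hz oscillatory components and
fractal (fGn) noise tuned to a target DFA exponent; a stylized single-lead
250 Hz ECG with one QRS complex per beat; per-gait-cycle biomechanical
parameters following configured linear fatigue trends; chest and foot
inertial streams carrying a pre-race synchronization shock with a known
clock lag; a 10 Hz GNSS track with configurable sloped sections; and a
rating-of-fatigue (ROF) log prompted every 10 minutes.  Every stage returns
the ground truth needed to score the corresponding pipeline stage.

The generator is deterministic: identical configuration and seed give
byte-identical outputs (one master seed, fixed per-subject / per-stream
substream derivation).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .hr_dynamics import RrSeries, EcgStream
from .ingest_sync import (GnssTrack, ImuStream, write_gnss_csv, write_gpx,
                          write_imu_csv)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SubjectRecording",
    "fractional_gaussian_noise",
    "generate_rr_series",
    "synthesize_ecg",
    "gait_cycle_truth",
    "generate_gait_recording",
    "generate_gnss_track",
    "generate_rof_schedule",
    "inject_rr_artifacts",
    "generate_subject",
    "write_recording",
]

#: meters of latitude per degree on the reference sphere
_M_PER_DEG = 6_371_000.0 * np.pi / 180.0

# default per-parameter linear drift over the race (fraction of baseline),
# signs following the fatigue responses the pipeline is built to detect
DEFAULT_TRENDS = {
    "t_c": +0.05, "t_f": -0.05, "FSA": -0.10, "FEA": +0.05,
    "omega_s": -0.05, "a_AP": +0.10, "a_ML": +0.03, "v": -0.04,
}
# per-cycle baselines (units as in the gait table)
GAIT_BASELINES = {
    "t_c": 0.26, "t_f": 0.11, "FSA": 12.0, "FEA": 8.0,
    "omega_s": 600.0, "a_AP": 0.30, "a_ML": 0.12,
}

# half-marathon race times (minutes) for the default 13-runner cohort:
# five fast (< 90), three mid, five slow (> 105)
DEFAULT_RACE_TIMES_MIN = (
    82.0, 83.0, 85.0, 87.0, 89.0,
    95.0, 99.0, 103.0,
    107.0, 111.0, 116.0, 121.0, 127.0,
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a flat-course half-marathon with recreational runners:
    race times spanning roughly 80-127 min (five fast, five slow), exercise
    heart rates rising from ~143 to ~162 bpm, ROF prompted every 10 min and
    climbing monotonically toward race end, a 2% RR artifact rate, and one
    8%-grade climb to exercise the slope-exclusion logic.
    """

    n_subjects: int = 13
    race_distance_m: float = 21_097.0
    race_times_min: tuple = DEFAULT_RACE_TIMES_MIN
    rr_baseline: float = 0.42            # s
    rr_drift_slope: float = -0.05        # s per race fraction (HR rises)
    hurst_alpha_target: float = 0.75     # DFA-α1 of the fGn noise component
    rr_noise_sd: float = 0.01            # s
    lf_amp: float = 0.004                # s, 0.1 Hz oscillation
    hf_amp: float = 0.008                # s, 0.3 Hz oscillation
    artifact_rate: float = 0.02          # fraction of beats perturbed
    cadence: float = 85.0                # strides/min (right foot)
    gait_noise_frac: float = 0.02        # white noise SD as fraction of baseline
    trends: dict = field(default_factory=lambda: dict(DEFAULT_TRENDS))
    slope_sections: tuple = ((5_000.0, 200.0, 8.0),)   # (start_m, length_m, grade_%)
    rof_start: tuple | None = None       # per-subject; None → seeded 2..5
    rof_end: tuple | None = None         # per-subject; None → seeded 8..10
    sync_lag: float = 0.5                # s, foot clock ahead of chest clock
    pre_duration: float = 60.0           # s of pre-race recording
    post_duration: float = 30.0          # s of post-race recording
    shock_time: float = 30.0             # s, within the pre period
    imu_fs: float = 200.0                # Hz
    gnss_fs: float = 10.0                # Hz
    ecg_fs: float = 250.0                # Hz
    ecg_snr_db: float | None = 20.0      # None → noise-free
    body_mass_kg: float = 70.0
    rof_interval_s: float = 600.0        # prompt every 10 min
    fast_below_min: float = 90.0         # race time: fast-group threshold
    slow_above_min: float = 105.0        # race time: slow-group threshold
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.rr_baseline <= 0.3:
            raise ValueError("rr_baseline must exceed 0.3 s")
        if not 0.0 <= self.artifact_rate < 0.5:
            raise ValueError("artifact_rate must be in [0, 0.5)")
        if self.cadence <= 0:
            raise ValueError("cadence must be positive")
        if len(self.race_times_min) < self.n_subjects:
            raise ValueError("need a race time per subject")
        starts = [s for s, _, _ in self.slope_sections]
        ends = [s + l for s, l, _ in self.slope_sections]
        for (a, b), a2 in zip(sorted(zip(starts, ends)), sorted(starts)[1:]):
            if a2 < b:
                raise ValueError("slope sections must not overlap")

    def race_duration(self, subject: int) -> float:
        """Race duration in seconds for one subject."""
        d = float(self.race_times_min[subject]) * 60.0
        if d <= 0:
            raise ValueError("race duration must be positive")
        return d

    def mean_speed(self, subject: int) -> float:
        return self.race_distance_m / self.race_duration(subject)

    def group_label(self, subject: int) -> str:
        t = self.race_times_min[subject]
        if t < self.fast_below_min:
            return "fast"
        if t > self.slow_above_min:
            return "slow"
        return "mid"

    def rng(self, subject: int, stream: int) -> np.random.Generator:
        """Deterministic substream for one subject and one signal family."""
        return np.random.default_rng([self.seed, subject, stream])


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline without re-reading config."""

    beat_times: np.ndarray = None                 # race-relative, clean
    injected_artifact_indices: np.ndarray = None  # RR-interval indices
    gait_truth: pd.DataFrame = None               # per-cycle true parameters
    slope_intervals: list = field(default_factory=list)   # race-relative (s)
    sync_lag: float = 0.0
    rof_per_segment: list = field(default_factory=list)
    race_interval: tuple = (0.0, 0.0)             # recording-relative

    def to_json(self, path) -> None:
        payload = {
            "beat_times": None if self.beat_times is None
            else np.round(self.beat_times, 6).tolist(),
            "injected_artifact_indices": None
            if self.injected_artifact_indices is None
            else np.asarray(self.injected_artifact_indices).tolist(),
            "gait_truth": None if self.gait_truth is None
            else self.gait_truth.round(6).to_dict(orient="list"),
            "slope_intervals": [list(map(float, iv)) for iv in self.slope_intervals],
            "sync_lag": float(self.sync_lag),
            "rof_per_segment": list(map(int, self.rof_per_segment)),
            "race_interval": list(map(float, self.race_interval)),
        }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# Fractal noise and the RR series
# ---------------------------------------------------------------------------

def fractional_gaussian_noise(n: int, alpha: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Stationary Gaussian noise with 1/f^β spectrum, β = 2α − 1.

    Spectral synthesis: white Gaussian noise is filtered in the frequency
    domain with ``f^(−β/2)`` so that the DFA exponent of the result
    approaches ``alpha`` (α = 0.5 white, 1.0 pink).  Output is standardized
    to zero mean and unit variance.
    """
    beta = 2.0 * alpha - 1.0
    w = rng.standard_normal(n)
    if abs(beta) < 1e-12:
        out = w
    else:
        spec = np.fft.rfft(w)
        f = np.fft.rfftfreq(n, d=1.0)
        scale = np.ones_like(f)
        scale[1:] = f[1:] ** (-beta / 2.0)
        scale[0] = 0.0
        out = np.fft.irfft(spec * scale, n)
    sd = out.std()
    if sd > 0:
        out = (out - out.mean()) / sd
    return out


def generate_rr_series(cfg: SimConfig, subject: int
                       ) -> tuple[RrSeries, GroundTruth]:
    """Clean RR series over one subject's race, plus its ground truth.

    ``RR(t) = baseline + drift·(t/T) + lf_amp·sin(2π·0.1·t)
    + hf_amp·sin(2π·0.3·t) + σ·fGn(α)``, clipped below at 0.25 s; beat
    times accumulate the intervals from race start (t = 0).
    """
    duration = cfg.race_duration(subject)
    rng = cfg.rng(subject, stream=1)
    min_rr = 0.25
    n_max = int(np.ceil(duration / min_rr)) + 2
    noise = fractional_gaussian_noise(n_max, cfg.hurst_alpha_target, rng)
    beat_times = [0.0]
    rr_list = []
    t = 0.0
    i = 0
    while t < duration and i < n_max:
        rr = (cfg.rr_baseline
              + cfg.rr_drift_slope * (t / duration)
              + cfg.lf_amp * np.sin(2 * np.pi * 0.1 * t)
              + cfg.hf_amp * np.sin(2 * np.pi * 0.3 * t)
              + cfg.rr_noise_sd * noise[i])
        rr = max(rr, min_rr)
        t += rr
        if t >= duration:
            break
        beat_times.append(t)
        rr_list.append(rr)
        i += 1
    series = RrSeries(beat_time=np.asarray(beat_times),
                      rr=np.asarray(rr_list))
    truth = GroundTruth(beat_times=np.asarray(beat_times), sync_lag=cfg.sync_lag)
    return series, truth


# ---------------------------------------------------------------------------
# ECG synthesis
# ---------------------------------------------------------------------------

def _qrs_template(fs: float) -> np.ndarray:
    """Stylized biphasic QRS complex, ~80 ms support, 1 mV R peak."""
    t = np.arange(-0.04, 0.04, 1.0 / fs)
    r = np.exp(-0.5 * (t / 0.008) ** 2)
    s = -0.25 * np.exp(-0.5 * ((t - 0.02) / 0.010) ** 2)
    q = -0.10 * np.exp(-0.5 * ((t + 0.02) / 0.010) ** 2)
    return r + s + q


def synthesize_ecg(rr: RrSeries, fs: float = 250.0,
                   snr_db: float | None = None,
                   rng: np.random.Generator | None = None) -> EcgStream:
    """ECG waveform with one template QRS complex at each beat time.

    Additive white Gaussian noise is scaled to the requested SNR (signal
    RMS over noise RMS, dB); ``snr_db=None`` leaves the trace noise-free.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if len(rr.beat_time) == 0:
        return EcgStream(time=np.array([]), mv=np.array([]), fs=fs)
    # half-second lead-in/out so edge QRS complexes are not truncated
    duration = rr.beat_time[-1] - rr.beat_time[0] + 1.0
    n = int(np.ceil(duration * fs))
    t0 = rr.beat_time[0] - 0.5
    x = np.zeros(n)
    tpl = _qrs_template(fs)
    half = len(tpl) // 2
    for bt in rr.beat_time:
        c = int(round((bt - t0) * fs))
        a, b = c - half, c - half + len(tpl)
        ta, tb = max(a, 0), min(b, n)
        if ta >= tb:
            continue
        x[ta:tb] += tpl[ta - a:len(tpl) - (b - tb)]
    if snr_db is not None and np.isfinite(snr_db):
        rng = rng or np.random.default_rng(0)
        sig_rms = np.sqrt(np.mean(x ** 2))
        noise_rms = sig_rms / (10.0 ** (snr_db / 20.0))
        x = x + rng.standard_normal(n) * noise_rms
    time = t0 + np.arange(n) / fs
    return EcgStream(time=time, mv=x, fs=fs)


# ---------------------------------------------------------------------------
# Gait recording
# ---------------------------------------------------------------------------

def _shock_pulse(t: np.ndarray, center: float, amp: float = 30.0,
                 width: float = 0.15) -> np.ndarray:
    """Gaussian-windowed sinusoid: the pre-race up-down shock movement."""
    env = np.exp(-0.5 * ((t - center) / width) ** 2)
    return amp * env * np.sin(2 * np.pi * 6.0 * (t - center))


def speed_profile(cfg: SimConfig, subject: int, t_race: np.ndarray) -> np.ndarray:
    """Running speed over the race: configured mean with the linear fade."""
    duration = cfg.race_duration(subject)
    frac = np.clip(np.asarray(t_race) / duration, 0.0, 1.0)
    trend = cfg.trends.get("v", 0.0)
    # linear trend centered so the time-average equals the configured mean
    return cfg.mean_speed(subject) * (1.0 + trend * (frac - 0.5))


def gait_cycle_truth(cfg: SimConfig, subject: int) -> pd.DataFrame:
    """Per-cycle true biomechanical parameters (no waveform synthesis).

    One row per right-foot gait cycle: the configured linear trends over
    race fraction plus white noise, the running-speed profile, and gait
    events (initial contact, toe-off, next initial contact) consistent with
    the mid-swing grid.  Times are recording-relative.
    """
    duration = cfg.race_duration(subject)
    rng = cfg.rng(subject, stream=2)
    t_g = 60.0 / cfg.cadence
    n_cycles = int(np.floor(duration / t_g)) - 1
    if n_cycles < 1:
        raise ValueError("race too short for one gait cycle")
    race_start = cfg.pre_duration
    ms_times = race_start + t_g * np.arange(n_cycles + 1)   # mid-swings
    frac = np.arange(n_cycles) / max(n_cycles - 1, 1)
    truth = pd.DataFrame({"cycle_index": np.arange(n_cycles),
                          "time": ms_times[:-1]})
    for name, base in GAIT_BASELINES.items():
        trend = cfg.trends.get(name, 0.0)
        clean = base * (1.0 + trend * frac)
        noisy = clean + cfg.gait_noise_frac * base * rng.standard_normal(n_cycles)
        if np.any(noisy <= 0) and name in ("t_c", "t_f"):
            raise ValueError(f"configured trend drives {name} non-positive")
        truth[name] = noisy
    truth["v"] = speed_profile(cfg, subject, ms_times[:-1] - race_start)
    truth["t_g"] = t_g
    truth["ic"] = ms_times[:-1] + 0.35 * t_g
    truth["to"] = truth["ic"] + truth["t_c"]
    truth["next_ic"] = truth["to"] + truth["t_f"]
    return truth


def generate_gait_recording(cfg: SimConfig, subject: int
                            ) -> tuple[pd.DataFrame, ImuStream, ImuStream]:
    """Per-cycle true parameters plus foot and chest inertial streams.

    The truth table carries one row per right-foot gait cycle with the
    configured linear trends and white noise.  The foot gyroscope sagittal
    channel has one dominant positive peak per cycle at mid-swing; the
    chest accelerometer AP/ML channels have per-cycle means ``a_AP·v`` and
    ``a_ML·v``.  Both streams include the synchronization shock in the
    pre-race period; foot timestamps run on a clock offset by
    ``cfg.sync_lag`` seconds.
    """
    duration = cfg.race_duration(subject)
    truth = gait_cycle_truth(cfg, subject)
    rng = cfg.rng(subject, stream=6)
    t_g = 60.0 / cfg.cadence
    n_cycles = len(truth)
    race_start = cfg.pre_duration
    ms_times = race_start + t_g * np.arange(n_cycles + 1)

    total = cfg.pre_duration + duration + cfg.post_duration
    n = int(total * cfg.imu_fs)
    t = np.arange(n) / cfg.imu_fs

    # --- foot stream (clock offset by sync_lag) -------------------------
    gyro_sag = 8.0 * rng.standard_normal(n)
    width = 0.06
    idx = np.searchsorted(t, ms_times[:-1])
    for i, c in zip(range(n_cycles), ms_times[:-1]):
        lo = max(int((c - 4 * width) * cfg.imu_fs), 0)
        hi = min(int((c + 4 * width) * cfg.imu_fs) + 1, n)
        gyro_sag[lo:hi] += truth["omega_s"].iloc[i] * np.exp(
            -0.5 * ((t[lo:hi] - c) / width) ** 2)
    foot_acc = np.zeros((n, 3))
    foot_acc[:, 1] = 0.5 * rng.standard_normal(n)
    foot_acc[:, 1] += _shock_pulse(t, cfg.shock_time)
    race_mask = (t >= race_start) & (t < race_start + duration)
    foot_acc[race_mask, 1] += 15.0 * np.abs(
        np.sin(np.pi * (t[race_mask] - race_start) / t_g))
    foot = ImuStream(time=t + cfg.sync_lag,
                     acc=foot_acc,
                     gyro=np.column_stack([gyro_sag,
                                           2.0 * rng.standard_normal(n),
                                           2.0 * rng.standard_normal(n)]),
                     fs=cfg.imu_fs)

    # --- chest stream ---------------------------------------------------
    v_t = np.zeros(n)
    v_t[race_mask] = speed_profile(cfg, subject, t[race_mask] - race_start)
    ap_cycle = np.interp(t, truth["time"], truth["a_AP"],
                         left=0.0, right=float(truth["a_AP"].iloc[-1]))
    ml_cycle = np.interp(t, truth["time"], truth["a_ML"],
                         left=0.0, right=float(truth["a_ML"].iloc[-1]))
    step = 2.0 * np.pi * (cfg.cadence * 2.0 / 60.0)   # step (not stride) rate
    acc = np.zeros((n, 3))
    acc[race_mask, 0] = (ap_cycle[race_mask] * v_t[race_mask]
                         * (1.0 + 0.05 * np.sin(step * t[race_mask])))
    acc[race_mask, 2] = (ml_cycle[race_mask] * v_t[race_mask]
                         * (1.0 + 0.05 * np.cos(step * t[race_mask])))
    acc[:, 0] += 0.02 * rng.standard_normal(n)
    acc[:, 2] += 0.02 * rng.standard_normal(n)
    acc[:, 1] = 0.5 * rng.standard_normal(n)
    acc[race_mask, 1] += 12.0 * np.abs(np.sin(step / 2.0 * t[race_mask]))
    acc[:, 1] += _shock_pulse(t, cfg.shock_time)
    chest = ImuStream(time=t, acc=acc,
                      gyro=np.column_stack([2.0 * rng.standard_normal(n)] * 3),
                      fs=cfg.imu_fs)
    return truth, foot, chest


# ---------------------------------------------------------------------------
# GNSS track
# ---------------------------------------------------------------------------

def generate_gnss_track(cfg: SimConfig, subject: int) -> GnssTrack:
    """10 Hz track along a straight northbound path with configured grades.

    Elevation integrates the configured slope sections' grades along the
    cumulative distance; the speed channel carries the running-speed
    profile.  Track time is recording time (race period only).
    """
    duration = cfg.race_duration(subject)
    t_race = np.arange(0.0, duration, 1.0 / cfg.gnss_fs)
    v = speed_profile(cfg, subject, t_race)
    if np.all(v <= 0):
        raise ValueError("degenerate track: zero speed profile")
    s = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1])
                                         * np.diff(t_race))])
    grade = np.zeros_like(s)
    for start_m, length_m, pct in cfg.slope_sections:
        grade[(s >= start_m) & (s < start_m + length_m)] = pct / 100.0
    ele = np.concatenate([[0.0], np.cumsum(0.5 * (grade[1:] + grade[:-1])
                                           * np.diff(s))])
    lat = 46.0 + s / _M_PER_DEG
    lon = np.full_like(s, 7.0)
    return GnssTrack(time=cfg.pre_duration + t_race, lat=lat, lon=lon,
                     ele=ele, speed=v, fs=cfg.gnss_fs)


def slope_intervals_true(cfg: SimConfig, subject: int) -> list[tuple[float, float]]:
    """Recording-time intervals covered by the configured slope sections."""
    track = generate_gnss_track(cfg, subject)
    v = track.speed
    t = track.time
    s = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(t))])
    out = []
    for start_m, length_m, _ in cfg.slope_sections:
        if start_m >= s[-1]:
            continue
        t0 = float(np.interp(start_m, s, t))
        t1 = float(np.interp(min(start_m + length_m, s[-1]), s, t))
        out.append((t0, t1))
    return out


# ---------------------------------------------------------------------------
# ROF schedule
# ---------------------------------------------------------------------------

def generate_rof_schedule(cfg: SimConfig, subject: int,
                          interval_s: float | None = None) -> pd.DataFrame:
    """Timestamped ROF log: one prompt per 10-min mark during the race.

    The trajectory is non-decreasing from the subject's start value (2-5)
    to the end value (8-10); explicit per-subject start/end values can be
    configured.  Warns when the race is too short to guarantee one prompt
    per 12.5% segment.
    """
    duration = cfg.race_duration(subject)
    rng = cfg.rng(subject, stream=3)
    if interval_s is None:
        interval_s = cfg.rof_interval_s
    if duration / 8.0 < interval_s:
        warnings.warn("race shorter than 8 prompt intervals; some segments "
                      "may lack a ROF value")
    n = int(np.floor(duration / interval_s))
    times = cfg.pre_duration + interval_s * np.arange(1, n + 1)
    start = (int(cfg.rof_start[subject]) if cfg.rof_start is not None
             else int(rng.integers(2, 6)))
    end = (int(cfg.rof_end[subject]) if cfg.rof_end is not None
           else int(rng.integers(8, 11)))
    if not (1 <= start <= 10 and 1 <= end <= 10):
        raise ValueError("ROF values must lie in 1..10")
    # non-decreasing integer path: sorted cumulative unit steps
    steps = np.sort(rng.choice(n, size=max(end - start, 0), replace=True))
    traj = start + np.searchsorted(steps, np.arange(n), side="right")
    traj = np.clip(traj, 1, 10)
    return pd.DataFrame({"time_s": times, "rof": traj.astype(int)})


# ---------------------------------------------------------------------------
# RR artifact injection
# ---------------------------------------------------------------------------

def inject_rr_artifacts(rr: RrSeries, rate: float,
                        rng: np.random.Generator | int = 0
                        ) -> tuple[RrSeries, np.ndarray]:
    """Perturb a fraction of RR intervals (halved or doubled values).

    Halving emulates a spurious extra detection, doubling a missed beat —
    the artifact etiology of electrode movement and poor skin contact.
    Beat times are rebuilt from the perturbed intervals.  Returns the new
    series and the perturbed interval indices.
    """
    if not 0.0 <= rate < 0.5:
        raise ValueError("rate must be in [0, 0.5)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = len(rr.rr)
    k = int(round(rate * n))
    if k == 0:
        return RrSeries(beat_time=rr.beat_time.copy(), rr=rr.rr.copy(),
                        artifact=rr.artifact.copy()), np.array([], dtype=int)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    new_rr = rr.rr.copy()
    halve = rng.random(k) < 0.5
    new_rr[idx[halve]] *= 0.5
    new_rr[idx[~halve]] *= 2.0
    bt = rr.beat_time[0] + np.concatenate([[0.0], np.cumsum(new_rr)])
    return RrSeries(beat_time=bt, rr=new_rr), idx


# ---------------------------------------------------------------------------
# Whole-subject bundle
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecording:
    subject: int
    group: str
    race_time_min: float
    rr_clean: RrSeries            # race-relative beat times
    rr_observed: RrSeries         # with injected artifacts
    gait_truth: pd.DataFrame
    foot: ImuStream
    chest: ImuStream
    track: GnssTrack
    rof_log: pd.DataFrame
    annotations: dict
    truth: GroundTruth
    ecg: EcgStream | None = None


def generate_subject(cfg: SimConfig, subject: int,
                     with_ecg: bool = False) -> SubjectRecording:
    """One subject's complete multi-sensor recording plus ground truth."""
    duration = cfg.race_duration(subject)
    race = (cfg.pre_duration, cfg.pre_duration + duration)
    rr, truth = generate_rr_series(cfg, subject)
    rr_obs, art_idx = inject_rr_artifacts(
        rr, cfg.artifact_rate, cfg.rng(subject, stream=4))
    gait_truth, foot, chest = generate_gait_recording(cfg, subject)
    track = generate_gnss_track(cfg, subject)
    rof_log = generate_rof_schedule(cfg, subject)
    truth.injected_artifact_indices = art_idx
    truth.gait_truth = gait_truth
    truth.slope_intervals = slope_intervals_true(cfg, subject)
    truth.race_interval = race
    annotations = {
        "pre_static": (0.0, cfg.shock_time),
        "pre_rest": (cfg.shock_time, race[0]),
        "race": race,
        "post_rest": (race[1], race[1] + cfg.post_duration),
    }
    ecg = None
    if with_ecg:
        ecg = synthesize_ecg(rr, fs=cfg.ecg_fs, snr_db=cfg.ecg_snr_db,
                             rng=cfg.rng(subject, stream=5))
    return SubjectRecording(
        subject=subject, group=cfg.group_label(subject),
        race_time_min=float(cfg.race_times_min[subject]),
        rr_clean=rr, rr_observed=rr_obs, gait_truth=gait_truth,
        foot=foot, chest=chest, track=track, rof_log=rof_log,
        annotations=annotations, truth=truth, ecg=ecg)


def write_recording(rec: SubjectRecording, out_dir) -> None:
    """Serialize one subject's recording as tidy CSV / GPX / JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"beat_time_s": rec.rr_observed.beat_time}).to_csv(
        out / "rr.csv", index=False)
    if rec.ecg is not None:
        pd.DataFrame({"time_s": rec.ecg.time, "mv": rec.ecg.mv}).to_csv(
            out / "ecg.csv", index=False)
    write_imu_csv(rec.foot, out / "foot_imu.csv")
    write_imu_csv(rec.chest, out / "chest_imu.csv")
    write_gnss_csv(rec.track, out / "gnss.csv")
    write_gpx(rec.track, out / "track.gpx")
    rec.rof_log.to_csv(out / "rof.csv", index=False)
    rec.truth.to_json(out / "ground_truth.json")
    (out / "annotations.json").write_text(json.dumps(
        {k: list(v) for k, v in rec.annotations.items()}))
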