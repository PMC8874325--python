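"""Heart-rate dynamics from single-lead ECG or RR-interval series.

The chain mirrors field practice for exercise HRV: the raw 250 Hz ECG is cut
into 120 s rolling windows with a 110 s overlap (one feature row every 10 s),
linearly resampled to 1,000 Hz, QRS complexes are detected with an
energy-ratio non-linear filter, RR outliers are flagged against the median of
their 60 neighbouring intervals (3 SD rule) and repaired by cubic-spline
interpolation, and windows with an artifact rate of 5% or more are discarded.
Per valid window the module computes time-domain (BPM, SDNN, RMSSD),
frequency-domain (LF 0.04-0.15 Hz, HF 0.15-1.5 Hz extended to cover
respiratory frequency while running, normalized fractions and LF/HF ratio),
and non-linear metrics (Poincaré SD1/SD2, detrended fluctuation analysis
exponents α1 over box widths 4<n<16 and α2 over 16<n<64 beats), plus the
cardiac cost (BPM per unit running speed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import signal as sps
from scipy.interpolate import CubicSpline, interp1d

__all__ = [
    "RrSeries",
    "EcgStream",
    "HrWindowFeatures",
    "SpectralBands",
    "window_stream",
    "resample_linear",
    "detect_qrs",
    "correct_rr",
    "validate_window",
    "time_domain",
    "frequency_domain",
    "poincare",
    "dfa",
    "cardiac_cost",
    "compute_hr_features",
    "MIN_RR_INTERVALS",
]

# window grid (seconds)
WINDOW_LENGTH_S = 120.0
WINDOW_OVERLAP_S = 110.0
# RR artifact correction
RR_OUTLIER_K = 3.0
RR_NEIGHBORS = 60
ARTIFACT_VALID_FRACTION = 0.05     # strict "<"
# QRS energy filter (unstated upstream; exposed here)
QRS_SHORT_ENERGY_S = 0.10
QRS_LONG_ENERGY_S = 1.00
QRS_EPS = 1e-10
QRS_MAD_FACTOR = 4.0
QRS_REFRACTORY_S = 0.25
# spectral analysis
TACHOGRAM_FS = 4.0                 # Hz, uniform resampling of the RR tachogram
WELCH_SEGMENT_S = 60.0
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 1.5)              # upper edge extended for running respiration
MIN_RR_INTERVALS = 2


@dataclass
class RrSeries:
    """Beat times with derived RR intervals and per-beat artifact flags.

    ``rr[i]`` is the interval ending at ``beat_time[i+1]``; the flag array
    has one entry per interval.
    """

    beat_time: np.ndarray          # seconds, strictly increasing
    rr: np.ndarray                 # seconds, rr[i] = beat_time[i+1] - beat_time[i]
    artifact: np.ndarray = field(default=None)  # bool per interval

    def __post_init__(self) -> None:
        self.beat_time = np.asarray(self.beat_time, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.artifact is None:
            self.artifact = np.zeros(self.rr.shape, dtype=bool)
        else:
            self.artifact = np.asarray(self.artifact, dtype=bool)
        if np.any(self.rr <= 0):
            raise ValueError("RR intervals must be positive")

    @classmethod
    def from_beat_times(cls, beat_time: np.ndarray) -> "RrSeries":
        bt = np.asarray(beat_time, dtype=float)
        return cls(beat_time=bt, rr=np.diff(bt))

    @classmethod
    def from_rr(cls, rr: np.ndarray, t0: float = 0.0) -> "RrSeries":
        rr = np.asarray(rr, dtype=float)
        bt = t0 + np.concatenate([[0.0], np.cumsum(rr)])
        return cls(beat_time=bt, rr=rr)

    def __len__(self) -> int:
        return len(self.rr)

    def slice_time(self, t0: float, t1: float) -> "RrSeries":
        """Intervals whose *ending* beat falls in ``[t0, t1)``."""
        end = self.beat_time[1:]
        keep = (end >= t0) & (end < t1)
        idx = np.nonzero(keep)[0]
        if idx.size == 0:
            return RrSeries(beat_time=np.array([t0]), rr=np.array([]),
                            artifact=np.array([], dtype=bool))
        bt = np.concatenate([[self.beat_time[idx[0]]], end[idx]])
        return RrSeries(beat_time=bt, rr=self.rr[idx], artifact=self.artifact[idx])


@dataclass
class EcgStream:
    """Uniformly sampled single-lead ECG voltage trace."""

    time: np.ndarray               # seconds
    mv: np.ndarray                 # millivolt
    fs: float                      # Hz

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.mv = np.asarray(self.mv, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")


@dataclass
class SpectralBands:
    lf: tuple[float, float] = LF_BAND
    hf: tuple[float, float] = HF_BAND


_FEATURE_COLUMNS = [
    "window_center", "BPM", "SDNN", "RMSSD", "LF", "HF", "pLF", "pHF",
    "LF_HF", "SD1", "SD2", "SD1_SD2", "DFA_a1", "DFA_a2", "CC",
    "valid", "artifact_rate",
]


@dataclass
class HrWindowFeatures:
    """One row of heart-rate dynamics per 120 s window (every 10 s)."""

    window_center: float
    BPM: float = np.nan
    SDNN: float = np.nan          # ms
    RMSSD: float = np.nan         # ms
    LF: float = np.nan            # ms²
    HF: float = np.nan            # ms²
    pLF: float = np.nan
    pHF: float = np.nan
    LF_HF: float = np.nan
    SD1: float = np.nan           # ms
    SD2: float = np.nan           # ms
    SD1_SD2: float = np.nan
    DFA_a1: float = np.nan
    DFA_a2: float = np.nan
    CC: float = np.nan            # beats/min per m/s
    valid: bool = False
    artifact_rate: float = np.nan


# ---------------------------------------------------------------------------
# Windowing and resampling
# ---------------------------------------------------------------------------

def window_stream(duration: float, length: float = WINDOW_LENGTH_S,
                  overlap: float = WINDOW_OVERLAP_S,
                  t0: float = 0.0) -> list[tuple[float, float]]:
    """Half-open rolling windows ``[start, start+length)`` stepping by
    ``length - overlap`` seconds from ``t0``; a trailing partial window is
    dropped."""
    if overlap >= length:
        raise ValueError("overlap must be smaller than the window length")
    step = length - overlap
    if duration < length:
        warnings.warn("signal shorter than one window; no windows produced")
        return []
    n = int(np.floor((duration - length) / step)) + 1
    return [(t0 + i * step, t0 + i * step + length) for i in range(n)]


def resample_linear(ecg: EcgStream, fs_out: float = 1000.0) -> EcgStream:
    """Piecewise-linear resampling onto a uniform grid at ``fs_out``."""
    if fs_out < ecg.fs:
        raise ValueError("fs_out must not be below the input rate")
    t_new = np.arange(ecg.time[0], ecg.time[-1] + 0.5 / fs_out, 1.0 / fs_out)
    return EcgStream(time=t_new, mv=np.interp(t_new, ecg.time, ecg.mv), fs=fs_out)


# ---------------------------------------------------------------------------
# QRS detection: short/long energy-ratio coefficient filter
# ---------------------------------------------------------------------------

def _moving_energy(x: np.ndarray, n: int) -> np.ndarray:
    # nearest-edge padding keeps the energy estimate unbiased at the
    # stream boundaries (zero padding would inflate the short/long ratio)
    return ndimage.uniform_filter1d(x * x, n, mode="nearest")


def detect_qrs(ecg: EcgStream,
               short_s: float = QRS_SHORT_ENERGY_S,
               long_s: float = QRS_LONG_ENERGY_S,
               mad_factor: float = QRS_MAD_FACTOR,
               refractory_s: float = QRS_REFRACTORY_S) -> np.ndarray:
    """R-peak times via an energy-ratio coefficient vector.

    A coefficient vector ``c = E_short / (E_long + ε)`` built from short-
    (0.10 s) and long-term (1.0 s) moving-average energies multiplies the
    rectified signal, heightening QRS peaks and suppressing slow
    perturbations.  Peaks of ``c·|x|`` above an adaptive threshold
    (median + ``mad_factor``·MAD) separated by the refractory period are
    returned as beat times.
    """
    x = ecg.mv - np.median(ecg.mv)
    if x.size == 0:
        return np.array([])
    e_short = _moving_energy(x, max(1, int(round(short_s * ecg.fs))))
    e_long = _moving_energy(x, max(1, int(round(long_s * ecg.fs))))
    c = e_short / (e_long + QRS_EPS)
    det = c * np.abs(x)
    med = np.median(det)
    mad = np.median(np.abs(det - med))
    thr = med + mad_factor * mad
    if mad == 0 and det.max() <= thr:
        return np.array([])
    peaks, _ = sps.find_peaks(det, height=thr,
                              distance=max(1, int(round(refractory_s * ecg.fs))))
    return ecg.time[peaks]


# ---------------------------------------------------------------------------
# RR artifact correction
# ---------------------------------------------------------------------------

def _flag_rr_outliers(x: np.ndarray, k: float, half: int) -> np.ndarray:
    n = len(x)
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        nb = np.concatenate([x[lo:i], x[i + 1:hi]])
        if nb.size < 2:
            continue
        med = np.median(nb)
        sd = nb.std(ddof=1)
        if sd == 0:
            if x[i] != med:
                flagged[i] = True
            continue
        if np.abs(x[i] - med) > k * sd:
            flagged[i] = True
    return flagged


def _replace_flagged(x: np.ndarray, flagged: np.ndarray) -> np.ndarray:
    good = np.nonzero(~flagged)[0]
    fixed = x.copy()
    idx = np.arange(len(x))
    interior = (idx >= good[0]) & (idx <= good[-1])
    spline = CubicSpline(good, x[good])
    tofix = flagged & interior
    fixed[tofix] = spline(idx[tofix])
    # edges: nearest retained value
    edge = flagged & ~interior
    fixed[edge] = np.interp(idx[edge], good, x[good])
    return fixed


def correct_rr(rr: RrSeries, k: float = RR_OUTLIER_K,
               neighbors: int = RR_NEIGHBORS,
               passes: int = 2) -> tuple[RrSeries, float]:
    """Flag and repair ectopic / missed-beat RR intervals.

    Interval *i* is flagged when it deviates from the median of its (up to)
    ``neighbors`` surrounding intervals — half on each side, excluding the
    interval itself, truncated at the series edges — by more than ``k``
    standard deviations of that neighbourhood.  Flagged intervals are
    replaced by a cubic spline fitted over beat index to the retained
    intervals (nearest-value extrapolation at the edges).  Detection and
    repair iterate (default two passes) so that clustered artifacts, which
    inflate their own neighbourhood's spread, are still caught; the
    artifact rate counts every interval flagged in any pass.
    """
    x = rr.rr
    n = len(x)
    if n == 0:
        return rr, 0.0
    half = neighbors // 2
    flagged = np.zeros(n, dtype=bool)
    fixed = x.copy()
    for _ in range(max(1, passes)):
        new = _flag_rr_outliers(fixed, k, half) & ~flagged
        if not new.any():
            break
        flagged |= new
        if (~flagged).sum() < 2:
            return (RrSeries(beat_time=rr.beat_time.copy(), rr=x.copy(),
                             artifact=np.ones(n, dtype=bool)), 1.0)
        fixed = _replace_flagged(x, flagged)
    rate = float(flagged.mean())
    bt = rr.beat_time[0] + np.concatenate([[0.0], np.cumsum(fixed)])
    return RrSeries(beat_time=bt, rr=fixed, artifact=flagged), rate


def validate_window(artifact_rate: float,
                    threshold: float = ARTIFACT_VALID_FRACTION) -> bool:
    """A window is valid iff its artifact rate is strictly below 5%."""
    if not 0.0 <= artifact_rate <= 1.0:
        raise ValueError("artifact rate must be a fraction in [0, 1]")
    return artifact_rate < threshold


# ---------------------------------------------------------------------------
# Time-domain metrics
# ---------------------------------------------------------------------------

def time_domain(rr: np.ndarray) -> tuple[float, float, float]:
    """BPM, SDNN (ms) and RMSSD (ms) of an RR-interval window (seconds)."""
    rr = np.asarray(rr, dtype=float)
    if len(rr) < MIN_RR_INTERVALS:
        raise ValueError("need at least two RR intervals")
    bpm = 60.0 / rr.mean()
    sdnn = rr.std(ddof=1) * 1000.0
    rmssd = float(np.sqrt(np.mean(np.diff(rr) ** 2))) * 1000.0
    return float(bpm), float(sdnn), float(rmssd)


# ---------------------------------------------------------------------------
# Frequency-domain metrics
# ---------------------------------------------------------------------------

def frequency_domain(rr_s: np.ndarray, beat_time: np.ndarray,
                     bands: SpectralBands | None = None,
                     fs: float = TACHOGRAM_FS,
                     normalize: str = "band",
                     ) -> tuple[float, float, float, float, float]:
    """LF/HF spectral powers of the RR tachogram.

    The tachogram (RR in ms against the ending beat time) is cubic-spline
    interpolated onto a uniform grid at ``fs``, linearly detrended, and its
    PSD estimated by Welch's method (60 s Hann segments, 50% overlap).  Band
    powers integrate the PSD over the LF (0.04-0.15 Hz) and HF (0.15-1.5 Hz)
    bands; fractions normalize by the in-band total (``pLF + pHF = 1``) or,
    with ``normalize='total'``, by the full PSD variance.
    Returns ``(LF, HF, pLF, pHF, LF_HF)`` with powers in ms².
    """
    bands = bands or SpectralBands()
    rr_ms = np.asarray(rr_s, dtype=float) * 1000.0
    t = np.asarray(beat_time, dtype=float)[1:]    # interval end times
    if len(rr_ms) < 4:
        return (np.nan,) * 5
    t_uni = np.arange(t[0], t[-1], 1.0 / fs)
    if t_uni.size < 8:
        return (np.nan,) * 5
    tach = interp1d(t, rr_ms, kind="cubic", fill_value="extrapolate")(t_uni)
    tach = sps.detrend(tach, type="linear")
    nper = min(len(tach), int(WELCH_SEGMENT_S * fs))
    f, psd = sps.welch(tach, fs=fs, window="hann", nperseg=nper,
                       noverlap=nper // 2)
    def band_power(lo: float, hi: float) -> float:
        m = (f >= lo) & (f < hi)
        if m.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[m], f[m]))
    lf = band_power(*bands.lf)
    hf = band_power(*bands.hf)
    denom = lf + hf if normalize == "band" else float(np.trapezoid(psd, f))
    plf = lf / denom if denom > 0 else np.nan
    phf = hf / denom if denom > 0 else np.nan
    lf_hf = lf / hf if hf > 0 else np.nan
    return lf, hf, plf, phf, lf_hf


# ---------------------------------------------------------------------------
# Non-linear metrics: Poincaré ellipse and DFA
# ---------------------------------------------------------------------------

def poincare(rr_s: np.ndarray) -> tuple[float, float, float]:
    """SD1 (transverse) and SD2 (longitudinal) Poincaré axes in ms.

    SD1 is the dispersion of successive-interval differences projected on
    the transverse axis, ``SD1 = RMS(Δrr)/√2`` — algebraically identical to
    ``RMSSD/√2``; SD2 is the standard deviation of the sums projected on
    the line of identity, ``SD2 = SD(rr[i]+rr[i+1])/√2``.
    """
    rr = np.asarray(rr_s, dtype=float) * 1000.0
    if len(rr) < 3:
        raise ValueError("need at least three RR intervals")
    d = np.diff(rr)
    s = rr[1:] + rr[:-1]
    sd1 = float(np.sqrt(np.mean(d ** 2) / 2.0))
    sd2 = float(np.std(s) / np.sqrt(2.0))
    ratio = sd1 / sd2 if sd2 > 0 else np.nan
    return sd1, sd2, ratio


def _dfa_scales(lo: int, hi: int, num: int = 10) -> np.ndarray:
    """Log-spaced integer box sizes strictly inside the open interval."""
    scales = np.unique(np.round(np.geomspace(lo + 1, hi - 1, num)).astype(int))
    return scales[(scales > lo) & (scales < hi)]


def dfa(rr: np.ndarray, scale_range: tuple[int, int],
        finite_size_correction: bool = True) -> float:
    """Detrended fluctuation analysis scaling exponent.

    The mean-centered series is integrated into a profile; for each box
    size ``n`` strictly inside the open ``scale_range`` the profile is split
    into non-overlapping boxes (forward and reversed segmentations are both
    used), each box is detrended with an order-1 fit, and the fluctuation
    ``F(n)`` is the RMS residual.  The exponent is the least-squares slope
    of ``log F`` against ``log n``.  Returns NaN when fewer than three
    scales are usable or the series is (near-)constant.

    At the short-term scales (boxes of 5-15 beats) plain order-1 DFA is
    biased upward because the box trend absorbs part of the fluctuation:
    for uncorrelated data ``E[F²(n)] = σ²(n²−4)/(15n)`` rather than
    ``∝ n``.  The modified estimator divides F²(n) by the exact
    uncorrelated-data expectation shape, ``(n²−4)/n²`` — the short-scale
    correction of Kantelhardt's modified DFA — which restores α = 0.5 for
    white noise and vanishes as n grows.
    """
    x = np.asarray(rr, dtype=float)
    if len(x) < 2 * scale_range[1]:
        return np.nan
    if np.std(x) == 0:
        return np.nan
    profile = np.cumsum(x - x.mean())
    scales = _dfa_scales(*scale_range)
    scales = scales[scales <= len(profile) // 2]
    if len(scales) < 3:
        return np.nan
    flucts = np.empty(len(scales))
    for k, n in enumerate(scales):
        n_boxes = len(profile) // n
        segs = []
        for prof in (profile[: n_boxes * n], profile[-n_boxes * n:]):
            shaped = prof.reshape(n_boxes, n)
            i = np.arange(n)
            # order-1 detrend per box, vectorized over boxes
            coeffs = np.polynomial.polynomial.polyfit(i, shaped.T, 1)
            trend = coeffs[0][:, None] + coeffs[1][:, None] * i
            segs.append(np.mean((shaped - trend) ** 2, axis=1))
        f2 = np.mean(np.concatenate(segs))
        if finite_size_correction:
            f2 *= n * n / (n * n - 4.0)
        flucts[k] = np.sqrt(f2)
    if np.any(flucts <= 0):
        return np.nan
    slope = np.polyfit(np.log(scales), np.log(flucts), 1)[0]
    return float(slope)


DFA_A1_RANGE = (4, 16)
DFA_A2_RANGE = (16, 64)


def cardiac_cost(bpm: float, speed: float) -> float:
    """Heart rate divided by running speed (beats·min⁻¹ per m·s⁻¹)."""
    if not np.isfinite(speed) or speed <= 0:
        return np.nan
    return bpm / speed


# ---------------------------------------------------------------------------
# Per-window driver
# ---------------------------------------------------------------------------

def compute_hr_features(rr: RrSeries,
                        speed_time: np.ndarray | None = None,
                        speed: np.ndarray | None = None,
                        length: float = WINDOW_LENGTH_S,
                        overlap: float = WINDOW_OVERLAP_S,
                        precorrected: bool = False) -> pd.DataFrame:
    """Heart-rate dynamics table, one row per rolling window (10 s stride).

    The RR series is corrected once over the full race (3 SD around the
    60-neighbour median, spline repair); windows inherit the artifact rate
    of the beats they contain and invalid windows (rate ≥ 5%) propagate as
    missing metric values, never zeros.
    """
    duration = rr.beat_time[-1] - rr.beat_time[0]
    wins = window_stream(duration, length, overlap, t0=rr.beat_time[0])
    if precorrected:
        corrected, flags = rr, rr.artifact
    else:
        corrected, _ = correct_rr(rr)
        flags = corrected.artifact
    rows = []
    for (a, b) in wins:
        center = 0.5 * (a + b)
        end = corrected.beat_time[1:]
        m = (end >= a) & (end < b)
        rr_win = corrected.rr[m]
        feat = HrWindowFeatures(window_center=center)
        if len(rr_win) >= MIN_RR_INTERVALS:
            rate = float(flags[m].mean()) if m.any() else 0.0
            feat.artifact_rate = rate
            feat.valid = validate_window(rate)
            if feat.valid:
                feat.BPM, feat.SDNN, feat.RMSSD = time_domain(rr_win)
                lf, hf, plf, phf, lfhf = frequency_domain(
                    rr_win, np.concatenate([[end[m][0] - rr_win[0]], end[m]]))
                feat.LF, feat.HF, feat.pLF, feat.pHF, feat.LF_HF = lf, hf, plf, phf, lfhf
                if len(rr_win) >= 3:
                    feat.SD1, feat.SD2, feat.SD1_SD2 = poincare(rr_win)
                feat.DFA_a1 = dfa(rr_win, DFA_A1_RANGE)
                feat.DFA_a2 = dfa(rr_win, DFA_A2_RANGE)
                if speed is not None and speed_time is not None:
                    sm = (speed_time >= a) & (speed_time < b)
                    if sm.any():
                        feat.CC = cardiac_cost(feat.BPM, float(np.mean(speed[sm])))
        rows.append(feat.__dict__)
    return pd.DataFrame(rows, columns=_FEATURE_COLUMNS)
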