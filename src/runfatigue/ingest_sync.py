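"""Sensor ingestion, clock synchronization, and course-based exclusion.

Reads the tidy CSV / GPX files produced by the recording (or by
:mod:`runfatigue.synthetic_data`), aligns the chest and foot sensor clocks
via the pre-race shock event, computes along-track distance and grade from
the GNSS stream, and builds exclusion masks for sloped race sections and
signal transients.

All times are seconds from recording start; all intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

EARTH_RADIUS_M = 6_371_000.0

__all__ = [
    "ImuStream",
    "GnssTrack",
    "ExclusionMask",
    "AmbiguousSyncError",
    "estimate_lag",
    "haversine_m",
    "cumulative_distance_m",
    "detect_slopes",
    "exclude_intervals",
    "remove_outliers_2sd",
    "segment_activities",
    "read_imu_csv",
    "write_imu_csv",
    "read_gnss_csv",
    "write_gnss_csv",
    "read_gpx",
    "write_gpx",
]


class AmbiguousSyncError(RuntimeError):
    """Raised when the cross-correlation peak is too weak to trust."""


@dataclass
class ImuStream:
    """Uniformly sampled 6-axis inertial stream.

    Acceleration axes follow the anatomical AP / SI / ML convention
    (anterior-posterior, superior-inferior, medio-lateral), in m/s²;
    gyroscope channels are in deg/s.
    """

    time: np.ndarray          # seconds, uniform
    acc: np.ndarray           # (n, 3): AP, SI, ML  [m/s²]
    gyro: np.ndarray          # (n, 3): sagittal, frontal, transverse [deg/s]
    fs: float                 # Hz

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.acc = np.atleast_2d(np.asarray(self.acc, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.time.size > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def acc_si(self) -> np.ndarray:
        return self.acc[:, 1]


@dataclass
class GnssTrack:
    """Timestamped GNSS fixes with elevation and speed (nominal 10 Hz)."""

    time: np.ndarray          # seconds
    lat: np.ndarray           # degrees
    lon: np.ndarray           # degrees
    ele: np.ndarray           # meters
    speed: np.ndarray         # m/s
    fs: float = 10.0

    def __post_init__(self) -> None:
        for name in ("time", "lat", "lon", "ele", "speed"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.abs(self.lat) > 90) or np.any(np.abs(self.lon) > 180):
            raise ValueError("coordinates out of range")
        if self.time.size > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class ExclusionMask:
    """Disjoint, sorted half-open time intervals to drop from analysis."""

    intervals: list[tuple[float, float]] = field(default_factory=list)
    reason: str = "slope"

    def __post_init__(self) -> None:
        self.intervals = sorted((float(a), float(b)) for a, b in self.intervals)
        for (a0, b0), (a1, _) in zip(self.intervals, self.intervals[1:]):
            if a1 < b0:
                raise ValueError("mask intervals must be disjoint")

    def contains(self, t: np.ndarray) -> np.ndarray:
        """Boolean mask: which times fall inside any interval."""
        t = np.asarray(t, dtype=float)
        inside = np.zeros(t.shape, dtype=bool)
        for a, b in self.intervals:
            inside |= (t >= a) & (t < b)
        return inside

    @property
    def total_duration(self) -> float:
        return float(sum(b - a for a, b in self.intervals))


# ---------------------------------------------------------------------------
# Clock synchronization via the shock event
# ---------------------------------------------------------------------------

def estimate_lag(acc_a: ImuStream, acc_b: ImuStream,
                 search_window: float = 30.0,
                 min_peak_corr: float = 0.5) -> float:
    """Lag of stream *b* relative to stream *a* from the shared shock event.

    Both vertical (SI) acceleration channels are linearly resampled to the
    higher of the two sampling rates, then the lag is taken as the argmax of
    the normalized cross-correlation within ``±search_window`` seconds.
    Adding the returned lag to stream *b*'s clock aligns the shock peaks.

    Raises
    ------
    AmbiguousSyncError
        If the normalized correlation peak is below ``min_peak_corr``.
    """
    fs = max(acc_a.fs, acc_b.fs)
    t0 = min(acc_a.time[0], acc_b.time[0])
    t1 = max(acc_a.time[-1], acc_b.time[-1])
    t = np.arange(t0, t1, 1.0 / fs)
    xa = np.interp(t, acc_a.time, acc_a.acc_si, left=0.0, right=0.0)
    xb = np.interp(t, acc_b.time, acc_b.acc_si, left=0.0, right=0.0)
    xa = xa - xa.mean()
    xb = xb - xb.mean()
    corr = sps.correlate(xa, xb, mode="full")
    lags = sps.correlation_lags(xa.size, xb.size, mode="full")
    max_lag = int(round(search_window * fs))
    keep = np.abs(lags) <= max_lag
    corr, lags = corr[keep], lags[keep]
    denom = np.sqrt(np.sum(xa ** 2) * np.sum(xb ** 2))
    if denom == 0:
        raise AmbiguousSyncError("flat signal, no shock event found")
    ncorr = corr / denom
    i = int(np.argmax(ncorr))
    if ncorr[i] < min_peak_corr:
        raise AmbiguousSyncError(
            f"correlation peak {ncorr[i]:.2f} below {min_peak_corr}")
    return float(lags[i] / fs)


# ---------------------------------------------------------------------------
# Geometry: Haversine distance and slope detection
# ---------------------------------------------------------------------------

def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in meters on a sphere of radius 6,371 km."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a)))


def cumulative_distance_m(track: GnssTrack) -> np.ndarray:
    """Cumulative along-track Haversine distance at each fix."""
    p = np.radians(np.column_stack([track.lat, track.lon]))
    dphi = np.diff(p[:, 0])
    dlam = np.diff(p[:, 1])
    a = (np.sin(dphi / 2) ** 2
         + np.cos(p[:-1, 0]) * np.cos(p[1:, 0]) * np.sin(dlam / 2) ** 2)
    step = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))
    return np.concatenate([[0.0], np.cumsum(step)])


def detect_slopes(track: GnssTrack, grade_threshold: float = 5.0,
                  window_m: float = 100.0) -> ExclusionMask:
    """Flag race sections whose grade exceeds the threshold over the window.

    A sliding window of ``window_m`` meters of along-track distance advances
    one GNSS fix at a time; a fix is flagged when the absolute elevation
    change across the window it starts, divided by the distance, is
    *strictly greater* than ``grade_threshold`` percent.  Maximal runs of
    flagged fixes become half-open exclusion intervals in track time.
    """
    dist = cumulative_distance_m(track)
    if dist[-1] < window_m:
        warnings.warn("track shorter than the grade window; no slopes detected")
        return ExclusionMask([], reason="slope")
    n = len(dist)
    # index of the first fix at least window_m ahead of each fix
    j_idx = np.searchsorted(dist, dist + window_m, side="left")
    flagged = np.zeros(n, dtype=bool)
    valid = j_idx < n
    i_arr = np.nonzero(valid)[0]
    j_arr = j_idx[valid]
    run = dist[j_arr] - dist[i_arr]
    ok = run > 0
    grade = np.zeros(i_arr.size)
    grade[ok] = np.abs(track.ele[j_arr[ok]] - track.ele[i_arr[ok]]) / run[ok] * 100.0
    # strict inequality: an exactly-threshold grade is not flagged (small
    # relative epsilon so float roundoff cannot promote it)
    hit = grade > grade_threshold * (1.0 + 1e-9)
    for i, j in zip(i_arr[hit], j_arr[hit]):
        flagged[i:j + 1] = True
    intervals: list[tuple[float, float]] = []
    in_run = False
    for k in range(n):
        if flagged[k] and not in_run:
            start = track.time[k]
            in_run = True
        elif not flagged[k] and in_run:
            intervals.append((start, track.time[k]))
            in_run = False
    if in_run:
        intervals.append((start, track.time[-1] + 1.0 / track.fs))
    return ExclusionMask(intervals, reason="slope")


def exclude_intervals(table: pd.DataFrame, mask: ExclusionMask,
                      time_col: str = "time_s") -> pd.DataFrame:
    """Drop rows whose time falls inside any mask interval (order kept)."""
    if not mask.intervals:
        return table
    inside = mask.contains(table[time_col].to_numpy())
    return table.loc[~inside].reset_index(drop=True)


def remove_outliers_2sd(values: np.ndarray,
                        windows: Sequence[tuple[int, int]] | None = None,
                        k: float = 2.0) -> np.ndarray:
    """Replace per-window >k·SD outliers by linear interpolation.

    ``windows`` are half-open index intervals (by default one window spanning
    the whole series).  Within each window, samples farther than ``k``
    standard deviations from the window mean are replaced by linear
    interpolation between the nearest retained neighbours; flagged endpoints
    take the nearest retained value.  A constant window (SD = 0) is returned
    unchanged.
    """
    x = np.asarray(values, dtype=float).copy()
    if windows is None:
        windows = [(0, len(x))]
    bad = np.zeros(len(x), dtype=bool)
    for a, b in windows:
        seg = x[a:b]
        if len(seg) < 3:
            continue
        mu, sd = seg.mean(), seg.std(ddof=1)
        if sd == 0:
            continue
        bad[a:b] = np.abs(seg - mu) > k * sd
    if not bad.any():
        return x
    good = ~bad
    if not good.any():
        return x
    idx = np.arange(len(x))
    x[bad] = np.interp(idx[bad], idx[good], x[good])
    return x


def segment_activities(annotations: dict[str, tuple[float, float]] | None = None,
                       acc_norm: np.ndarray | None = None,
                       time: np.ndarray | None = None,
                       var_threshold: float = 4.0,
                       win_s: float = 5.0,
                       fs: float | None = None) -> dict[str, tuple[float, float]]:
    """Label recording intervals (pre/post static, rest, walk, and race).

    With explicit ``annotations`` (the normal path) they are validated and
    passed through.  The heuristic fallback thresholds the moving variance
    of the acceleration norm to find the single sustained high-activity
    interval and labels it ``race``.

    Raises
    ------
    ValueError
        If no ``race`` interval can be determined.
    """
    if annotations is not None:
        if "race" not in annotations:
            raise ValueError("annotations lack the mandatory 'race' interval")
        return dict(annotations)
    if acc_norm is None or time is None:
        raise ValueError("need annotations or an acceleration stream")
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(time)))
    w = max(3, int(round(win_s * fs)))
    x = pd.Series(np.asarray(acc_norm, dtype=float))
    mv = x.rolling(w, center=True, min_periods=1).var().to_numpy()
    active = mv > var_threshold
    if not active.any():
        raise ValueError("no sustained activity found; cannot locate race")
    # the race is the longest contiguous active run (short bursts such as
    # the synchronization shock also exceed the variance threshold)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], active.view(np.int8),
                                                   [0]])))
    starts, ends = edges[::2], edges[1::2]
    k = int(np.argmax(ends - starts))
    i0, i1 = starts[k], ends[k] - 1
    out: dict[str, tuple[float, float]] = {"race": (float(time[i0]), float(time[i1]))}
    if i0 > 0:
        out["pre_rest"] = (float(time[0]), float(time[i0]))
    if i1 < len(time) - 1:
        out["post_rest"] = (float(time[i1]), float(time[-1]))
    return out


# ---------------------------------------------------------------------------
# File I/O: tidy CSV and GPX 1.1
# ---------------------------------------------------------------------------

def write_imu_csv(stream: ImuStream, path) -> None:
    df = pd.DataFrame({
        "time_s": stream.time,
        "acc_ap": stream.acc[:, 0], "acc_si": stream.acc[:, 1],
        "acc_ml": stream.acc[:, 2],
        "gyro_sag": stream.gyro[:, 0], "gyro_fro": stream.gyro[:, 1],
        "gyro_tra": stream.gyro[:, 2],
    })
    df.to_csv(path, index=False)


def read_imu_csv(path, fs: float | None = None) -> ImuStream:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    return ImuStream(
        time=t,
        acc=df[["acc_ap", "acc_si", "acc_ml"]].to_numpy(),
        gyro=df[["gyro_sag", "gyro_fro", "gyro_tra"]].to_numpy(),
        fs=fs,
    )


def write_gnss_csv(track: GnssTrack, path) -> None:
    pd.DataFrame({
        "time_s": track.time, "lat": track.lat, "lon": track.lon,
        "ele_m": track.ele, "speed_mps": track.speed,
    }).to_csv(path, index=False)


def read_gnss_csv(path) -> GnssTrack:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 10.0
    return GnssTrack(time=t, lat=df["lat"].to_numpy(), lon=df["lon"].to_numpy(),
                     ele=df["ele_m"].to_numpy(), speed=df["speed_mps"].to_numpy(),
                     fs=fs)


_GPX_NS = "http://www.topografix.com/GPX/1/1"


def write_gpx(track: GnssTrack, path) -> None:
    """Serialize a track as GPX 1.1 (trkpt with ele; time in seconds attr)."""
    ET.register_namespace("", _GPX_NS)
    gpx = ET.Element(f"{{{_GPX_NS}}}gpx", version="1.1", creator="runfatigue")
    seg = ET.SubElement(ET.SubElement(gpx, f"{{{_GPX_NS}}}trk"),
                        f"{{{_GPX_NS}}}trkseg")
    for t, la, lo, el in zip(track.time, track.lat, track.lon, track.ele):
        pt = ET.SubElement(seg, f"{{{_GPX_NS}}}trkpt",
                           lat=f"{la:.7f}", lon=f"{lo:.7f}")
        ET.SubElement(pt, f"{{{_GPX_NS}}}ele").text = f"{el:.2f}"
        ET.SubElement(pt, f"{{{_GPX_NS}}}time").text = f"{t:.3f}"
    ET.ElementTree(gpx).write(path, xml_declaration=True, encoding="unicode")


def read_gpx(path) -> GnssTrack:
    root = ET.parse(path).getroot()
    time, lat, lon, ele = [], [], [], []
    for pt in root.iter(f"{{{_GPX_NS}}}trkpt"):
        lat.append(float(pt.get("lat")))
        lon.append(float(pt.get("lon")))
        e = pt.find(f"{{{_GPX_NS}}}ele")
        ele.append(float(e.text) if e is not None else 0.0)
        tnode = pt.find(f"{{{_GPX_NS}}}time")
        time.append(float(tnode.text) if tnode is not None else len(time) * 0.1)
    t = np.asarray(time)
    speed = np.zeros_like(t)
    track = GnssTrack(time=t, lat=np.asarray(lat), lon=np.asarray(lon),
                      ele=np.asarray(ele), speed=speed)
    d = cumulative_distance_m(track)
    if len(t) > 1:
        track.speed = np.gradient(d, t)
    return track
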