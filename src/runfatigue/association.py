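"""Linear and non-linear gait–heart-rate association per race segment.

For each subject and each of the 8 race segments, a selected biomechanical
series (contact time, foot-strike angle, vertical stiffness, speed, trunk AP
acceleration ratio) is aligned with a physiological series (BPM, SDNN,
DFA-α1, SD2 — the last added for its strong long-range trends): outliers in
non-overlapping 10-sample windows are median-replaced, the per-cycle
biomechanics are averaged over the same 120 s / 10 s rolling grid the heart
metrics live on, and the Pearson correlation (with its p-value) and the
classical distance correlation quantify linear and non-linear dependence.
With 13 subjects this yields 104 segment instances for each of the
5 × 4 = 20 parameter pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as st

from .hr_dynamics import WINDOW_LENGTH_S, WINDOW_OVERLAP_S

__all__ = [
    "BIOMECH_SELECTION",
    "PHYSIO_SELECTION",
    "AlignedPair",
    "despike_median_windows",
    "rolling_mean_windows",
    "align_series",
    "pearson_p",
    "distance_correlation",
    "compute_associations",
    "summarize",
]

BIOMECH_SELECTION = ["t_c", "FSA", "k_vert", "v", "a_AP"]
PHYSIO_SELECTION = ["BPM", "SDNN", "DFA_a1", "SD2"]
MIN_POINTS = 5


@dataclass
class AlignedPair:
    subject: int
    segment: int
    biomech: str
    physio: str
    x: np.ndarray
    y: np.ndarray


def despike_median_windows(values: np.ndarray, window: int = 10,
                           k: float = 2.0, blanket: bool = False) -> np.ndarray:
    """Outlier replacement in non-overlapping windows of ``window`` samples.

    Within each window, samples deviating from the window median by more
    than ``k`` window standard deviations are replaced by that median.
    ``blanket=True`` replaces the whole window by its median instead.
    """
    x = np.asarray(values, dtype=float).copy()
    for a in range(0, len(x), window):
        seg = x[a:a + window]
        if len(seg) < 3:
            continue
        med = np.median(seg)
        if blanket:
            x[a:a + window] = med
            continue
        sd = seg.std(ddof=1)
        if sd == 0:
            continue
        bad = np.abs(seg - med) > k * sd
        seg[bad] = med
        x[a:a + window] = seg
    return x


def rolling_mean_windows(time: np.ndarray, values: np.ndarray,
                         interval: tuple[float, float],
                         length: float = WINDOW_LENGTH_S,
                         overlap: float = WINDOW_OVERLAP_S,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Mean of a series over 120 s windows stepping 10 s inside an interval.

    Matches the rolling grid of the heart-rate features so both series end
    up synchronized, equally sampled, and equally long.  Returns window
    centers and means (NaN where the window holds no samples).
    """
    a, b = interval
    step = length - overlap
    t = np.asarray(time, dtype=float)
    x = np.asarray(values, dtype=float)
    centers, means = [], []
    start = a
    while start + length <= b + 1e-9:
        m = (t >= start) & (t < start + length)
        centers.append(start + length / 2.0)
        means.append(float(np.nanmean(x[m])) if m.any() else np.nan)
        start += step
    return np.asarray(centers), np.asarray(means)


def align_series(biomech_time: np.ndarray, biomech_values: np.ndarray,
                 physio_time: np.ndarray, physio_values: np.ndarray,
                 segment: tuple[float, float],
                 despike_window: int = 10) -> tuple[np.ndarray, np.ndarray] | None:
    """Synchronize one biomech / physio series pair over one race segment.

    Both inputs are despiked (10-sample non-overlapping median windows);
    the biomechanical series is then averaged on the 120 s / 10 s rolling
    grid and matched to the physiological windows whose centers fall in the
    segment.  Returns ``(x, y)`` or None when fewer than 5 common points
    survive.
    """
    bx = despike_median_windows(biomech_values, despike_window)
    py = despike_median_windows(physio_values, despike_window)
    centers, x = rolling_mean_windows(biomech_time, bx, segment)
    if len(centers) < MIN_POINTS:
        return None
    # match physio windows to the biomech grid by window center (both live
    # on the common 10 s stride)
    pt = np.asarray(physio_time, dtype=float)
    idx = np.searchsorted(pt, centers)
    idx = np.clip(idx, 0, len(pt) - 1)
    left = np.clip(idx - 1, 0, len(pt) - 1)
    idx = np.where(np.abs(pt[left] - centers) < np.abs(pt[idx] - centers),
                   left, idx)
    match = np.abs(pt[idx] - centers) < 5.0 + 1e-9
    x, y = x[match], py[idx[match]]
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < MIN_POINTS:
        return None
    return x[ok], y[ok]


def pearson_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with two-sided t-distribution p-value (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    r, p = st.pearsonr(x, y)
    return float(r), float(p)


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Classical (V-statistic) sample distance correlation in [0, 1].

    Pairwise Euclidean distance matrices of x and y are double-centered;
    the squared distance covariance is the mean of their elementwise
    product and the correlation normalizes by the distance variances.
    Returns 0 when either distance variance vanishes (constant input).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if n != y.size:
        raise ValueError("series must have equal length")
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    A = a - a.mean(axis=0)[None, :] - a.mean(axis=1)[:, None] + a.mean()
    B = b - b.mean(axis=0)[None, :] - b.mean(axis=1)[:, None] + b.mean()
    dcov2 = (A * B).mean()
    dvarx = (A * A).mean()
    dvary = (B * B).mean()
    if dvarx <= 0 or dvary <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvarx * dvary)))


def compute_associations(biomech_streams: dict[str, tuple[np.ndarray, np.ndarray]],
                         physio_streams: dict[str, tuple[np.ndarray, np.ndarray]],
                         segments: list[tuple[float, float]],
                         subject: int = 0,
                         biomech_names: list[str] | None = None,
                         physio_names: list[str] | None = None) -> pd.DataFrame:
    """Per subject-segment-pair Pearson r, p and distance correlation.

    Every subject × segment × pair combination is attempted; pairs with too
    few common points are recorded with NaN results so the attempt count
    stays visible downstream.
    """
    biomech_names = biomech_names or BIOMECH_SELECTION
    physio_names = physio_names or PHYSIO_SELECTION
    rows = []
    for bname, pname in product(biomech_names, physio_names):
        bt, bv = biomech_streams[bname]
        pt, pv = physio_streams[pname]
        for s, seg in enumerate(segments, start=1):
            pair = align_series(bt, bv, pt, pv, seg)
            if pair is None:
                r = p = dc = np.nan
                npts = 0
            else:
                x, y = pair
                r, p = pearson_p(x, y)
                dc = distance_correlation(x, y)
                npts = len(x)
            rows.append(dict(subject=subject, segment=s,
                             pair=f"{bname}|{pname}", biomech=bname,
                             physio=pname, r=r, p=p, dcor=dc, n_points=npts))
    return pd.DataFrame(rows)


def summarize(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-pair association summary across all subject-segment instances.

    Counts the instances with a significant linear correlation (raw
    p < 0.05), the median (IQR) of r over those significant instances only,
    and the median (IQR) of the distance correlation over *all* instances.
    """
    rows = []
    for pair, grp in records.groupby("pair"):
        sig = grp[grp["p"] < alpha]
        r_sig = sig["r"].dropna()
        dc = grp["dcor"].dropna()
        def miqr(v):
            if len(v) == 0:
                return np.nan, np.nan
            q1, q3 = np.percentile(v, [25, 75])
            return float(np.median(v)), float(q3 - q1)
        r_med, r_iqr = miqr(r_sig)
        d_med, d_iqr = miqr(dc)
        rows.append(dict(pair=pair, n_attempted=len(grp),
                         n_significant=int(len(sig)),
                         r_median=r_med, r_iqr=r_iqr,
                         dcor_median=d_med, dcor_iqr=d_iqr))
    return pd.DataFrame(rows)
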