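"""Race segmentation, per-segment aggregation, normalization, and ROF states.

The race is split into 8 equal segments (12.5% each, time-based by default);
every parameter stream is summarised per segment by its median and IQR; the
medians are normalized against a reference segment — the fastest segment for
biomechanical parameters, the first ("non-fatigued") segment for
physiological parameters.  Each segment receives the subject's rating of
fatigue (ROF, 1-10, prompted every 10 min), the baseline-subtracted ΔROF,
the pooled ΔROF state (0, [1,2], [3,4], ≥5), and the subject's low / medium
/ high ROF level labels.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "N_SEGMENTS",
    "split_race",
    "segment_of",
    "aggregate",
    "normalize",
    "assign_rof",
    "delta_rof_state",
    "build_segment_matrix",
    "BIOMECH_PARAMS",
    "PHYSIO_PARAMS",
]

N_SEGMENTS = 8

BIOMECH_PARAMS = ["t_c", "t_f", "t_s", "t_g", "cadence", "D_f", "FSA",
                  "FEA", "omega_s", "k_vert", "v", "a_AP", "a_ML"]
PHYSIO_PARAMS = ["BPM", "SDNN", "RMSSD", "LF", "HF", "pLF", "pHF", "LF_HF",
                 "SD1", "SD2", "SD1_SD2", "DFA_a1", "DFA_a2", "CC"]

DELTA_ROF_STATES = ["0", "[1,2]", "[3,4]", ">=5"]


def split_race(race: tuple[float, float], n: int = N_SEGMENTS,
               ) -> list[tuple[float, float]]:
    """Partition the race interval into ``n`` contiguous half-open segments
    of equal extent."""
    if n < 2:
        raise ValueError("need at least two segments")
    a, b = race
    if b <= a:
        raise ValueError("empty race interval")
    edges = np.linspace(a, b, n + 1)
    return [(float(edges[i]), float(edges[i + 1])) for i in range(n)]


def split_race_by_distance(track_time: np.ndarray, track_dist: np.ndarray,
                           n: int = N_SEGMENTS) -> list[tuple[float, float]]:
    """Distance-based variant: segment edges at equal along-track distance,
    mapped back to track time."""
    edges_d = np.linspace(track_dist[0], track_dist[-1], n + 1)
    edges_t = np.interp(edges_d, track_dist, track_time)
    return [(float(edges_t[i]), float(edges_t[i + 1])) for i in range(n)]


def segment_of(t: np.ndarray, segments: list[tuple[float, float]]) -> np.ndarray:
    """Segment number (1-based) per time, 0 where outside the race."""
    t = np.asarray(t, dtype=float)
    out = np.zeros(t.shape, dtype=int)
    for i, (a, b) in enumerate(segments, start=1):
        out[(t >= a) & (t < b)] = i
    # closed right edge for the final segment
    out[t == segments[-1][1]] = len(segments)
    return out


def aggregate(time: np.ndarray, values: np.ndarray,
              segments: list[tuple[float, float]]) -> pd.DataFrame:
    """Per-segment median and IQR (Q3−Q1, linear-interpolation quantiles)."""
    t = np.asarray(time, dtype=float)
    x = np.asarray(values, dtype=float)
    seg = segment_of(t, segments)
    rows = []
    for s in range(1, len(segments) + 1):
        xs = x[(seg == s) & np.isfinite(x)]
        if xs.size == 0:
            rows.append({"segment": s, "median": np.nan, "iqr": np.nan,
                         "n_samples": 0})
        else:
            q1, q3 = np.percentile(xs, [25, 75])
            rows.append({"segment": s, "median": float(np.median(xs)),
                         "iqr": float(q3 - q1), "n_samples": int(xs.size)})
    return pd.DataFrame(rows)


def normalize(matrix: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Divide per-segment medians by a reference segment's median.

    ``mode='biomech'``: the reference is the segment with the highest median
    running speed (requires a ``v`` parameter in the matrix);
    ``mode='physio'``: the reference is segment 1, the non-fatigued state.
    Expects a long table with columns ``parameter, segment, median`` (one
    subject).  Adds ``normalized_median`` and ``reference_segment``.
    """
    out = matrix.copy()
    if mode == "biomech":
        vrows = out[out["parameter"] == "v"]
        if vrows.empty or vrows["median"].isna().all():
            raise ValueError("biomech normalization needs the speed parameter")
        ref_seg = int(vrows.loc[vrows["median"].idxmax(), "segment"])
    elif mode == "physio":
        ref_seg = 1
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    norm = np.full(len(out), np.nan)
    for param, grp in out.groupby("parameter"):
        ref = grp.loc[grp["segment"] == ref_seg, "median"]
        refval = float(ref.iloc[0]) if len(ref) else np.nan
        if not np.isfinite(refval) or refval == 0:
            continue
        norm[grp.index] = grp["median"].to_numpy() / refval
    out["normalized_median"] = norm
    out["reference_segment"] = ref_seg
    return out


def delta_rof_state(delta: float) -> str:
    """Pool ΔROF into the onset states 0, [1,2], [3,4], ≥5."""
    if not np.isfinite(delta):
        return "missing"
    d = int(round(delta))
    if d <= 0:
        return "0"
    if d <= 2:
        return "[1,2]"
    if d <= 4:
        return "[3,4]"
    return ">=5"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def assign_rof(rof_time: np.ndarray, rof: np.ndarray,
               segments: list[tuple[float, float]]) -> pd.DataFrame:
    """Per-segment ROF, ΔROF, ΔROF state and L/M/H level for one subject.

    The segment ROF is the median of the prompts falling inside it, rounded
    half-up to an integer; ΔROF subtracts the first-segment baseline.  The
    L / M / H levels mark the segments attaining the subject's lowest,
    medium and highest recorded ROF, where the medium value is the recorded
    value closest to the median of the distinct recorded values (ties break
    to the lower value).
    """
    t = np.asarray(rof_time, dtype=float)
    r = np.asarray(rof, dtype=float)
    seg = segment_of(t, segments)
    rows = []
    for s in range(1, len(segments) + 1):
        vals = r[seg == s]
        if vals.size == 0:
            warnings.warn(f"no ROF prompt in segment {s}")
            rows.append({"segment": s, "rof": np.nan})
        else:
            rows.append({"segment": s, "rof": _round_half_up(float(np.median(vals)))})
    df = pd.DataFrame(rows)
    baseline = df["rof"].iloc[0]
    df["delta_rof"] = df["rof"] - baseline
    df["delta_state"] = [delta_rof_state(d) for d in df["delta_rof"]]
    recorded = sorted(set(df["rof"].dropna().astype(int)))
    level = np.full(len(df), "", dtype=object)
    if recorded:
        lo, hi = recorded[0], recorded[-1]
        med = float(np.median(recorded))
        mid = min(recorded, key=lambda v: (abs(v - med), v))
        for i, rv in enumerate(df["rof"]):
            if not np.isfinite(rv):
                continue
            labs = []
            if rv == lo:
                labs.append("L")
            if rv == mid:
                labs.append("M")
            if rv == hi:
                labs.append("H")
            level[i] = "".join(labs)
    df["level"] = level
    return df


def build_segment_matrix(param_streams: dict[str, tuple[np.ndarray, np.ndarray]],
                         segments: list[tuple[float, float]],
                         rof_time: np.ndarray, rof: np.ndarray,
                         subject: int = 0) -> pd.DataFrame:
    """Long-format per-subject segment feature matrix.

    ``param_streams`` maps parameter name to ``(time, values)``.
    Biomechanical and physiological parameters are normalized against their
    respective reference segments and the ROF assignment is joined on.
    """
    pieces = []
    for name, (t, x) in param_streams.items():
        agg = aggregate(t, x, segments)
        agg.insert(0, "parameter", name)
        pieces.append(agg)
    long = pd.concat(pieces, ignore_index=True)
    bio = long[long["parameter"].isin(BIOMECH_PARAMS)].reset_index(drop=True)
    phys = long[~long["parameter"].isin(BIOMECH_PARAMS)].reset_index(drop=True)
    parts = []
    if not bio.empty:
        parts.append(normalize(bio, "biomech"))
    if not phys.empty:
        parts.append(normalize(phys, "physio"))
    out = pd.concat(parts, ignore_index=True)
    rofdf = assign_rof(rof_time, rof, segments)
    out = out.merge(rofdf, on="segment", how="left")
    out.insert(0, "subject", subject)
    return out
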