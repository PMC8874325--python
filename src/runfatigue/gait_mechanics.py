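"""Per-gait-cycle running biomechanics.

Cycles are delimited at mid-swing, the dominant positive peak of the
sagittal foot angular velocity; only right-foot cycles are analysed and the
first and last 10 steps of the race are trimmed to avoid transients.  Per
cycle the module derives temporal parameters (contact, flight, swing and
cycle time, cadence), the duty factor, the spring-mass vertical stiffness
(sine-wave ground-reaction-force model), and trunk acceleration ratios
normalized by running speed.  Foot-strike angle, eversion angle and peak
swing velocity arrive as per-cycle inputs from upstream event-level
estimators and pass through unchanged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps

from .ingest_sync import ImuStream

__all__ = [
    "GRAVITY",
    "DEFAULT_BODY_MASS_KG",
    "segment_cycles_midswing",
    "trim_steps",
    "duty_factor",
    "vertical_stiffness",
    "trunk_ratios",
    "temporal_params",
    "build_gait_table",
    "GAIT_PARAMETERS",
]

GRAVITY = 9.81                     # m/s²
DEFAULT_BODY_MASS_KG = 70.0
TRIM_STEPS_N = 10
MIDSWING_MIN_SEPARATION_S = 0.4

#: canonical per-cycle parameter columns consumed downstream
GAIT_PARAMETERS = ["t_c", "t_f", "t_s", "t_g", "cadence", "D_f",
                   "FSA", "FEA", "omega_s", "k_vert", "v", "a_AP", "a_ML"]


def segment_cycles_midswing(foot_gyro: ImuStream,
                            min_prominence: float | None = None,
                            min_separation_s: float = MIDSWING_MIN_SEPARATION_S,
                            ) -> np.ndarray:
    """Mid-swing times from the sagittal foot angular-velocity channel.

    One gait cycle spans two consecutive mid-swings.  Returns the peak
    times; fewer than two peaks means no complete cycle.
    """
    w = foot_gyro.gyro[:, 0]
    if min_prominence is None:
        spread = np.percentile(w, 98) - np.median(w)
        min_prominence = max(0.3 * spread, 1e-9)
    dist = max(1, int(round(min_separation_s * foot_gyro.fs)))
    peaks, _ = sps.find_peaks(w, prominence=min_prominence, distance=dist)
    # keep only clearly positive swings
    peaks = peaks[w[peaks] > 0]
    return foot_gyro.time[peaks]


def trim_steps(cycles: pd.DataFrame, n: int = TRIM_STEPS_N) -> pd.DataFrame:
    """Drop the first and last ``n`` cycles (race-start/finish transients)."""
    if len(cycles) <= 2 * n:
        warnings.warn("too few cycles to trim; returning empty table")
        return cycles.iloc[0:0]
    return cycles.iloc[n:len(cycles) - n].reset_index(drop=True)


def duty_factor(t_c: float, t_g: float) -> float:
    """Contact time over stride (cycle) time; flags out-of-range cycles."""
    if t_g <= 0:
        raise ValueError("cycle time must be positive")
    if t_c > t_g:
        return np.nan
    return t_c / t_g


def vertical_stiffness(t_c: float, t_f: float,
                       mass: float = DEFAULT_BODY_MASS_KG) -> float:
    """Spring-mass vertical stiffness from contact and flight time, kN/m.

    Sine-wave vertical ground-reaction-force model: the peak force is
    ``F_max = m·g·(π/2)·(t_f/t_c + 1)`` and the centre-of-mass vertical
    displacement during contact ``Δz = F_max·t_c²/(m·π²) − g·t_c²/8``;
    stiffness is ``F_max/Δz``.  Returns NaN when the displacement is not
    positive (non-physical cycle).
    """
    if t_c <= 0 or t_f < 0 or mass <= 0:
        raise ValueError("need t_c > 0, t_f >= 0, mass > 0")
    f_max = mass * GRAVITY * (np.pi / 2.0) * (t_f / t_c + 1.0)
    dz = f_max * t_c ** 2 / (mass * np.pi ** 2) - GRAVITY * t_c ** 2 / 8.0
    if dz <= 0:
        return np.nan
    return f_max / dz / 1000.0


def trunk_ratios(chest_acc: ImuStream, speed_time: np.ndarray,
                 speed: np.ndarray, window: tuple[float, float],
                 rectified: bool = True) -> tuple[float, float]:
    """Speed-normalized trunk acceleration over a cycle-aligned window.

    ``a_AP = mean|acc_AP| / mean(v)`` and likewise for the medio-lateral
    channel; normalization by speed isolates the fatigue response from
    pacing changes.  Returns ``(nan, nan)`` when the window has no speed
    samples or non-positive mean speed.
    """
    a, b = window
    m = (chest_acc.time >= a) & (chest_acc.time < b)
    sm = (speed_time >= a) & (speed_time < b)
    if not m.any() or not sm.any():
        return np.nan, np.nan
    v = float(np.mean(speed[sm]))
    if v <= 0:
        return np.nan, np.nan
    ap = chest_acc.acc[m, 0]
    ml = chest_acc.acc[m, 2]
    if rectified:
        ap, ml = np.abs(ap), np.abs(ml)
    return float(np.mean(ap)) / v, float(np.mean(ml)) / v


def temporal_params(ic: float, to: float, next_ic: float,
                    ms: float, next_ms: float) -> dict[str, float]:
    """Temporal parameters of one cycle from its gait events.

    ``ic``/``to`` are initial contact and toe-off of the cycle's stance,
    ``next_ic`` the following initial contact; the cycle time spans
    mid-swing to mid-swing (the segmentation basis) and swing time is the
    remainder ``t_g − t_c``.
    """
    t_c = to - ic
    t_f = next_ic - to
    t_g = next_ms - ms
    if t_c <= 0 or t_g <= 0 or t_f < 0:
        return {k: np.nan for k in ("t_c", "t_f", "t_s", "t_g", "cadence")}
    return {"t_c": t_c, "t_f": t_f, "t_s": t_g - t_c, "t_g": t_g,
            "cadence": 60.0 / t_g}


def build_gait_table(midswing_times: np.ndarray,
                     events: pd.DataFrame | None = None,
                     cycle_params: pd.DataFrame | None = None,
                     chest_acc: ImuStream | None = None,
                     speed_time: np.ndarray | None = None,
                     speed: np.ndarray | None = None,
                     mass: float = DEFAULT_BODY_MASS_KG,
                     trim: int = TRIM_STEPS_N) -> pd.DataFrame:
    """Assemble the per-cycle biomechanics table.

    Parameters
    ----------
    midswing_times
        Cycle boundaries (right foot), from :func:`segment_cycles_midswing`.
    events
        Optional per-cycle gait events with columns ``ic``, ``to``,
        ``next_ic`` (seconds).  Without events the temporal parameters
        cannot be formed and the corresponding columns are NaN.
    cycle_params
        Optional per-cycle kinematic inputs (``FSA``, ``FEA``, ``omega_s``
        and, when events are absent, ``t_c``/``t_f``) passed through from
        upstream estimators or the generator.
    """
    n_cycles = len(midswing_times) - 1
    if n_cycles < 1:
        return pd.DataFrame(columns=["cycle_index", "time"] + GAIT_PARAMETERS)
    rows = []
    for i in range(n_cycles):
        ms, next_ms = midswing_times[i], midswing_times[i + 1]
        row: dict[str, float] = {"cycle_index": i, "time": ms,
                                 "t_g": next_ms - ms}
        if events is not None and i < len(events):
            ev = events.iloc[i]
            row.update(temporal_params(ev["ic"], ev["to"], ev["next_ic"],
                                       ms, next_ms))
        rows.append(row)
    table = pd.DataFrame(rows)
    if cycle_params is not None:
        cp = cycle_params.iloc[:n_cycles].reset_index(drop=True)
        for col in cp.columns:
            if col in ("cycle_index", "time"):
                continue
            if col in table.columns and table[col].notna().any():
                continue
            table[col] = cp[col].to_numpy()
    if "t_c" in table and "t_g" in table:
        table["D_f"] = [duty_factor(tc, tg) if np.isfinite(tc) and tg > 0
                        else np.nan
                        for tc, tg in zip(table["t_c"], table["t_g"])]
        table["cadence"] = 60.0 / table["t_g"]
        if "t_f" in table:
            table["t_s"] = table["t_g"] - table["t_c"]
            table["k_vert"] = [
                vertical_stiffness(tc, tf, mass)
                if np.isfinite(tc) and np.isfinite(tf) and tc > 0 and tf >= 0
                else np.nan
                for tc, tf in zip(table["t_c"], table["t_f"])]
    if chest_acc is not None and speed is not None and speed_time is not None:
        ap, ml, vv = [], [], []
        for i in range(n_cycles):
            win = (midswing_times[i], midswing_times[i + 1])
            a, m = trunk_ratios(chest_acc, speed_time, speed, win)
            ap.append(a)
            ml.append(m)
            sm = (speed_time >= win[0]) & (speed_time < win[1])
            vv.append(float(np.mean(speed[sm])) if sm.any() else np.nan)
        table["a_AP"], table["a_ML"], table["v"] = ap, ml, vv
    for col in GAIT_PARAMETERS:
        if col not in table.columns:
            table[col] = np.nan
    return trim_steps(table, trim)
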