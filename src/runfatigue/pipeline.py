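"""End-to-end orchestration: recordings → features → statistics.

Runs every stage in method order for each subject — clock synchronization
via the shock event, slope exclusion from the GNSS track, gait-cycle
biomechanics, heart-rate dynamics on the rolling window grid, 8-segment
aggregation/normalization with ROF states — then pools subjects for the
repeated-measures battery, the mixed-effects performance model and the
gait–heart association analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association as assoc
from . import fatigue_stats as fs
from . import gait_mechanics as gm
from . import hr_dynamics as hr
from . import ingest_sync as ing
from . import race_segmentation as rs
from .synthetic_data import SimConfig, SubjectRecording, generate_subject

__all__ = ["SubjectResult", "CohortResult", "run_subject", "run_cohort"]


@dataclass
class SubjectResult:
    subject: int
    group: str
    race_time_min: float
    gait_table: pd.DataFrame
    hr_features: pd.DataFrame
    segment_matrix: pd.DataFrame
    association_records: pd.DataFrame
    estimated_lag: float
    slope_mask: ing.ExclusionMask


@dataclass
class CohortResult:
    subjects: list[SubjectResult]
    segment_matrix: pd.DataFrame
    battery: dict[str, pd.DataFrame]
    lme: dict[str, "fs.LmeResult"]
    association_records: pd.DataFrame
    association_summary: pd.DataFrame


def run_subject(cfg: SimConfig, subject: int,
                rec: SubjectRecording | None = None) -> SubjectResult:
    """Process one subject's recording through every analysis stage."""
    rec = rec or generate_subject(cfg, subject)
    race = rec.annotations["race"]

    # 1. clock sync on the pre-race period containing the shock event
    def _crop(s: ing.ImuStream, t1: float) -> ing.ImuStream:
        m = s.time < t1
        return ing.ImuStream(time=s.time[m], acc=s.acc[m], gyro=s.gyro[m],
                             fs=s.fs)
    lag = ing.estimate_lag(_crop(rec.chest, race[0]),
                           _crop(rec.foot, race[0]))
    foot = ing.ImuStream(time=rec.foot.time + lag, acc=rec.foot.acc,
                         gyro=rec.foot.gyro, fs=rec.foot.fs)

    # 2. slope exclusion from the GNSS track
    mask = ing.detect_slopes(rec.track)

    # 3. gait cycles from mid-swing peaks; per-cycle biomechanics
    in_race = (foot.time >= race[0]) & (foot.time < race[1])
    foot_race = ing.ImuStream(time=foot.time[in_race], acc=foot.acc[in_race],
                              gyro=foot.gyro[in_race], fs=foot.fs)
    ms = gm.segment_cycles_midswing(foot_race)
    events = rec.gait_truth[["ic", "to", "next_ic"]]
    cyc_params = rec.gait_truth[["FSA", "FEA", "omega_s"]]
    gait = gm.build_gait_table(ms, events=events, cycle_params=cyc_params,
                               chest_acc=rec.chest,
                               speed_time=rec.track.time,
                               speed=rec.track.speed,
                               mass=cfg.body_mass_kg)
    gait = ing.exclude_intervals(gait, mask, time_col="time")

    # 4. per-segment 2-SD despiking of the chest-derived channels
    segments = rs.split_race(race)
    seg_windows = []
    for a, b in segments:
        idx = np.nonzero((gait["time"].to_numpy() >= a)
                         & (gait["time"].to_numpy() < b))[0]
        if idx.size:
            seg_windows.append((int(idx[0]), int(idx[-1] + 1)))
    for col in ("v", "a_AP", "a_ML"):
        gait[col] = ing.remove_outliers_2sd(gait[col].to_numpy(), seg_windows)

    # 5. heart-rate dynamics on the rolling window grid (recording time)
    rr = hr.RrSeries(beat_time=rec.rr_observed.beat_time + race[0],
                     rr=rec.rr_observed.rr)
    feats = hr.compute_hr_features(rr, speed_time=rec.track.time,
                                   speed=rec.track.speed)
    if mask.intervals:
        feats = feats.loc[~mask.contains(
            feats["window_center"].to_numpy())].reset_index(drop=True)

    # 6. segment matrix with ROF assignment
    streams: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    gt = gait["time"].to_numpy()
    for p in rs.BIOMECH_PARAMS:
        if p in gait.columns:
            streams[p] = (gt, gait[p].to_numpy())
    ft = feats["window_center"].to_numpy()
    for p in rs.PHYSIO_PARAMS:
        if p in feats.columns:
            streams[p] = (ft, feats[p].to_numpy())
    matrix = rs.build_segment_matrix(
        streams, segments, rec.rof_log["time_s"].to_numpy(),
        rec.rof_log["rof"].to_numpy(), subject=subject)

    # 7. associations between selected gait and heart series
    bstreams = {p: (gt, gait[p].to_numpy()) for p in assoc.BIOMECH_SELECTION}
    pstreams = {p: (ft, feats[p].to_numpy()) for p in assoc.PHYSIO_SELECTION}
    records = assoc.compute_associations(bstreams, pstreams, segments,
                                         subject=subject)
    return SubjectResult(subject=subject, group=rec.group,
                         race_time_min=rec.race_time_min, gait_table=gait,
                         hr_features=feats, segment_matrix=matrix,
                         association_records=records, estimated_lag=lag,
                         slope_mask=mask)


def run_cohort(cfg: SimConfig, subjects: list[int] | None = None,
               designs: tuple[str, ...] = ("segments", "rof_levels",
                                           "delta_rof"),
               lme_responders: tuple[str, ...] = ("BPM", "t_c", "DFA_a1"),
               ) -> CohortResult:
    """Full study: every subject, the test battery, LME and associations."""
    subjects = subjects if subjects is not None else list(range(cfg.n_subjects))
    per_subject = [run_subject(cfg, s) for s in subjects]
    matrix = pd.concat([r.segment_matrix for r in per_subject],
                       ignore_index=True)
    groups = {r.subject: r.group for r in per_subject}
    battery = {d: fs.run_battery(matrix, d) for d in designs}
    lme: dict[str, fs.LmeResult] = {}
    long = matrix[["subject", "segment", "parameter", "normalized_median",
                   "delta_rof"]].copy()
    long["performance"] = long["subject"].map(groups)
    for responder in lme_responders:
        sub = long[long["parameter"] == responder].rename(
            columns={"normalized_median": "value"})
        try:
            lme[responder] = fs.fit_lme(sub, responder="value")
        except fs.InsufficientDataError:
            continue
    records = pd.concat([r.association_records for r in per_subject],
                        ignore_index=True)
    summary = assoc.summarize(records)
    return CohortResult(subjects=per_subject, segment_matrix=matrix,
                        battery=battery, lme=lme,
                        association_records=records,
                        association_summary=summary)
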