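# runfatigue

Concurrent analysis of running-induced acute fatigue from wearable-sensor
recordings: gait biomechanics from foot/chest inertial units, heart-rate
dynamics from single-lead ECG, course context from GNSS, and perceived
fatigue from the 1–10 rating-of-fatigue (ROF) scale — processed together so
that the biomechanical, physiological and psychological responses to a long
run can be compared on one 8-segment race timeline.

The package is aimed at sports-science and biosignal researchers who record
endurance runs in the field (one ECG chest sensor, chest + foot IMUs, a GNSS
receiver, and periodic ROF prompts) and want a tested, reproducible pipeline
from raw streams to the statistics.

## What it computes

**Preprocessing** — chest/foot clock synchronization by cross-correlating the
shared pre-race "shock" movement; Haversine distance along the GNSS track;
exclusion of race sections with a grade strictly above 5% over 100 m;
per-segment 2-SD outlier replacement.

**Gait mechanics** (per right-foot gait cycle, first/last 10 steps trimmed) —
contact, flight, swing and cycle time from mid-swing-segmented foot
gyroscope data; duty factor `D_f = t_c / t_g`; spring-mass vertical
stiffness from the sine-wave GRF model,

```
F_max = m g (π/2) (t_f/t_c + 1),   Δz = F_max t_c² / (m π²) − g t_c² / 8,
k_vert = F_max / Δz
```

and speed-normalized trunk acceleration ratios `a_AP = mean|acc_AP| / v̄`,
`a_ML` likewise. Foot-strike angle, eversion angle and peak swing velocity
enter as per-cycle inputs from upstream event-level estimators.

**Heart-rate dynamics** (120 s rolling windows, 110 s overlap → one row per
10 s) — ECG resampled 250→1,000 Hz; QRS detection via a short/long
energy-ratio coefficient filter; RR outliers flagged against the median of
60 neighbouring intervals (3 SD) and spline-repaired; windows with ≥5%
artifacts dropped. Metrics: BPM, SDNN, RMSSD; Welch band powers LF
(0.04–0.15 Hz) and HF (0.15–1.5 Hz, extended for running respiration) with
`pLF + pHF = 1`; Poincaré SD1/SD2; DFA-α1 (boxes 4<n<16) and α2 (16<n<64)
with a short-scale finite-size correction; cardiac cost `CC = BPM / v`.

**Race segmentation** — 8 equal segments; per-segment median and IQR;
biomechanics normalized by the fastest segment, physiology by segment 1;
ROF, ΔROF (baseline-subtracted) and the pooled onset states
0 / [1,2] / [3,4] / ≥5 attached per segment.

**Statistics** — Friedman tests with Kendall's W (`es_F = χ²/(n(k−1))`) and
pairwise Wilcoxon signed-rank tests with `es_W = |Z|/√N` across race
segments (S1/S5/S8), pooled ROF levels (L/M/H) and ΔROF states; a linear
mixed model `responder ~ ΔROF × performance + (ΔROF | subject)` comparing
fast (<90 min) and slow (>105 min) runners, with Wald 95% CIs and the
Nakagawa conditional R².

**Associations** — per subject-segment Pearson r (with p) and the classical
distance correlation between five gait series (t_c, FSA, k_vert, v, a_AP)
and four heart series (BPM, SDNN, DFA-α1, SD2): 20 pairs × 8 segments ×
subjects, summarised as significant-correlation counts and median (IQR)
effect magnitudes.

A first-class synthetic-data generator (`runfatigue.synthetic_data`) emulates
the full recording set-up — RR series with tunable drift, oscillatory and
fractal structure, stylized ECG, per-cycle gait trends, slope sections, ROF
schedules, a known inter-sensor clock lag, and injected RR artifacts — with
ground truth for every stage, so the entire chain is testable without any
field data.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from runfatigue import SimConfig, run_subject

cfg = SimConfig(
    race_times_min=(24, 25, 26, 27, 28, 29, 30, 31, 32, 33, 34, 35, 36),
    race_distance_m=6_000, rof_interval_s=170, slope_sections=(),
    fast_below_min=29, slow_above_min=31, seed=11,
)
res = run_subject(cfg, subject=0)
print(f"clock lag applied to foot sensor: {res.estimated_lag:+.3f} s")
print(f"gait cycles analysed: {len(res.gait_table)}")
print(f"HR feature windows:   {len(res.hr_features)}")
m = res.segment_matrix
tc = m[m.parameter == "t_c"].set_index("segment")
print("contact time, normalized median per segment:")
print("  " + "  ".join(f"S{s}={v:.3f}" for s, v in tc.normalized_median.items()))
```

prints

```
clock lag applied to foot sensor: -0.500 s
gait cycles analysed: 2016
HR feature windows:   133
contact time, normalized median per segment:
  S1=1.000  S2=1.006  S3=1.013  S4=1.018  S5=1.025  S6=1.033  S7=1.036  S8=1.045
```

The recovered −0.500 s lag is exactly the clock offset the generator imposed
between the foot and chest sensors; the contact-time medians climb ≈4.5%
from the first to the last race segment, matching the +5% fatigue drift
configured for this subject (the segment-1 and segment-8 medians sit at race
fractions ~0.06 and ~0.94, so the end-to-end rise is slightly under the full
drift). A `runfatigue` CLI (`simulate`, `preprocess`, `hr`, `analyze`)
wraps the same calls for shell use.

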