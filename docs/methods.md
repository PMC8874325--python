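# Methods

This note documents the models, estimators and numerical choices behind
`runfatigue`, and what the synthetic-data experiments do and do not show.

## Study design the package assumes

One subject's recording comprises a pre-race period (quiet standing, a
"shock" synchronization movement — all sensors shaken together — then
rest), the race itself, and a short post-race period. Analysis uses the
race only, split into 8 equal time segments (12.5% each). ROF (rating of
fatigue, integer 1–10) is prompted every 10 minutes; with races of 80+
minutes every segment contains at least one prompt. All intervals are
half-open `[start, end)` in seconds from recording start.

Time-based segmentation is the default because ROF prompts are time-based;
a distance-based variant (`split_race_by_distance`) is available and
coincides with it at constant speed.

## Sensor synchronization

The chest and foot sensors run on independent clocks. The lag is the
argmax of the normalized cross-correlation of the vertical (SI)
acceleration channels over the pre-race window containing the shock, after
linear resampling to the higher of the two rates. The lag is reported at
that sample resolution — no sub-sample refinement — and a normalized peak
below 0.5 raises an error rather than silently mis-aligning. The
correlation must be computed on the shock-containing pre-race period:
including the race dilutes the peak with step-bounce energy that is not
synchronous across body sites.

## Course exclusion

Along-track distance accumulates Haversine steps on a sphere of radius
6,371 km. A 100 m sliding window advances one GNSS fix at a time; a fix is
flagged when |Δelevation|/distance over the window is *strictly* greater
than 5% (a small relative epsilon guards the boundary against float
roundoff, so an exactly-5% grade is never flagged). Grade is unsigned:
both climbs and descents are excluded. Maximal flagged runs become
exclusion intervals applied to every time-indexed product (gait cycles,
heart-rate windows).

## Gait mechanics

Cycles are delimited at mid-swing — the dominant positive sagittal
angular-velocity peak of the right foot (minimum separation 0.4 s;
prominence defaults to a percentile-based estimate of the signal spread).
Cycle time t_g is mid-swing to mid-swing; swing time is t_g − t_c. The
first and last 10 steps are trimmed. Temporal parameters need
initial-contact and toe-off events, which the pipeline takes from the
generator's ground truth (or an external event table); estimating them
from raw foot signals is out of scope, as are foot-strike angle, eversion
angle and peak swing velocity, which are consumed as per-cycle inputs and
passed through to all downstream statistics.

Vertical stiffness uses the sine-wave vertical-GRF spring-mass closed form
(peak force from the flight/contact ratio, COM displacement by double
integration), reported in kN/m; Δz ≤ 0 marks the cycle invalid. Body mass
is a per-subject input, 70 kg by default. Trunk ratios use rectified means
(`mean|acc|`) per cycle window; a signed-mean variant is a keyword switch.

## Heart-rate dynamics

- **Windows.** 120 s length, 110 s overlap → a feature row every 10 s;
  trailing partial windows are dropped.
- **QRS.** The detector forms a coefficient vector c = E_short/(E_long+ε)
  from moving-average energies (0.10 s and 1.0 s, nearest-edge padding so
  boundaries are unbiased) and multiplies it with the rectified signal;
  peaks above median + 4·MAD with a 0.25 s refractory period are beats.
  The energy-window lengths, threshold and refractory period are exposed
  as keyword arguments.
- **RR correction.** An interval is an outlier when it deviates from the
  median of its 60 neighbours (30 per side, excluding itself, truncated at
  edges) by more than 3 neighbourhood SDs. Flagged intervals are replaced
  by a cubic spline over beat index through retained beats
  (nearest-neighbour at the edges). Detection and repair run twice:
  clustered artifacts inflate their own neighbourhood's SD and a single
  pass misses ~10% of them at a 2% artifact rate. Windows with an
  artifact rate ≥ 5% (strict `<` for validity) propagate as missing —
  never zero.
- **Spectra.** The tachogram (RR in ms at interval end times) is
  cubic-interpolated to a uniform 4 Hz, linearly detrended, and Welch
  PSD-estimated (60 s Hann segments, 50% overlap). LF integrates
  0.04–0.15 Hz and HF 0.15–1.5 Hz — the HF band's upper edge is extended
  to cover respiratory frequency while running, which makes HF
  exercise-specific and not comparable to resting references. Fractions
  normalize by the in-band total, so pLF + pHF = 1 identically; a
  total-variance normalization is a keyword switch.
- **Poincaré.** SD1 = RMS(ΔRR)/√2 — algebraically identical to RMSSD/√2 —
  and SD2 = SD(RR_i + RR_{i+1})/√2.
- **DFA.** Profile integration of the mean-centered series; log-spaced
  integer boxes strictly inside the open ranges (α1: 5–15, α2: 17–63);
  order-1 detrending per non-overlapping box with forward and reversed
  segmentations averaged; α is the least-squares slope of log F vs log n.
  Plain DFA is biased at the short α1 scales: for uncorrelated data
  E[F²(n)] = σ²(n²−4)/(15n), not ∝ n, which inflates white-noise α1 to
  ≈0.57 over boxes 5–15. The estimator therefore applies the short-scale
  finite-size correction F² × n²/(n²−4) (the modified-DFA idea of
  correcting by the uncorrelated-data expectation), restoring α = 0.50 for
  white noise while shifting pink noise only to ≈0.95; the correction is
  negligible at the α2 scales. `finite_size_correction=False` gives the
  textbook estimator.
- **Cardiac cost.** BPM divided by mean window speed; missing when speed
  is unavailable or non-positive.

## Segment features and ROF states

Per segment: median and IQR (linear-interpolation quantiles).
Normalization divides each segment median by a reference median — the
fastest segment (by median speed) for biomechanics, including speed
itself; segment 1 (the non-fatigued state) for physiology. ΔROF subtracts
the segment-1 ROF; states pool 0 / [1,2] / [3,4] / ≥5 because runners
rarely report unit increments. When several prompts fall in one segment
the median is taken, rounded half-up. L/M/H mark the segments attaining
the subject's lowest / medium / highest recorded ROF, the medium being the
recorded value closest to the median of distinct values (ties to the lower
value).

## Inference

Friedman tests use within-subject mid-ranks with the tie-corrected χ² and
Kendall's W = χ²/(n(k−1)) as effect size; pairwise contrasts use the
two-sided Wilcoxon signed-rank with zero differences dropped, tie-corrected
variance, a 0.5 continuity correction, and es_W = |Z|/√N with N the
non-zero pairs. No multiplicity correction is applied (a small number of
planned contrasts). Duplicate conditions within a subject (equal ROF or
ΔROF on several segments) collapse to the median parameter value before
testing, and normalized medians are the tested quantity.

The mixed model is `responder ~ ΔROF × performance + (ΔROF | subject)`
with ΔROF numeric (not pooled). Estimation is by REML: with ~10 subjects,
plain-ML variance estimates are biased low and their Wald 95% intervals
cover a known slope only ≈92% of the time versus ≈95% under REML
(400-seed simulation); `reml=False` restores plain ML. Significance
requires p ≤ 0.05 *and* the Wald CI excluding zero. A singular random
intercept+slope fit falls back to a random intercept (flagged), and a
degenerate fit with no usable random structure falls back to OLS — the
zero-random-variance limit. Conditional R² follows the Nakagawa variance
partition (σ²_fixed + σ²_random)/(σ²_fixed + σ²_random + σ²_residual),
with the random contribution averaged over the observed design.

## Associations

Per subject-segment, the biomechanical series is despiked in
non-overlapping 10-sample windows (samples beyond 2 window-SDs of the
window median are set to that median — not blanket smoothing; a blanket
variant is a keyword), then averaged over the same 120 s / 10 s rolling
grid the heart features live on; the two series are matched by window
center. Pearson r uses the t-distribution p-value (n−2 df, raw — no
multiplicity correction, counts of p < 0.05 are reported as such); the
distance correlation is the classical biased V-statistic
(double-centered distance matrices), zero when either distance variance
vanishes, with no significance test attached. Summaries per pair: the
count of significant linear correlations, median (IQR) of r over
significant instances only, and median (IQR) of dCor over all instances.

## Synthetic-data generator

The generator is the package's test bed and defines its study conditions:
13 runners (five fast, three mid, five slow by race time), half-marathon
distance by default, ROF prompted every 10 min rising monotonically from a
2–5 start to an 8–10 finish, a 0.5 s inter-sensor clock lag, a 2% RR
artifact rate, and one 8%-grade climb.

- **RR model.** RR(t) = baseline + drift·(t/T) + lf·sin(2π·0.1t) +
  hf·sin(2π·0.3t) + σ·fGn(α), clipped at 0.25 s. The fractal component is
  spectrally synthesized 1/f^β noise with β = 2α − 1, so its DFA exponent
  is controllable (calibration verified at α ∈ {0.5, 0.75, 1.0}). This
  additive structure is the simplest that yields non-trivial LF/HF,
  SDNN/RMSSD and DFA targets simultaneously.
- **ECG.** A stylized biphasic QRS template at each beat time plus white
  noise at a configurable SNR; morphology realism is a non-goal — only
  R-peak timing matters downstream. Half-second lead-in/out prevents edge
  truncation of the first and last complexes.
- **Gait.** Per-cycle parameters follow configured linear drifts over race
  fraction plus white noise; defaults impose the fatigue signature the
  pipeline is designed to detect (t_c +5%, t_f −5%, FSA −10%, ω_s −5%,
  a_AP +10%, speed −4%; stiffness falls emergently through t_c/t_f). The
  foot gyroscope carries one Gaussian pulse per mid-swing; chest AP/ML
  channels have per-cycle means a_AP·v and a_ML·v.
- **Artifacts.** Injected by halving or doubling selected intervals
  (extra/missed detections — the electrode-motion etiology).
- **GNSS.** A straight northbound path on the sphere; elevation integrates
  the configured grades; the speed channel carries the profile. Straight
  geometry is sufficient for Haversine-based grade logic.
- **Determinism.** One master seed; per-subject/per-stream substreams via
  `default_rng([seed, subject, stream])`. Identical configuration and seed
  reproduce byte-identical outputs.

What the generator does **not** emulate: ECG morphology variation and
noise non-stationarity, GNSS multipath, gait asymmetry, forefoot-strike
patterns, respiratory coupling, or any distributional realism of the
cohort beyond the configured summary trends. Passing tests therefore
demonstrate correctness of the algorithms and recoverability of imposed
effects — not field performance on real recordings.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the cohort at reduced race
durations (24–36 min over 6 km, ROF prompts every 170 s, group thresholds
scaled accordingly) — large enough that every segment holds hundreds of
gait cycles and ≥5 heart-rate windows, small enough to run the full
13-subject chain in about two minutes. The type-I-error experiment uses
500 generator seeds; mixed-model CI coverage uses 300 seeds in the test
suite and 120 in the acceptance script; DFA calibration uses 100 seeds of
1,000-beat series. Spot checks (stiffness closed form, Haversine,
Kendall's W at perfect concordance) are exact.

## Known limitations

- Gait-event (IC/TO) detection from raw signals is not implemented; the
  pipeline consumes events from the generator or an external estimator.
- The HF band's printed overlap with LF in some descriptions of this
  protocol is resolved as 0.15–1.5 Hz (the conventional lower edge with
  the exercise-extended upper edge).
- One source document refers to an `a_SG` quantity and once calls a_AP
  "medio-lateral"; the package implements the methods definition (AP
  acceleration over speed) and does not guess at the inconsistency.
- Distance-correlation significance is not computed (magnitudes only).
- Wilcoxon p-values use the normal approximation; exact enumeration
  appears only as a test oracle (agreement within 0.005 at n = 13).
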