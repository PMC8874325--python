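"""Shared fixtures: a scaled synthetic cohort exercising every stage.

The cohort keeps the study design (13 runners, five fast / three mid /
five slow, ROF prompts guaranteed once per segment, the configured fatigue
trends) while shortening races so the full pipeline runs in seconds per
subject; the performance-group thresholds scale with the race times.
"""

import warnings

import pytest

from runfatigue.pipeline import run_cohort, run_subject
from runfatigue.synthetic_data import SimConfig

SCALED_RACE_TIMES = (24.0, 25.0, 26.0, 27.0, 28.0,
                     29.0, 30.0, 31.0,
                     32.0, 33.0, 34.0, 35.0, 36.0)


def scaled_config(**overrides) -> SimConfig:
    base = dict(
        race_times_min=SCALED_RACE_TIMES,
        race_distance_m=6_000.0,
        rof_interval_s=170.0,
        slope_sections=(),
        fast_below_min=29.0,
        slow_above_min=31.0,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def cohort_cfg() -> SimConfig:
    return scaled_config()


@pytest.fixture(scope="session")
def cohort(cohort_cfg):
    """Full end-to-end run of the scaled 13-subject cohort."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_cohort(cohort_cfg)


@pytest.fixture(scope="session")
def subject0(cohort_cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_subject(cohort_cfg, 0)


# ---------------------------------------------------------------------------
# simulation helpers shared by the statistics and acceptance tests
# ---------------------------------------------------------------------------

def null_segment_medians(seed: int, n_subjects: int = 13):
    """Per-subject 8-segment medians of a trend-free gait parameter.

    Uses the generator's per-cycle model with all drifts removed, so the
    segment medians are exchangeable across segments (the null of every
    repeated-measures contrast).
    """
    import numpy as np

    from runfatigue.race_segmentation import aggregate, split_race
    from runfatigue.synthetic_data import gait_cycle_truth

    cfg = scaled_config(trends={}, gait_noise_frac=0.05,
                        race_times_min=(6.0,) * 13, race_distance_m=1500.0,
                        rof_interval_s=44.0, seed=seed)
    rows = []
    for s in range(n_subjects):
        truth = gait_cycle_truth(cfg, s)
        segs = split_race((truth["time"].iloc[0], truth["time"].iloc[-1] + 0.7))
        agg = aggregate(truth["time"].to_numpy(), truth["t_c"].to_numpy(), segs)
        rows.append(agg["median"].to_numpy())
    import numpy as _np
    return _np.asarray(rows)


def simulate_lme_dataset(seed, beta_slope=0.05, beta_group=0.1,
                         beta_inter=0.0, n_subjects=10, sd_icept=0.05,
                         sd_slope=0.01, sd_eps=0.05):
    """Draw one longitudinal dataset from the mixed-model data-generating
    process (random intercept+slope per subject, fast/slow group shift)."""
    import numpy as np
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        perf = "fast" if s < n_subjects // 2 else "slow"
        b0 = rng.normal(0.0, sd_icept)
        b1 = rng.normal(0.0, sd_slope)
        for seg in range(8):
            drof = float(min(seg, 6))
            y = (1.0 + b0 + (beta_slope + b1) * drof
                 + (beta_group + beta_inter * drof) * (perf == "slow")
                 + rng.normal(0.0, sd_eps))
            rows.append(dict(subject=s, delta_rof=drof, value=y,
                             performance=perf))
    return pd.DataFrame(rows)
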