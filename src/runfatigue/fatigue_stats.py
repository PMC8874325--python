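"""Inferential battery for repeated-measures fatigue effects.

Three designs share the same machinery: race progression (segments S1, S5,
S8), pooled perceived-fatigue levels (L, M, H) and baseline-subtracted ΔROF
onset states (0 vs [1,2] / [3,4] / ≥5).  Each parameter gets a Friedman
test with Kendall's W as effect size, ``es_F = χ² / (n·(k−1))``, plus the
printed pairwise Wilcoxon signed-rank contrasts with ``es_W = |Z|/√N``.
No multiplicity correction is applied (a small number of planned
contrasts).  Performance-group effects use a linear mixed-effects model
``responder ~ ΔROF * performance + (ΔROF | subject)`` with Wald 95%
confidence intervals and the Nakagawa conditional R².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st

import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "StatResult",
    "LmeResult",
    "friedman_W",
    "wilcoxon_es",
    "significance_stars",
    "run_battery",
    "fit_lme",
    "FAST_RACE_TIME_MIN",
    "SLOW_RACE_TIME_MIN",
]

FAST_RACE_TIME_MIN = 90.0      # race time below this → "fast" group
SLOW_RACE_TIME_MIN = 105.0     # race time above this → "slow" group

SEGMENT_CONTRASTS = [("S1", "S5"), ("S5", "S8"), ("S1", "S8")]
LEVEL_CONTRASTS = [("L", "M"), ("M", "H"), ("L", "H")]
DELTA_CONTRASTS = [("0", "[1,2]"), ("0", "[3,4]"), ("0", ">=5")]


@dataclass
class StatResult:
    parameter: str
    comparison: str
    test: str                  # "friedman" | "wilcoxon"
    statistic: float           # χ² or Z
    p: float
    effect_size: float
    n: int
    k: int
    stars: str = ""


@dataclass
class LmeResult:
    responder: str
    fixed_effects: pd.DataFrame    # term, estimate, p, ci_low, ci_high, significant
    random_variances: dict
    conditional_r2: float
    converged: bool
    random_slope: bool


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Friedman test with Kendall's W effect size
# ---------------------------------------------------------------------------

def friedman_W(data: np.ndarray) -> tuple[float, float, float]:
    """Friedman χ² (tie-corrected), p, and Kendall's W.

    ``data`` is a complete subjects × conditions matrix.  Within-subject
    mid-ranks feed the tie-corrected Friedman statistic; the p-value comes
    from the χ² distribution with k−1 degrees of freedom, and the effect
    size is Kendall's coefficient of concordance ``W = χ² / (n·(k−1))``.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[1] < 3:
        raise InsufficientDataError("need an n×k matrix with k >= 3")
    n, k = x.shape
    if n < 2:
        raise InsufficientDataError("need at least two subjects")
    ranks = np.apply_along_axis(st.rankdata, 1, x)
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(col_sums ** 2) - 3.0 * n * (k + 1)
    # tie correction: per-row sum of (t³ − t) over tied groups
    tie_sum = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts ** 3 - counts))
    denom = 1.0 - tie_sum / (n * k * (k ** 2 - 1))
    if denom <= 0:
        return 0.0, 1.0, 0.0
    chi2 /= denom
    p = float(st.chi2.sf(chi2, k - 1))
    w = chi2 / (n * (k - 1))
    return float(chi2), p, float(w)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank with |Z|/sqrt(N) effect size
# ---------------------------------------------------------------------------

def wilcoxon_es(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, int]:
    """Two-sided paired Wilcoxon signed-rank: Z, p, effect size, N.

    Zero differences are dropped (Wilcoxon's rule).  The normal
    approximation uses the tie-corrected variance and a 0.5 continuity
    correction toward the mean; the effect size is ``|Z| / √N`` with N the
    number of non-zero-difference pairs.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0, 0.0, 0
    ranks = st.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(counts ** 3 - counts)) / 48.0
    if var <= 0:
        return 0.0, 1.0, 0.0, n
    diff = w_plus - mu
    # continuity correction toward the mean
    cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
    z = (diff - cc) / np.sqrt(var)
    p = float(2.0 * st.norm.sf(abs(z)))
    p = min(p, 1.0)
    es = abs(z) / np.sqrt(n)
    return float(z), p, float(es), n


def significance_stars(p: float) -> str:
    """Printed star convention: * for p∈(0.01,0.05], ** for (0.001,0.01],
    *** for <0.001."""
    if not np.isfinite(p) or p > 0.05:
        return ""
    if p < 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    return "*"


# ---------------------------------------------------------------------------
# Battery over the three repeated-measures designs
# ---------------------------------------------------------------------------

def _condition_values(matrix: pd.DataFrame, design: str
                      ) -> tuple[pd.DataFrame, list[str], list[tuple[str, str]]]:
    """Reshape the long segment matrix into per-subject condition values.

    Returns a long frame (subject, parameter, condition, value) plus the
    ordered condition labels and the pairwise contrasts of the design.
    Duplicate conditions within a subject (same ROF level or same ΔROF
    state on several segments) collapse to the median parameter value.
    """
    m = matrix.copy()
    if design == "segments":
        m = m[m["segment"].isin([1, 5, 8])]
        m["condition"] = "S" + m["segment"].astype(int).astype(str)
        conditions = ["S1", "S5", "S8"]
        contrasts = SEGMENT_CONTRASTS
    elif design == "rof_levels":
        rows = []
        for lab in ("L", "M", "H"):
            sel = m[m["level"].astype(str).str.contains(lab, regex=False)]
            sel = sel.assign(condition=lab)
            rows.append(sel)
        m = pd.concat(rows, ignore_index=True)
        conditions = ["L", "M", "H"]
        contrasts = LEVEL_CONTRASTS
    elif design == "delta_rof":
        m = m[m["delta_state"].isin(["0", "[1,2]", "[3,4]", ">=5"])]
        m = m.assign(condition=m["delta_state"])
        conditions = ["0", "[1,2]", "[3,4]", ">=5"]
        contrasts = DELTA_CONTRASTS
    else:
        raise ValueError(f"unknown design {design!r}")
    collapsed = (m.groupby(["subject", "parameter", "condition"])
                  ["normalized_median"].median().rename("value").reset_index())
    return collapsed, conditions, contrasts


def run_battery(matrix: pd.DataFrame, design: str,
                parameters: list[str] | None = None) -> pd.DataFrame:
    """Friedman + pairwise Wilcoxon results for every parameter of a design.

    ``matrix`` is the long per-subject segment matrix from
    :func:`runfatigue.race_segmentation.build_segment_matrix` stacked over
    subjects.  Subjects with missing cells are listwise-deleted per
    contrast.  Returns a tidy results table with statistics, p-values,
    effect sizes and significance stars.
    """
    long, conditions, contrasts = _condition_values(matrix, design)
    if parameters is None:
        parameters = sorted(long["parameter"].unique())
    results: list[dict] = []
    for param in parameters:
        sub = long[long["parameter"] == param]
        wide = sub.pivot_table(index="subject", columns="condition",
                               values="value", aggfunc="median")
        have = [c for c in conditions if c in wide.columns]
        # Friedman across all design conditions (complete rows only)
        if len(have) >= 3:
            comp = wide[have].dropna()
            if len(comp) >= 2:
                try:
                    chi2, p, w = friedman_W(comp.to_numpy())
                    results.append(dict(
                        parameter=param, comparison="|".join(have),
                        test="friedman", statistic=chi2, p=p, effect_size=w,
                        n=len(comp), k=len(have), stars=significance_stars(p)))
                except InsufficientDataError:
                    pass
        for a, b in contrasts:
            if a not in wide.columns or b not in wide.columns:
                continue
            pair = wide[[a, b]].dropna()
            if len(pair) < 5:
                continue
            z, p, es, n_eff = wilcoxon_es(pair[a].to_numpy(), pair[b].to_numpy())
            results.append(dict(
                parameter=param, comparison=f"{a}|{b}", test="wilcoxon",
                statistic=z, p=p, effect_size=es, n=n_eff, k=2,
                stars=significance_stars(p)))
    return pd.DataFrame(results)


# ---------------------------------------------------------------------------
# Linear mixed-effects model with performance grouping
# ---------------------------------------------------------------------------

def assign_performance(race_time_min: float,
                       fast_below: float = FAST_RACE_TIME_MIN,
                       slow_above: float = SLOW_RACE_TIME_MIN) -> str:
    """Label a runner fast / slow / mid from the race time in minutes."""
    if race_time_min < fast_below:
        return "fast"
    if race_time_min > slow_above:
        return "slow"
    return "mid"


def fit_lme(data: pd.DataFrame, responder: str = "value",
            reml: bool = True) -> LmeResult:
    """Mixed model ``responder ~ ΔROF * performance + (ΔROF | subject)``.

    ``data`` needs columns ``value`` (or the named responder), ``delta_rof``
    (numeric, not pooled), ``performance`` ({fast, slow}) and ``subject``.
    Estimated by restricted maximum likelihood by default — with the small
    subject counts of this design, plain-ML variance estimates are biased
    low and their Wald intervals undercover (≈92% vs the REML ≈95% at the
    nominal level in simulation); ``reml=False`` restores plain ML.
    Fixed-effect p-values and 95% CIs are
    Wald-based, and a term is reported significant when p ≤ 0.05 *and* its
    CI excludes zero.  A singular random intercept+slope fit is retried
    with a random intercept only (flagged via ``random_slope=False``).
    The conditional R² follows the Nakagawa variance partition
    ``(σ²_f + σ²_r) / (σ²_f + σ²_r + σ²_ε)``.
    """
    d = data.dropna(subset=[responder, "delta_rof", "performance", "subject"])
    d = d[d["performance"].isin(["fast", "slow"])].copy()
    n_per_group = {g: d.loc[d["performance"] == g, "subject"].nunique()
                   for g in ("fast", "slow")}
    if min(n_per_group.values()) < 2:
        raise InsufficientDataError("need >= 2 subjects per performance group")
    d["performance"] = pd.Categorical(d["performance"], ["fast", "slow"])
    formula = f"{responder} ~ delta_rof * performance"

    def _fit(re_formula: str):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, d, groups=d["subject"],
                                re_formula=re_formula)
            return model.fit(reml=reml, method=["lbfgs", "powell"])

    def _usable(f) -> bool:
        return (np.all(np.isfinite(np.asarray(f.cov_re)))
                and np.all(np.isfinite(f.fe_params))
                and np.all(np.isfinite(f.bse_fe)))

    random_slope = True
    fit = None
    try:
        cand = _fit("~delta_rof")
        if _usable(cand):
            fit = cand
    except Exception:
        pass
    if fit is None:
        random_slope = False
        try:
            cand = _fit("~1")
            if _usable(cand):
                fit = cand
        except Exception:
            pass
    if fit is None:
        # degenerate limit: no usable random structure, plain linear model
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = smf.ols(formula, d).fit()
        ci = ols.conf_int()
        fixed = pd.DataFrame({
            "term": ols.params.index, "estimate": ols.params.to_numpy(),
            "p": ols.pvalues.to_numpy(), "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy()})
        fixed["significant"] = ((fixed["p"] <= 0.05)
                                & ((fixed["ci_low"] > 0) | (fixed["ci_high"] < 0)))
        return LmeResult(responder=responder, fixed_effects=fixed,
                         random_variances={"residual": float(ols.scale)},
                         conditional_r2=float(ols.rsquared),
                         converged=True, random_slope=False)

    fe = fit.fe_params
    ci = fit.conf_int().loc[fe.index]
    pvals = fit.pvalues.loc[fe.index]
    fixed = pd.DataFrame({
        "term": fe.index,
        "estimate": fe.to_numpy(),
        "p": pvals.to_numpy(),
        "ci_low": ci[0].to_numpy(),
        "ci_high": ci[1].to_numpy(),
    })
    fixed["significant"] = ((fixed["p"] <= 0.05)
                            & ((fixed["ci_low"] > 0) | (fixed["ci_high"] < 0)))

    # Nakagawa variance partition on the training data
    exog = fit.model.exog
    var_f = float(np.var(exog @ fe.to_numpy()))
    z_cols = ["_icept"] + (["delta_rof"] if random_slope else [])
    z = np.column_stack([np.ones(len(d))]
                        + ([d["delta_rof"].to_numpy()] if random_slope else []))
    g = np.asarray(fit.cov_re)
    var_r = float(np.mean(np.einsum("ij,jk,ik->i", z, g, z)))
    var_e = float(fit.scale)
    r2c = (var_f + var_r) / (var_f + var_r + var_e)
    rand_named = {f"{a}:{b}": float(g[i, j])
                  for i, a in enumerate(z_cols) for j, b in enumerate(z_cols)
                  if i <= j}
    rand_named["residual"] = var_e
    return LmeResult(responder=responder, fixed_effects=fixed,
                     random_variances=rand_named, conditional_r2=float(r2c),
                     converged=bool(fit.converged), random_slope=random_slope)
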