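"""Group-difference tests and effect sizes.

One-tailed Welch t-tests compare raw and z-scored ROI values between groups
in fixed, modality-specific directions (lower FA/FAt, higher FW in patients),
with Cohen's d and its large-sample 95% CI. Summary deviation measures,
whose distributions are skewed, are compared with one-tailed Wilcoxon
rank-sum tests and Cliff's delta with the Feng & Cliff consistent-variance,
asymmetric-bounds confidence interval. A one-sided paired t-test compares
per-ROI effect sizes obtained from z-scores against those from raw values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Hypothesized direction of the patient group relative to controls.
MODALITY_DIRECTION = {"FA": "less", "FAt": "less", "FW": "greater"}

#: Default tails for the summary-measure comparisons (patients vs controls):
#: more abnormal ROIs, more extreme severity (more negative for FA/FAt),
#: lower mean z for FA/FAt (higher for FW), larger spread, more mass in the
#: significant range. The tails for severity and sd_z are package defaults.
SUMMARY_DIRECTION = {
    "load": "greater",
    "severity": "less",
    "mean_z": "less",
    "sd_z": "greater",
    "frac_sig_range": "greater",
}


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    effect_size: float
    ci_low: float
    ci_high: float
    direction: str
    method: str


@dataclass(frozen=True)
class EffectSize:
    estimate: float
    ci_low: float
    ci_high: float
    method: str


def _check_direction(direction: str) -> None:
    if direction not in ("less", "greater"):
        raise ValueError(f"direction must be 'less' or 'greater', got {direction!r}")


def cohens_d(a, b, ci_level: float = 0.95) -> EffectSize:
    """Classical Cohen's d: (mean(a) - mean(b)) / pooled SD (n-1 weights).

    The CI uses the standard large-sample variance
    d^2 / (2(n1+n2)) + (n1+n2)/(n1*n2); no small-sample (Hedges) correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("cohens_d needs >= 2 observations per sample")
    pooled = np.sqrt(
        ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    )
    if pooled == 0.0:
        raise ValueError("pooled SD is zero; Cohen's d undefined")
    d = (a.mean() - b.mean()) / pooled
    se = np.sqrt(d**2 / (2 * (n1 + n2)) + (n1 + n2) / (n1 * n2))
    zq = stats.norm.ppf(0.5 + ci_level / 2)
    return EffectSize(float(d), float(d - zq * se), float(d + zq * se), "cohens_d")


def welch_t(a, b, direction: str = "less") -> TestResult:
    """One-tailed Welch t-test of mean(a) vs mean(b), with Cohen's d CI.

    ``direction='less'`` tests the alternative mean(a) < mean(b). With both
    variances zero and equal means the test is uninformative and p = 1.
    """
    _check_direction(direction)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t needs >= 2 observations per sample")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            es = (0.0, 0.0, 0.0)
            return TestResult(0.0, 1.0, *es, direction, "welch_t")
        stat = np.inf if a.mean() > b.mean() else -np.inf
        p = 0.0 if (stat > 0) == (direction == "greater") else 1.0
        return TestResult(float(stat), p, np.nan, np.nan, np.nan, direction, "welch_t")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=direction)
    try:
        es = cohens_d(a, b)
        d, lo, hi = es.estimate, es.ci_low, es.ci_high
    except ValueError:
        d = lo = hi = np.nan
    return TestResult(float(res.statistic), float(res.pvalue), d, lo, hi,
                      direction, "welch_t")


def wilcoxon_ranksum(a, b, direction: str = "less",
                     exact_cutoff: int = 20) -> TestResult:
    """One-tailed two-sample Wilcoxon rank-sum test, with Cliff's delta CI.

    Midranks handle ties. P-values are exact by enumeration for combined
    n <= ``exact_cutoff`` (ties permitting) and use the continuity-corrected
    normal approximation above it. The statistic reported is the rank sum of
    sample ``a``.
    """
    _check_direction(direction)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 1 or b.size < 1:
        raise ValueError("wilcoxon_ranksum needs >= 1 observation per sample")
    small = a.size + b.size <= exact_cutoff
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=direction, method=method)
    rank_sum = float(res.statistic) + a.size * (a.size + 1) / 2.0
    es = cliffs_delta(a, b)
    return TestResult(rank_sum, float(res.pvalue), es.estimate, es.ci_low,
                      es.ci_high, direction, f"wilcoxon_ranksum[{method}]")


def cliffs_delta(a, b, ci_level: float = 0.95) -> EffectSize:
    """Cliff's delta = [#(a_i > b_j) - #(a_i < b_j)] / (n1*n2), in [-1, 1].

    The CI uses the consistent variance estimate of the dominance matrix row
    and column means with the asymmetric bounded transformation, so the
    bounds stay inside [-1, 1].
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise ValueError("cliffs_delta needs >= 1 observation per sample")
    dom = np.sign(a[:, None] - b[None, :])
    delta = float(dom.mean())
    if n1 < 2 or n2 < 2:
        return EffectSize(delta, -1.0, 1.0, "cliffs_delta")
    di = dom.mean(axis=1)
    dj = dom.mean(axis=0)
    s_di = np.sum((di - delta) ** 2) / (n1 - 1)
    s_dj = np.sum((dj - delta) ** 2) / (n2 - 1)
    s_dij = np.sum((dom - delta) ** 2) / (n1 * n2 - 1)
    var = (
        n2**2 * (n1 - 1) * s_di + n1**2 * (n2 - 1) * s_dj - (n1 * n2 - 1) * s_dij
    ) / (n1 * n2 * (n1 - 1) * (n2 - 1))
    var = max(var, 0.0)
    zq = stats.norm.ppf(0.5 + ci_level / 2)
    if abs(delta) == 1.0 or var == 0.0:
        # degenerate: complete dominance or constant dominance matrix
        return EffectSize(delta, min(delta, delta), max(delta, delta), "cliffs_delta")
    denom = 1.0 - delta**2 + zq**2 * var
    half = zq * np.sqrt(var) * np.sqrt((1.0 - delta**2) ** 2 + zq**2 * var)
    lo = (delta - delta**3 - half) / denom
    hi = (delta - delta**3 + half) / denom
    return EffectSize(delta, float(lo), float(hi), "cliffs_delta")


def compare_effectsize_paired(es_z, es_raw) -> TestResult:
    """One-sided paired t-test that per-ROI effect sizes from z-scores exceed
    those from raw values, with the paired Cohen's d (mean diff / SD diff)."""
    es_z = np.asarray(es_z, float)
    es_raw = np.asarray(es_raw, float)
    if es_z.shape != es_raw.shape or es_z.ndim != 1:
        raise ValueError("paired effect-size vectors must be 1-D and equal length")
    diff = es_z - es_raw
    sd = diff.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(diff).max())):
        raise ValueError("paired differences have zero variance")
    res = stats.ttest_rel(es_z, es_raw, alternative="greater")
    d = float(diff.mean() / sd)
    se = 1.0 / np.sqrt(diff.size)  # large-sample SE of a paired d, approx
    return TestResult(float(res.statistic), float(res.pvalue), d,
                      d - 1.96 * se, d + 1.96 * se, "greater", "paired_t")


def roi_group_comparison(
    values: pd.DataFrame,
    groups: pd.Series,
    modality: str,
    value_kind: str = "raw",
    alpha_levels: tuple[float, ...] = (0.05, 0.01, 0.001),
) -> pd.DataFrame:
    """Per-ROI one-tailed Welch tests in the modality's fixed direction.

    ``values`` is a subjects x ROIs table (raw measures or z-scores) indexed
    by subject id; ``groups`` maps each id to 'control' or 'patient'. The
    returned effect size is direction-aligned: positive d means the groups
    differ in the hypothesized direction (e.g. lower FA in patients).
    """
    direction = MODALITY_DIRECTION[modality]
    groups = groups.loc[values.index]
    pat = values.loc[groups == "patient"]
    ctl = values.loc[groups == "control"]
    if len(pat) == 0 or len(ctl) == 0:
        raise ValueError("both groups must be present for ROI comparisons")
    rows = []
    for roi in values.columns:
        res = welch_t(pat[roi].to_numpy(), ctl[roi].to_numpy(), direction)
        sign = -1.0 if direction == "less" else 1.0
        row = {
            "roi": roi,
            "modality": modality,
            "kind": value_kind,
            "statistic": res.statistic,
            "p": res.p_value,
            "d": sign * res.effect_size,
            "ci_low": sign * (res.ci_high if sign < 0 else res.ci_low),
            "ci_high": sign * (res.ci_low if sign < 0 else res.ci_high),
        }
        for lev in alpha_levels:
            row[f"significant_at_{lev:g}"] = res.p_value < lev
        rows.append(row)
    return pd.DataFrame(rows)


def summary_group_comparison(
    summaries: pd.DataFrame, groups: pd.Series, modality: str,
    directions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Wilcoxon rank-sum tests of each summary measure (patients vs controls)."""
    directions = SUMMARY_DIRECTION if directions is None else directions
    groups = groups.loc[summaries.index]
    pat = summaries.loc[groups == "patient"]
    ctl = summaries.loc[groups == "control"]
    flip = {"less": "greater", "greater": "less"}
    rows = []
    for measure in summaries.columns:
        direction = directions[measure]
        if measure == "mean_z" and modality == "FW":
            direction = flip[direction]
        res = wilcoxon_ranksum(pat[measure].to_numpy(), ctl[measure].to_numpy(),
                               direction)
        rows.append({
            "measure": measure, "modality": modality, "statistic": res.statistic,
            "p": res.p_value, "cliffs_delta": res.effect_size,
            "ci_low": res.ci_low, "ci_high": res.ci_high, "direction": direction,
        })
    return pd.DataFrame(rows)
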