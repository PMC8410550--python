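"""Abnormality counts, per-subject deviation summaries, and the regularized
z-score distribution with its discriminative "significant range".

A z-score is called abnormal when |z| exceeds a two-sided Bonferroni-corrected
standard-normal quantile (2.9913 for 18 ROIs at alpha = .05): supra-normal
above the threshold, infra-normal below its negative. Per-subject summaries
are the fraction of abnormal ROIs ("load"), the signed z with the largest
absolute value ("severity"), the mean and SD of the 18 z-scores, and the
fraction of ROIs inside the significant range.

The significant range is found by estimating each subject's z-score density
(Gaussian-kernel regularized, 50 equal bins over (-10, 10)), comparing the
two groups bin-by-bin with one-tailed Welch t-tests (patients > controls),
and taking the longest contiguous run of significant bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

N_BINS = 50
Z_RANGE = (-10.0, 10.0)
BIN_WIDTH = (Z_RANGE[1] - Z_RANGE[0]) / N_BINS  # 0.4
#: Default floor on the per-subject KDE bandwidth: one bin width.
KDE_BANDWIDTH_FLOOR = BIN_WIDTH


def bin_centers() -> np.ndarray:
    """Centers of the 50 equal bins covering (-10, 10)."""
    edges = np.linspace(*Z_RANGE, N_BINS + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def bonferroni_z_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Two-sided standard-normal quantile at 1 - alpha/(2*n_tests)."""
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(stats.norm.ppf(1.0 - alpha / (2.0 * n_tests)))


def count_abnormal_per_roi(
    Z: pd.DataFrame, threshold: float, direction: str
) -> tuple[pd.Series, int]:
    """Count abnormal subjects per ROI and subjects with >= 1 abnormal ROI.

    ``direction`` is "infra" (z < -threshold) or "supra" (z > +threshold).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if direction == "infra":
        abnormal = Z < -threshold
    elif direction == "supra":
        abnormal = Z > threshold
    else:
        raise ValueError(f"direction must be 'infra' or 'supra', got {direction!r}")
    return abnormal.sum(axis=0), int(abnormal.any(axis=1).sum())


@dataclass(frozen=True)
class SummaryMeasures:
    """Per-subject scalar deviation statistics over the 18 ROI z-scores."""

    load: float
    severity: float
    mean_z: float
    sd_z: float
    frac_sig_range: float

    FIELDS = ("load", "severity", "mean_z", "sd_z", "frac_sig_range")


@dataclass(frozen=True)
class SignificantRange:
    """Z interval whose density is elevated in patients, per one modality.

    ``lower``/``upper`` are the outer edges of the longest contiguous run of
    significant bins; both are NaN when no bin is significant.
    """

    modality: str
    lower: float
    upper: float
    per_bin_p: np.ndarray

    @property
    def is_empty(self) -> bool:
        return not np.isfinite(self.lower)

    def contains(self, z) -> np.ndarray:
        z = np.asarray(z, float)
        if self.is_empty:
            return np.zeros(z.shape, dtype=bool)
        return (z > self.lower) & (z < self.upper)


def summary_measures(
    z_row, threshold: float, sig_range: SignificantRange | None = None
) -> SummaryMeasures:
    """Summaries of one subject's ROI z-scores; see the module docstring."""
    z = np.asarray(z_row, float)
    if not np.isfinite(z).all():
        raise ValueError("z-scores must all be finite")
    n = z.size
    load = float((np.abs(z) > threshold).sum() / n)
    severity = float(z[int(np.argmax(np.abs(z)))])
    frac = 0.0
    if sig_range is not None:
        frac = float(sig_range.contains(z).sum() / n)
    return SummaryMeasures(load, severity, float(z.mean()),
                           float(z.std(ddof=1)), frac)


def summary_table(
    Z: pd.DataFrame, threshold: float, sig_range: SignificantRange | None = None
) -> pd.DataFrame:
    """Per-subject summary measures for a z-score matrix (rows: subjects)."""
    rows = {
        sid: summary_measures(Z.loc[sid].to_numpy(), threshold, sig_range)
        for sid in Z.index
    }
    return pd.DataFrame(
        {f: [getattr(rows[sid], f) for sid in Z.index] for f in SummaryMeasures.FIELDS},
        index=Z.index,
    )


@dataclass
class ZDensity:
    """One subject's regularized z-score density over the 50 bins."""

    subject_id: str
    bin_centers: np.ndarray
    density: np.ndarray


def silverman_bandwidth(z: np.ndarray) -> float:
    """Silverman's rule-of-thumb KDE bandwidth, floored at one bin width."""
    n = z.size
    spread = min(z.std(ddof=1), stats.iqr(z) / 1.349) if n > 1 else 0.0
    if spread == 0.0:
        return KDE_BANDWIDTH_FLOOR
    return max(0.9 * spread * n ** (-0.2), KDE_BANDWIDTH_FLOOR)


def z_density(z_row, kde_bandwidth: float | None = None,
              subject_id: str = "") -> ZDensity:
    """Gaussian-KDE z-score density at the 50 bin centers for one subject.

    With the default bandwidth (Silverman's rule floored at one bin width),
    18 points give a strongly regularized density. The density integrates to
    ~1 when the mass is interior to (-10, 10).
    """
    z = np.asarray(z_row, float)
    if z.size < 1 or not np.isfinite(z).all():
        raise ValueError("z_density needs at least one finite z-score")
    bw = silverman_bandwidth(z) if kde_bandwidth is None else float(kde_bandwidth)
    if bw <= 0:
        raise ValueError(f"kde_bandwidth must be > 0, got {bw}")
    centers = bin_centers()
    dens = stats.norm.pdf((centers[:, None] - z[None, :]) / bw).mean(axis=1) / bw
    return ZDensity(subject_id, centers, dens)


def density_matrix(Z: pd.DataFrame, kde_bandwidth: float | None = None) -> np.ndarray:
    """Subjects x 50 matrix of per-subject regularized z densities."""
    return np.vstack([
        z_density(Z.loc[sid].to_numpy(), kde_bandwidth, str(sid)).density
        for sid in Z.index
    ])


def significant_range(
    densities_controls: np.ndarray,
    densities_patients: np.ndarray,
    alpha: float = 0.05,
    modality: str = "",
    correction: str | None = None,
) -> SignificantRange:
    """Longest contiguous run of bins with elevated patient density.

    Per-bin one-tailed Welch t-tests (patient mean density > control mean
    density); a bin with zero variance in both groups gets p = 1. Per-bin
    p-values are by default not multiplicity-corrected (pass
    ``correction='bonferroni'`` to divide alpha by the number of bins).
    The returned bounds are the outer edges of the run's first and last bin.
    """
    dc = np.asarray(densities_controls, float)
    dp = np.asarray(densities_patients, float)
    if dc.shape[0] < 2 or dp.shape[0] < 2:
        raise ValueError("significant_range needs >= 2 subjects per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(dp, dc, axis=0, equal_var=False, alternative="greater")
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    level = alpha / p.size if correction == "bonferroni" else alpha
    sig = p < level

    best_start, best_len = -1, 0
    start = None
    for i, flag in enumerate([*sig, False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    if best_len == 0:
        return SignificantRange(modality, np.nan, np.nan, p)
    centers = bin_centers()
    lower = centers[best_start] - BIN_WIDTH / 2
    upper = centers[best_start + best_len - 1] + BIN_WIDTH / 2
    return SignificantRange(modality, float(lower), float(upper), p)
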