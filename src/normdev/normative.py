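"""Sex-stratified kernel-regression normative curves and deviation z-scores.

The normative range of a diffusion measure in one ROI is modeled, within each
sex stratum of the control group, as an age-conditional weighted mean and SD
estimated with the Nadaraya-Watson (NW) estimator under a Gaussian kernel:

    m_h(x)  = sum_i y_i K((x - x_i)/h) / sum_i K((x - x_i)/h)
    s_h^2(x) = sum_i (y_i - m_h(x))^2 K((x - x_i)/h) / sum_i K((x - x_i)/h)

with bandwidth h chosen per (ROI, modality, sex) by minimizing the
leave-one-out cross-validation error CV(h) = mean_j (y_j - m_{h,-j}(x_j))^2
over a fixed grid. Individual deviations are z-scores
(y - m_h(age)) / s_h(age), truncated to [-10, 10]; controls are scored
against the model that excludes them (leave-one-out), reusing the bandwidth
selected on the full stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_cohort import Cohort

Z_TRUNC = 10.0
SD_FLOOR = 1e-6
SEXES = ("M", "F")


def default_bandwidth_grid() -> np.ndarray:
    """40 log-spaced bandwidths from 0.5 to 50 years."""
    return np.logspace(np.log10(0.5), np.log10(50.0), 40)


class ExtrapolationError(ValueError):
    """All kernel weights vanished for a query age (out-of-support query)."""

    def __init__(self, age: float):
        super().__init__(f"no reference subject carries kernel weight at age {age:g}")
        self.age = age


def gaussian_kernel(u):
    """Standard-normal density kernel K(u) = exp(-u^2/2) / sqrt(2*pi)."""
    u = np.asarray(u, float)
    return np.exp(-0.5 * u**2) / np.sqrt(2.0 * np.pi)


@dataclass
class NormativeCurve:
    """Fitted normative reference for one (ROI, modality, sex) stratum.

    Stores the stratum's control ages/values and the CV-selected bandwidth;
    evaluable at any age for the age-conditional mean and SD.
    """

    roi: str
    modality: str
    sex: str
    ref_ages: np.ndarray
    ref_values: np.ndarray
    bandwidth: float
    sd_floor: float = SD_FLOOR
    ref_ids: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.ref_ages = np.asarray(self.ref_ages, float)
        self.ref_values = np.asarray(self.ref_values, float)
        if self.ref_ages.shape != self.ref_values.shape or self.ref_ages.ndim != 1:
            raise ValueError("ref_ages and ref_values must be 1-D and equally long")
        if self.ref_ages.size < 2:
            raise ValueError("a normative curve needs at least 2 reference points")
        if self.bandwidth <= 0:
            raise ValueError(f"bandwidth must be > 0, got {self.bandwidth}")

    def evaluate(self, ages) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized (mean, sd) at the query ages."""
        return _nw_eval(self.ref_ages, self.ref_values, self.bandwidth,
                        np.atleast_1d(np.asarray(ages, float)), self.sd_floor)


def _stabilized_weights(ref_ages: np.ndarray, h: float, query_ages: np.ndarray) -> np.ndarray:
    """Kernel weight matrix (n_query, n_ref), stabilized per query row.

    The smallest squared scaled distance in each row is subtracted before
    exponentiation (a constant factor per row, which cancels in the NW
    ratios), so the best-supported reference point always gets weight 1.
    """
    u2 = ((query_ages[:, None] - ref_ages[None, :]) / h) ** 2
    u2min = u2.min(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        w = np.exp(-0.5 * (u2 - u2min))
    bad = ~np.isfinite(w).all(axis=1) | (w.sum(axis=1) == 0.0)
    if bad.any():
        raise ExtrapolationError(float(query_ages[np.argmax(bad)]))
    return w


def _nw_eval(ref_ages, ref_values, h, query_ages, sd_floor=SD_FLOOR):
    w = _stabilized_weights(ref_ages, h, query_ages)
    denom = w.sum(axis=1)
    mean = w @ ref_values / denom
    var = (w * (ref_values[None, :] - mean[:, None]) ** 2).sum(axis=1) / denom
    sd = np.maximum(np.sqrt(np.maximum(var, 0.0)), sd_floor)
    return mean, sd


def nw_mean(x: float, curve: NormativeCurve) -> float:
    """NW age-conditional mean at age x; convex combination of ref values."""
    return float(curve.evaluate([x])[0][0])


def nw_sd(x: float, curve: NormativeCurve) -> float:
    """NW age-conditional SD at age x, floored at curve.sd_floor."""
    return float(curve.evaluate([x])[1][0])


def cv_score(h: float, ages, values) -> float:
    """Mean squared leave-one-out NW prediction error at bandwidth h.

    A left-out point whose remaining kernel weights all underflow (isolated
    age at a tiny bandwidth) falls back to the leave-one-out sample mean, so
    CV stays finite without discarding data.
    """
    ages = np.asarray(ages, float)
    values = np.asarray(values, float)
    n = ages.size
    if n < 2:
        raise ValueError("cv_score needs at least 2 points")
    if h <= 0:
        raise ValueError(f"bandwidth must be > 0, got {h}")
    w = np.exp(-0.5 * ((ages[:, None] - ages[None, :]) / h) ** 2)
    np.fill_diagonal(w, 0.0)
    denom = w.sum(axis=0)
    total = values.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        pred = values @ w / denom
    vanished = denom == 0.0
    if vanished.any():
        pred[vanished] = (total - values[vanished]) / (n - 1)
    return float(np.mean((values - pred) ** 2))


def _cv_scores_grid(ages: np.ndarray, values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.array([cv_score(h, ages, values) for h in grid])


def select_bandwidth(ages, values, grid=None) -> float:
    """Grid argmin of the LOO CV error; ties broken toward the smallest h."""
    ages = np.asarray(ages, float)
    values = np.asarray(values, float)
    grid = default_bandwidth_grid() if grid is None else np.asarray(grid, float)
    if grid.size == 0 or (grid <= 0).any():
        raise ValueError("bandwidth grid must be nonempty and positive")
    if ages.size < 3:
        raise ValueError("bandwidth selection needs at least 3 points")
    scores = _cv_scores_grid(ages, values, grid)
    if not np.isfinite(scores).any():
        raise ValueError("no bandwidth in the grid yields a finite CV score")
    order = np.argsort(grid)  # ascending -> argmin picks the smallest tied h
    best = order[int(np.nanargmin(scores[order]))]
    return float(grid[best])


def select_bandwidths_shared(ages, values_matrix, grid=None) -> np.ndarray:
    """CV bandwidth per column of ``values_matrix`` (n subjects x R ROIs).

    Equivalent to calling :func:`select_bandwidth` per column, but the kernel
    weight matrices -- which depend only on the shared ages -- are computed
    once per grid point. Used when fitting all ROIs of one sex stratum.
    """
    ages = np.asarray(ages, float)
    V = np.asarray(values_matrix, float)
    grid = default_bandwidth_grid() if grid is None else np.asarray(grid, float)
    if grid.size == 0 or (grid <= 0).any():
        raise ValueError("bandwidth grid must be nonempty and positive")
    if ages.size < 3:
        raise ValueError("bandwidth selection needs at least 3 points")
    n, n_roi = V.shape
    d2 = (ages[:, None] - ages[None, :]) ** 2
    col_totals = V.sum(axis=0)
    scores = np.empty((grid.size, n_roi))
    for gi, h in enumerate(grid):
        w = np.exp(-0.5 * d2 / h**2)
        np.fill_diagonal(w, 0.0)
        denom = w.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pred = (w.T @ V) / denom[:, None]
        vanished = denom == 0.0
        if vanished.any():
            pred[vanished] = (col_totals[None, :] - V[vanished]) / (n - 1)
        scores[gi] = np.mean((V - pred) ** 2, axis=0)
    order = np.argsort(grid)
    best = order[np.nanargmin(scores[order], axis=0)]
    return grid[best]


def fit_normative(
    cohort: Cohort, roi: str, modality: str, sex: str, grid=None,
    sd_floor: float = SD_FLOOR,
) -> NormativeCurve:
    """Fit one normative curve from the sex-matched controls of a cohort."""
    ids = cohort.ids(group="control", sex=sex)
    if len(ids) < 3:
        raise ValueError(
            f"need >= 3 {sex} controls to fit {roi}/{modality}, got {len(ids)}"
        )
    ages = cohort.ages_for(ids)
    values = cohort.values_for(modality, roi, ids)
    h = select_bandwidth(ages, values, grid)
    return NormativeCurve(roi, modality, sex, ages, values, h,
                          sd_floor=sd_floor, ref_ids=np.asarray(ids))


def fit_all_curves(
    cohort: Cohort, modality: str, grid=None, sd_floor: float = SD_FLOOR,
) -> dict[tuple[str, str], NormativeCurve]:
    """Fit curves for every (ROI, sex) stratum of one modality.

    Bandwidths are CV-selected exactly as in :func:`fit_normative`, sharing
    the kernel matrices across the ROIs of each sex stratum.
    """
    curves: dict[tuple[str, str], NormativeCurve] = {}
    rois = cohort.roi_names
    for sex in SEXES:
        ids = cohort.ids(group="control", sex=sex)
        if len(ids) == 0 and (cohort.subjects["sex"] != sex).all():
            continue  # sex absent from the cohort entirely (single-sex run)
        if len(ids) < 3:
            raise ValueError(
                f"need >= 3 {sex} controls to fit {modality} curves, got {len(ids)}"
            )
        ages = cohort.ages_for(ids)
        V = cohort.measures[modality].loc[ids, rois].to_numpy(float)
        hs = select_bandwidths_shared(ages, V, grid)
        for j, roi in enumerate(rois):
            curves[(roi, sex)] = NormativeCurve(
                roi, modality, sex, ages, V[:, j], float(hs[j]),
                sd_floor=sd_floor, ref_ids=np.asarray(ids),
            )
    return curves


def zscore(age: float, sex: str, value: float, curve: NormativeCurve) -> float:
    """Deviation z = (value - m_h(age)) / s_h(age), truncated to [-10, 10]."""
    if curve.sex != sex:
        raise ValueError(f"curve is for sex {curve.sex!r}, subject is {sex!r}")
    m, s = curve.evaluate([age])
    return float(np.clip((value - m[0]) / s[0], -Z_TRUNC, Z_TRUNC))


def zscores_patients(
    cohort: Cohort, curves: dict[tuple[str, str], NormativeCurve], modality: str,
    group: str = "patient",
) -> pd.DataFrame:
    """Z-score every subject of ``group`` against the sex-matched curves.

    Returns a subjects x ROIs DataFrame (index: subject id); values are
    truncated to [-10, 10]. ``.attrs['modality']`` records the modality.
    """
    rois = cohort.roi_names
    for sex in cohort.subjects.loc[cohort.subjects["group"] == group, "sex"].unique():
        for roi in rois:
            if (roi, sex) not in curves:
                raise ValueError(f"missing normative curve for ROI {roi!r}, sex {sex!r}")
    ids = cohort.ids(group=group)
    out = pd.DataFrame(index=pd.Index(ids, name="id"), columns=rois, dtype=float)
    for sex in SEXES:
        sids = cohort.ids(group=group, sex=sex)
        if len(sids) == 0:
            continue
        ages = cohort.ages_for(sids)
        for roi in rois:
            m, s = curves[(roi, sex)].evaluate(ages)
            z = (cohort.values_for(modality, roi, sids) - m) / s
            out.loc[sids, roi] = np.clip(z, -Z_TRUNC, Z_TRUNC)
    out.attrs["modality"] = modality
    return out


def _loo_zscores(ages: np.ndarray, values: np.ndarray, h: float,
                 sd_floor: float = SD_FLOOR) -> np.ndarray:
    """Leave-one-out NW z-score of each point against the remaining points."""
    n = ages.size
    u2 = ((ages[:, None] - ages[None, :]) / h) ** 2
    np.fill_diagonal(u2, np.inf)  # exclude self; exp(-inf) = 0
    u2 -= np.where(np.isfinite(u2), u2, np.inf).min(axis=1, keepdims=True)
    w = np.exp(-0.5 * u2)
    denom = w.sum(axis=1)
    if (denom == 0.0).any() or not np.isfinite(denom).all():
        raise ExtrapolationError(float(ages[np.argmax(denom == 0.0)]))
    mean = w @ values / denom
    var = (w * (values[None, :] - mean[:, None]) ** 2).sum(axis=1) / denom
    sd = np.maximum(np.sqrt(np.maximum(var, 0.0)), sd_floor)
    return np.clip((values - mean) / sd, -Z_TRUNC, Z_TRUNC)


def zscores_controls_loo(
    cohort: Cohort, modality: str, grid=None, sd_floor: float = SD_FLOOR,
    curves: dict[tuple[str, str], NormativeCurve] | None = None,
) -> pd.DataFrame:
    """Leave-one-out z-scores for every control subject.

    Each control is compared with a normative model built from all other
    controls of the same sex. The bandwidth is the one selected once per
    (ROI, sex) stratum on the full stratum (pass precomputed ``curves`` to
    reuse an existing fit rather than re-selecting here).
    """
    rois = cohort.roi_names
    ids = cohort.ids(group="control")
    out = pd.DataFrame(index=pd.Index(ids, name="id"), columns=rois, dtype=float)
    for sex in SEXES:
        sids = cohort.ids(group="control", sex=sex)
        if len(sids) == 0:
            continue
        if len(sids) < 4:
            raise ValueError(
                f"leave-one-out z-scores need >= 4 {sex} controls, got {len(sids)}"
            )
        ages = cohort.ages_for(sids)
        V = cohort.measures[modality].loc[sids, rois].to_numpy(float)
        if curves is not None:
            hs = [curves[(roi, sex)].bandwidth for roi in rois]
        else:
            hs = select_bandwidths_shared(ages, V, grid)
        for j, roi in enumerate(rois):
            out.loc[sids, roi] = _loo_zscores(ages, V[:, j], float(hs[j]), sd_floor)
    out.attrs["modality"] = modality
    return out


def bandwidth_table(curves: dict[tuple[str, str], NormativeCurve]) -> pd.DataFrame:
    """Long-format (roi, modality, sex, h) table of selected bandwidths."""
    rows = [
        {"roi": c.roi, "modality": c.modality, "sex": c.sex, "h": c.bandwidth}
        for c in curves.values()
    ]
    return pd.DataFrame(rows)
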