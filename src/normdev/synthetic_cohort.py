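"""Synthetic cohorts with the statistical structure the normative analysis assumes.

Real ROI-level diffusion tables from the motivating clinical dataset are not
distributable, so this module generates cohorts with the same statistical
skeleton: smooth ROI-specific age trajectories with sex offsets in healthy
controls, plus subtle group effects (lower FA/FAt, higher FW) placed in a
random, per-patient subset of tracts -- the "heterogeneous abnormality
location" premise that motivates deviation-based analysis.

The whole-skeleton column is the mean of the 17 tract columns, as in atlas
pipelines that average a diffusion measure over the skeletonized white
matter. A per-subject global offset shared across tracts models the strong
within-subject correlation of ROI means seen in real data; it also gives the
skeleton average a non-degenerate between-subject variance.

``oracle_curves`` exposes the exact generative mean and SD so that normative
fits can be tested for parameter recovery without circularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

MODALITIES = ("FA", "FAt", "FW")

#: 17 tract ROIs + whole-skeleton average. Four canonical labels; the
#: remaining tracts carry generic names.
DEFAULT_ROI_NAMES: tuple[str, ...] = (
    "Fmajor",
    "Fminor",
    "Fornix",
    *[f"Tract{i:02d}" for i in range(4, 18)],
    "WM-skeleton",
)

N_TRACTS = 17
N_ROIS = 18

#: Direction of the group effect per modality (patients relative to controls).
EFFECT_SIGN = {"FA": -1.0, "FAt": -1.0, "FW": +1.0}

_VALUE_CLIP = (0.01, 0.99)


def default_trajectory_params() -> dict[str, np.ndarray]:
    """Per-tract quadratic age-trajectory coefficients, one (17, 3) array per
    modality.

    Row i holds (c0, c1, c2) of value(a) = c0 + c1*(a-30) + c2*(a-30)^2.
    FA and FAt peak near age 30 (negative curvature, small per-ROI peak
    shift); FW increases monotonically with age. Bases vary across tracts to
    span the plausible range of tract-mean values.
    """
    i = np.arange(N_TRACTS, dtype=float)
    out: dict[str, np.ndarray] = {}

    # FA: bases 0.38..0.57, curvature ~ -2e-5..-4.4e-5, peak ages 26..34
    c2 = -(2.0 + 0.15 * i) * 1e-5
    peak = 26.0 + 0.5 * i
    c1 = -2.0 * c2 * (peak - 30.0)
    c0 = 0.38 + 0.012 * i
    out["FA"] = np.column_stack([c0, c1, c2])

    # FAt: free-water-corrected anisotropy sits above FA in the same tracts
    out["FAt"] = np.column_stack([c0 + 0.05, c1, c2])

    # FW: low fractional volume, slow monotone rise with age
    out["FW"] = np.column_stack(
        [0.10 + 0.004 * i, 8e-4 + 2e-5 * i, np.zeros(N_TRACTS)]
    )
    return out


def default_roi_prevalence_weights() -> np.ndarray:
    """Relative probability of each tract being implicated in a patient.

    Abnormality locations vary across patients, but not exchangeably: some
    tracts are implicated far more often than others (in the motivating
    clinical data the Forceps major tops the infra-normal counts). The
    default declines linearly from the first tract to a 10x lower weight for
    the last; weights are normalized internally.
    """
    return np.linspace(3.0, 0.3, N_TRACTS)


def default_sex_offset() -> dict[str, np.ndarray]:
    """Additive male-minus-female shift per tract (applied to males)."""
    i = np.arange(N_TRACTS)
    alt = np.where(i % 2 == 0, 1.0, -1.0)
    return {
        "FA": 0.006 + 0.002 * alt,
        "FAt": 0.006 + 0.002 * alt,
        "FW": -0.003 + 0.001 * alt,
    }


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for one synthetic cohort.

    Demographic defaults are the study marginals of the motivating dataset:
    512 controls (age 30.15 [14.26] y, 54.49% male) and 601 patients
    (age 31.46 [12.31] y, 63.23% male).

    ``effect_size_range`` is the per-modality range (Cohen's-d scale,
    relative to the tract between-subject SD) of the shift applied to each
    affected tract of each patient; the number of affected tracts per patient
    is uniform over ``affected_roi_count_range`` (inclusive). Effect
    directions are fixed: FA/FAt down, FW up.

    ``subject_sd_ratio`` scales a per-subject offset shared across tracts
    (SD = ratio * noise_sd); ``sd_age_slope`` optionally makes the residual
    noise heteroscedastic: SD multiplied by 1 + slope*(age-30)/40.
    """

    n_controls: int = 512
    n_patients: int = 601
    seed: int = 0
    roi_names: tuple[str, ...] = DEFAULT_ROI_NAMES
    age_mean_sd_controls: tuple[float, float] = (30.15, 14.26)
    age_mean_sd_patients: tuple[float, float] = (31.46, 12.31)
    male_fraction_controls: float = 0.5449
    male_fraction_patients: float = 0.6323
    trajectory_params: Mapping[str, np.ndarray] = field(
        default_factory=default_trajectory_params
    )
    sex_offset: Mapping[str, np.ndarray] = field(default_factory=default_sex_offset)
    effect_size_range: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {m: (0.5, 1.5) for m in MODALITIES}
    )
    affected_roi_count_range: tuple[int, int] = (1, 6)
    roi_prevalence_weights: np.ndarray = field(
        default_factory=default_roi_prevalence_weights
    )
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"FA": 0.02, "FAt": 0.02, "FW": 0.015}
    )
    subject_sd_ratio: float = 0.75
    sd_age_slope: float = 0.0
    age_range: tuple[float, float] = (8.0, 70.0)
    #: 'truncnorm' draws ages from the configured group marginals truncated
    #: to age_range; 'uniform' covers age_range evenly (useful for tests that
    #: need full kernel support at the range boundaries).
    age_distribution: str = "truncnorm"

    def __post_init__(self) -> None:
        if self.n_controls <= 0:
            raise ValueError(f"n_controls must be positive, got {self.n_controls}")
        if self.n_patients <= 0:
            raise ValueError(f"n_patients must be positive, got {self.n_patients}")
        if len(self.roi_names) != N_ROIS:
            raise ValueError(
                f"roi_names must have exactly {N_ROIS} labels, got {len(self.roi_names)}"
            )
        for name, frac in (
            ("male_fraction_controls", self.male_fraction_controls),
            ("male_fraction_patients", self.male_fraction_patients),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        for mod in MODALITIES:
            if self.noise_sd[mod] <= 0:
                raise ValueError(f"noise_sd[{mod}] must be > 0, got {self.noise_sd[mod]}")
            lo, hi = self.effect_size_range[mod]
            if lo < 0 or hi < lo:
                raise ValueError(
                    f"effect_size_range[{mod}] must satisfy 0 <= lo <= hi, got ({lo}, {hi})"
                )
            if np.asarray(self.trajectory_params[mod]).shape != (N_TRACTS, 3):
                raise ValueError(
                    f"trajectory_params[{mod}] must have shape ({N_TRACTS}, 3)"
                )
            if len(np.atleast_1d(self.sex_offset[mod])) not in (1, N_TRACTS):
                raise ValueError(f"sex_offset[{mod}] must be scalar or length {N_TRACTS}")
        lo, hi = self.affected_roi_count_range
        if not (1 <= lo <= hi <= N_TRACTS):
            raise ValueError(
                f"affected_roi_count_range must be within 1..{N_TRACTS}, got ({lo}, {hi})"
            )
        weights = np.asarray(self.roi_prevalence_weights, float)
        if weights.shape != (N_TRACTS,) or (weights <= 0).any():
            raise ValueError(
                f"roi_prevalence_weights must be {N_TRACTS} positive values"
            )
        if self.subject_sd_ratio < 0:
            raise ValueError(f"subject_sd_ratio must be >= 0, got {self.subject_sd_ratio}")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError(f"age_range must be increasing, got {self.age_range}")
        if self.age_distribution not in ("truncnorm", "uniform"):
            raise ValueError(
                f"age_distribution must be 'truncnorm' or 'uniform', "
                f"got {self.age_distribution!r}"
            )

    def null(self) -> "CohortConfig":
        """Copy of this config in which the groups are exchangeable.

        Group effects are zeroed and the patients' age/sex marginals are set
        to the controls', so patient and control values are drawn from
        identical distributions (a true null for type-I checks).
        """
        return replace(
            self,
            effect_size_range={m: (0.0, 0.0) for m in MODALITIES},
            age_mean_sd_patients=self.age_mean_sd_controls,
            male_fraction_patients=self.male_fraction_controls,
        )


@dataclass
class Cohort:
    """Subject table plus one subjects x 18-ROI measure matrix per modality.

    ``subjects`` has columns (id, age, sex, group) indexed 0..n-1;
    ``measures[mod]`` is a DataFrame indexed by subject id with the ROI
    labels as columns, aligned with ``subjects.id``.
    """

    subjects: pd.DataFrame
    measures: dict[str, pd.DataFrame]

    @property
    def roi_names(self) -> list[str]:
        return list(next(iter(self.measures.values())).columns)

    def ids(self, group: str | None = None, sex: str | None = None) -> pd.Index:
        mask = pd.Series(True, index=self.subjects.index)
        if group is not None:
            mask &= self.subjects["group"] == group
        if sex is not None:
            mask &= self.subjects["sex"] == sex
        return pd.Index(self.subjects.loc[mask, "id"])

    def subset(self, ids: pd.Index) -> "Cohort":
        sub = self.subjects[self.subjects["id"].isin(ids)].reset_index(drop=True)
        meas = {m: df.loc[sub["id"]] for m, df in self.measures.items()}
        return Cohort(sub, meas)

    def values_for(self, modality: str, roi: str, ids: pd.Index) -> np.ndarray:
        return self.measures[modality].loc[ids, roi].to_numpy(float)

    def ages_for(self, ids: pd.Index) -> np.ndarray:
        lookup = self.subjects.set_index("id")["age"]
        return lookup.loc[ids].to_numpy(float)

    def write(self, out_dir: str | Path,
              modalities: tuple[str, ...] | None = None) -> None:
        """Write subjects.tsv plus one <modality>.tsv per (selected) modality."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)
        for mod, df in self.measures.items():
            if modalities is not None and mod not in modalities:
                continue
            df.rename_axis("id").reset_index().to_csv(
                out / f"{mod}.tsv", sep="\t", index=False
            )

    @classmethod
    def read(cls, in_dir: str | Path, modalities: tuple[str, ...] = MODALITIES) -> "Cohort":
        """Read a cohort from the TSV layout produced by :meth:`write`."""
        src = Path(in_dir)
        subjects = pd.read_csv(src / "subjects.tsv", sep="\t")
        measures = {}
        for mod in modalities:
            path = src / f"{mod}.tsv"
            if path.exists():
                measures[mod] = pd.read_csv(path, sep="\t").set_index("id")
        if not measures:
            raise FileNotFoundError(f"no modality tables found in {src}")
        return cls(subjects, measures)


def _truncnorm_ages(rng, n, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _noise_scale(config: CohortConfig, ages: np.ndarray) -> np.ndarray:
    return np.maximum(1.0 + config.sd_age_slope * (ages - 30.0) / 40.0, 0.05)


def _tract_trajectory(coeffs: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Evaluate per-tract trajectories; returns (n_subjects, 17)."""
    a = ages[:, None] - 30.0
    c0, c1, c2 = coeffs[:, 0], coeffs[:, 1], coeffs[:, 2]
    return c0[None, :] + c1[None, :] * a + c2[None, :] * a**2


def tract_sd(config: CohortConfig, modality: str) -> float:
    """Total between-subject SD of one tract (subject offset + residual)."""
    return float(config.noise_sd[modality]) * float(
        np.hypot(config.subject_sd_ratio, 1.0)
    )


def _generate_group(
    config: CohortConfig,
    rng: np.random.Generator,
    n: int,
    age_mean_sd: tuple[float, float],
    male_fraction: float,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Draw ages, sexes and control-model tract values (n x 17 per modality)."""
    if config.age_distribution == "uniform":
        ages = rng.uniform(*config.age_range, size=n)
    else:
        ages = _truncnorm_ages(rng, n, *age_mean_sd, *config.age_range)
    male = rng.random(n) < male_fraction
    scale = _noise_scale(config, ages)
    values: dict[str, np.ndarray] = {}
    for mod in MODALITIES:
        traj = _tract_trajectory(np.asarray(config.trajectory_params[mod], float), ages)
        offset = np.broadcast_to(
            np.atleast_1d(np.asarray(config.sex_offset[mod], float)), (N_TRACTS,)
        )
        sd = config.noise_sd[mod]
        subj = rng.normal(0.0, config.subject_sd_ratio * sd, size=(n, 1))
        eps = rng.normal(0.0, sd, size=(n, N_TRACTS)) * scale[:, None]
        values[mod] = traj + male[:, None] * offset[None, :] + subj + eps
    sexes = np.where(male, "M", "F")
    return ages, sexes, values


def _apply_group_effects(
    config: CohortConfig, rng: np.random.Generator, values: dict[str, np.ndarray]
) -> None:
    """Shift a random per-patient tract subset in the fixed modality directions."""
    n = next(iter(values.values())).shape[0]
    lo_k, hi_k = config.affected_roi_count_range
    counts = rng.integers(lo_k, hi_k + 1, size=n)
    weights = np.asarray(config.roi_prevalence_weights, float)
    p = weights / weights.sum()
    for s in range(n):
        affected = rng.choice(N_TRACTS, size=counts[s], replace=False, p=p)
        for mod in MODALITIES:
            lo, hi = config.effect_size_range[mod]
            if hi <= 0.0:
                # keep the RNG stream aligned between null and effect configs
                rng.uniform(lo, hi, size=counts[s])
                continue
            d = rng.uniform(lo, hi, size=counts[s])
            values[mod][s, affected] += EFFECT_SIGN[mod] * d * tract_sd(config, mod)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a deterministic synthetic cohort for the given config.

    Controls follow the normative generative model (trajectory + sex offset
    + subject offset + residual noise); patients additionally receive the
    modality-signed group effect in a per-patient random subset of tracts.
    The skeleton column is computed as the mean of the 17 tract columns
    after clipping to (0.01, 0.99).
    """
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_demo_c, rng_demo_p, rng_effects = (
        np.random.default_rng(streams[0]),
        np.random.default_rng(streams[1]),
        np.random.default_rng(streams[2]),
    )

    ages_c, sex_c, vals_c = _generate_group(
        config, rng_demo_c, config.n_controls,
        config.age_mean_sd_controls, config.male_fraction_controls,
    )
    ages_p, sex_p, vals_p = _generate_group(
        config, rng_demo_p, config.n_patients,
        config.age_mean_sd_patients, config.male_fraction_patients,
    )
    _apply_group_effects(config, rng_effects, vals_p)

    ids = [f"ctrl-{i + 1:04d}" for i in range(config.n_controls)] + [
        f"pat-{i + 1:04d}" for i in range(config.n_patients)
    ]
    subjects = pd.DataFrame(
        {
            "id": ids,
            "age": np.concatenate([ages_c, ages_p]),
            "sex": np.concatenate([sex_c, sex_p]),
            "group": ["control"] * config.n_controls + ["patient"] * config.n_patients,
        }
    )
    measures = {}
    for mod in MODALITIES:
        tracts = np.clip(
            np.vstack([vals_c[mod], vals_p[mod]]), *_VALUE_CLIP
        )
        full = np.column_stack([tracts, tracts.mean(axis=1)])
        measures[mod] = pd.DataFrame(full, index=pd.Index(ids, name="id"),
                                     columns=list(config.roi_names))
    return Cohort(subjects, measures)


class OracleCurves:
    """Exact generative mean/SD functions, for parameter-recovery tests.

    Assumes the (0.01, 0.99) clip is inactive, which holds for the default
    trajectories over the configured age range.
    """

    def __init__(self, config: CohortConfig):
        self.config = config

    def mean(self, roi: str, modality: str, sex: str, ages) -> np.ndarray:
        ages = np.atleast_1d(np.asarray(ages, float))
        cfg = self.config
        coeffs = np.asarray(cfg.trajectory_params[modality], float)
        offsets = np.broadcast_to(
            np.atleast_1d(np.asarray(cfg.sex_offset[modality], float)), (N_TRACTS,)
        )
        tracts = _tract_trajectory(coeffs, ages)
        if sex == "M":
            tracts = tracts + offsets[None, :]
        roi_idx = list(cfg.roi_names).index(roi)
        if roi_idx < N_TRACTS:
            return tracts[:, roi_idx]
        return tracts.mean(axis=1)

    def sd(self, roi: str, modality: str, ages) -> np.ndarray:
        ages = np.atleast_1d(np.asarray(ages, float))
        cfg = self.config
        base = cfg.noise_sd[modality]
        g = _noise_scale(cfg, ages)
        r = cfg.subject_sd_ratio
        roi_idx = list(cfg.roi_names).index(roi)
        if roi_idx < N_TRACTS:
            return base * np.sqrt(r**2 + g**2)
        return base * np.sqrt(r**2 + g**2 / N_TRACTS)


def oracle_curves(config: CohortConfig) -> OracleCurves:
    """Ground-truth mean/SD used by :func:`generate_cohort`."""
    return OracleCurves(config)
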