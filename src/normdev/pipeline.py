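"""End-to-end orchestration: simulate -> fit -> z-scores -> stats -> predict.

``run_pipeline`` runs every stage on one cohort (synthetic by default, or a
directory of tables in the same schema) and writes all module outputs plus a
manifest (config, seed, package version) into a run directory. ``report``
condenses a finished run into five CSV summaries: per-ROI effect sizes raw
vs z, summary-measure effects, per-ROI AUC raw vs z, combined-feature AUCs,
and the best modality per ROI.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, deviation, group_stats, normative, prediction
from .synthetic_cohort import MODALITIES, Cohort, CohortConfig, generate_cohort

log = logging.getLogger("normdev")

COMBINED_SPECS = ("z:FA:all", "z:FAt:all", "z:FW:all", "z:FAt+FW:all")


@dataclass
class RunConfig:
    """Settings of one pipeline run; every unspecified analysis parameter has
    an explicit, overridable default here."""

    out_dir: str = "normdev_run"
    cohort_dir: str | None = None      # read tables instead of simulating
    seed: int = 0
    modalities: tuple[str, ...] = MODALITIES
    n_controls: int = 512
    n_patients: int = 601
    alpha: float = 0.05
    z_threshold_override: float | None = None  # None -> computed quantile
    grid_min: float = 0.5
    grid_max: float = 50.0
    grid_size: int = 40
    kde_bandwidth: float | None = None  # None -> Silverman, floored
    k_folds: int = 10
    ridge_lambda: float = 1.0
    by_sex: bool = False
    per_roi_auc: bool = True
    cohort_overrides: dict = field(default_factory=dict)

    @property
    def bandwidth_grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.grid_min), np.log10(self.grid_max),
                           self.grid_size)

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_controls=self.n_controls, n_patients=self.n_patients,
            seed=self.seed, **self.cohort_overrides,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "modalities" in raw:
            raw["modalities"] = tuple(raw["modalities"])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in dataclasses.asdict(self).items()},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %-14s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = config.bandwidth_grid

    cohort = _stage("simulate")(_load_or_simulate)(config)
    cohort.write(out, tuple(config.modalities))
    groups = cohort.subjects.set_index("id")["group"]
    n_rois = len(cohort.roi_names)
    threshold = (
        config.z_threshold_override
        if config.z_threshold_override is not None
        else deviation.bonferroni_z_threshold(n_rois, config.alpha)
    )

    all_curves: dict[str, dict] = {}
    zscores: dict[str, pd.DataFrame] = {}
    sig_ranges: dict[str, deviation.SignificantRange] = {}
    summaries: dict[str, pd.DataFrame] = {}
    abnormal: dict[str, dict] = {}
    for mod in config.modalities:
        curves = _stage(f"fit-{mod}")(normative.fit_all_curves)(cohort, mod, grid)
        all_curves[mod] = curves
        z_pat = normative.zscores_patients(cohort, curves, mod)
        z_ctl = _stage(f"zscores-{mod}")(normative.zscores_controls_loo)(
            cohort, mod, curves=curves
        )
        Z = pd.concat([z_ctl, z_pat])
        Z.attrs["modality"] = mod
        zscores[mod] = Z
        Z.rename_axis("id").reset_index().to_csv(
            out / f"zscores_{mod}.tsv", sep="\t", index=False
        )

        dens_c = deviation.density_matrix(z_ctl, config.kde_bandwidth)
        dens_p = deviation.density_matrix(z_pat, config.kde_bandwidth)
        sig = deviation.significant_range(dens_c, dens_p, config.alpha, mod)
        sig_ranges[mod] = sig
        with open(out / f"sig_range_{mod}.json", "w") as fh:
            json.dump(
                {"modality": mod, "lower": None if sig.is_empty else sig.lower,
                 "upper": None if sig.is_empty else sig.upper,
                 "per_bin_p": sig.per_bin_p.tolist()},
                fh, indent=1,
            )

        summ = deviation.summary_table(Z, threshold, sig)
        summaries[mod] = summ
        summ.rename_axis("id").reset_index().to_csv(
            out / f"summary_measures_{mod}.tsv", sep="\t", index=False
        )

        direction = "supra" if mod == "FW" else "infra"
        per_roi_p, n_pat = deviation.count_abnormal_per_roi(z_pat, threshold, direction)
        _, n_ctl = deviation.count_abnormal_per_roi(z_ctl, threshold, direction)
        abnormal[mod] = {
            "direction": direction,
            "patients_with_abnormal_roi": n_pat,
            "controls_with_abnormal_roi": n_ctl,
            "per_roi_patient_counts": per_roi_p.to_dict(),
        }

    normative.bandwidth_table(
        {k: c for mod in all_curves for k, c in all_curves[mod].items()}
    ).to_csv(out / "bandwidths.tsv", sep="\t", index=False)
    with open(out / "abnormal_counts.json", "w") as fh:
        json.dump(abnormal, fh, indent=1)

    stats_frames = []
    summary_frames = []
    for mod in config.modalities:
        raw_tbl = group_stats.roi_group_comparison(
            cohort.measures[mod], groups, mod, "raw")
        z_tbl = group_stats.roi_group_comparison(zscores[mod], groups, mod, "z")
        raw_tbl.to_csv(out / f"group_stats_{mod}_raw.tsv", sep="\t", index=False)
        z_tbl.to_csv(out / f"group_stats_{mod}_z.tsv", sep="\t", index=False)
        stats_frames += [raw_tbl, z_tbl]
        summary_frames.append(
            group_stats.summary_group_comparison(summaries[mod], groups, mod)
        )
    pd.concat(summary_frames).to_csv(out / "summary_stats.tsv", sep="\t", index=False)

    specs = [s for s in COMBINED_SPECS
             if all(m in config.modalities for m in s.split(":")[1].split("+"))]
    if config.per_roi_auc:
        for mod in config.modalities:
            specs += [f"z:{mod}:{roi}" for roi in cohort.roi_names]
            specs += [f"raw:{mod}:{roi}" for roi in cohort.roi_names]
    if "FA" in config.modalities:
        specs.append("z:FA:all+summaries")
    results = _stage("predict")(prediction.cross_validate)(
        cohort, specs, config.k_folds, config.ridge_lambda, config.seed, grid,
        config.alpha,
    )
    _write_cv(out, results, config.seed)

    if config.by_sex:
        by_sex = _stage("predict-by-sex")(prediction.sex_stratified_cv)(
            cohort, [s for s in COMBINED_SPECS if s in specs],
            config.k_folds, config.ridge_lambda, config.seed, grid, config.alpha,
        )
        for sex, res in by_sex.items():
            _write_cv(out, res, config.seed, suffix=f"_{sex}")

    manifest = {
        "package_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_subjects": int(len(cohort.subjects)),
        "z_threshold": threshold,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out


def _load_or_simulate(config: RunConfig) -> Cohort:
    if config.cohort_dir is not None:
        return Cohort.read(config.cohort_dir, tuple(config.modalities))
    return generate_cohort(config.cohort_config())


def _write_cv(out: Path, results: dict[str, prediction.CVResult], seed: int,
              suffix: str = "") -> None:
    rows, coef_rows = [], []
    for spec, res in results.items():
        for fold, a in enumerate(res.fold_aucs):
            rows.append({"feature_set": spec, "fold": fold, "auc": a,
                         "mean_auc": res.mean_auc, "seed": seed})
        for fold, coefs in enumerate(res.coefficients):
            for feat, c in coefs.items():
                coef_rows.append({"feature_set": spec, "fold": fold,
                                  "feature": feat, "coefficient": c})
    pd.DataFrame(rows).to_csv(out / f"cv_results{suffix}.tsv", sep="\t",
                              index=False)
    pd.DataFrame(coef_rows).to_csv(out / f"coefficients{suffix}.tsv", sep="\t",
                                   index=False)


REPORT_FILES = (
    "report_effectsizes_roi.csv",
    "report_effectsizes_summary.csv",
    "report_auc_per_roi.csv",
    "report_auc_combined.csv",
    "report_best_modality_per_roi.csv",
)


def report(run_dir: str | Path) -> list[Path]:
    """Condense a finished run into five CSV summary tables."""
    run = Path(run_dir)
    missing = [f for f in ("cv_results.tsv", "summary_stats.tsv")
               if not (run / f).exists()]
    stats_files = sorted(run.glob("group_stats_*_*.tsv"))
    if missing or not stats_files:
        raise FileNotFoundError(
            f"incomplete run in {run}: missing {missing or 'group_stats tables'}"
        )

    # 1. per-ROI effect sizes, raw vs z, per modality
    frames = [pd.read_csv(f, sep="\t") for f in stats_files]
    es = pd.concat(frames).pivot_table(
        index=["roi", "modality"], columns="kind", values="d"
    ).reset_index()
    es.to_csv(run / REPORT_FILES[0], index=False)

    # 2. summary-measure effect sizes
    pd.read_csv(run / "summary_stats.tsv", sep="\t").to_csv(
        run / REPORT_FILES[1], index=False)

    cv = pd.read_csv(run / "cv_results.tsv", sep="\t")
    cv_mean = cv.groupby("feature_set", as_index=False)["auc"].mean()
    parts = cv_mean["feature_set"].str.split(":", expand=True)
    cv_mean["kind"], cv_mean["modality"], cv_mean["target"] = (
        parts[0], parts[1], parts[2])

    # 3. per-ROI AUC raw vs z
    per_roi = cv_mean[cv_mean["target"] != "all"]
    per_roi_tbl = per_roi.pivot_table(
        index=["target", "modality"], columns="kind", values="auc"
    ).reset_index().rename(columns={"target": "roi"})
    per_roi_tbl.to_csv(run / REPORT_FILES[2], index=False)

    # 4. combined all-ROI AUCs (FA, FAt, FW, FAt+FW)
    combined = cv_mean[(cv_mean["target"] == "all") & (cv_mean["kind"] == "z")]
    combined[["modality", "auc"]].to_csv(run / REPORT_FILES[3], index=False)

    # 5. best modality per ROI by z-score AUC
    z_roi = per_roi[per_roi["kind"] == "z"]
    if len(z_roi):
        best = z_roi.loc[z_roi.groupby("target")["auc"].idxmax(),
                         ["target", "modality", "auc"]]
        best = best.rename(columns={"target": "roi", "modality": "best_modality"})
    else:
        best = pd.DataFrame(columns=["roi", "best_modality", "auc"])
    best.to_csv(run / REPORT_FILES[4], index=False)
    return [run / f for f in REPORT_FILES]
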