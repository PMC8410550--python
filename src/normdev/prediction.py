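"""Case-control classification from normative deviations and raw values.

Subjects are split into k group-balanced folds (each fold gets floor(n/k)
subjects of each group; the remainders go one-per-fold to disjoint folds, so
with 512 controls / 601 patients and k = 10 the fold compositions are exactly
seven (51, 60), two (52, 60) and one (51, 61)). In every round the normative
curves -- including the bandwidth choice -- are refit on the training-fold
controls only, training-control z-scores are leave-one-out, and test subjects
are scored against the training model, so nothing about the test fold leaks
into the features. The classifier is L2-penalized (ridge) logistic
regression on train-standardized features; the evaluation metric is the
Mann-Whitney AUC of the test-fold patient probabilities, averaged unweighted
over the k folds.

Feature-set specs are strings "<kind>:<modalities>:<roi-or-all>[+summaries]",
e.g. ``raw:FA:Fmajor``, ``z:FA:all``, ``z:FAt+FW:all``, ``z:FA:all+summaries``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from . import normative
from .deviation import (
    bonferroni_z_threshold,
    density_matrix,
    significant_range,
    summary_table,
)
from .synthetic_cohort import Cohort


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index (0..k-1) per control and per patient, in cohort order."""

    control_folds: np.ndarray
    patient_folds: np.ndarray
    k: int

    def fold_sizes(self) -> list[tuple[int, int]]:
        """(controls, patients) per fold, as a sorted multiset."""
        return sorted(
            (int((self.control_folds == f).sum()), int((self.patient_folds == f).sum()))
            for f in range(self.k)
        )


def make_folds(n_controls: int, n_patients: int, k: int, seed: int = 0) -> FoldAssignment:
    """Group-balanced k-fold partition with disjoint remainder placement.

    Each fold receives floor(n/k) subjects of each group. The n mod k
    remainder subjects of each group go one-per-fold, with the remainder
    folds of the two groups disjoint whenever k >= r_controls + r_patients,
    so no fold is enlarged on both groups at once. Membership is randomized
    by ``seed``; the multiset of fold compositions is seed-invariant.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n_controls < k or n_patients < k:
        raise ValueError(
            f"need at least k={k} subjects per group, got {n_controls}/{n_patients}"
        )
    rng = np.random.default_rng(seed)
    r_c, r_p = n_controls % k, n_patients % k
    fold_order = rng.permutation(k)
    extra_c, extra_p = fold_order[:r_c], fold_order[r_c:r_c + r_p]
    if r_c + r_p > k:  # disjointness infeasible; wrap around
        extra_p = np.concatenate([fold_order[r_c:], fold_order[: r_c + r_p - k]])

    def assign(n: int, extras: np.ndarray) -> np.ndarray:
        folds = np.concatenate([np.repeat(np.arange(k), n // k), extras]).astype(int)
        return rng.permutation(folds)

    return FoldAssignment(assign(n_controls, extra_c), assign(n_patients, extra_p), k)


@dataclass
class FeatureSet:
    name: str
    matrix: pd.DataFrame  # subjects x features
    provenance: str

    def __post_init__(self) -> None:
        if self.matrix.isna().any().any():
            raise ValueError(f"feature set {self.name!r} contains missing values")


def _parse_spec(spec: str) -> tuple[str, list[str], str, bool]:
    with_summaries = spec.endswith("+summaries")
    body = spec.removesuffix("+summaries")
    parts = body.split(":")
    if len(parts) != 3 or parts[0] not in ("raw", "z"):
        raise ValueError(
            f"feature spec must be '<raw|z>:<modalities>:<roi|all>', got {spec!r}"
        )
    kind, mods, roi = parts
    return kind, mods.split("+"), roi, with_summaries


def build_feature_set(
    cohort: Cohort,
    zscores: dict[str, pd.DataFrame] | None,
    summaries: dict[str, pd.DataFrame] | None,
    spec: str,
    ids: pd.Index | None = None,
) -> FeatureSet:
    """Assemble the subjects x features matrix named by ``spec``.

    Column order is deterministic: modalities in the order listed in the
    spec, ROIs in cohort canonical order within each modality, summary
    measures appended last (first listed modality).
    """
    kind, mods, roi, with_summaries = _parse_spec(spec)
    ids = cohort.subjects["id"] if ids is None else pd.Index(ids)
    blocks = []
    for mod in mods:
        source = cohort.measures[mod] if kind == "raw" else zscores[mod]
        missing = [i for i in ids if i not in source.index]
        if missing:
            raise ValueError(f"ids missing from {kind}:{mod} table: {missing[:3]}...")
        cols = cohort.roi_names if roi == "all" else [roi]
        block = source.loc[ids, cols]
        block.columns = [f"{kind}:{mod}:{c}" for c in cols]
        blocks.append(block)
    if with_summaries:
        if summaries is None:
            raise ValueError(f"spec {spec!r} needs summary tables")
        block = summaries[mods[0]].loc[ids]
        block.columns = [f"summary:{mods[0]}:{c}" for c in block.columns]
        blocks.append(block)
    matrix = pd.concat(blocks, axis=1)
    provenance = "combined" if with_summaries else kind
    return FeatureSet(spec, matrix, provenance)


@dataclass
class RidgeLogisticModel:
    """L2-penalized logistic fit on train-standardized features."""

    coef: np.ndarray          # on the standardized scale
    intercept: float
    feature_means: np.ndarray
    feature_scales: np.ndarray
    feature_names: list[str]

    def decision(self, X: np.ndarray) -> np.ndarray:
        Xs = (X - self.feature_means) / self.feature_scales
        return Xs @ self.coef + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the patient (positive) class."""
        return 1.0 / (1.0 + np.exp(-self.decision(np.asarray(X, float))))


def fit_l2_logistic(
    X, y, lam: float = 1.0, feature_names: list[str] | None = None,
    max_iter: int = 2000, tol: float = 1e-10,
) -> RidgeLogisticModel:
    """Minimize sum of logistic losses + (lam/2)*||w||^2, intercept unpenalized.

    Features are standardized to zero mean / unit SD using the training
    statistics (constant columns get scale 1). Deterministic given inputs.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("y must contain both classes, coded 0/1")
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales[scales == 0.0] = 1.0
    Xs = (X - means) / scales
    C = 1.0 / lam if lam > 0 else 1e12
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=max_iter, tol=tol)
    clf.fit(Xs, y)
    if int(np.max(clf.n_iter_)) >= max_iter:
        raise RuntimeError(
            f"ridge logistic fit did not converge in {max_iter} iterations "
            f"(n={X.shape[0]}, p={X.shape[1]}, lambda={lam})"
        )
    names = feature_names or [f"x{i}" for i in range(X.shape[1])]
    return RidgeLogisticModel(clf.coef_.ravel().copy(), float(clf.intercept_[0]),
                              means, scales, names)


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(random patient scores above random control),
    ties counted 1/2. ``labels`` are 0 (control) / 1 (patient)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("auc needs both classes present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class CVResult:
    """Cross-validated performance of one feature set."""

    name: str
    fold_aucs: np.ndarray
    coefficients: list[pd.Series] = field(repr=False)
    seed: int = 0

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    def mean_coefficients(self) -> pd.Series:
        return pd.concat(self.coefficients, axis=1).mean(axis=1)


def _needed_modalities(specs: list[str]) -> tuple[set[str], set[str], bool]:
    z_mods: set[str] = set()
    raw_mods: set[str] = set()
    any_summaries = False
    for spec in specs:
        kind, mods, _, with_summaries = _parse_spec(spec)
        (z_mods if kind == "z" else raw_mods).update(mods)
        if with_summaries:
            z_mods.update(mods[:1])
            any_summaries = True
    return z_mods, raw_mods, any_summaries


def _fold_zscores(
    cohort: Cohort, train_ids: pd.Index, test_ids: pd.Index, modality: str,
    grid, n_rois: int, alpha: float, want_summaries: bool,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-fold z-scores (and summaries) with training-only normative fits."""
    train = cohort.subset(train_ids)
    curves = normative.fit_all_curves(train, modality, grid)
    z_train_controls = normative.zscores_controls_loo(train, modality, curves=curves)
    z_train_patients = normative.zscores_patients(train, curves, modality)
    test = cohort.subset(test_ids)
    z_test = pd.concat([
        normative.zscores_patients(test, curves, modality, group=g)
        for g in ("control", "patient")
    ])
    z_all = pd.concat([z_train_controls, z_train_patients, z_test])
    if not want_summaries:
        return z_all, None
    threshold = bonferroni_z_threshold(n_rois, alpha)
    dens_c = density_matrix(z_train_controls)
    dens_p = density_matrix(z_train_patients)
    sig = significant_range(dens_c, dens_p, alpha, modality)
    return z_all, summary_table(z_all, threshold, sig)


def cross_validate(
    cohort: Cohort,
    specs: str | list[str],
    k: int = 10,
    lam: float = 1.0,
    seed: int = 0,
    grid=None,
    alpha: float = 0.05,
) -> CVResult | dict[str, CVResult]:
    """k-fold CV of one or several feature sets with per-fold normative refits.

    Passing several specs shares the (expensive) per-fold normative fits
    across feature sets, so every classifier is evaluated on identical folds.
    Returns a single CVResult for a string spec, else a dict keyed by spec.
    """
    single = isinstance(specs, str)
    spec_list = [specs] if single else list(specs)
    # sorted ids make the fold assignment invariant to subject row order
    ctrl_ids = pd.Index(sorted(cohort.ids(group="control")))
    pat_ids = pd.Index(sorted(cohort.ids(group="patient")))
    folds = make_folds(len(ctrl_ids), len(pat_ids), k, seed)
    z_mods, _raw_mods, want_summaries = _needed_modalities(spec_list)
    n_rois = len(cohort.roi_names)

    fold_aucs = {s: [] for s in spec_list}
    fold_coefs: dict[str, list[pd.Series]] = {s: [] for s in spec_list}
    labels_all = cohort.subjects.set_index("id")["group"].eq("patient").astype(int)

    for f in range(k):
        test_ids = pd.Index(
            np.concatenate([
                np.asarray(ctrl_ids)[folds.control_folds == f],
                np.asarray(pat_ids)[folds.patient_folds == f],
            ])
        )
        train_ids = pd.Index(
            np.concatenate([
                np.asarray(ctrl_ids)[folds.control_folds != f],
                np.asarray(pat_ids)[folds.patient_folds != f],
            ])
        )
        zscores: dict[str, pd.DataFrame] = {}
        summaries: dict[str, pd.DataFrame] = {}
        for mod in sorted(z_mods):
            z_all, summ = _fold_zscores(
                cohort, train_ids, test_ids, mod, grid, n_rois, alpha,
                want_summaries,
            )
            zscores[mod] = z_all
            if summ is not None:
                summaries[mod] = summ
        for spec in spec_list:
            fs_train = build_feature_set(cohort, zscores, summaries or None,
                                         spec, ids=train_ids)
            fs_test = build_feature_set(cohort, zscores, summaries or None,
                                        spec, ids=test_ids)
            model = fit_l2_logistic(
                fs_train.matrix.to_numpy(), labels_all.loc[train_ids].to_numpy(),
                lam, feature_names=list(fs_train.matrix.columns),
            )
            probs = model.predict_proba(fs_test.matrix.to_numpy())
            fold_aucs[spec].append(auc(probs, labels_all.loc[test_ids].to_numpy()))
            fold_coefs[spec].append(pd.Series(model.coef, index=model.feature_names))

    results = {
        s: CVResult(s, np.asarray(fold_aucs[s]), fold_coefs[s], seed)
        for s in spec_list
    }
    return results[spec_list[0]] if single else results


def sex_stratified_cv(
    cohort: Cohort, specs: str | list[str], k: int = 10, lam: float = 1.0,
    seed: int = 0, grid=None, alpha: float = 0.05,
) -> dict[str, CVResult | dict[str, CVResult]]:
    """Run :func:`cross_validate` separately within each sex."""
    out = {}
    for sex in ("M", "F"):
        ids = cohort.ids(sex=sex)
        sub = cohort.subset(ids)
        n_c = len(sub.ids(group="control"))
        n_p = len(sub.ids(group="patient"))
        if n_c < k or n_p < k:
            raise ValueError(
                f"sex {sex}: need >= k={k} subjects per group, got {n_c}/{n_p}"
            )
        out[sex] = cross_validate(sub, specs, k, lam, seed, grid, alpha)
    return out
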