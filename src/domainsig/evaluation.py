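"""Performance metrics and nested cross-validation for threshold tuning.

The positive class throughout is the *poor* outcome: a true positive is
a poor-outcome patient predicted poor. The signature-selection
threshold ``c`` is the only tuned hyperparameter; it is chosen inside
each training portion by leave-one-out cross-validation (LOOCV) and
then validated on the held-out portion, either over 5 stratified outer
folds (``nested_cv``) or by outer LOOCV for small cohorts (``loocv``).

Signature selection and feature construction are label-free (they use
only the interactome and expression values), so they are computed once
per threshold; class labels enter only the naïve Bayes fits, which are
restricted to training patients. All fits are routed through
:func:`_fit_for_patients`, which takes the explicit patient-id list —
tests hook it to verify that held-out patients never leak into a fit.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import naive_bayes as nb
from .expression import GOOD, POOR, FeatureMatrix, PatientCohort, patient_features
from .naive_bayes import Prediction
from .network import InteractomeBundle, ScoreConfig, score_all, select_signatures

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = tuple(range(10, 151, 10))


@dataclass
class ConfusionMetrics:
    """Confusion counts with accuracy / sensitivity / specificity.

    Undefined ratios (empty denominator) are reported as None rather
    than coerced to 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float | None:
        return (self.tp + self.tn) / self.total if self.total else None

    @property
    def sensitivity(self) -> float | None:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def specificity(self) -> float | None:
        denom = self.tn + self.fp
        return self.tn / denom if denom else None


@dataclass
class FoldResult:
    """One outer fold: tuned threshold, held-out patients, their metrics."""

    chosen_c: float
    test_patients: list[str]
    metrics: ConfusionMetrics


@dataclass
class CVResult:
    """Cross-validation outcome: per-fold results plus pooled metrics."""

    folds: list[FoldResult]
    pooled: ConfusionMetrics
    predictions: list[Prediction]
    roc: list[tuple[float, float]]
    auc: float
    seed: int


def confusion(
    predictions: list[Prediction], labels: dict[str, str]
) -> ConfusionMetrics:
    """Confusion counts with poor outcome as the positive class."""
    if not predictions:
        raise ValueError("no predictions to score")
    tp = fp = tn = fn = 0
    for pred in predictions:
        truth = labels[pred.patient]
        if truth == POOR:
            if pred.predicted == POOR:
                tp += 1
            else:
                fn += 1
        else:
            if pred.predicted == GOOD:
                tn += 1
            else:
                fp += 1
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def roc_auc(
    posteriors: dict[str, float], labels: dict[str, str]
) -> tuple[list[tuple[float, float]], float]:
    """ROC curve and trapezoidal AUC of poor-outcome posteriors.

    ``posteriors`` maps patient -> posterior probability of the poor
    outcome. Equal scores are grouped by the threshold sweep.
    """
    patients = sorted(posteriors)
    y_true = np.array([1 if labels[p] == POOR else 0 for p in patients])
    if y_true.min() == y_true.max():
        raise ValueError("ROC requires both outcome classes")
    scores = np.array([posteriors[p] for p in patients])
    fpr, tpr, _ = _sk_roc_curve(y_true, scores, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_sk_auc(fpr, tpr))


def _stratified_folds(
    patients: list[str], labels: dict[str, str], n_folds: int, seed: int
) -> list[list[str]]:
    """Seeded stratified partition of patients into ``n_folds`` test sets."""
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for cls in (GOOD, POOR):
        members = [p for p in patients if labels[p] == cls]
        if len(members) < n_folds:
            raise ValueError(
                f"class {cls!r} has {len(members)} patients; "
                f"cannot stratify into {n_folds} folds"
            )
        order = rng.permutation(len(members))
        for i, j in enumerate(order):
            folds[i % n_folds].append(members[j])
    return [sorted(f) for f in folds]


@dataclass(eq=False)
class _PreparedFeatures:
    """Label-free per-threshold feature columns shared by all folds."""

    features: FeatureMatrix
    binned: np.ndarray
    columns_by_c: dict[float, list[int]]
    row_index: dict[str, int]


def _prepare_features(
    bundle: InteractomeBundle,
    cohort: PatientCohort,
    c_grid: list[float],
    cfg: ScoreConfig,
    use_mutations: bool,
    mode: str,
) -> _PreparedFeatures:
    reports = score_all(bundle, cfg)
    sigs_by_c: dict[float, set[str]] = {}
    for c in sorted(set(c_grid)):
        sigs = select_signatures(
            reports, dataclasses.replace(cfg, threshold_c=c), use_mutations
        )
        if not sigs:
            logger.info("threshold c=%s selects no signature; skipped", c)
            continue
        sigs_by_c[c] = sigs
    if not sigs_by_c:
        raise ValueError("no threshold in the grid selects any signature")
    union = sorted(set().union(*sigs_by_c.values()))
    features = patient_features(union, bundle, cohort, mode=mode)
    kept = set(features.signatures)
    columns_by_c: dict[float, list[int]] = {}
    col = {s: j for j, s in enumerate(features.signatures)}
    for c, sigs in sigs_by_c.items():
        usable = sorted(sigs & kept)
        if not usable:
            logger.info("threshold c=%s has no usable signature features; skipped", c)
            continue
        columns_by_c[c] = [col[s] for s in usable]
    if not columns_by_c:
        raise ValueError("no threshold in the grid yields usable features")
    binned = nb.discretize_matrix(features.values)
    row_index = {p: i for i, p in enumerate(features.patients)}
    return _PreparedFeatures(
        features=features, binned=binned, columns_by_c=columns_by_c,
        row_index=row_index,
    )


def _fit_for_patients(
    prep: _PreparedFeatures,
    fit_patient_ids: list[str],
    columns: list[int],
    labels: dict[str, str],
    alpha: float,
) -> nb.NBModel:
    """Fit the naïve Bayes on exactly the named patients.

    The explicit patient-id list is the leakage boundary: everything a
    fit sees is derived from these rows only.
    """
    rows = [prep.row_index[p] for p in fit_patient_ids]
    binned = prep.binned[np.ix_(rows, columns)]
    y = np.array([nb.CLASSES.index(labels[p]) for p in fit_patient_ids])
    sig_names = [prep.features.signatures[j] for j in columns]
    return nb.fit_binned(binned, y, sig_names, alpha=alpha)


def _predict_patient(
    prep: _PreparedFeatures, model: nb.NBModel, patient: str, columns: list[int]
) -> Prediction:
    bins = prep.binned[prep.row_index[patient], columns]
    return nb.predict_binned(model, bins, patient=patient)


def _inner_loocv_accuracy(
    prep: _PreparedFeatures,
    train: list[str],
    columns: list[int],
    labels: dict[str, str],
    alpha: float,
) -> float | None:
    """LOOCV accuracy of the classifier at one threshold, or None if
    any leave-one-out split empties a class."""
    correct = 0
    for held in train:
        rest = [p for p in train if p != held]
        if len({labels[p] for p in rest}) < 2:
            return None
        model = _fit_for_patients(prep, rest, columns, labels, alpha)
        pred = _predict_patient(prep, model, held, columns)
        if pred.predicted == labels[held]:
            correct += 1
    return correct / len(train)


def _tune_c(
    prep: _PreparedFeatures,
    train: list[str],
    labels: dict[str, str],
    alpha: float,
) -> float:
    """Pick the threshold maximizing inner LOOCV accuracy (ties -> smallest c)."""
    best_c: float | None = None
    best_acc = -1.0
    for c in sorted(prep.columns_by_c):
        acc = _inner_loocv_accuracy(prep, train, prep.columns_by_c[c], labels, alpha)
        if acc is None:
            logger.info("threshold c=%s skipped in tuning (degenerate split)", c)
            continue
        if acc > best_acc:
            best_acc, best_c = acc, c
    if best_c is None:
        raise ValueError("threshold tuning failed for every c in the grid")
    return best_c


def _run_protocol(
    bundle: InteractomeBundle,
    cohort: PatientCohort,
    test_sets: list[list[str]],
    c_grid: list[float],
    cfg: ScoreConfig,
    use_mutations: bool,
    alpha: float,
    mode: str,
    seed: int,
) -> CVResult:
    prep = _prepare_features(bundle, cohort, list(c_grid), cfg, use_mutations, mode)
    labels = cohort.labels
    all_patients = list(cohort.patients)
    folds: list[FoldResult] = []
    predictions: list[Prediction] = []
    for test in test_sets:
        test_set = set(test)
        train = [p for p in all_patients if p not in test_set]
        chosen_c = _tune_c(prep, train, labels, alpha)
        columns = prep.columns_by_c[chosen_c]
        model = _fit_for_patients(prep, train, columns, labels, alpha)
        fold_preds = [_predict_patient(prep, model, p, columns) for p in test]
        predictions.extend(fold_preds)
        folds.append(
            FoldResult(
                chosen_c=chosen_c,
                test_patients=list(test),
                metrics=confusion(fold_preds, labels),
            )
        )
    pooled = confusion(predictions, labels)
    posteriors = {p.patient: 1.0 - p.posterior_good for p in predictions}
    roc, auc_value = roc_auc(posteriors, labels)
    return CVResult(
        folds=folds,
        pooled=pooled,
        predictions=predictions,
        roc=roc,
        auc=auc_value,
        seed=seed,
    )


def nested_cv(
    bundle: InteractomeBundle,
    cohort: PatientCohort,
    c_grid: list[float] | tuple[float, ...] = DEFAULT_C_GRID,
    use_mutations: bool = False,
    seed: int = 0,
    alpha: float = 1.0,
    cfg: ScoreConfig | None = None,
    n_folds: int = 5,
    mode: str = "rank",
) -> CVResult:
    """Five-fold nested cross-validation with inner LOOCV threshold tuning.

    Patients are split into ``n_folds`` seeded stratified outer folds.
    Within each 80% training portion, every threshold ``c`` in the grid
    is scored by LOOCV accuracy of the full pipeline (signatures at c ->
    features -> naïve Bayes); the best ``c`` (smallest on ties) is used
    to train on the whole portion and predict the held-out 20%. Fold
    predictions are pooled into overall metrics and a ROC curve.
    """
    cfg = cfg or ScoreConfig()
    if len(cohort.patients) < 10:
        raise ValueError("nested CV requires at least 10 patients")
    test_sets = _stratified_folds(cohort.patients, cohort.labels, n_folds, seed)
    return _run_protocol(
        bundle, cohort, test_sets, list(c_grid), cfg, use_mutations, alpha, mode, seed
    )


def loocv(
    bundle: InteractomeBundle,
    cohort: PatientCohort,
    c_grid: list[float] | tuple[float, ...] = DEFAULT_C_GRID,
    use_mutations: bool = False,
    seed: int = 0,
    alpha: float = 1.0,
    cfg: ScoreConfig | None = None,
    mode: str = "rank",
) -> CVResult:
    """Outer leave-one-out CV for small cohorts (quadratic in n).

    Each patient is held out once; the threshold is tuned by inner
    LOOCV on the remaining n−1 patients with the same rule as
    :func:`nested_cv`, and the held-out patient is predicted. Pooled
    metrics cover all n out-of-fold predictions.
    """
    cfg = cfg or ScoreConfig()
    counts = {cls: sum(1 for p in cohort.patients if cohort.labels[p] == cls)
              for cls in (GOOD, POOR)}
    if min(counts.values()) < 2:
        raise ValueError("LOOCV requires at least 2 patients per class")
    test_sets = [[p] for p in cohort.patients]
    return _run_protocol(
        bundle, cohort, test_sets, list(c_grid), cfg, use_mutations, alpha, mode, seed
    )
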