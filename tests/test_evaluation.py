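"""Confusion metrics, ROC/AUC and the cross-validation protocols."""

import itertools

import numpy as np
import pytest

import domainsig.evaluation as evaluation
from domainsig import (
    Prediction,
    SimConfig,
    confusion,
    loocv,
    nested_cv,
    roc_auc,
    simulate_bundle,
    simulate_cohort,
)

from conftest import make_star_bundle


def _preds(pred_labels):
    return [
        Prediction(patient=f"pt{i}", predicted=l, scores={}, posterior_good=0.5)
        for i, l in enumerate(pred_labels)
    ]


def _labels(true_labels):
    return {f"pt{i}": l for i, l in enumerate(true_labels)}


class TestConfusion:
    def test_printed_formula_example(self):
        # tp=2, tn=3, fp=1, fn=0
        preds = _preds(["poor", "poor", "good", "good", "good", "poor"])
        labels = _labels(["poor", "poor", "good", "good", "good", "good"])
        m = confusion(preds, labels)
        assert (m.tp, m.fp, m.tn, m.fn) == (2, 1, 3, 0)
        assert m.accuracy == pytest.approx(5 / 6)
        assert m.sensitivity == pytest.approx(1.0)
        assert m.specificity == pytest.approx(0.75)

    def test_perfect_classifier(self):
        labels = ["poor", "good", "poor", "good"]
        m = confusion(_preds(labels), _labels(labels))
        assert m.accuracy == m.sensitivity == m.specificity == 1.0

    def test_undefined_sensitivity_reported_absent(self):
        m = confusion(_preds(["good", "good"]), _labels(["good", "good"]))
        assert m.sensitivity is None
        assert m.specificity == 1.0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            confusion([], {})

    def test_all_81_small_matrices_match_hand_formulas(self):
        """Metrics agree with the closed-form definitions for every
        confusion matrix with entries in 0..2."""
        for tp, fp, tn, fn in itertools.product(range(3), repeat=4):
            truth, predicted = [], []
            truth += ["poor"] * tp; predicted += ["poor"] * tp
            truth += ["good"] * fp; predicted += ["poor"] * fp
            truth += ["good"] * tn; predicted += ["good"] * tn
            truth += ["poor"] * fn; predicted += ["good"] * fn
            if not truth:
                continue
            m = confusion(_preds(predicted), _labels(truth))
            assert (m.tp, m.fp, m.tn, m.fn) == (tp, fp, tn, fn)
            assert m.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn))
            if tp + fn:
                assert m.sensitivity == pytest.approx(tp / (tp + fn))
            else:
                assert m.sensitivity is None
            if tn + fp:
                assert m.specificity == pytest.approx(tn / (tn + fp))
            else:
                assert m.specificity is None


class TestRocAuc:
    def test_perfect_separation(self):
        post = {"a": 0.9, "b": 0.8, "c": 0.2, "d": 0.1}
        labels = {"a": "poor", "b": "poor", "c": "good", "d": "good"}
        _, a = roc_auc(post, labels)
        assert a == 1.0

    def test_hand_ranked_sweep(self):
        post = {"a": 0.9, "b": 0.8, "c": 0.3}
        labels = {"a": "poor", "b": "good", "c": "good"}
        _, a = roc_auc(post, labels)
        assert a == pytest.approx(1.0)

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(0)
        n = 2000
        post = {f"p{i}": float(rng.random()) for i in range(n)}
        labels = {p: ("poor" if rng.random() < 0.5 else "good") for p in post}
        _, a = roc_auc(post, labels)
        # AUC of independent scores ~ 0.5 with SE ~ 1/sqrt(12 * n/2)
        assert abs(a - 0.5) < 3 / np.sqrt(12 * n / 2)

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc({"a": 0.4, "b": 0.6}, {"a": "good", "b": "good"})

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        post = {f"p{i}": float(rng.random()) for i in range(50)}
        labels = {p: ("poor" if rng.random() < 0.4 else "good") for p in post}
        _, a1 = roc_auc(post, labels)
        _, a2 = roc_auc({p: v**3 for p, v in post.items()}, labels)
        assert a1 == pytest.approx(a2)


def _sim(seed=0, **kw):
    kw = {
        "n_proteins": 60,
        "n_domains": 30,
        "n_singlish_hubs": 3,
        "hub_degree": 6,
        "n_patients_good": 14,
        "n_patients_poor": 10,
        **kw,
    }
    cfg = SimConfig(seed=seed, **kw)
    bundle, truth = simulate_bundle(cfg)
    cohort = simulate_cohort(bundle, truth, cfg)
    return bundle, cohort


class TestNestedCV:
    def test_planted_signal_is_separable(self):
        bundle, cohort = _sim(
            seed=2, effect_delta=1.0, noise_sigma=0.001,
            n_singlish_hubs=5, n_patients_good=18, n_patients_poor=12,
        )
        res = nested_cv(bundle, cohort, c_grid=[50], seed=2)
        assert res.pooled.accuracy == 1.0
        assert res.auc == 1.0

    def test_folds_partition_cohort(self):
        bundle, cohort = _sim(seed=3)
        res = nested_cv(bundle, cohort, c_grid=[50], seed=3)
        seen = [p for f in res.folds for p in f.test_patients]
        assert sorted(seen) == sorted(cohort.patients)
        # stratification: both classes in every fold
        for f in res.folds:
            fold_labels = {cohort.labels[p] for p in f.test_patients}
            assert fold_labels == {"good", "poor"}

    def test_determinism_per_seed(self):
        bundle, cohort = _sim(seed=4)
        r1 = nested_cv(bundle, cohort, c_grid=[30, 50], seed=11)
        r2 = nested_cv(bundle, cohort, c_grid=[30, 50], seed=11)
        assert [f.test_patients for f in r1.folds] == [
            f.test_patients for f in r2.folds
        ]
        assert [f.chosen_c for f in r1.folds] == [f.chosen_c for f in r2.folds]
        assert r1.pooled == r2.pooled and r1.auc == r2.auc

    def test_permuted_labels_near_majority_rate(self):
        bundle, cohort = _sim(seed=5, effect_delta=0.0)
        res = nested_cv(bundle, cohort, c_grid=[50], seed=5)
        n = len(cohort.patients)
        majority = 14 / n
        se = np.sqrt(majority * (1 - majority) / n)
        assert abs(res.pooled.accuracy - majority) <= 3 * se + 1e-12

    def test_no_signature_threshold_errors(self):
        bundle, cohort = _sim(seed=6)
        with pytest.raises(ValueError):
            nested_cv(bundle, cohort, c_grid=[1e9], seed=6)

    def test_test_patients_never_enter_fits(self, monkeypatch):
        """Leakage guard: every NB fit sees only training patients."""
        bundle, cohort = _sim(seed=7)
        real_fit = evaluation._fit_for_patients
        fits: list[set] = []

        def spy(prep, fit_patient_ids, columns, labels, alpha):
            fits.append(set(fit_patient_ids))
            return real_fit(prep, fit_patient_ids, columns, labels, alpha)

        monkeypatch.setattr(evaluation, "_fit_for_patients", spy)
        res = nested_cv(bundle, cohort, c_grid=[50], seed=7)
        assert fits
        # fits happen fold by fold: with a single c, each fold performs
        # |train| inner-LOOCV fits followed by one final fit on the train set
        n = len(cohort.patients)
        pos = 0
        for fold in res.folds:
            test = set(fold.test_patients)
            n_train = n - len(test)
            segment = fits[pos: pos + n_train + 1]
            pos += n_train + 1
            assert len(segment) == n_train + 1
            for fitted in segment:
                assert not (fitted & test), "held-out patient entered a fit"
            assert segment[-1] == set(cohort.patients) - test
        assert pos == len(fits)


class TestLOOCV:
    def test_matches_manual_fold_enumeration(self):
        """Pooled confusion equals n independent fit/predict runs."""
        bundle, cohort = _sim(seed=8, n_patients_good=4, n_patients_poor=4)
        res = loocv(bundle, cohort, c_grid=[50], seed=8)
        # manual: for each patient, fit on the rest, predict it
        import domainsig.naive_bayes as nb
        from domainsig import patient_features, score_all, select_signatures, ScoreConfig

        cfg = ScoreConfig(threshold_c=50)
        sigs = sorted(select_signatures(score_all(bundle, cfg), cfg))
        fm = patient_features(sigs, bundle, cohort)
        manual = {}
        for i, p in enumerate(cohort.patients):
            rest = [q for q in cohort.patients if q != p]
            rest_idx = [fm.patients.index(q) for q in rest]
            sub = nb.fit_binned(
                nb.discretize_matrix(fm.values[rest_idx]),
                np.array([nb.CLASSES.index(cohort.labels[q]) for q in rest]),
                fm.signatures,
            )
            manual[p] = nb.predict(sub, fm.values[i], patient=p).predicted
        for pred in res.predictions:
            assert pred.predicted == manual[pred.patient]

    def test_perfect_signal_accuracy_one(self):
        bundle, cohort = _sim(
            seed=9, effect_delta=1.0, noise_sigma=0.001,
            n_singlish_hubs=5, n_patients_good=8, n_patients_poor=6,
        )
        res = loocv(bundle, cohort, c_grid=[50], seed=9)
        assert res.pooled.accuracy == 1.0

    def test_constant_features_predict_majority(self):
        """Identical feature vectors with mixed labels -> constant
        prediction, accuracy = majority fraction."""
        bundle, truth = simulate_bundle(
            SimConfig(n_proteins=30, n_domains=20, n_singlish_hubs=1,
                      hub_degree=4, seed=10)
        )
        cfg = SimConfig(n_proteins=30, n_domains=20, n_singlish_hubs=1,
                        hub_degree=4, seed=10,
                        n_patients_good=5, n_patients_poor=3)
        cohort = simulate_cohort(bundle, truth, cfg)
        # overwrite expression so every patient is identical
        cohort.values[:] = cohort.values[:, [0]]
        res = loocv(bundle, cohort, c_grid=[10], seed=10)
        predicted = {p.predicted for p in res.predictions}
        assert len(predicted) == 1
        # in LOOCV the majority among the remaining n-1 is still "good"
        assert res.pooled.accuracy == pytest.approx(5 / 8)

    def test_too_few_per_class_errors(self):
        bundle, cohort = _sim(seed=11, n_patients_good=4, n_patients_poor=1)
        with pytest.raises(ValueError):
            loocv(bundle, cohort, c_grid=[50], seed=11)
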