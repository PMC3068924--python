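"""Binned naïve Bayes classifier for good- vs poor-outcome prediction.

Features are per-patient co-expression-difference values in [0, 1],
discretized into 20 equal-width bins. Class priors are empirical
training frequencies (P(C) = X_C / X) and per-signature bin likelihoods
are (optionally Laplace-smoothed) empirical bin frequencies. Prediction
is the MAP rule on P(x|C)P(C), computed in log space with log-sum-exp
normalization so that products over many signatures never underflow.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .expression import FeatureMatrix, GOOD, POOR

logger = logging.getLogger(__name__)

N_BINS = 20
CLASSES = (GOOD, POOR)

_SERIAL_VERSION = 1


def discretize(value: float) -> int:
    """Bin a feature value into one of 20 half-open bins [k/20, (k+1)/20).

    1.0 falls into the last bin (19). Values outside [0, 1] are clamped
    with a warning; non-finite input is an error.
    """
    if not math.isfinite(value):
        raise ValueError(f"cannot discretize non-finite value {value!r}")
    if value < 0.0 or value > 1.0:
        logger.warning("feature value %s outside [0, 1]; clamped", value)
        value = min(max(value, 0.0), 1.0)
    return min(int(value * N_BINS), N_BINS - 1)


def discretize_matrix(values: np.ndarray) -> np.ndarray:
    """Vectorized :func:`discretize` over an array of feature values."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("cannot discretize non-finite values")
    if values.size and (values.min() < 0.0 or values.max() > 1.0):
        logger.warning("feature values outside [0, 1]; clamped")
        values = np.clip(values, 0.0, 1.0)
    return np.minimum((values * N_BINS).astype(int), N_BINS - 1)


@dataclass(eq=False)
class NBModel:
    """Fitted naïve Bayes model.

    ``likelihoods`` has shape (2 classes, n signatures, 20 bins); class
    axis order follows :data:`CLASSES` = ("good", "poor").
    """

    signatures: list[str]
    priors: np.ndarray
    likelihoods: np.ndarray
    alpha: float
    class_counts: np.ndarray
    classes: tuple[str, str] = CLASSES

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=float)
        self.likelihoods = np.asarray(self.likelihoods, dtype=float)
        self.class_counts = np.asarray(self.class_counts, dtype=int)
        if self.priors.shape != (2,) or not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must be a length-2 vector summing to 1")
        if self.likelihoods.shape != (2, len(self.signatures), N_BINS):
            raise ValueError("likelihood table shape mismatch")
        if np.any(self.likelihoods < 0):
            raise ValueError("negative likelihood")
        if self.likelihoods.size and not np.allclose(
            self.likelihoods.sum(axis=2), 1.0, atol=1e-9
        ):
            raise ValueError("each 20-bin likelihood vector must sum to 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    def prior(self, cls: str) -> float:
        return float(self.priors[self.classes.index(cls)])

    def to_json(self) -> str:
        payload = {
            "format_version": _SERIAL_VERSION,
            "classes": list(self.classes),
            "signatures": list(self.signatures),
            "n_bins": N_BINS,
            "alpha": self.alpha,
            "priors": self.priors.tolist(),
            "class_counts": self.class_counts.tolist(),
            "likelihoods": self.likelihoods.tolist(),
        }
        return json.dumps(payload, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NBModel":
        payload = json.loads(text)
        if payload.get("format_version") != _SERIAL_VERSION:
            raise ValueError(
                f"unsupported model format version {payload.get('format_version')!r}"
            )
        if payload.get("n_bins") != N_BINS:
            raise ValueError("model was fitted with a different bin count")
        return cls(
            signatures=list(payload["signatures"]),
            priors=np.array(payload["priors"]),
            likelihoods=np.array(payload["likelihoods"]),
            alpha=float(payload["alpha"]),
            class_counts=np.array(payload["class_counts"]),
            classes=tuple(payload["classes"]),
        )


@dataclass
class Prediction:
    """MAP prediction for one patient with log-posterior diagnostics."""

    patient: str
    predicted: str
    scores: dict[str, float]
    posterior_good: float


def fit_binned(
    binned: np.ndarray, y: np.ndarray, signatures: list[str], alpha: float = 1.0
) -> NBModel:
    """Fit from a pre-discretized (patients x signatures) bin matrix.

    ``y`` holds class indices (0 = good, 1 = poor). Likelihoods follow
    the Laplace rule (count + alpha) / (X_C + 20·alpha); alpha = 0 gives
    the plain empirical frequency.
    """
    binned = np.asarray(binned, dtype=int)
    y = np.asarray(y, dtype=int)
    n_sig = len(signatures)
    if binned.shape != (y.size, n_sig):
        raise ValueError("binned matrix shape does not match labels/signatures")
    class_counts = np.array([(y == 0).sum(), (y == 1).sum()])
    if (class_counts == 0).any():
        raise ValueError("each class needs at least one training patient")
    counts = np.zeros((2, n_sig, N_BINS))
    for c in (0, 1):
        rows = binned[y == c]
        for s in range(n_sig):
            counts[c, s] = np.bincount(rows[:, s], minlength=N_BINS)
    denom = (class_counts + N_BINS * alpha).astype(float)
    likelihoods = (counts + alpha) / denom[:, None, None]
    priors = class_counts / class_counts.sum()
    return NBModel(
        signatures=list(signatures),
        priors=priors,
        likelihoods=likelihoods,
        alpha=alpha,
        class_counts=class_counts,
    )


def fit(
    features: FeatureMatrix, labels: dict[str, str], alpha: float = 1.0
) -> NBModel:
    """Fit the classifier from a feature matrix and outcome labels."""
    y = np.array(
        [CLASSES.index(labels[p]) for p in features.patients], dtype=int
    )
    binned = discretize_matrix(features.values)
    return fit_binned(binned, y, features.signatures, alpha=alpha)


def predict_binned(
    model: NBModel, bins: np.ndarray, patient: str = ""
) -> Prediction:
    """MAP prediction from a pre-discretized feature vector."""
    bins = np.asarray(bins, dtype=int)
    if bins.shape != (len(model.signatures),):
        raise ValueError("feature vector does not cover the model's signatures")
    idx = np.arange(len(model.signatures))
    with np.errstate(divide="ignore"):
        log_prior = np.log(model.priors)
        log_lik = np.log(model.likelihoods[:, idx, bins])
    scores = log_prior + log_lik.sum(axis=1)
    if np.all(np.isneginf(scores)):
        logger.warning(
            "patient %s: zero probability under both classes; defaulting to good",
            patient,
        )
        return Prediction(
            patient=patient,
            predicted=GOOD,
            scores={GOOD: float("-inf"), POOR: float("-inf")},
            posterior_good=0.5,
        )
    norm = logsumexp(scores)
    posterior_good = float(np.exp(scores[0] - norm))
    predicted = GOOD if scores[0] >= scores[1] else POOR
    return Prediction(
        patient=patient,
        predicted=predicted,
        scores={GOOD: float(scores[0]), POOR: float(scores[1])},
        posterior_good=posterior_good,
    )


def predict(model: NBModel, features: np.ndarray, patient: str = "") -> Prediction:
    """MAP prediction from one patient's raw feature vector in [0, 1]."""
    bins = discretize_matrix(np.asarray(features, dtype=float).reshape(-1))
    return predict_binned(model, bins, patient=patient)


def predict_cohort(model: NBModel, features: FeatureMatrix) -> list[Prediction]:
    """Predict every patient in a feature matrix, aligning signatures."""
    col = {s: j for j, s in enumerate(features.signatures)}
    missing = [s for s in model.signatures if s not in col]
    if missing:
        raise ValueError(f"feature matrix lacks model signatures: {missing}")
    order = [col[s] for s in model.signatures]
    binned = discretize_matrix(features.values[:, order])
    return [
        predict_binned(model, binned[i], patient=p)
        for i, p in enumerate(features.patients)
    ]
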