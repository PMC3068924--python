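"""Co-expression scoring of gene signatures against their PPI neighborhood.

Two related quantities live here. The group-level *discrimination
score* of a signature measures how differently it co-expresses (Pearson
correlation across patients) with its network neighbors between the
good- and poor-outcome groups. The per-patient *feature* is the mean
absolute rank-scaled expression difference between the signature and
its neighbors within a single patient — the quantity the classifier
consumes, guaranteed to lie in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .network import InteractomeBundle

logger = logging.getLogger(__name__)

GOOD = "good"
POOR = "poor"


@dataclass(eq=False)
class PatientCohort:
    """Expression matrix (genes x patients) with binary outcome labels."""

    genes: list[str]
    patients: list[str]
    values: np.ndarray
    labels: dict[str, str]

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.patients = list(self.patients)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.patients)):
            raise ValueError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.patients)} patients"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.patients)) != len(self.patients):
            raise ValueError("duplicate patient identifiers")
        missing = [p for p in self.patients if p not in self.labels]
        if missing:
            raise ValueError(f"patients without outcome label: {missing}")
        bad = {p: l for p, l in self.labels.items() if l not in (GOOD, POOR)}
        if bad:
            raise ValueError(f"labels must be '{GOOD}' or '{POOR}', got {bad}")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    def gene_row(self, gene: str) -> np.ndarray:
        return self.values[self._gene_index[gene], :]

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    def group_columns(self, label: str) -> np.ndarray:
        """Column indices of patients with the given outcome label."""
        return np.array(
            [i for i, p in enumerate(self.patients) if self.labels[p] == label],
            dtype=int,
        )


@dataclass(eq=False)
class FeatureMatrix:
    """Patients x signatures matrix of per-patient features in [0, 1]."""

    patients: list[str]
    signatures: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.patients = list(self.patients)
        self.signatures = list(self.signatures)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patients), len(self.signatures)):
            raise ValueError(
                f"feature matrix shape {self.values.shape} does not match "
                f"{len(self.patients)} patients x {len(self.signatures)} signatures"
            )
        if self.values.size and (
            self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12
        ):
            raise ValueError("feature values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patients, columns=self.signatures)

    def row(self, patient: str) -> np.ndarray:
        return self.values[self.patients.index(patient), :]


@dataclass
class DiscriminationScore:
    """Group-level co-expression difference of a signature, in [0, 1]."""

    signature: str
    n_neighbors: int
    per_neighbor: dict[str, tuple[float, float]]
    score: float


def pearson(xs: np.ndarray, ys: np.ndarray) -> float:
    """Product-moment correlation of two vectors.

    Constant input yields NaN (flagged with a warning) — callers treat
    the pair as unusable rather than imputing a value.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise ValueError(f"length mismatch: {xs.shape} vs {ys.shape}")
    if xs.ndim != 1 or xs.size < 3:
        raise ValueError("pearson requires 1-d vectors of length >= 3")
    xd = xs - xs.mean()
    yd = ys - ys.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0.0:
        logger.warning("pearson undefined for constant vector; returning NaN")
        return float("nan")
    return float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))


def discrimination_score(
    signature: str, bundle: InteractomeBundle, cohort: PatientCohort
) -> DiscriminationScore:
    """Mean absolute good-vs-poor correlation difference over neighbors.

    score = (1 / 2n) Σ_i |r_good(x, p_i) − r_poor(x, p_i)| where the
    factor 1/2 maps the raw range [0, 2] onto [0, 1]. Neighbors missing
    from the expression matrix or with undefined correlation in either
    group are excluded (n shrinks accordingly).
    """
    if not cohort.has_gene(signature):
        raise ValueError(f"signature {signature!r} not measured in the cohort")
    good_cols = cohort.group_columns(GOOD)
    poor_cols = cohort.group_columns(POOR)
    if good_cols.size < 3 or poor_cols.size < 3:
        raise ValueError("each outcome group needs at least 3 patients")
    x = cohort.gene_row(signature)
    per_neighbor: dict[str, tuple[float, float]] = {}
    for nb in bundle.neighbors(signature):
        if not cohort.has_gene(nb):
            logger.warning("neighbor %s not in expression matrix; excluded", nb)
            continue
        y = cohort.gene_row(nb)
        r_good = pearson(x[good_cols], y[good_cols])
        r_poor = pearson(x[poor_cols], y[poor_cols])
        if np.isnan(r_good) or np.isnan(r_poor):
            logger.warning("neighbor %s has undefined correlation; excluded", nb)
            continue
        per_neighbor[nb] = (r_good, r_poor)
    n = len(per_neighbor)
    if n == 0:
        raise ValueError(f"signature {signature!r} has no usable neighbor")
    score = sum(abs(rg - rp) for rg, rp in per_neighbor.values()) / (2 * n)
    return DiscriminationScore(
        signature=signature, n_neighbors=n, per_neighbor=per_neighbor, score=score
    )


def rank_scale_patient(column: np.ndarray) -> np.ndarray:
    """Map one patient's expression column onto [0, 1] by average ranks.

    Genes are ranked ascending with ties averaged and scaled as
    (rank − 1)/(G − 1); an all-equal column maps to 0.5 everywhere.
    """
    column = np.asarray(column, dtype=float)
    if column.ndim != 1 or column.size < 2:
        raise ValueError("rank scaling requires at least 2 genes")
    ranks = rankdata(column, method="average")
    return (ranks - 1.0) / (column.size - 1.0)


def rank_scale_matrix(values: np.ndarray) -> np.ndarray:
    """Rank-scale every patient column of a genes x patients matrix."""
    values = np.asarray(values, dtype=float)
    ranks = rankdata(values, method="average", axis=0)
    return (ranks - 1.0) / (values.shape[0] - 1.0)


def _minmax_scale_matrix(values: np.ndarray) -> np.ndarray:
    """Per-patient min-max scaling onto [0, 1]; constant columns -> 0.5."""
    values = np.asarray(values, dtype=float)
    lo = values.min(axis=0, keepdims=True)
    hi = values.max(axis=0, keepdims=True)
    span = hi - lo
    out = np.full_like(values, 0.5)
    ok = (span > 0).ravel()
    out[:, ok] = (values[:, ok] - lo[:, ok]) / span[:, ok]
    return out


def patient_features(
    signatures: list[str],
    bundle: InteractomeBundle,
    cohort: PatientCohort,
    mode: str = "rank",
) -> FeatureMatrix:
    """Per-patient signature features: mean |ê(signature) − ê(neighbor)|.

    ``ê`` is the patient's rank-scaled expression (``mode="raw"``
    substitutes per-patient min-max scaling). Signatures absent from
    the expression matrix or without any measured neighbor are dropped
    with a warning; the result columns follow the surviving signature
    order.
    """
    if not signatures:
        raise ValueError("empty signature list")
    if mode == "rank":
        scaled = rank_scale_matrix(cohort.values)
    elif mode == "raw":
        scaled = _minmax_scale_matrix(cohort.values)
    else:
        raise ValueError(f"unknown feature mode {mode!r}")
    kept: list[str] = []
    cols: list[np.ndarray] = []
    gene_index = {g: i for i, g in enumerate(cohort.genes)}
    for sig in signatures:
        if sig not in gene_index:
            logger.warning("signature %s not measured; dropped", sig)
            continue
        nbr_rows = [
            gene_index[nb] for nb in bundle.neighbors(sig) if nb in gene_index
        ]
        if not nbr_rows:
            logger.warning("signature %s has no measured neighbor; dropped", sig)
            continue
        diffs = np.abs(scaled[nbr_rows, :] - scaled[gene_index[sig], :][None, :])
        kept.append(sig)
        cols.append(diffs.mean(axis=0))
    if not kept:
        raise ValueError("no signature has a usable neighborhood in this cohort")
    values = np.column_stack(cols)
    return FeatureMatrix(patients=cohort.patients, signatures=kept, values=values)
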