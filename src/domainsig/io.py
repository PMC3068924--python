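"""Readers, writers, run configuration and the end-to-end pipeline.

All tabular formats are plain TSV (UTF-8, tab-separated, ``#`` comment
lines, no quoting); identifiers are opaque case-sensitive strings.
The five inputs are: a 2-column PPI edge list, a 2-column
protein→domain annotation, a 2-column DDI catalog, a 2-column
domain→mutation-count table, and an expression matrix (first column
gene id, remaining columns patients) with a 2-column patient→label
file. Writers iterate in sorted order so outputs are byte-identical
across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import naive_bayes as nb
from .evaluation import DEFAULT_C_GRID, CVResult, loocv, nested_cv
from .expression import FeatureMatrix, PatientCohort, patient_features
from .network import (
    InteractomeBundle,
    ScoreConfig,
    canonical_pair,
    score_all,
    select_signatures,
)
from .simulate import GroundTruth, SimConfig

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input line, reported with file and line number."""


def _iter_rows(path: str | Path, n_cols: int):
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != n_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_cols} tab-separated fields, "
                    f"got {len(parts)}"
                )
            if any(not p.strip() for p in parts):
                raise ParseError(f"{path}:{lineno}: empty field")
            yield lineno, [p.strip() for p in parts]


def read_ppi(path: str | Path) -> tuple[set[tuple[str, str]], set[str]]:
    """Read a 2-column PPI edge list; dedupe and drop self-loops (logged)."""
    edges: set[tuple[str, str]] = set()
    proteins: set[str] = set()
    n_records = n_self = n_dup = 0
    for _, (a, b) in _iter_rows(path, 2):
        n_records += 1
        proteins.update((a, b))
        if a == b:
            n_self += 1
            continue
        pair = canonical_pair(a, b)
        if pair in edges:
            n_dup += 1
        edges.add(pair)
    if n_records == 0:
        raise ParseError(f"{path}: empty PPI file")
    logger.info(
        "read %d PPI records: %d edges kept, %d duplicates, %d self-loops dropped",
        n_records, len(edges), n_dup, n_self,
    )
    return edges, proteins


def read_annotation(path: str | Path) -> dict[str, set[str]]:
    """Read protein→domain rows into a protein→domain-set map."""
    annotation: dict[str, set[str]] = {}
    for _, (protein, domain) in _iter_rows(path, 2):
        annotation.setdefault(protein, set()).add(domain)
    return annotation


def read_ddi(path: str | Path) -> set[tuple[str, str]]:
    """Read the DDI catalog as canonical unordered domain pairs."""
    return {canonical_pair(a, b) for _, (a, b) in _iter_rows(path, 2)}


def read_mutations(path: str | Path) -> dict[str, int]:
    """Read domain→somatic-mutation-count rows."""
    counts: dict[str, int] = {}
    p = Path(path)
    for lineno, (domain, value) in _iter_rows(p, 2):
        try:
            c = int(value)
        except ValueError as exc:
            raise ParseError(f"{p}:{lineno}: non-integer count {value!r}") from exc
        if c < 0:
            raise ParseError(f"{p}:{lineno}: negative count {c}")
        counts[domain] = counts.get(domain, 0) + c
    return counts


def read_bundle(
    ppi_path: str | Path,
    annotation_path: str | Path,
    ddi_path: str | Path,
    mutations_path: str | Path | None = None,
) -> InteractomeBundle:
    """Assemble an :class:`InteractomeBundle` from the input files.

    Proteins appearing only in the annotation table are retained as
    isolated (degree-0) nodes.
    """
    edges, proteins = read_ppi(ppi_path)
    annotation = read_annotation(annotation_path)
    proteins |= set(annotation)
    ddi = read_ddi(ddi_path)
    mutations = read_mutations(mutations_path) if mutations_path else {}
    return InteractomeBundle(
        proteins=frozenset(proteins),
        edges=frozenset(edges),
        annotation={p: frozenset(d) for p, d in annotation.items()},
        ddi_catalog=frozenset(ddi),
        mutation_counts=mutations,
    )


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x patients expression TSV (first column gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ParseError(f"{path}: duplicate gene or patient identifiers")
    return df.astype(float)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read patient→outcome (good|poor) rows."""
    labels: dict[str, str] = {}
    p = Path(path)
    for lineno, (patient, label) in _iter_rows(p, 2):
        if label not in ("good", "poor"):
            raise ParseError(f"{p}:{lineno}: label must be good|poor, got {label!r}")
        labels[patient] = label
    return labels


def read_cohort(expression_path: str | Path, labels_path: str | Path) -> PatientCohort:
    df = read_expression(expression_path)
    labels = read_labels(labels_path)
    return PatientCohort(
        genes=[str(g) for g in df.index],
        patients=[str(p) for p in df.columns],
        values=df.to_numpy(),
        labels=labels,
    )


# ---------------------------------------------------------------------------
# writers


def _write_pairs(path: Path, pairs, header: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {header}\n")
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")


def write_bundle(bundle: InteractomeBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the four network inputs (sorted, deterministic bytes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ppi": outdir / "ppi.tsv",
        "annotation": outdir / "annotation.tsv",
        "ddi": outdir / "ddi.tsv",
        "mutations": outdir / "mutations.tsv",
    }
    _write_pairs(paths["ppi"], bundle.edges, "protein_a\tprotein_b")
    rows = [(p, d) for p, ds in bundle.annotation.items() for d in ds]
    _write_pairs(paths["annotation"], rows, "protein\tdomain")
    _write_pairs(paths["ddi"], bundle.ddi_catalog, "domain_a\tdomain_b")
    mut_rows = [(d, str(c)) for d, c in bundle.mutation_counts.items() if c > 0]
    _write_pairs(paths["mutations"], mut_rows, "domain\tcount")
    return paths


def write_cohort(cohort: PatientCohort, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr_path = outdir / "expression.tsv"
    df = pd.DataFrame(cohort.values, index=cohort.genes, columns=cohort.patients)
    df.index.name = "gene"
    df.to_csv(expr_path, sep="\t", float_format="%.10g")
    labels_path = outdir / "labels.tsv"
    _write_pairs(labels_path, cohort.labels.items(), "patient\toutcome")
    return {"expression": expr_path, "labels": labels_path}


def write_simulation(
    bundle: InteractomeBundle,
    truth: GroundTruth,
    cohort: PatientCohort,
    outdir: str | Path,
) -> dict[str, Path]:
    """Emit the five pipeline inputs plus the ground-truth JSON."""
    outdir = Path(outdir)
    paths = write_bundle(bundle, outdir)
    paths.update(write_cohort(cohort, outdir))
    truth_path = outdir / "ground_truth.json"
    payload = {
        "planted_signatures": sorted(truth.planted_signatures),
        "hub_neighbors": {h: list(ns) for h, ns in sorted(truth.hub_neighbors.items())},
        "hub_domain": dict(sorted(truth.hub_domain.items())),
        "coupling_good": truth.coupling_good,
        "coupling_poor": truth.coupling_poor,
    }
    truth_path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
    paths["ground_truth"] = truth_path
    return paths


def write_report(
    reports, signatures: set[str], path: str | Path
) -> Path:
    """Write the per-protein scoring report TSV (one row per domain)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "protein\tdomain\tnum_ddis\tscore_plain\tscore_mutation\t"
            "interface_class\tis_signature\n"
        )
        for r in sorted(reports, key=lambda r: r.protein):
            is_sig = "yes" if r.protein in signatures else "no"
            rows = sorted(r.ddi_counts.items()) or [("-", 0)]
            for domain, count in rows:
                fh.write(
                    f"{r.protein}\t{domain}\t{count}\t{r.score_plain:.10g}\t"
                    f"{r.score_mutation:.10g}\t{r.interface_class}\t{is_sig}\n"
                )
    return path


def write_features(features: FeatureMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = features.to_frame()
    df.index.name = "patient"
    df.to_csv(path, sep="\t", float_format="%.10g")
    return path


def write_cv_report(result: CVResult, outdir: str | Path) -> dict[str, Path]:
    """Write the CV JSON report, per-patient predictions and ROC points."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def metrics_dict(m):
        return {
            "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn,
            "accuracy": m.accuracy,
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
        }

    report = {
        "seed": result.seed,
        "auc": result.auc,
        "pooled": metrics_dict(result.pooled),
        "folds": [
            {
                "chosen_c": f.chosen_c,
                "n_test": len(f.test_patients),
                "metrics": metrics_dict(f.metrics),
            }
            for f in result.folds
        ],
    }
    report_path = outdir / "cv_report.json"
    report_path.write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")

    pred_path = outdir / "predictions.tsv"
    with open(pred_path, "w", encoding="utf-8") as fh:
        fh.write("patient\tpredicted\tposterior_good\n")
        for p in sorted(result.predictions, key=lambda p: p.patient):
            fh.write(f"{p.patient}\t{p.predicted}\t{p.posterior_good:.10g}\n")

    roc_path = outdir / "roc.tsv"
    with open(roc_path, "w", encoding="utf-8") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in result.roc:
            fh.write(f"{fpr:.10g}\t{tpr:.10g}\n")
    return {"cv_report": report_path, "predictions": pred_path, "roc": roc_path}


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (loadable from YAML)."""

    ppi: str
    annotation: str
    ddi: str
    expression: str
    labels: str
    mutations: str | None = None
    outdir: str = "domainsig_out"
    seed: int = 0
    use_mutations: bool = False
    feature_mode: str = "rank"
    alpha: float = 1.0
    protocol: str = "five_fold"
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    score: ScoreConfig = field(default_factory=ScoreConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        score_kwargs = raw.pop("score", {}) or {}
        if "c_grid" in raw:
            raw["c_grid"] = tuple(raw["c_grid"])
        return cls(score=ScoreConfig(**score_kwargs), **raw)

    def validate(self) -> None:
        required = {
            "ppi": self.ppi, "annotation": self.annotation, "ddi": self.ddi,
            "expression": self.expression, "labels": self.labels,
        }
        if self.mutations is not None:
            required["mutations"] = self.mutations
        missing = {k: v for k, v in required.items() if not Path(v).is_file()}
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        if self.protocol not in ("five_fold", "loocv"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.use_mutations and self.mutations is None:
            raise ValueError("use_mutations=True requires a mutations file")


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Score → signatures → features → cross-validation, writing artifacts.

    Deterministic for fixed seed and inputs. On error, partially
    written outputs from this run are removed before the stage-tagged
    exception propagates.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        stage = "read"
        bundle = read_bundle(cfg.ppi, cfg.annotation, cfg.ddi, cfg.mutations)
        cohort = read_cohort(cfg.expression, cfg.labels)

        stage = "score"
        reports = score_all(bundle, cfg.score)
        signatures = select_signatures(reports, cfg.score, cfg.use_mutations)
        report_path = write_report(reports, signatures, outdir / "scores.tsv")
        written.append(report_path)

        stage = "features"
        if not signatures:
            raise ValueError(
                f"no protein scores over threshold c={cfg.score.threshold_c}"
            )
        features = patient_features(
            sorted(signatures), bundle, cohort, mode=cfg.feature_mode
        )
        written.append(write_features(features, outdir / "features.tsv"))

        stage = "cv"
        protocol = nested_cv if cfg.protocol == "five_fold" else loocv
        result = protocol(
            bundle,
            cohort,
            c_grid=cfg.c_grid,
            use_mutations=cfg.use_mutations,
            seed=cfg.seed,
            alpha=cfg.alpha,
            cfg=cfg.score,
            mode=cfg.feature_mode,
        )
        cv_paths = write_cv_report(result, outdir)
        written.extend(cv_paths.values())

        stage = "model"
        model = nb.fit(features, cohort.labels, alpha=cfg.alpha)
        model_path = outdir / "model.json"
        model_path.write_text(model.to_json() + "\n")
        written.append(model_path)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
    artifacts = {
        "scores": outdir / "scores.tsv",
        "features": outdir / "features.tsv",
        "model": outdir / "model.json",
        **cv_paths,
    }
    return artifacts
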