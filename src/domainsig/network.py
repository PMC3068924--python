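"""Interactome bundle and domain-interaction scoring.

The central object is the :class:`InteractomeBundle`: a protein-protein
interaction (PPI) graph together with Pfam-style domain annotation, a
catalog of domain-domain interactions (DDIs), and per-domain somatic
mutation counts. Proteins are scored by how many DDI-mediated contacts
each of their domains realizes with neighboring proteins; high-scoring
proteins ("gene signatures") tend to be hubs whose interactions are
funnelled through a single reused interface and are therefore mutually
exclusive.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

import networkx as nx
from scipy.stats import norm

logger = logging.getLogger(__name__)

Pair = tuple[str, str]

INTERFACE_SINGLISH = "singlish"
INTERFACE_MULTIPLE = "multiple"
INTERFACE_NONE = "none"


def canonical_pair(a: str, b: str) -> Pair:
    """Order-independent representation of an unordered pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ScoreConfig:
    """Parameters of the domain index score.

    Parameters
    ----------
    weight_base:
        Base ``W`` of the exponential weight applied to a domain's DDI
        count; must exceed 1 so that heavily engaged domains dominate.
    threshold_c:
        Signature selection threshold ``c``; proteins scoring over it
        become gene signatures.
    mutation_mode:
        How somatic mutation counts enter the modified score:
        ``"multiplicative"`` multiplies each domain term by
        ``1 + NumSMs(d)``, ``"additive"`` adds ``NumSMs(d)`` per engaged
        domain, ``"off"`` ignores mutations.
    ddi_count_mode:
        ``"instances"`` counts every (neighbor, neighbor-domain) contact;
        ``"types"`` counts distinct DDI types instead.
    strict_threshold:
        If True (default), a signature must score strictly over
        ``threshold_c``; if False, ties pass.
    """

    weight_base: float = 2.0
    threshold_c: float = 50.0
    mutation_mode: str = "multiplicative"
    ddi_count_mode: str = "instances"
    strict_threshold: bool = True

    def __post_init__(self) -> None:
        if not self.weight_base > 1:
            raise ValueError(f"weight_base must be > 1, got {self.weight_base}")
        if self.threshold_c < 0:
            raise ValueError(f"threshold_c must be >= 0, got {self.threshold_c}")
        if self.mutation_mode not in ("off", "multiplicative", "additive"):
            raise ValueError(f"unknown mutation_mode {self.mutation_mode!r}")
        if self.ddi_count_mode not in ("instances", "types"):
            raise ValueError(f"unknown ddi_count_mode {self.ddi_count_mode!r}")


@dataclass(eq=False)
class InteractomeBundle:
    """PPI graph + domain annotation + DDI catalog + mutation counts.

    Edges and DDI pairs are stored canonically (lexicographically
    ordered tuples); self-interactions are rejected here — file readers
    drop them before construction. ``annotation`` may omit proteins
    (empty domain set) and ``mutation_counts`` defaults to 0 for
    unlisted domains.
    """

    proteins: frozenset[str]
    edges: frozenset[Pair]
    annotation: dict[str, frozenset[str]]
    ddi_catalog: frozenset[Pair]
    mutation_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.proteins = frozenset(self.proteins)
        canon_edges = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-interaction {a!r} is not allowed")
            if a not in self.proteins or b not in self.proteins:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown protein")
            canon_edges.add(canonical_pair(a, b))
        self.edges = frozenset(canon_edges)
        self.annotation = {p: frozenset(ds) for p, ds in self.annotation.items()}
        self.ddi_catalog = frozenset(canonical_pair(a, b) for a, b in self.ddi_catalog)
        for d, c in self.mutation_counts.items():
            if c < 0:
                raise ValueError(f"negative mutation count for domain {d!r}")

    @cached_property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.proteins)
        g.add_edges_from(self.edges)
        return g

    def neighbors(self, protein: str) -> list[str]:
        """Interaction partners of ``protein``, sorted for determinism."""
        self._require(protein)
        return sorted(self.graph.neighbors(protein))

    def domains(self, protein: str) -> frozenset[str]:
        return self.annotation.get(protein, frozenset())

    def num_mutations(self, domain: str) -> int:
        return self.mutation_counts.get(domain, 0)

    def has_ddi(self, d1: str, d2: str) -> bool:
        return canonical_pair(d1, d2) in self.ddi_catalog

    def _require(self, protein: str) -> None:
        if protein not in self.proteins:
            raise KeyError(f"unknown protein {protein!r}")


@dataclass
class DomainIndexReport:
    """Per-protein scoring report.

    ``ddi_counts`` holds ``NumDDIs(d)`` per annotated domain;
    ``score_plain`` and ``score_mutation`` are the domain index score
    without and with somatic-mutation weighting.
    """

    protein: str
    ddi_counts: dict[str, int]
    score_plain: float
    score_mutation: float
    interface_class: str


@dataclass
class DomainEnrichmentResult:
    """One-proportion Z-test of a domain's DDI share in signatures vs genome."""

    domain: str
    count_in_signatures: int
    count_genome: int
    z_score: float
    p_value: float


def count_domain_ddis(
    protein: str, bundle: InteractomeBundle, mode: str = "instances"
) -> dict[str, int]:
    """Count DDI engagement of each domain of ``protein``.

    For every domain ``d`` of the protein, counts the (neighbor,
    neighbor-domain) instances ``(d, d')`` found in the DDI catalog,
    aggregated over all network neighbors. With ``mode="types"`` the
    count collapses to the number of distinct DDI types instead.
    Domains with no match map to 0; an unannotated protein yields an
    empty map.
    """
    bundle._require(protein)
    own = bundle.domains(protein)
    counts: dict[str, int] = {d: 0 for d in own}
    if not own:
        return counts
    for d in own:
        if mode == "instances":
            counts[d] = sum(
                1
                for p in bundle.graph.neighbors(protein)
                for d2 in bundle.domains(p)
                if bundle.has_ddi(d, d2)
            )
        elif mode == "types":
            counts[d] = len(
                {
                    canonical_pair(d, d2)
                    for p in bundle.graph.neighbors(protein)
                    for d2 in bundle.domains(p)
                    if bundle.has_ddi(d, d2)
                }
            )
        else:
            raise ValueError(f"unknown counting mode {mode!r}")
    return counts


def classify_interface(protein: str, bundle: InteractomeBundle) -> str:
    """Classify a protein by the DDI types it realizes with neighbors.

    ``singlish``: exactly one DDI type, realized with at least two
    distinct neighbors (so the interactions compete for one interface);
    ``multiple``: two or more distinct DDI types; ``none`` otherwise.
    """
    bundle._require(protein)
    realized: dict[Pair, set[str]] = {}
    for p in bundle.graph.neighbors(protein):
        for d in bundle.domains(protein):
            for d2 in bundle.domains(p):
                if bundle.has_ddi(d, d2):
                    realized.setdefault(canonical_pair(d, d2), set()).add(p)
    if not realized:
        return INTERFACE_NONE
    if len(realized) >= 2:
        return INTERFACE_MULTIPLE
    (neighbors,) = realized.values()
    return INTERFACE_SINGLISH if len(neighbors) >= 2 else INTERFACE_NONE


def domain_index_score(
    protein: str, bundle: InteractomeBundle, cfg: ScoreConfig | None = None
) -> DomainIndexReport:
    """Score a protein by exponentially weighted per-domain DDI counts.

    ``score_plain = Σ_d W^NumDDIs(d)`` over domains with at least one
    DDI; zero-count domains contribute nothing (not ``W^0``).
    ``score_mutation`` additionally weights each engaged domain by its
    somatic mutation count according to ``cfg.mutation_mode``.
    """
    cfg = cfg or ScoreConfig()
    counts = count_domain_ddis(protein, bundle, cfg.ddi_count_mode)
    engaged = {d: c for d, c in counts.items() if c >= 1}
    score_plain = float(sum(cfg.weight_base**c for c in engaged.values()))
    if cfg.mutation_mode == "multiplicative":
        score_mutation = float(
            sum(
                cfg.weight_base**c * (1 + bundle.num_mutations(d))
                for d, c in engaged.items()
            )
        )
    elif cfg.mutation_mode == "additive":
        score_mutation = score_plain + float(
            sum(bundle.num_mutations(d) for d in engaged)
        )
    else:  # off
        score_mutation = score_plain
    return DomainIndexReport(
        protein=protein,
        ddi_counts=counts,
        score_plain=score_plain,
        score_mutation=score_mutation,
        interface_class=classify_interface(protein, bundle),
    )


def score_all(
    bundle: InteractomeBundle, cfg: ScoreConfig | None = None
) -> list[DomainIndexReport]:
    """Score every protein in the bundle (sorted by protein id)."""
    cfg = cfg or ScoreConfig()
    return [domain_index_score(p, bundle, cfg) for p in sorted(bundle.proteins)]


def select_signatures(
    reports: Iterable[DomainIndexReport],
    cfg: ScoreConfig | None = None,
    use_mutations: bool = False,
) -> set[str]:
    """Proteins whose chosen score exceeds the threshold ``c``.

    The comparison is strict by default ("over the threshold");
    ``cfg.strict_threshold=False`` switches to >=. Deterministic and
    order-independent.
    """
    cfg = cfg or ScoreConfig()
    out = set()
    for r in reports:
        s = r.score_mutation if use_mutations else r.score_plain
        if (s > cfg.threshold_c) if cfg.strict_threshold else (s >= cfg.threshold_c):
            out.add(r.protein)
    return out


def _ddi_instance_counts(
    proteins: Iterable[str], bundle: InteractomeBundle
) -> Counter[str]:
    """Total realized DDI instances per domain over the given proteins."""
    counts: Counter[str] = Counter()
    for x in proteins:
        for d, c in count_domain_ddis(x, bundle).items():
            if c:
                counts[d] += c
    return counts


def domain_overrepresentation(
    signatures: set[str], bundle: InteractomeBundle
) -> list[DomainEnrichmentResult]:
    """Test each signature domain for DDI over-representation.

    For every domain appearing on signature proteins, its share of
    signature DDI instances is compared against its genome-wide share
    by a one-proportion Z-test (normal approximation, two-sided).
    Results are sorted by ascending p-value, ties broken by domain id.
    """
    if not signatures:
        return []
    unknown = signatures - bundle.proteins
    if unknown:
        raise KeyError(f"unknown proteins in signature set: {sorted(unknown)}")
    genome = _ddi_instance_counts(bundle.proteins, bundle)
    total_genome = sum(genome.values())
    if total_genome == 0:
        raise ValueError("no DDI instances realized anywhere in the bundle")
    sig_counts = _ddi_instance_counts(signatures, bundle)
    total_sig = sum(sig_counts.values())
    domains = sorted({d for p in signatures for d in bundle.domains(p)})
    results = []
    for d in domains:
        cs = sig_counts.get(d, 0)
        cg = genome.get(d, 0)
        p0 = cg / total_genome
        if total_sig == 0 or p0 <= 0.0 or p0 >= 1.0:
            # degenerate null: the observed share cannot deviate
            z = 0.0
        else:
            phat = cs / total_sig
            z = (phat - p0) / math.sqrt(p0 * (1 - p0) / total_sig)
        p = float(2.0 * norm.sf(abs(z)))
        results.append(
            DomainEnrichmentResult(
                domain=d,
                count_in_signatures=cs,
                count_genome=cg,
                z_score=float(z),
                p_value=min(p, 1.0),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.domain))
    return results
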