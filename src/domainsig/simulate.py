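"""Seeded synthetic interactome bundles and patient cohorts.

The generator plants ``n_singlish_hubs`` star-shaped hub proteins whose
interactions with all spokes run through one dedicated domain-domain
interaction type: the hub carries a private domain ``h`` that pairs only
with a private partner domain ``q`` carried by each of its
``hub_degree`` spokes. This guarantees the hub is a singlish-interface
protein with NumDDIs(h) = hub_degree, so planted hubs are unambiguous
ground-truth signatures. Around the planted stars sit Erdős–Rényi
background edges, random domain annotation, and a sparse random DDI
catalog over the non-reserved domains.

Cohorts plant class-dependent co-expression: in good-outcome patients a
hub's spokes track the hub signal tightly (spoke = hub + N(0, σ)); in
poor-outcome patients the coupling is attenuated by ``effect_delta``
(spoke = (1 − Δ)·hub + N(0, σ)). ``effect_delta = 0`` defines the null
cohort in which the two classes are exchangeable. All randomness is
driven by ``SimConfig.seed`` through two spawned streams (bundle,
cohort), so identical configs reproduce identical data byte for byte.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .expression import GOOD, POOR, PatientCohort
from .network import InteractomeBundle, canonical_pair

_BUNDLE_STREAM = (0,)
_COHORT_STREAM = (1,)


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the stated simulation world.

    200 proteins with 5 planted singlish hubs of degree 8 give hub
    scores of 2^8 = 256, comfortably over the canonical signature
    threshold c = 50, while sparse background DDIs keep non-hub scores
    far below it. The cohort defaults (60 good / 40 poor patients,
    full decoupling Δ = 1 at noise σ = 0.2) describe a strong planted
    signal; Δ = 0 gives the matched null.
    """

    n_proteins: int = 200
    n_domains: int = 60
    domains_per_protein: float = 2.0
    n_singlish_hubs: int = 5
    hub_degree: int = 8
    background_edge_prob: float = 0.02
    ddi_density: float = 0.01
    mutation_rate: float = 2.0
    n_patients_good: int = 60
    n_patients_poor: int = 40
    effect_delta: float = 1.0
    noise_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.n_domains, self.n_singlish_hubs) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_singlish_hubs and self.hub_degree < 2:
            raise ValueError("hub_degree must be >= 2")
        for p in (self.background_edge_prob, self.ddi_density):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.effect_delta < 0:
            raise ValueError("effect_delta must be >= 0")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0")
        if self.n_singlish_hubs * 2 > self.n_domains:
            raise ValueError("need 2 reserved domains per hub")
        if self.hub_degree >= self.n_proteins:
            raise ValueError("hub_degree must be smaller than n_proteins")


@dataclass
class GroundTruth:
    """What the simulator planted: hub signatures and class couplings."""

    planted_signatures: frozenset[str]
    hub_neighbors: dict[str, tuple[str, ...]]
    hub_domain: dict[str, str]
    coupling_good: float = 1.0
    coupling_poor: float = 0.0


def _protein_id(i: int) -> str:
    return f"P{i:04d}"


def _domain_id(i: int) -> str:
    return f"D{i:04d}"


def simulate_bundle(cfg: SimConfig) -> tuple[InteractomeBundle, GroundTruth]:
    """Generate a seeded interactome with planted singlish hubs."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=_BUNDLE_STREAM))
    proteins = [_protein_id(i) for i in range(cfg.n_proteins)]
    domains = [_domain_id(i) for i in range(cfg.n_domains)]

    hubs = [proteins[i] for i in sorted(
        rng.choice(cfg.n_proteins, size=cfg.n_singlish_hubs, replace=False)
    )]
    hub_set = set(hubs)
    non_hubs = [p for p in proteins if p not in hub_set]

    # first 2 domains per hub are reserved: h_i (on the hub) and q_i (on spokes)
    reserved = domains[: 2 * cfg.n_singlish_hubs]
    background_domains = domains[2 * cfg.n_singlish_hubs:]

    annotation: dict[str, set[str]] = {p: set() for p in proteins}
    edges: set[tuple[str, str]] = set()
    ddi_catalog: set[tuple[str, str]] = set()
    mutation_counts: dict[str, int] = {}
    hub_neighbors: dict[str, tuple[str, ...]] = {}
    hub_domain: dict[str, str] = {}

    # spoke sets are sampled disjointly so that every planted spoke can
    # couple to exactly one hub signal in the cohort generator
    if cfg.n_singlish_hubs * cfg.hub_degree > len(non_hubs):
        raise ValueError("not enough non-hub proteins for disjoint hub spokes")
    available = list(non_hubs)
    for i, hub in enumerate(hubs):
        h, q = reserved[2 * i], reserved[2 * i + 1]
        annotation[hub] = {h}
        hub_domain[hub] = h
        ddi_catalog.add(canonical_pair(h, q))
        picks = sorted(rng.choice(len(available), size=cfg.hub_degree, replace=False))
        spokes = [available[j] for j in picks]
        available = [p for j, p in enumerate(available) if j not in set(picks)]
        hub_neighbors[hub] = tuple(spokes)
        for s in spokes:
            annotation[s].add(q)
            edges.add(canonical_pair(hub, s))
        mutation_counts[h] = int(rng.poisson(cfg.mutation_rate))

    # random background annotation over non-reserved domains
    if background_domains:
        for p in non_hubs:
            k = min(int(rng.poisson(cfg.domains_per_protein)), len(background_domains))
            if k:
                picks = rng.choice(len(background_domains), size=k, replace=False)
                annotation[p].update(background_domains[j] for j in sorted(picks))

    # Erdős–Rényi background edges over all protein pairs
    if cfg.background_edge_prob > 0:
        pairs = list(itertools.combinations(proteins, 2))
        mask = rng.random(len(pairs)) < cfg.background_edge_prob
        for (a, b), keep in zip(pairs, mask):
            if keep:
                edges.add(canonical_pair(a, b))

    # sparse random DDI catalog over background domains only, so planted
    # hub interfaces stay the sole DDI type of each hub
    if cfg.ddi_density > 0 and len(background_domains) >= 2:
        dpairs = list(itertools.combinations(background_domains, 2))
        mask = rng.random(len(dpairs)) < cfg.ddi_density
        for (a, b), keep in zip(dpairs, mask):
            if keep:
                ddi_catalog.add(canonical_pair(a, b))

    bundle = InteractomeBundle(
        proteins=frozenset(proteins),
        edges=frozenset(edges),
        annotation={p: frozenset(ds) for p, ds in annotation.items()},
        ddi_catalog=frozenset(ddi_catalog),
        mutation_counts=mutation_counts,
    )
    truth = GroundTruth(
        planted_signatures=frozenset(hubs),
        hub_neighbors=hub_neighbors,
        hub_domain=hub_domain,
        coupling_good=1.0,
        coupling_poor=1.0 - cfg.effect_delta,
    )
    return bundle, truth


def simulate_cohort(
    bundle: InteractomeBundle, truth: GroundTruth, cfg: SimConfig
) -> PatientCohort:
    """Generate an expression cohort with planted class-dependent coupling.

    Genes are the bundle's proteins. Every gene starts as independent
    standard-normal noise; each planted hub keeps its own signal and its
    spokes are overwritten with ``coupling·hub + N(0, noise_sigma)``,
    where the coupling is 1 for good-outcome patients and
    ``1 − effect_delta`` for poor-outcome patients. A gene that spokes
    for several hubs is attached to the first hub in sorted order.
    """
    if cfg.n_patients_good < 1 or cfg.n_patients_poor < 1:
        raise ValueError("each outcome class needs at least one patient")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=_COHORT_STREAM))
    genes = sorted(bundle.proteins)
    gene_index = {g: i for i, g in enumerate(genes)}
    n_patients = cfg.n_patients_good + cfg.n_patients_poor
    patients = [f"PT{i:04d}" for i in range(n_patients)]
    labels = {
        p: (GOOD if i < cfg.n_patients_good else POOR)
        for i, p in enumerate(patients)
    }
    coupling = np.array(
        [truth.coupling_good if labels[p] == GOOD else truth.coupling_poor
         for p in patients]
    )

    values = rng.normal(0.0, 1.0, size=(len(genes), n_patients))
    assigned: set[str] = set()
    for hub in sorted(truth.planted_signatures):
        hub_row = values[gene_index[hub], :]
        for spoke in truth.hub_neighbors[hub]:
            if spoke in assigned:
                continue
            assigned.add(spoke)
            noise = rng.normal(0.0, cfg.noise_sigma, size=n_patients)
            values[gene_index[spoke], :] = coupling * hub_row + noise

    return PatientCohort(genes=genes, patients=patients, values=values, labels=labels)
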