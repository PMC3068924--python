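import numpy as np
import pytest

from domainsig import InteractomeBundle, PatientCohort, canonical_pair


def make_bundle(edges, annotation, ddi, mutations=None, extra_proteins=()):
    """Convenience constructor for small hand-built bundles."""
    proteins = {p for e in edges for p in e} | set(annotation) | set(extra_proteins)
    return InteractomeBundle(
        proteins=frozenset(proteins),
        edges=frozenset(edges),
        annotation={p: frozenset(d) for p, d in annotation.items()},
        ddi_catalog=frozenset(ddi),
        mutation_counts=dict(mutations or {}),
    )


def random_bundle(rng, max_proteins=10, max_domains=6, mutation_max=0):
    """Random small bundle for oracle-equivalence checks."""
    n_prot = rng.integers(2, max_proteins + 1)
    n_dom = rng.integers(1, max_domains + 1)
    proteins = [f"p{i}" for i in range(n_prot)]
    domains = [f"d{i}" for i in range(n_dom)]
    edges = set()
    for i in range(n_prot):
        for j in range(i + 1, n_prot):
            if rng.random() < 0.4:
                edges.add((proteins[i], proteins[j]))
    annotation = {}
    for p in proteins:
        k = int(rng.integers(0, min(3, n_dom) + 1))
        if k:
            annotation[p] = set(rng.choice(domains, size=k, replace=False))
    ddi = set()
    for i in range(n_dom):
        for j in range(i, n_dom):  # same-domain pairs allowed
            if rng.random() < 0.35:
                ddi.add(canonical_pair(domains[i], domains[j]))
    mutations = {}
    if mutation_max:
        for d in domains:
            if rng.random() < 0.5:
                mutations[d] = int(rng.integers(0, mutation_max + 1))
    return make_bundle(edges, annotation, ddi, mutations, extra_proteins=proteins)


def brute_force_ddi_counts(protein, bundle):
    """Independent triple loop over (neighbor, own domain, neighbor domain)."""
    counts = {d: 0 for d in bundle.annotation.get(protein, frozenset())}
    for a, b in bundle.edges:
        if protein not in (a, b):
            continue
        other = b if a == protein else a
        for d in bundle.annotation.get(protein, frozenset()):
            for d2 in bundle.annotation.get(other, frozenset()):
                if canonical_pair(d, d2) in bundle.ddi_catalog:
                    counts[d] += 1
    return counts


def brute_force_scores(protein, bundle, base=2.0, mutation_mode="multiplicative"):
    """Independent score evaluation from the brute-force counts."""
    counts = brute_force_ddi_counts(protein, bundle)
    plain = sum(base**c for c in counts.values() if c >= 1)
    muts = bundle.mutation_counts
    if mutation_mode == "multiplicative":
        mut = sum(
            base**c * (1 + muts.get(d, 0)) for d, c in counts.items() if c >= 1
        )
    elif mutation_mode == "additive":
        mut = plain + sum(muts.get(d, 0) for d, c in counts.items() if c >= 1)
    else:
        mut = plain
    return plain, mut


def brute_force_nb_posteriors(train_bins, train_labels, test_bins, alpha):
    """Direct evaluation of P(x|C)P(C) by multiplying bin frequencies.

    train_bins: list of per-patient bin tuples; train_labels: list of
    "good"/"poor"; returns dict class -> unnormalized posterior.
    """
    classes = ("good", "poor")
    n = len(train_labels)
    out = {}
    for cls in classes:
        rows = [b for b, l in zip(train_bins, train_labels) if l == cls]
        x_c = len(rows)
        prob = x_c / n
        for s, b in enumerate(test_bins):
            count = sum(1 for r in rows if r[s] == b)
            prob *= (count + alpha) / (x_c + 20 * alpha)
        out[cls] = prob
    return out


def make_star_bundle(degree, with_mutations=0):
    """Singlish hub: one hub domain pairing with one spoke domain."""
    hub = "HUB"
    spokes = [f"S{i}" for i in range(degree)]
    edges = {(hub, s) for s in spokes}
    annotation = {hub: {"dH"}, **{s: {"dQ"} for s in spokes}}
    mutations = {"dH": with_mutations} if with_mutations else {}
    return make_bundle(edges, annotation, {("dH", "dQ")}, mutations), hub


@pytest.fixture
def toy_bundle():
    """Protein A with two neighbors; catalog realizes (d1,d2) and (d1,d3)."""
    return make_bundle(
        edges={("A", "B"), ("A", "C")},
        annotation={"A": {"d1", "d4"}, "B": {"d2", "d3"}, "C": {"d2"}},
        ddi={("d1", "d2"), ("d1", "d3")},
    )


@pytest.fixture
def toy_cohort():
    """8-patient cohort (4 good / 4 poor) over 5 genes, seeded."""
    rng = np.random.default_rng(7)
    genes = ["A", "B", "C", "D", "E"]
    patients = [f"pt{i}" for i in range(8)]
    labels = {p: ("good" if i < 4 else "poor") for i, p in enumerate(patients)}
    values = rng.normal(size=(5, 8))
    return PatientCohort(genes=genes, patients=patients, values=values, labels=labels)
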