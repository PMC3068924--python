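"""Score a tiny hand-built interactome by domain-interaction engagement.

Builds a six-protein network in which SRC-like protein "HUB" contacts
four partners through one reused SH2-style interface, while "MULTI"
uses two different interfaces. Prints each protein's per-domain DDI
counts, domain index scores with and without somatic-mutation
weighting, and its interface class.
"""

from domainsig import InteractomeBundle, ScoreConfig, score_all

bundle = InteractomeBundle(
    proteins=frozenset({"HUB", "MULTI", "A", "B", "C", "D"}),
    edges=frozenset({
        ("HUB", "A"), ("HUB", "B"), ("HUB", "C"), ("HUB", "D"),
        ("MULTI", "A"), ("MULTI", "B"),
    }),
    annotation={
        "HUB": frozenset({"SH2"}),
        "MULTI": frozenset({"PDZ", "ANK"}),
        "A": frozenset({"pTyr"}),
        "B": frozenset({"pTyr", "PDZ_lig"}),
        "C": frozenset({"pTyr"}),
        "D": frozenset({"pTyr"}),
    },
    ddi_catalog=frozenset({("SH2", "pTyr"), ("PDZ", "PDZ_lig"), ("ANK", "pTyr")}),
    mutation_counts={"SH2": 3},  # somatic mutations observed in the SH2 domain
)

print(f"{'protein':<8} {'domain':<8} {'NumDDIs':>7} {'plain':>7} "
      f"{'with-mut':>8}  interface")
for report in score_all(bundle, ScoreConfig()):
    for domain, count in sorted(report.ddi_counts.items()):
        print(f"{report.protein:<8} {domain:<8} {count:>7} "
              f"{report.score_plain:>7.0f} {report.score_mutation:>8.0f}  "
              f"{report.interface_class}")

print()
print("HUB engages 4 partners through the single SH2-pTyr interaction, so")
print("those contacts are mutually exclusive (singlish interface) and its")
print("score 2^4 = 16 is quadrupled to 64 by the 3 SH2 somatic mutations.")
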