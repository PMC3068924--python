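# domainsig

Network-based gene signatures for cancer outcome prediction, built on
the structure of protein interaction *interfaces*.

Many prognostic classifiers pick marker genes by expression alone.
`domainsig` instead scores each protein by how its domains engage the
domain–domain interaction (DDI) catalog across its protein–protein
interaction (PPI) neighborhood. Proteins that contact many partners
through one reused interface ("singlish-interface" hubs, e.g. an
SH2-domain kinase binding many phosphotyrosine partners) make those
interactions mutually exclusive, so disrupting that interface — for
example by somatic mutations inside the domain — can rewire the
network. Such proteins are selected as **gene signatures**, each
patient's expression profile is summarized by how strongly every
signature's co-expression with its network neighbors is perturbed, and
a binned naïve Bayes classifier predicts good vs poor outcome under a
nested cross-validation protocol. A seeded simulator generates
interactomes and patient cohorts with known planted ground truth, so
the whole pipeline is testable without external databases.

## The model

For a protein *x* with annotated domains *D(x)*, each domain *d* gets a
count over the PPI neighbors of *x*:

```
NumDDIs(d) = Σ_{p ∈ neighbors(x)} Σ_{d' ∈ D(p)} 1[(d, d') ∈ DDI catalog]
```

counted per neighbor-domain *instance*. The **domain index score** is

```
S(x) = Σ_{d ∈ D(x), NumDDIs(d) ≥ 1} 2^NumDDIs(d)
```

optionally weighted by somatic mutation counts per domain,
`S_mut(x) = Σ_d 2^NumDDIs(d) · (1 + NumSMs(d))` (multiplicative mode,
default; an additive mode is available). Proteins with `S > c` are gene
signatures; `c` is the single tuned hyperparameter.

For patient *k*, each signature *i* yields the feature

```
v_i(k) = mean_{p ∈ N_i} | ê_k(i) − ê_k(p) |  ∈ [0, 1]
```

where `ê_k` is the patient's rank-scaled expression and `N_i` the
measured PPI neighbors of the signature. Features are discretized into
20 equal bins and classified by naïve Bayes with empirical priors
`P(C) = X_C / X`, Laplace-smoothed bin likelihoods, and the MAP rule on
`P(x|C) P(C)`. Performance (accuracy, sensitivity and specificity with
*poor* outcome as the positive class, plus ROC/AUC) is estimated by
5-fold nested cross-validation: the threshold `c` is tuned by
leave-one-out CV inside each 80% training portion and validated on the
held-out 20%; an outer-LOOCV variant serves small cohorts. A
group-level diagnostic, the discrimination score
`(1/2n) Σ_i |r_good(x, p_i) − r_poor(x, p_i)|` over Pearson
correlations, ranks signatures by how differently they co-express with
neighbors in the two outcome groups.

## Worked example

```bash
python examples/05_cross_validation.py
```

prints (seed 0, 200 simulated proteins with 5 planted hubs, 60 good +
40 poor patients):

```
planted signal (delta = 1, neighbors decouple in poor patients):
  chosen c per fold : [10, 10, 10, 10, 10]
  pooled accuracy   : 0.970  (tp=37 fp=0 tn=60 fn=3)
  sensitivity/specificity : 0.925 / 1.000
  AUC               : 1.000

null cohort (delta = 0, classes exchangeable):
  chosen c per fold : [10, 10, 10, 10, 10]
  pooled accuracy   : 0.570  (tp=3 fp=6 tn=54 fn=37)
  sensitivity/specificity : 0.075 / 0.900
  AUC               : 0.508
```

When poor-outcome patients lose hub–neighbor co-expression the
classifier recovers the outcome almost perfectly; on the matched null
cohort (identical except that the planted effect is removed) accuracy
falls back to the majority-class rate and AUC to ≈ 0.5 — evidence that
the protocol never leaks held-out labels. The other examples cover
protein scoring (`01`), signature selection and domain
over-representation (`02`), per-patient features (`03`), the classifier
itself (`04`), and the file-based pipeline with TSV/JSON artifacts
(`06`).

## Input formats

Tab-separated, UTF-8, `#` comments: PPI edge list (protein, protein),
domain annotation (protein, Pfam-style domain), DDI catalog (domain,
domain), somatic mutation counts (domain, count), expression matrix
(first column gene, remaining columns patients) and labels (patient,
good|poor). `domainsig.io.read_bundle` / `read_cohort` load them;
`run_pipeline(RunConfig(...))` executes score → signatures → features →
cross-validation and writes TSV/JSON reports deterministically.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch on the seeded simulated world:
it generates the interactome and cohort, scores all proteins, selects
signatures at the canonical threshold c = 50, runs nested
cross-validation, prints the pooled metrics, and writes the result JSON
to `--out`.
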