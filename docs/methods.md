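# Methods

## Scope and assumptions

`domainsig` scores proteins in a PPI network by the domain–domain
interaction (DDI) structure of their neighborhood, treats high-scoring
proteins as gene signatures, and classifies patient outcome from how
strongly each signature's co-expression with its neighbors is perturbed
in a given patient. The method assumes that (i) PPIs are mediated by
DDIs; (ii) proteins whose interactions are funnelled through one reused
interface ("singlish-interface" hubs) are points of fragility, because
those interactions are mutually exclusive and a single disrupted
interface detaches many partners; and (iii) this disruption is visible
in expression data as a loss of co-expression between the hub and its
partners in poor-outcome patients. All identifiers are opaque
case-sensitive strings; no identifier mapping across databases is
attempted.

## Domain index score

For protein *x* with domain set *D(x)*, each domain's engagement is
counted per neighbor-domain instance:
`NumDDIs(d) = Σ_{p ∈ N(x)} Σ_{d' ∈ D(p)} 1[(d,d') ∈ catalog]`. A
neighbor contributing two matching domains counts twice; the same DDI
type realized with five neighbors counts five times. An alternative
`types` counting mode (distinct DDI types only) is available behind
`ScoreConfig.ddi_count_mode` but is not the default: instance counting
is what makes reused-interface hubs score highly, which is the point of
the statistic.

The plain score is `S(x) = Σ_{d: NumDDIs(d) ≥ 1} W^NumDDIs(d)` with
`W = 2`. Domains with zero realized DDIs contribute nothing (not
`2^0 = 1`): a domain-rich but non-interacting protein should not
accumulate score. The mutation-aware score multiplies each engaged
domain's term by `(1 + NumSMs(d))`, where `NumSMs(d)` is the somatic
mutation count recorded for the domain; with all counts zero it equals
the plain score, and it can never fall below it. An additive
combination (`S + Σ NumSMs`) is provided as a config alternative
because the exact combination rule is a genuinely open design point;
the multiplicative form is the default because it scales a domain's
weight with both its connectivity and its mutational burden, which is
consistent with signature thresholds rising when mutation data are
switched on. Signature selection uses a strict comparison `S > c`
(configurable to ≥); `c` defaults to 50.

Interface classification collects the realized DDI types between the
protein and its neighbors: exactly one type realized with ≥ 2 distinct
neighbors is `singlish`; ≥ 2 types is `multiple`; anything else
(including one type with a single neighbor, where no mutual exclusion
arises) is `none`.

Domain over-representation among signatures uses a one-proportion
Z-test: a domain's share of DDI instances within signature proteins is
tested against its genome-wide share (normal approximation, two-sided
p). When the null proportion is degenerate (0 or 1) the observed share
cannot deviate and z is defined as 0, p = 1.

## Expression features

Two related quantities are exposed, because the group-level statistic
cannot serve as a per-patient classifier input:

- **Discrimination score** (diagnostic, group level):
  `(1/2n) Σ_i |r_good(x, p_i) − r_poor(x, p_i)|` over the n usable
  neighbors, where each r is a Pearson correlation across the patients
  of one outcome group. The factor 1/2 maps the raw range [0, 2] onto
  [0, 1]. Each group must have ≥ 3 patients; neighbors missing from the
  matrix or with undefined (constant-vector) correlation are excluded
  and n reduced — no imputation.
- **Per-patient feature** (classifier input):
  `v_i(k) = mean_{p ∈ N_i} |ê_k(i) − ê_k(p)|` with `ê_k` the patient's
  expression column rank-scaled to [0, 1] (average ranks for ties,
  `(rank − 1)/(G − 1)`; an all-tied column maps to 0.5). Rank scaling
  guarantees the [0, 1] range that the 20-bin discretization requires
  on any platform and makes features invariant under strictly monotone
  per-patient transformations; a per-patient min-max (`raw`) mode
  exists behind a flag for data already on a bounded scale. Signatures
  not measured in the cohort, or with no measured neighbor, are dropped
  with a warning.

## Classifier

Features are discretized into 20 half-open equal bins on [0, 1]
(`floor(20v)`, with 1.0 assigned to bin 19). Priors are class
frequencies `X_C / X`; likelihoods are per-signature bin frequencies
with Laplace smoothing `(count + α)/(X_C + 20α)`. α defaults to 1
because empty bins otherwise force zero posteriors; α = 0 reproduces
the plain empirical estimator (zero-probability bins then yield −∞ log
scores, and a patient impossible under both classes is assigned the
majority class, good, with a warning). Prediction is MAP on
`P(x|C)P(C)`, computed in log space and normalized by log-sum-exp so
products over many signatures cannot underflow; exact ties go to good
(the majority class in the motivating cohorts, and the conservative
choice for a "poor" call). Models serialize to versioned JSON.

## Evaluation protocols

The positive class is poor outcome: sensitivity is the fraction of poor
patients called poor. Undefined ratios (empty denominators) are
reported as absent rather than 0. ROC curves sweep the unique posterior
values (ties grouped) and AUC is trapezoidal, via scikit-learn's
metrics.

`nested_cv` draws 5 seeded, stratified outer folds (stratification is
required: with ~25–40% poor patients, unstratified folds occasionally
lose a class). Within each 80% training portion, every threshold c in
the grid (default 10, 20, …, 150) is scored by leave-one-out CV of the
full downstream pipeline; the best c — smallest on ties, since larger
signature sets degrade gracefully while tiny ones are brittle — trains
on the whole portion and predicts the held-out 20%. Fold predictions
are pooled for the headline metrics and the ROC (per-fold metrics are
also reported). `loocv` applies the same inner rule with outer
leave-one-out for small cohorts; it is quadratic in cohort size and
intended for n up to a few hundred.

Signature selection and feature construction are label-free, so they
are computed once per threshold and shared across folds; labels enter
only the naïve Bayes fits, which receive an explicit list of training
patient ids. That list is the leakage boundary the test suite hooks to
verify held-out patients never reach a fit.

## Synthetic data

`simulate_bundle` plants `n_singlish_hubs` star centers: hub *i*
carries one private domain `h_i`, its `hub_degree` spokes each carry
the private partner domain `q_i`, and `(h_i, q_i)` is the only catalog
pair touching either domain, so the hub is singlish with
`NumDDIs(h_i) = hub_degree` by construction. Spoke sets are sampled
disjointly across hubs so that every spoke can couple to exactly one
hub signal in the cohort generator. Background structure is
Erdős–Rényi edges (p = 0.02 over 200 proteins, mean degree ≈ 4, a
desk-scale stand-in for interactome sparsity), Poisson(2) domains per
protein over the non-reserved domains, and a sparse random DDI catalog
(density 0.01) over non-reserved domain pairs. Hub domains receive
Poisson(2) somatic mutation counts; all other domains 0.

`simulate_cohort` gives every gene independent N(0, 1) expression, then
rewrites each hub's spokes as `coupling · hub + N(0, σ)` with coupling
1 in good patients and `1 − effect_delta` in poor patients
(σ = 0.2 by default; `effect_delta = 1` fully decouples, 0 defines the
null world). Defaults are 60 good and 40 poor patients. Two spawned
seed streams (bundle, cohort) make all outputs byte-reproducible.

What the simulator does **not** emulate: real microarray intensity
distributions, probe effects, batch structure, scale-free PPI degree
distributions, correlated domain content, or missing values. A green
test therefore establishes the machinery (scoring, selection, features,
classifier, CV protocol, determinism) on a world with known truth — not
performance on any real cohort.

## Numerical and degenerate-input choices

- Pearson correlation of a constant vector is NaN (flagged), and such
  neighbors are excluded rather than imputed; correlations are clipped
  to [−1, 1] against rounding.
- Feature values outside [0, 1] (possible only through user-supplied
  matrices) are clamped with a warning before binning; non-finite
  values are errors.
- Thresholds yielding zero signatures are skipped during tuning with a
  logged notice; if every threshold is skipped the protocol errors.
- Duplicate and self-interaction PPI records are dropped at read time
  with logged counts; a protein present only in the annotation table is
  kept as an isolated node; unannotated proteins score 0 rather than
  erroring (domain coverage of real proteomes is incomplete).
- Enrichment results sort by (p-value, domain id) for deterministic
  output; all writers iterate in sorted order so repeated runs are
  byte-identical.

## Known limitations

- The per-patient rank-difference feature discards expression
  magnitude; cohorts whose signal lives in amplitude rather than rank
  order need the `raw` feature mode.
- With 20 bins and α = 1, small training classes are noticeably
  smoothed; planted-signal classification accuracy on the default
  simulated world plateaus around 0.94–0.99 depending on seed, limited
  by poor-outcome patients whose hub signals happen to sit near the
  cohort median, where decoupling is invisible to rank differences.
- `loocv` with a threshold grid costs O(n² · |grid|) classifier fits.
- The Z-test for domain enrichment uses the normal approximation, which
  is anti-conservative for domains with very few DDI instances.
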