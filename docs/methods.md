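# Methods

## What is being modelled

Tumors from Lynch-syndrome families carry a germline pathogenic variant in
one MMR gene (MLH1, MSH2, MSH6 or PMS2); a somatic second hit abolishes
mismatch repair, which (i) removes the protein — detectable by IHC — and
(ii) lets replication slippage at mononucleotide repeats go uncorrected —
detectable as MSI. The package implements three detectors of this state and
an exact framework for measuring their pairwise agreement on a cohort, plus
a generator producing synthetic cohorts with the statistical structure the
analysis assumes.

## Synthetic cohort generator

The generator is the package's stand-in for FFPE tumor material; its
defaults are the study conditions, fixed once.

**Cohort composition.** 97 tumors with exact marginals: genes
MLH1/MSH2/MSH6/PMS2 = 9/64/23/1, carriers/FDRs = 74/23, ureter/renal
pelvis/bladder = 27/34/36. Covariate vectors are built with exact counts and
shuffled independently, so the marginals are deterministic while the joint
is random. Every tumor is treated as an independent sample; the source
cohort contains a few synchronous/metachronous multi-tumor patients whose
within-patient correlation is not modelled.

**Ground truth.** FDR tumors are MMR-proficient with probability 0.25 (the
FDR group can include non-carriers); carrier bladder tumors are sporadic
(proficient) with probability 0.1; everything else is deficient. These
mixture weights are knobs, not estimates.

**Read model.** Each marker receives `depth` = 2000 reads (the assay's
target depth). A read derives from the somatic deleted allele with
probability purity × clonal fraction (purity 0.6; clonal fraction uniform
on 0.4–0.9, multiplied by a gene attenuation factor — 0.5 for MSH6, which
repeatedly shows weaker instability, 1.0 otherwise). The somatic deletion
size per marker is a rounded normal with mean 4 bp (2 bp for MSH6, sd 1.5),
clipped to at least 1. PCR/FFPE stutter then shortens the read by
k ~ Geometric(λ = 0.05) repeat units (truncated at the allele length), with
one-base insertions at λ/10 — deletion-dominated, because insertion rates
do not separate MSI from MSS samples while deletion rates do. Reads are
drawn in a single multinomial over the induced length distribution, which
is distributionally identical to per-read simulation; the closed-form
deletion frequency implied by this mixture is exposed as
`expected_deletion_frequency` and used as the oracle in tests.

**Fragment-length assay emulation.** Deficient tumors draw each of the five
markers unstable with probability 0.6 × attenuation; the default is well
below 1 because urothelial tumors often show only subtle repeat shifts that
a trace reader will not call, making the fragment-length assay noticeably
less sensitive than sequencing. Proficient tumors have a 0.02 per-marker
false-positive rate. Non-unstable markers become "suggestive" (a 1–2 bp
trace shift unresolvable without germline DNA) with probability 0.05.

**IHC emulation.** Deficient tumors lose the family gene's protein and its
heterodimer partner; positivity fractions for lost proteins come from
Beta(1.5, 40) (mass concentrated below the 10 % cutoff) and for retained
proteins from Beta(20, 4). Missense-variant tumors retain expression with
probability 0.8 despite functional deficiency. The internal control is
absent with probability 0.02, which makes the stain non-evaluable.

**Quality and dropout.** DNA concentration is lognormal (log-mean 3.0,
log-sd 1.6 ng/µL), so roughly 2 of 97 samples fall at or below the strict
"> 1 ng/µL" analyzability threshold. Block age is uniform on 3–40 years;
per-assay non-evaluability is Bernoulli with logistic probability
σ(−3.0 + 0.08 × block_age), rising monotonically with archival age (~10 %
at 10 years, ~50 % at 38 years, averaging near the ~25–30 % dropout the
assays experience).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: locus-specific stutter profiles and quasi-
monomorphic variant alleles, polymerase/sequencing base errors, smMIP
single-molecule tag structure and PCR duplicates, subclonal MMR loss,
inter-observer variation in trace reading and stain scoring, and the true
genomic identities of the sequencing markers (the registry is a synthetic
stand-in with repeat lengths 7–27 drawn from a fixed internal seed).

## Feature extraction

Deletion = observed length strictly below the registry reference; with no
matched normal the germline allele is assumed at reference (markers are
chosen quasi-monomorphic). Allelic bias b is the fraction of deleted reads
at the single modal deleted length; the quantity is named in the assay
literature but not defined there, so this operational definition is a
reimplementation choice. Ties for the modal deleted length break toward the
larger deletion for determinism. A marker is evaluable at ≥ 200 reads (10 %
of the 2000-read target; the threshold is ours). A sample needs ≥ 50 % of
its panel evaluable, otherwise it is non-evaluable — the source analysis
reports only sample-level exclusions, no marker-coverage rule.

## Classifier

The approach is named naive-Bayes in the assay literature; the density
family is not published, so this implementation chooses Beta
class-conditionals for both features: bounded support, closed-form
method-of-moments fit, robust at d = 0. Choices that matter:

- **Shrinkage.** Per sample, d′ = (d·D + ε)/(D + 2ε) with ε = 1 read, so
  all-zero markers have finite likelihoods; the same shrinkage is applied
  at scoring time for consistency. The bias uses the analogous shrinkage
  with the deleted-read count as denominator, fitted only on samples with
  observed deletions (uniform Beta(1,1) fallback when a class has none);
  correspondingly the b-term is skipped when a scored marker shows no
  deletions.
- **Variance floor.** The method-of-moments variance is floored at 1e-4
  (and capped at 95 % of the Bernoulli bound). The floor keeps the
  class-conditional concentrations moderate when a class is nearly
  constant, which both regularizes 50-sample fits and keeps the fitted
  likelihood ratios monotone over the decision range.
- **Monotonicity.** Beta pairs with unequal concentrations are not globally
  likelihood-ratio ordered; the guarantee the classifier needs is that the
  log-LR in d is nondecreasing across the region between the two class
  means (where the call flips). `check_monotone` verifies this numerically
  at train time and rejects violating fits; it is opt-in because
  deliberately mis-labelled fits (the label-shuffled null calibration)
  legitimately violate it.
- **Priors and ties.** Equal class priors — the published decision
  threshold at 0 implies a prior-free likelihood-ratio rule. S = 0 is
  called MSS (the source defines only < 0 and > 0; ties resolve
  conservatively). Natural logarithms throughout, so the score scale is not
  comparable to other implementations' printed score ranges.

Cross-validation uses deterministic stratified k-folds (per-class
permutation, round-robin assignment) implemented in ~10 lines rather than
pulling in a heavier dependency.

## Concordance statistics

- Wilson score intervals (no continuity correction) for concordance; exact
  Clopper–Pearson (Beta-quantile) intervals for sensitivity and
  specificity. The source names Wilson for concordance but its printed
  bounds match no standard interval variant exactly (Wilson, Wilson with
  continuity, Agresti–Coull, Jeffreys and Clopper–Pearson were all
  checked); the standard Wilson formula is fixed here and diverges from two
  printed bounds by up to 0.4 percentage points.
- Exact McNemar: p = min(1, 2·P(X ≤ min(b,c))), X ~ Binomial(b+c, ½);
  p = 1 with no discordant pairs. Fisher's exact test is two-sided by the
  probability-mass rule. Both are cross-checked in the test suite against
  brute-force enumeration oracles.
- Pairs non-evaluable on either side are dropped listwise per assay, so
  each assay keeps its own denominator (68/72/72 on the published counts).

## Degenerate inputs and numerics

Empty confusion tables, empty margins, zero-margin Fisher tables,
single-class training sets, markers absent from a training class, duplicate
marker ids and out-of-range fractions all raise typed errors naming the
offending quantity. Proportions are clipped to [1e-4, 1−1e-4] before Beta
fitting. All randomness flows through NumPy `default_rng` generators seeded
from a single master seed via `SeedSequence.spawn`, so every pipeline run
is bit-reproducible given the seed.

## Problem sizes

The default study conditions — 97 tumors, 2000 reads per amplicon,
5 + 24 + 54 markers, 102 training samples, 5-fold cross-validation — run
end-to-end in a few seconds, so tests and the acceptance script use them
directly; a handful of unit tests reduce depth to 400–500 reads where only
the noise structure, not read-level precision, is under test.

## Known limitations

- The synthetic marker registry cannot reproduce marker-specific behavior
  of the real panels; panel-level differences in the simulation arise only
  from panel size and gene attenuation, so the simulated 24- vs 54-marker
  contrast is weaker than the real one.
- Simulated MSI scores are on the natural-log Beta-ratio scale and are not
  numerically comparable to published score ranges.
- The concordance framework treats IHC as an error-free reference when
  computing sensitivity/specificity, as the source analysis does; IHC
  misclassification is not propagated.
- Instability probabilities and noise levels are documented simulation
  knobs chosen to qualitatively match reported proportions, not estimates
  fitted to data.
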