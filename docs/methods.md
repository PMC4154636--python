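# Methods

## Model structure

The unit of prediction is one individual × one dichotomous phenotype. The
model is a three-layer network: observed genotypes (doses 0/1/2 at
annotated sites) feed per-gene alteration probabilities, which feed four
Bernoulli "mechanism" variables — phenotype explained by high-penetrance
variants (S_VH), low-penetrance variants (S_VL), high-penetrance genes
(S_GH), or low-penetrance genes (S_GL) — whose joint state determines the
phenotype indicator Y through a noisy-OR conditional:

    P(Y=1 | s) = 1 − Π_c (1 − w_c)^{s_c},   s_c ~ Bernoulli(q_c) independently,

with weights w = (π_VL, ρ_VH, ρ_GH, ρ_GL) and the low-penetrance-variant
mechanism always active (q_VL = 1). Marginalising the mechanism states
gives the closed form

    P(Y=1) = 1 − (1 − π_VL)(1 − q_VH ρ_VH)(1 − q_GH ρ_GH)(1 − q_GL ρ_GL)

where q_c is the probability that category c is genetically activated and
ρ_c its aggregate penetrance. The test suite verifies the closed form
against the 2⁴-state exhaustive enumeration to 1e−12 on randomised
parameters.

Assumptions inherited from the modelling tradition this follows, encoded
as an explicit parameter policy rather than hidden: GWAS hits and
uncurated gene associations are low penetrance; curated disease mutations
("DM" class) and their genes are high penetrance; a carried
high-penetrance variant dominates the posterior (emergent from ρ_VH =
0.95 rather than a hard override — with ρ_VH = 1 the dominance is exact);
gene–gene and variant–variant interactions are ignored (evidence
multiplies); only small-scale non-silent variants are considered; gene
alteration uses only rare (MAF < 0.01) variants.

## GWAS evidence

A hit's reported odds ratio OR, risk-allele frequency f and the phenotype
prevalence π determine per-genotype risks: odds are multiplicative per
allele, o_g = o₀·ORᵍ, r_g = o_g/(1+o_g), and the baseline o₀ is solved
(Brent's method, tolerance 1e−10, bracket (0, 10³)) so that the
Hardy–Weinberg-weighted mean risk equals π:

    (1−f)² r₀ + 2f(1−f) r₁ + f² r₂ = π.

This forces r₀ < π < r₂ whenever OR > 1: non-carriers are at
below-average risk, which is what makes a dose-0 genotype protective.
Each hit contributes a likelihood ratio r_dose/π; the chain multiplies
the prior and is capped (default 0.99) so that common variants alone can
never assert certainty. Hits whose site cannot be reconciled with the
genome's call (allele mismatch) are excluded from the chain rather than
imputed. Inclusion filter: 1 < OR ≤ 20; effect sizes reported as beta
coefficients are treated as log-odds and exponentiated first.

## Gene evidence

Per gene, the individual's rare non-silent calls are selected (MAF < 0.01
in every population recorded in the knowledge base — a config switch
relaxes this to *any* population; unobserved alleles count as rare;
consequence must be in the non-silent set, default {missense, nonsense,
frameshift, splice-site, in-frame-indel, stop-loss}). Their functional
p-values — from any variant scorer that emits p-values; scores are just a
mapping — are combined with Fisher's method, T = −2 Σ ln p over k
variants (p floored at 1e−10 so T stays finite).

The alteration posterior applies Bayes' rule with a parametric
alternative: damaging variants' p-values are taken as Beta(a, 1), so T is
Gamma(k, rate a/2) under the alternative and chi-square(2k) under the
null, giving the closed-form likelihood ratio a^k·exp((1−a)T/2) and

    P(altered | T, k) = expit(logit(ρ) + k ln a + (1−a)T/2).

Defaults a = 0.3, ρ = 0.05, both configurable and surfaced, not hidden:
they encode beliefs about the scorer's behaviour on damaging variants
(how concentrated near 0 its p-values are) and the base rate of genuinely
altered phenotype genes. With a = 1 the posterior reduces to ρ for every
T; for a < 1 it is strictly increasing in T. A gene with no qualifying
scored variant contributes 0. Within a phenotype, a gene annotated both
HIGH (curated) and LOW (mined) counts only as HIGH.

Category activation is a noisy-OR across the category's genes,
q = 1 − Π(1 − p_gene). A practical consequence, asserted in the tests:
adding a variant with p = 1 leaves T unchanged but increases k, which
*changes* the posterior — the null gains degrees of freedom.

## Priors

Prevalence entries are keyed by (phenotype, ancestry, gender, age band)
with ALL-wildcards and half-open age bands [lo, hi) in years. Lookup
takes the most specific matching entry, relaxing the age band first, then
ancestry, then gender, down to the phenotype-global row; a phenotype with
no entry raises a distinct signal and is excluded from prediction.
Genome-only evaluation replaces every prior with the cohort-average
prevalence (the mean of each phenotype's most global row). Single-category
modes (vh/vl/gh/gl) zero every other evidence term but keep the
prevalence as the leak, so a no-evidence individual still sits at the
prior in every mode.

## Cohort evaluation

Per phenotype, participants are ranked by descending posterior (ties by
participant id) and scored with the Mann–Whitney AUC (midranks; half
credit per tied case–control pair). Participants with unknown status, and
participants of a gender the phenotype does not apply to (declared in a
config map), are excluded and counted.

Two permutation nulls: shuffling participant identities applies one
permutation to all phenotype columns simultaneously, preserving the
within-participant correlation structure across phenotypes; shuffling
labels permutes one phenotype's status vector, treating phenotypes as
independent and exchangeable. Both use the add-one estimator
p = (1 + #{perm AUC ≥ observed})/(1 + n_perm), default n_perm = 10⁴,
seeds mandatory. The label test additionally supports exact enumeration
for a single case, where the null is uniform over the n possible case
positions and p = rank/n exactly; with one case at rank r and no ties,
AUC = (n−r)/(n−1). FDR is Benjamini–Hochberg on the permutation p-values
(the standard, reproducible choice; an empirical pooled-permutation FDR
would require the full joint result set of a specific cohort and is not
attempted).

The burden baseline counts rare (MAF < 0.01 in all recorded populations)
alleles with functional p-value below a threshold (default 0.05) in the
phenotype's annotated genes, het = 1 and hom = 2, ranked descending with
ties by participant id.

## Profile matching

A profile is a present/absent/unknown vector over phenotypes. The match
likelihood is independent-Bernoulli over known statuses, with each
posterior clamped into [ε, 1−ε] (ε = 1e−6) so hard 0/1 posteriors cannot
produce infinite log-likelihoods; unknowns contribute nothing. Ineligible
profiles (decoys known to belong to no sequenced sample) are excluded
before ranking; ties break by profile id. The random-matching null draws
each genome's top profile independently and uniformly over eligible
profiles, so the count of correct top-1 matches is Binomial(n_genomes,
1/n_profiles); the Monte-Carlo estimate is always reported alongside the
exact binomial tail. A permutation (without-replacement) null variant is
available behind a flag.

## Synthetic data

The generator emulates exactly the structure the model assumes: GWAS
genotypes in Hardy–Weinberg proportions with f ~ U(0.05, 0.5) and OR
log-uniform on (1, 20] (every generated hit passes the inclusion filter);
curated-variant carriage Bernoulli at low frequency (< 0.01 by
construction — high penetrance entails low prevalence); per-gene rare
non-silent variant counts Poisson, p-values Beta(a, 1) in truly altered
genes (altered with prior 0.05) and Uniform otherwise; occasional common
"distractor" variants with damaging-looking scores that the MAF filter
must remove; demographics uniform over declared vocabularies. Phenotype
status is drawn Bernoulli from the same closed-form posterior used in
inference. That choice makes rank-recovery a well-posed oracle — the
model is evaluated on data generated from its own assumptions — and
deliberately does *not* test model misspecification; passing recovery
tests says the implementation is faithful and the signal identifiable,
not that the model fits real cohorts. Sequencing error, linkage
disequilibrium between hits, and population structure are not simulated.

Two reference study designs ship as constructors. The hp-driven trait is
a 1-in-1000 near-Mendelian condition: ten curated variants, carrier
frequency 0.005 each, across ten high-penetrance genes, with the
rare-variant gene channel silent so the curated variants are the only
genetic signal. The GWAS-driven trait is a common complex condition
(prevalence 0.1): eight hits plus four mined low-penetrance genes whose
Poisson(1) rare variants are scored noise. Problem sizes used in the
recovery checks — cohorts of 500, 20 replicates — keep every generated
individual's full prediction pipeline exercised while the whole suite
stays fast.

## Numerical choices and degenerate inputs

* Posterior and activation formulas are plain products in [0,1]; the
  gene-alteration posterior is computed on the logit scale for stability.
* The penetrance solver refuses inputs outside 1 < OR ≤ 20, f ∈ (0,1),
  π ∈ (0,1) and reports the (OR, f, π) triple when no root exists in the
  bracket; solved triples are memoised, as cohorts re-use the same hits.
* Fisher's method floors p-values at 1e−10; empty p-value collections are
  a distinct "no evidence" signal, not T = 0.
* Rank ties everywhere break by ascending identifier, so reports are
  deterministic.
* Coordinates are 1-based, fully closed, forward strand in all formats;
  indels are compared as given without left-alignment, so knowledge base
  and genomes must share coordinate provenance (documented limitation).
* Absence of a call means homozygous genomic reference; no-call regions
  are not representable in the supported inputs. Dosing a risk allele
  that is itself the reference allele therefore requires the hit's
  `ref_allele` field; when it is unrecorded, an uncalled site doses 0.

## Known limitations

The category penetrances (ρ_VH = 0.95, ρ_GH = 0.8, ρ_GL = 0.3) and the
alteration-model parameters are fixed policy, not fitted — there is no
training step, and no cohort information enters the parameters. The
gene-alteration alternative is parametric (Beta(a,1)); a scorer whose
p-values behave differently under damage will mis-calibrate the gene
channel. Zygosity of curated variants is ignored beyond carriage (any
match activates the category — dominant-acting assumption; het matches
are logged). Phasing, imputation, structural and copy-number variation
are out of scope. Noisy-OR across many annotated genes saturates: a
phenotype with hundreds of annotated genes will show inflated activation
unless the per-gene prior is lowered accordingly.
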