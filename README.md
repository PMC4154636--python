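# phenobayes

Bayesian prediction of dichotomous clinical phenotypes from personal
genome variant calls.

Genome interpretation pipelines annotate variants one at a time; what an
individual actually wants to know is the probability that they have (or
will manifest) a specific trait, given *all* the relevant variants they
carry and who they are. `phenobayes` implements a probabilistic model that
integrates, per phenotype:

* a **prevalence prior** π stratified by ancestry, gender and age band;
* **GWAS hits** (common, low-penetrance variants), dosed by risk-allele
  count and converted to per-genotype risks from the reported odds ratio;
* **curated disease mutations** (high-penetrance variants, "DM" class);
* **phenotype-associated genes** (high- or low-penetrance), scored by the
  probability that the individual's rare non-silent variants altered the
  gene product.

It is aimed at methods developers and adult-cohort studies (volunteer
sequencing projects with self-reported trait questionnaires), not at
diagnostics. Alongside the model it ships the cohort evaluation machinery
(AUC, two permutation nulls, Benjamini–Hochberg FDR, a rare-allele burden
baseline), a genome↔phenotypic-profile matcher, and a synthetic-data
generator so that everything is testable without access to any restricted
database.

## The model

Evidence is organised into four independent Bernoulli "mechanism"
categories — high-penetrance variants (S_VH), low-penetrance variants
(S_VL), high-penetrance genes (S_GH), low-penetrance genes (S_GL) — and
the phenotype indicator Y follows a noisy-OR conditional over the active
mechanisms:

```
P(Y=1) = 1 − (1 − π_VL) · (1 − q_VH·ρ_VH) · (1 − q_GH·ρ_GH) · (1 − q_GL·ρ_GL)
```

* `π_VL` is the prior updated by a chain of per-hit GWAS likelihood
  ratios `LR = r_dose / π`, where the per-genotype risks `r_g` come from
  multiplicative per-allele odds `o_g = o₀·ORᵍ` with `o₀` solved so the
  Hardy–Weinberg-weighted mean risk equals π (so a non-carrier is
  genuinely *below* average risk);
* `q_VH` is 1 iff the genome carries a curated disease mutation for the
  phenotype;
* `q_GH`, `q_GL` are noisy-ORs of per-gene alteration posteriors: each
  gene's rare (MAF < 0.01) non-silent variants' functional p-values are
  combined with Fisher's method, `T = −2 Σ ln p`, and fed through Bayes'
  rule against a Beta(a, 1) alternative — the likelihood ratio is
  `a^k · exp((1−a)T/2)`;
* `ρ_VH ≥ ρ_GH ≥ ρ_GL` are category penetrance weights (defaults 0.95,
  0.8, 0.3) encoding the assumption that curated variants act strongly
  and mined gene associations weakly.

With no genetic evidence the posterior is exactly the prior. Profile
matching scores a genome against a trait questionnaire with an
independent Bernoulli likelihood, `Σ ln p̃` over reported-present traits
plus `Σ ln(1−p̃)` over reported-absent ones, and ranks profiles from most
to least probable.

## Worked example

`examples/01_predict_individual.py` builds a one-phenotype knowledge base
(GWAS hit with OR 2 and risk-allele frequency 0.3; one curated DM variant
in gene GENE_H; one mined gene GENE_L; prevalence 0.10) and predicts four
individuals:

```
per-dose risks for the GWAS hit: r0=0.0632 r1=0.1189 r2=0.2125 (prevalence 0.10)

no relevant variants                posterior=0.0632  (pi_VL=0.063 q_VH=0 q_GH=0.000 q_GL=0.000)
het GWAS risk allele                posterior=0.1189  (pi_VL=0.119 q_VH=0 q_GH=0.000 q_GL=0.000)
rare damaging missense in GENE_L    posterior=0.1183  (pi_VL=0.063 q_VH=0 q_GH=0.000 q_GL=0.196)
curated disease mutation (het)      posterior=0.9532  (pi_VL=0.063 q_VH=1 q_GH=0.000 q_GL=0.000)
```

Reading the numbers: the Hardy–Weinberg constraint pushes a non-carrier
*below* the 0.10 prior (0.063) because carrying zero risk alleles is
itself informative; one risk allele lifts the posterior to the
heterozygote risk (0.119); a rare damaging missense raises the
low-penetrance-gene activation to 0.196, worth about the same; and a
curated disease mutation dominates everything (0.95 penetrance weight).

The other examples cover cohort evaluation (`02`, AUC/permutation/FDR
with a Figure-style rank-ordered report), profile matching against
decoys with the random-matching null (`03`), and the model-vs-burden
contrast (`04`).

A `phenobayes` CLI wraps the same functions (`simulate`, `predict`,
`evaluate`, `match`, `matchnull`); every input and output is plain TSV,
and VCF genome input is supported.

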