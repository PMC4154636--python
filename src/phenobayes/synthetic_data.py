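"""Synthetic knowledge bases, cohorts and phenotypic profiles.

The generator emulates the statistical structure the prediction model
assumes, so every other module can be exercised end to end without any
external database:

* GWAS hits with risk-allele frequencies uniform on (0.05, 0.5) and odds
  ratios log-uniform on (1, 20] (so every generated hit passes the
  inclusion filter);
* curated high-penetrance variants placed inside high-penetrance genes,
  carried at low frequency (carrier probability < 0.01, reflecting the
  assumption that highly penetrant variants are rare);
* per-gene rare non-silent variant counts Poisson-distributed, with
  functional p-values drawn Beta(a, 1) when the gene is truly altered and
  Uniform(0, 1) otherwise, plus occasional common "distractor" variants
  that the MAF filter must remove;
* genotypes at GWAS hits in Hardy–Weinberg proportions;
* phenotype status drawn Bernoulli from the same closed-form posterior
  used in inference — parameter and rank recovery are therefore
  well-posed oracles (at the cost of not testing model misspecification);
* phenotypic profiles copying cohort statuses with unknown-masking, plus
  decoy profiles drawn from the cohort marginals, a configurable fraction
  of them flagged ineligible.

All randomness flows through one seeded generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation_kb import (
    ALL,
    AnnotationKB,
    GeneAssociation,
    GwasHit,
    HIGH,
    HighPenetranceVariant,
    LOW,
    PrevalenceEntry,
    PrevalenceTable,
    write_kb,
)
from .bayes_model import ModelParams, predict
from .functional_scoring import AlterationModelParams, VariantKey, write_scores
from .genome_io import (
    ABSENT,
    PRESENT,
    UNKNOWN,
    CohortPhenotypes,
    GenotypeCall,
    PersonalGenome,
    write_genomes_tsv,
    write_participants_tsv,
    write_phenotypes_tsv,
)
from .profile_matching import PhenotypeProfile, write_profiles_tsv

ANCESTRIES = ("EUR", "AFR", "EAS")
GENDERS = ("F", "M")
POPULATIONS = ("EA", "AA")


@dataclass(frozen=True)
class PhenotypeSpec:
    """Generative settings for one synthetic phenotype."""

    name: str
    prevalence: float
    n_gwas_hits: int = 0
    n_high_pen_genes: int = 0
    n_low_pen_genes: int = 0
    n_hp_variants: int = 0
    hp_carrier_freq: float = 0.005
    rare_variant_mean: float = 1.0  # Poisson mean per gene per individual

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0,1)")
        if not 0.0 <= self.hp_carrier_freq < 0.01:
            raise ValueError(
                "hp_carrier_freq must lie in [0, 0.01): highly penetrant "
                "variants are rare by assumption"
            )


@dataclass
class SimConfig:
    """Cohort-level generative settings."""

    n_participants: int
    phenotypes: list[PhenotypeSpec]
    or_support: tuple[float, float] = (1.0, 20.0)  # log-uniform, open at 1
    raf_support: tuple[float, float] = (0.05, 0.5)
    beta_shape: float = 0.3  # p-value law Beta(a,1) in altered genes
    gene_altered_prior: float = 0.05
    distractor_rate: float = 0.2  # common damaging-looking variant per gene
    profile_missingness: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1.0 <= self.or_support[0] < self.or_support[1] <= 20.0:
            raise ValueError("odds-ratio support must lie within (1, 20]")
        if not 0.0 < self.raf_support[0] < self.raf_support[1] < 1.0:
            raise ValueError("risk-allele-frequency support must lie in (0,1)")


def hp_driven_spec(name: str = "hp_trait") -> PhenotypeSpec:
    """A near-Mendelian trait: rare (1/1000), driven by curated variants.

    Ten disease mutations, each carried with probability 0.005, spread over
    ten high-penetrance genes. The rare-variant gene channel is silent
    (``rare_variant_mean=0``): the phenotype is driven by the curated
    variants alone, so carriers stand out against the prevalence baseline.
    """
    return PhenotypeSpec(
        name=name,
        prevalence=0.001,
        n_hp_variants=10,
        n_high_pen_genes=10,
        hp_carrier_freq=0.005,
        rare_variant_mean=0.0,
    )


def gwas_driven_spec(name: str = "gwas_trait") -> PhenotypeSpec:
    """A common complex trait (prevalence 0.1) driven by eight GWAS hits,
    with four mined low-penetrance genes contributing rare-variant noise."""
    return PhenotypeSpec(
        name=name,
        prevalence=0.1,
        n_gwas_hits=8,
        n_low_pen_genes=4,
    )


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# genome layout constants (1-based coordinates, one chromosome per phenotype)
_GWAS_BASE = 1_000_000
_GENE_BASE = 10_000_000
_GENE_SPACING = 100_000
_GENE_LENGTH = 50_000


def gen_kb(config: SimConfig, rng=None) -> AnnotationKB:
    """Generate a knowledge base matching the config.

    Each phenotype lives on its own synthetic chromosome; gene sets are
    disjoint across categories within a phenotype; every generated GWAS
    hit passes the odds-ratio inclusion filter by construction; the
    prevalence table holds one ALL-wildcard row per phenotype.
    """
    rng = _rng(config.seed if rng is None else rng)
    kb = AnnotationKB()
    for i, spec in enumerate(config.phenotypes):
        chrom = f"chr{i + 1}"
        lo, hi = config.or_support
        for j in range(spec.n_gwas_hits):
            odds = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            odds = max(odds, np.nextafter(1.0, 2.0))  # strictly > 1
            kb.gwas_hits.append(
                GwasHit(
                    rsid=f"rs{i + 1}{j:04d}",
                    chrom=chrom,
                    pos=_GWAS_BASE + j * 1000,
                    risk_allele="G",
                    other_allele="A",
                    effect_size=odds,
                    risk_allele_freq=float(rng.uniform(*config.raf_support)),
                    phenotype=spec.name,
                    ref_allele="A",
                )
            )
        genes_high = [f"{spec.name}_GH{j}" for j in range(spec.n_high_pen_genes)]
        genes_low = [f"{spec.name}_GL{j}" for j in range(spec.n_low_pen_genes)]
        if spec.n_hp_variants and not genes_high:
            genes_high = [f"{spec.name}_GH0"]
        for j, gene in enumerate(genes_high + genes_low):
            start = _GENE_BASE + j * _GENE_SPACING
            kb.gene_regions[gene] = (chrom, start, start + _GENE_LENGTH - 1)
        for gene in genes_high:
            kb.gene_assocs.append(GeneAssociation(gene, spec.name, HIGH))
        for gene in genes_low:
            kb.gene_assocs.append(
                GeneAssociation(gene, spec.name, LOW, zscore=float(rng.uniform(4.1, 9.0)))
            )
        for k in range(spec.n_hp_variants):
            gene = genes_high[k % len(genes_high)]
            chrom_g, start, _end = kb.gene_regions[gene]
            kb.hp_variants.append(
                HighPenetranceVariant(
                    chrom=chrom_g,
                    pos=start + k,  # distinct site per variant
                    ref_allele="C",
                    alt_allele="T",
                    gene=gene,
                    phenotype=spec.name,
                )
            )
        kb.prevalence.add(
            PrevalenceEntry(
                phenotype=spec.name,
                ancestry=ALL,
                gender=ALL,
                age_lo=None,
                age_hi=None,
                prevalence=spec.prevalence,
                source="synthetic",
            )
        )
    kb.__post_init__()
    return kb


def gen_cohort(
    kb: AnnotationKB,
    config: SimConfig,
    rng=None,
    model_params: ModelParams = ModelParams(),
) -> tuple[list[PersonalGenome], CohortPhenotypes, dict[VariantKey, float]]:
    """Generate genomes, statuses and functional scores for a cohort.

    GWAS doses follow Hardy–Weinberg proportions of the hit's risk-allele
    frequency; curated-variant carriage is Bernoulli(hp_carrier_freq);
    per-gene rare non-silent variant counts are Poisson, their p-values
    Beta(a, 1) in truly altered genes (altered with the configured prior)
    and Uniform otherwise. Phenotype status is then drawn Bernoulli from
    the model's own closed-form posterior, so recovery tests are
    well-posed. The rare variants' allele frequencies and consequence
    labels are registered into ``kb`` in place.
    """
    rng = _rng(config.seed if rng is None else rng)
    alteration = AlterationModelParams(
        prior_altered=config.gene_altered_prior, beta_shape=config.beta_shape
    )
    scores: dict[VariantKey, float] = {}
    genomes: list[PersonalGenome] = []
    next_offset = {gene: 100 for gene in kb.gene_regions}  # position allocator

    for p in range(config.n_participants):
        pid = f"S{p:04d}"
        calls: list[GenotypeCall] = []
        for spec in config.phenotypes:
            for hit in kb.gwas_for(spec.name):
                f = hit.risk_allele_freq
                dose = int(
                    rng.choice(3, p=[(1 - f) ** 2, 2 * f * (1 - f), f**2])
                )
                if dose:
                    calls.append(
                        GenotypeCall(
                            chrom=hit.chrom,
                            pos=hit.pos,
                            ref_allele=hit.other_allele,
                            alt_allele=hit.risk_allele,
                            allele_count=dose,
                        )
                    )
            for v in kb.hp_variants_for(spec.name):
                if rng.random() < spec.hp_carrier_freq:
                    calls.append(
                        GenotypeCall(
                            chrom=v.chrom,
                            pos=v.pos,
                            ref_allele=v.ref_allele,
                            alt_allele=v.alt_allele,
                            allele_count=1,
                        )
                    )
            genes = kb.genes_for(spec.name, HIGH) + kb.genes_for(spec.name, LOW)
            for gene in genes:
                chrom, start, end = kb.gene_regions[gene]
                altered = rng.random() < config.gene_altered_prior
                n_vars = int(rng.poisson(spec.rare_variant_mean))
                for _ in range(n_vars):
                    pos = start + next_offset[gene]
                    next_offset[gene] += 1
                    if pos > end:  # gene saturated; skip silently
                        continue
                    alt = str(rng.choice(["C", "G", "T"]))
                    call = GenotypeCall(
                        chrom=chrom,
                        pos=pos,
                        ref_allele="A",
                        alt_allele=alt,
                        allele_count=1 if rng.random() < 0.95 else 2,
                    )
                    calls.append(call)
                    key = (chrom, pos, alt)
                    kb.allele_freqs[key] = {
                        popn: float(rng.uniform(1e-4, 0.009))
                        for popn in POPULATIONS
                    }
                    kb.consequences[(chrom, pos, "A", alt)] = "missense"
                    p_value = (
                        float(rng.beta(config.beta_shape, 1.0))
                        if altered
                        else float(rng.uniform())
                    )
                    scores[(chrom, pos, "A", alt)] = max(p_value, 1e-12)
                if rng.random() < config.distractor_rate:
                    # a common, damaging-looking variant the MAF filter
                    # must exclude from gene scoring
                    pos = start + next_offset[gene]
                    next_offset[gene] += 1
                    call = GenotypeCall(
                        chrom=chrom, pos=pos, ref_allele="A",
                        alt_allele="T", allele_count=1,
                    )
                    calls.append(call)
                    kb.allele_freqs[(chrom, pos, "T")] = {
                        popn: 0.02 for popn in POPULATIONS
                    }
                    kb.consequences[(chrom, pos, "A", "T")] = "missense"
                    scores[(chrom, pos, "A", "T")] = max(
                        float(rng.beta(config.beta_shape, 1.0)), 1e-12
                    )
        genomes.append(
            PersonalGenome(
                participant_id=pid,
                calls=calls,
                age=float(rng.uniform(20, 80)),
                gender=str(rng.choice(GENDERS)),
                ancestry=str(rng.choice(ANCESTRIES)),
            )
        )

    status = {}
    for spec in config.phenotypes:
        column = {}
        for genome in genomes:
            post = predict(
                genome, spec.name, kb, scores, model_params,
                mode="full", alteration_params=alteration,
            ).posterior
            column[genome.participant_id] = (
                PRESENT if rng.random() < post else ABSENT
            )
        status[spec.name] = column
    frame = pd.DataFrame(status).reindex([g.participant_id for g in genomes])
    return genomes, CohortPhenotypes(frame), scores


def gen_profiles(
    cohort: CohortPhenotypes,
    n_decoys: int,
    missingness: float,
    rng=None,
    seed: int = 0,
    ineligible_fraction: float = 0.5,
    decoy_marginals: Mapping[str, float] | None = None,
) -> tuple[list[PhenotypeProfile], dict[str, str]]:
    """Profiles for every cohort member plus decoys; returns a truth map.

    True profiles copy the cohort statuses with each known status masked
    to unknown at the missingness rate. Decoys draw each phenotype
    independently from the cohort marginal frequency of the phenotype
    (or supplied marginals) and a fraction of them are flagged ineligible
    — profiles known to belong to no sequenced sample, excludable before
    ranking. Profile identifiers are shuffled so position encodes nothing.
    """
    rng = _rng(seed if rng is None else rng)
    if not 0.0 <= missingness < 1.0:
        raise ValueError("missingness must lie in [0,1)")
    phenotypes = cohort.phenotypes
    if decoy_marginals is None:
        decoy_marginals = {}
        for pheno in phenotypes:
            col = cohort.frame[pheno]
            known = col.isin([PRESENT, ABSENT])
            decoy_marginals[pheno] = (
                float((col[known] == PRESENT).mean()) if known.any() else 0.5
            )

    n_true = len(cohort.participants)
    ids = [f"PRF{j:04d}" for j in range(n_true + n_decoys)]
    rng.shuffle(ids)

    def mask(status: str) -> str:
        if status != UNKNOWN and rng.random() < missingness:
            return UNKNOWN
        return status

    profiles = []
    truth: dict[str, str] = {}
    for idx, pid in enumerate(cohort.participants):
        statuses = {
            pheno: mask(cohort.status(pid, pheno)) for pheno in phenotypes
        }
        profiles.append(PhenotypeProfile(ids[idx], statuses, eligible=True))
        truth[pid] = ids[idx]
    n_ineligible = int(round(ineligible_fraction * n_decoys))
    for d in range(n_decoys):
        statuses = {
            pheno: mask(
                PRESENT if rng.random() < decoy_marginals[pheno] else ABSENT
            )
            for pheno in phenotypes
        }
        profiles.append(
            PhenotypeProfile(
                ids[n_true + d], statuses, eligible=(d >= n_ineligible)
            )
        )
    profiles.sort(key=lambda p: p.profile_id)
    return profiles, truth


def simulate_to_dir(
    config: SimConfig,
    outdir: str | Path,
    n_decoys: int = 0,
    model_params: ModelParams = ModelParams(),
) -> None:
    """Generate a full study and write it in the package's TSV dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    kb = gen_kb(config, rng)
    genomes, cohort, scores = gen_cohort(kb, config, rng, model_params)
    profiles, truth = gen_profiles(
        cohort, n_decoys, config.profile_missingness, rng
    )
    write_kb(kb, outdir / "kb")
    write_genomes_tsv(genomes, outdir / "genomes.tsv")
    write_participants_tsv(genomes, outdir / "participants.tsv")
    write_phenotypes_tsv(cohort, outdir / "phenotypes.tsv")
    write_scores(scores, outdir / "scores.tsv")
    write_profiles_tsv(
        profiles, outdir / "profiles.tsv", outdir / "eligibility.tsv"
    )
    pd.DataFrame(
        [{"participant_id": k, "profile_id": v} for k, v in truth.items()],
        columns=["participant_id", "profile_id"],
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "seed.txt", "w") as fh:
        fh.write(f"seed={config.seed}\n")
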