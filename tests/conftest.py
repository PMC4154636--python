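import numpy as np
import pytest

from phenobayes import (
    ALL,
    AnnotationKB,
    GeneAssociation,
    GenotypeCall,
    GwasHit,
    HIGH,
    HighPenetranceVariant,
    LOW,
    PersonalGenome,
    PrevalenceEntry,
)


@pytest.fixture
def kb():
    """Hand-built KB for one phenotype with every evidence category.

    pheno_a on chr1: one GWAS hit at 1000 (risk G over ref A, OR 2,
    f 0.3); one curated DM variant C>T at 5010 inside HIGH gene GENE_H
    (5000-5999); mined LOW gene GENE_L (6000-6999). Rare missense
    variants are annotated at 6100 (p recorded in the scores fixture) and
    a common missense at 6200 that the MAF filter must drop; a synonymous
    rare variant sits at 6300.
    """
    kb = AnnotationKB(
        gwas_hits=[
            GwasHit(
                rsid="rs1", chrom="chr1", pos=1000,
                risk_allele="G", other_allele="A",
                effect_size=2.0, risk_allele_freq=0.3,
                phenotype="pheno_a", ref_allele="A",
            )
        ],
        hp_variants=[
            HighPenetranceVariant(
                chrom="chr1", pos=5010, ref_allele="C", alt_allele="T",
                gene="GENE_H", phenotype="pheno_a",
            )
        ],
        gene_assocs=[
            GeneAssociation("GENE_H", "pheno_a", HIGH),
            GeneAssociation("GENE_L", "pheno_a", LOW, zscore=5.0),
        ],
        allele_freqs={
            ("chr1", 6100, "G"): {"EA": 0.005, "AA": 0.002},
            ("chr1", 6200, "G"): {"EA": 0.005, "AA": 0.02},
            ("chr1", 6300, "T"): {"EA": 0.001},
        },
        consequences={
            ("chr1", 6100, "A", "G"): "missense",
            ("chr1", 6200, "A", "G"): "missense",
            ("chr1", 6300, "A", "T"): "synonymous",
        },
        gene_regions={
            "GENE_H": ("chr1", 5000, 5999),
            "GENE_L": ("chr1", 6000, 6999),
        },
    )
    kb.prevalence.add(
        PrevalenceEntry("pheno_a", ALL, ALL, None, None, 0.1, "global")
    )
    return kb


@pytest.fixture
def scores():
    return {
        ("chr1", 6100, "A", "G"): 0.05,
        ("chr1", 6200, "A", "G"): 0.01,
        ("chr1", 6300, "A", "T"): 0.02,
    }


@pytest.fixture
def genome():
    """Carrier of the GWAS risk allele (het), the DM variant (het), and
    one rare missense in GENE_L, plus filtered-out distractors."""
    return PersonalGenome(
        participant_id="S1",
        calls=[
            GenotypeCall("chr1", 1000, "A", "G", 1),
            GenotypeCall("chr1", 5010, "C", "T", 1),
            GenotypeCall("chr1", 6100, "A", "G", 1),
            GenotypeCall("chr1", 6200, "A", "G", 1),  # common -> dropped
            GenotypeCall("chr1", 6300, "A", "T", 1),  # synonymous -> dropped
        ],
        age=45, gender="F", ancestry="EUR",
    )


@pytest.fixture
def empty_genome():
    return PersonalGenome(
        participant_id="S0", calls=[], age=50, gender="M", ancestry="EUR"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240904)
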