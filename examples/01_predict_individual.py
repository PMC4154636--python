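"""Predict one individual's probability of a phenotype from their variants.

Builds a miniature knowledge base for a fictional trait — one GWAS hit, one
curated disease mutation in a high-penetrance gene, one literature-mined
low-penetrance gene — plus a small personal genome, then walks the model
through prevalence lookup, GWAS dosing, gene scoring and the noisy-OR
posterior.
"""

from phenobayes import (
    ALL,
    AnnotationKB,
    GeneAssociation,
    GenotypeCall,
    GwasHit,
    HighPenetranceVariant,
    PersonalGenome,
    PrevalenceEntry,
    gwas_genotype_penetrance,
    predict,
)

kb = AnnotationKB(
    gwas_hits=[
        GwasHit("rs1", "chr1", 1000, risk_allele="G", other_allele="A",
                effect_size=2.0, risk_allele_freq=0.3, phenotype="trait",
                ref_allele="A")
    ],
    hp_variants=[
        HighPenetranceVariant("chr1", 5010, "C", "T", gene="GENE_H",
                              phenotype="trait")
    ],
    gene_assocs=[GeneAssociation("GENE_L", "trait", "LOW", zscore=5.0)],
    allele_freqs={("chr1", 6100, "G"): {"EA": 0.005, "AA": 0.002}},
    consequences={("chr1", 6100, "A", "G"): "missense"},
    gene_regions={"GENE_H": ("chr1", 5000, 5999),
                  "GENE_L": ("chr1", 6000, 6999)},
)
kb.prevalence.add(PrevalenceEntry("trait", ALL, ALL, None, None, 0.10))
scores = {("chr1", 6100, "A", "G"): 0.02}  # a damaging-looking missense

# What does one GWAS risk allele imply? The odds ratio, allele frequency
# and prevalence pin down per-genotype risks under Hardy-Weinberg.
risks = gwas_genotype_penetrance(odds_ratio=2.0, freq=0.3, prior=0.10)
print(f"per-dose risks for the GWAS hit: r0={risks.r0:.4f} "
      f"r1={risks.r1:.4f} r2={risks.r2:.4f} (prevalence 0.10)")
print("  -> a non-carrier is at below-average risk; a homozygous carrier "
      "roughly doubles the prior.\n")

individuals = {
    "no relevant variants": [],
    "het GWAS risk allele": [GenotypeCall("chr1", 1000, "A", "G", 1)],
    "rare damaging missense in GENE_L": [GenotypeCall("chr1", 6100, "A", "G", 1)],
    "curated disease mutation (het)": [GenotypeCall("chr1", 5010, "C", "T", 1)],
}
for label, calls in individuals.items():
    genome = PersonalGenome("demo", calls, age=45, gender="F", ancestry="EUR")
    res = predict(genome, "trait", kb, scores)
    b = res.breakdown
    print(f"{label:35s} posterior={res.posterior:.4f}  "
          f"(pi_VL={b['pi_vl']:.3f} q_VH={b['q_vh']:.0f} "
          f"q_GH={b['q_gh']:.3f} q_GL={b['q_gl']:.3f})")

print("\nThe curated mutation dominates (penetrance weight 0.95); the GWAS "
      "and gene channels nudge the 0.10 prior up or down.")
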