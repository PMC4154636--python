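"""Compare the integrated model against a rare-allele burden baseline.

On a GWAS-driven phenotype the burden of rare damaging alleles in the
phenotype's gene set carries little signal, while the model also dosed
the common risk alleles: the model's AUC should win. The contrast is
repeated over ten replicate cohorts.
"""

import numpy as np

import phenobayes as pb
from phenobayes.cohort_eval import auc, burden_baseline
from phenobayes.genome_io import PRESENT

print(f"{'replicate':>9s} {'model AUC':>10s} {'burden AUC':>11s}")
wins = 0
for seed in range(10):
    cfg = pb.SimConfig(
        n_participants=300, phenotypes=[pb.gwas_driven_spec()], seed=seed
    )
    rng = np.random.default_rng(seed)
    kb = pb.gen_kb(cfg, rng)
    genomes, cohort, scores = pb.gen_cohort(kb, cfg, rng)
    y = (cohort.frame["gwas_trait"] == PRESENT).astype(int).to_numpy()
    post = pb.predict_cohort(genomes, ["gwas_trait"], kb, scores)
    model_auc = auc(post["gwas_trait"].to_numpy(), y)
    burden = burden_baseline(genomes, kb, "gwas_trait", scores).reindex(
        post.index
    )
    burden_auc = auc(burden.to_numpy(), y)
    wins += model_auc > burden_auc
    print(f"{seed:>9d} {model_auc:>10.3f} {burden_auc:>11.3f}")

print(f"\nmodel beats burden in {wins}/10 replicates: counting damaging "
      "alleles misses the common-variant signal the model doses "
      "through GWAS odds ratios.")
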