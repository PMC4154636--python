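"""Match genomes to phenotypic profiles by Bernoulli likelihood.

Simulates 40 individuals over twenty phenotypes (a small trait
questionnaire), builds one true profile per individual (10% of statuses
masked unknown) plus 40 decoy profiles (half flagged ineligible and
excluded up front), ranks all eligible profiles for each genome, and
compares the result with the uniformly-random matching null.
"""

import numpy as np

import phenobayes as pb

specs = [pb.gwas_driven_spec(f"trait_{i}") for i in range(14)] + [
    pb.hp_driven_spec(f"rare_{i}") for i in range(6)
]
cfg = pb.SimConfig(n_participants=40, phenotypes=specs, seed=5)
rng = np.random.default_rng(cfg.seed)
kb = pb.gen_kb(cfg, rng)
genomes, cohort, scores = pb.gen_cohort(kb, cfg, rng)
posteriors = pb.predict_cohort(genomes, cohort.phenotypes, kb, scores)

profiles, truth = pb.gen_profiles(
    cohort, n_decoys=40, missingness=0.1, rng=rng, ineligible_fraction=0.5
)
n_eligible = sum(p.eligible for p in profiles)

results = [
    pb.rank_profiles(g.participant_id,
                     posteriors.loc[g.participant_id].to_dict(), profiles)
    for g in genomes
]
n_top1, mean_rank = pb.evaluate_matching(results, truth)
print(f"eligible profiles ranked per genome: {n_eligible}")
print(f"correct top-1 matches: {n_top1} / {len(genomes)}")
print(f"mean rank of the true profile: {mean_rank:.1f} "
      f"(random guessing would average {(n_eligible + 1) / 2:.1f})")

null = pb.null_matching_significance(
    n_genomes=len(genomes), n_profiles=n_eligible, threshold=n_top1,
    n_trials=10_000, seed=cfg.seed,
)
print(f"\nP(random matching achieves >= {n_top1} correct): "
      f"empirical {null.empirical_significance:.4g} over {null.n_trials} "
      f"trials; exact binomial tail {null.exact_binomial_tail:.4g}")
print("A mean rank well below the random-guess average — and a small "
      "tail probability when any top-1 hits occur — shows the profiles "
      "carry identifying signal; twenty dichotomous traits is still far "
      "less information than a full questionnaire.")
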