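"""The phenotype-prediction model.

Evidence for a dichotomous phenotype is organised into four mechanism
categories: high-penetrance variants (curated disease mutations carried by
the individual), low-penetrance variants (GWAS hits, dosed by risk-allele
count), and high- and low-penetrance phenotype-associated genes (scored by
the probability that rare non-silent variants altered the gene product).
Each category is an independent Bernoulli "mechanism" that can explain the
phenotype; the phenotype indicator Y follows a noisy-OR conditional over
the active mechanisms, with the GWAS-updated prevalence acting as the
leak. The closed-form posterior is

    P(Y=1) = 1 − (1 − π_VL) (1 − q_VH ρ_VH) (1 − q_GH ρ_GH) (1 − q_GL ρ_GL)

where π_VL is the prevalence prior updated by the per-hit GWAS likelihood
ratios, q_c is the probability that category c is genetically activated,
and ρ_c is the category's aggregate penetrance. The same quantity equals
the expectation over the 2⁴ joint mechanism states of the noisy-OR
conditional, which the test suite verifies by exhaustive enumeration.

GWAS penetrance per genotype is derived from the reported odds ratio,
risk-allele frequency and phenotype prevalence: per-genotype odds are
o_g = o₀·ORᵍ, and the baseline o₀ is solved so that the
Hardy–Weinberg-weighted mean risk equals the prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from scipy.optimize import brentq

from .annotation_kb import HIGH, LOW, AnnotationKB, average_prevalence
from .exceptions import NoPrevalence, NotPredictable
from .functional_scoring import AlterationModelParams, VariantKey, score_gene
from .genome_io import PersonalGenome, match_hp_variant, risk_allele_dose

MODES = ("full", "genome_only", "prevalence_only", "vh", "vl", "gh", "gl")

#: solver bracket for the baseline odds o0 and convergence tolerance
_O0_MAX = 1e3
_HWE_TOL = 1e-10


@dataclass(frozen=True)
class ModelParams:
    """Category penetrances and numerical guards.

    Defaults encode the ordering assumption that curated disease variants
    act with near-complete penetrance, curated disease genes below them,
    and mined gene associations lowest; the posterior contribution of the
    multiplicative GWAS chain is capped below 1.
    """

    rho_vh: float = 0.95
    rho_gh: float = 0.80
    rho_gl: float = 0.30
    posterior_cap: float = 0.99
    gwas_model: str = "multiplicative-odds"

    def __post_init__(self) -> None:
        for name in ("rho_vh", "rho_gh", "rho_gl"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if not 0.0 < self.posterior_cap < 1.0:
            raise ValueError("posterior_cap must lie in (0,1)")
        if self.gwas_model != "multiplicative-odds":
            raise ValueError(f"unknown gwas_model {self.gwas_model!r}")


@dataclass(frozen=True)
class PenetranceTriple:
    """Per-dose risks (r0, r1, r2) for one GWAS hit, tied to the prior
    they were solved against."""

    r0: float
    r1: float
    r2: float
    prior: float

    def __getitem__(self, dose: int) -> float:
        return (self.r0, self.r1, self.r2)[dose]


@dataclass
class MechanismEvidence:
    """Per-category genetic evidence for one individual and phenotype."""

    q_vh: float = 0.0
    q_gh: float = 0.0
    q_gl: float = 0.0
    gwas_lr: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("q_vh", "q_gh", "q_gl"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        for lr in self.gwas_lr:
            if not (lr >= 0.0 and math.isfinite(lr)):
                raise ValueError(f"GWAS likelihood ratio invalid: {lr}")


@dataclass
class PosteriorResult:
    participant_id: str
    phenotype: str
    prior: float
    posterior: float
    breakdown: dict[str, float]
    mode: str


@lru_cache(maxsize=65536)
def gwas_genotype_penetrance(
    odds_ratio: float, freq: float, prior: float
) -> PenetranceTriple:
    """Per-genotype phenotype risks implied by a GWAS hit.

    Odds are multiplicative per risk allele: o_g = o0·OR^g, r_g =
    o_g/(1+o_g). The baseline odds o0 is solved so that the
    Hardy–Weinberg-weighted mean risk over doses equals the phenotype
    prevalence ``prior``. Under OR > 1 this forces r0 < prior < r2: a
    non-carrier is at below-average risk.
    """
    if not 1.0 < odds_ratio <= 20.0:
        raise ValueError(f"odds ratio must lie in (1,20], got {odds_ratio}")
    if not 0.0 < freq < 1.0:
        raise ValueError(f"risk allele frequency must lie in (0,1), got {freq}")
    if not 0.0 < prior < 1.0:
        raise ValueError(f"prior must lie in (0,1), got {prior}")

    w = ((1 - freq) ** 2, 2 * freq * (1 - freq), freq**2)

    def hwe_mean_minus_prior(o0: float) -> float:
        total = 0.0
        for g in range(3):
            og = o0 * odds_ratio**g
            total += w[g] * og / (1.0 + og)
        return total - prior

    lo, hi = 1e-300, _O0_MAX
    if hwe_mean_minus_prior(hi) < 0:
        raise ValueError(
            f"no baseline-odds root in (0, {_O0_MAX}) for OR={odds_ratio}, "
            f"f={freq}, prior={prior}"
        )
    o0 = brentq(hwe_mean_minus_prior, lo, hi, xtol=_HWE_TOL, rtol=8.9e-16)
    risks = tuple(
        o0 * odds_ratio**g / (1.0 + o0 * odds_ratio**g) for g in range(3)
    )
    return PenetranceTriple(*risks, prior=prior)


def gwas_update(
    prior: float,
    hits: Iterable[tuple[int, PenetranceTriple]],
    cap: float = 0.99,
) -> float:
    """Prevalence updated by a chain of per-hit likelihood ratios.

    Each hit contributes LR = r_dose / prior; the chain multiplies the
    prior and is clamped at ``cap``. Hits whose dose is None
    (unresolvable site) must be excluded by the caller before this point.
    """
    updated = prior
    any_hit = False
    for dose, risks in hits:
        if abs(risks.prior - prior) > 1e-9:
            raise ValueError(
                f"penetrance solved against prior {risks.prior}, but update "
                f"uses prior {prior}"
            )
        updated *= risks[dose] / prior
        any_hit = True
    return min(cap, updated) if any_hit else prior


def category_activation(gene_posteriors: Iterable[float]) -> float:
    """Noisy-OR across a category's genes: q = 1 − Π(1 − p)."""
    q_complement = 1.0
    for p in gene_posteriors:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"gene posterior out of [0,1]: {p}")
        q_complement *= 1.0 - p
    return 1.0 - q_complement


def posterior(
    evidence: MechanismEvidence,
    params: ModelParams,
    prior: float,
    mode: str = "full",
    participant_id: str = "",
    phenotype: str = "",
) -> PosteriorResult:
    """Posterior probability of the phenotype given all category evidence.

    Modes: ``full`` combines everything; ``prevalence_only`` returns the
    prior; ``genome_only`` is algebraically the full formula (the caller
    supplies the cohort-average baseline prior instead of the
    phenotype-specific one); single-category modes ``vh``/``vl``/``gh``/
    ``gl`` zero every evidence term except the named one, keeping the
    prevalence as the leak so that no-evidence individuals still sit at
    the prior.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if not 0.0 < prior < 1.0:
        raise NoPrevalence(f"prior must lie in (0,1), got {prior}")

    pi_vl = prior
    if evidence.gwas_lr:
        for lr in evidence.gwas_lr:
            pi_vl *= lr
        pi_vl = min(params.posterior_cap, pi_vl)

    q_vh, q_gh, q_gl = evidence.q_vh, evidence.q_gh, evidence.q_gl
    if mode == "prevalence_only":
        post = prior
        pi_vl, q_vh, q_gh, q_gl = prior, 0.0, 0.0, 0.0
    else:
        if mode in ("vh", "gh", "gl"):
            pi_vl = prior
        if mode in ("vl", "gh", "gl"):
            q_vh = 0.0
        if mode in ("vh", "vl", "gl"):
            q_gh = 0.0
        if mode in ("vh", "vl", "gh"):
            q_gl = 0.0
        post = 1.0 - (
            (1.0 - pi_vl)
            * (1.0 - q_vh * params.rho_vh)
            * (1.0 - q_gh * params.rho_gh)
            * (1.0 - q_gl * params.rho_gl)
        )
    return PosteriorResult(
        participant_id=participant_id,
        phenotype=phenotype,
        prior=prior,
        posterior=post,
        breakdown={"pi_vl": pi_vl, "q_vh": q_vh, "q_gh": q_gh, "q_gl": q_gl},
        mode=mode,
    )


def collect_evidence(
    genome: PersonalGenome,
    phenotype: str,
    kb: AnnotationKB,
    scores: Mapping[VariantKey, float],
    prior: float,
    alteration_params: AlterationModelParams = AlterationModelParams(),
) -> MechanismEvidence:
    """Assemble the four categories of evidence for one individual."""
    lrs = []
    for hit in kb.gwas_for(phenotype):
        dose = risk_allele_dose(genome, hit)
        if dose is None:
            continue  # unresolvable sites are excluded, not imputed
        risks = gwas_genotype_penetrance(
            hit.effect_size, hit.risk_allele_freq, prior
        )
        lrs.append(risks[dose] / prior)

    q_vh = 1.0 if match_hp_variant(genome, kb, phenotype) else 0.0
    q_gh = category_activation(
        score_gene(genome, g, phenotype, kb, scores, alteration_params)
        for g in kb.genes_for(phenotype, HIGH)
    )
    q_gl = category_activation(
        score_gene(genome, g, phenotype, kb, scores, alteration_params)
        for g in kb.genes_for(phenotype, LOW)
    )
    return MechanismEvidence(q_vh=q_vh, q_gh=q_gh, q_gl=q_gl, gwas_lr=lrs)


def predict(
    genome: PersonalGenome,
    phenotype: str,
    kb: AnnotationKB,
    scores: Mapping[VariantKey, float],
    params: ModelParams = ModelParams(),
    mode: str = "full",
    alteration_params: AlterationModelParams = AlterationModelParams(),
    prior: float | None = None,
) -> PosteriorResult:
    """Full pipeline: prior lookup → evidence collection → posterior.

    In ``genome_only`` mode the prior defaults to the cohort-average
    prevalence (every phenotype and individual assigned the same
    baseline); otherwise it is looked up by the individual's ancestry,
    gender and age. A phenotype with neither annotations nor prevalence
    is not predictable.
    """
    has_annotations = bool(
        kb.gwas_for(phenotype)
        or kb.hp_variants_for(phenotype)
        or kb.genes_for(phenotype, HIGH)
        or kb.genes_for(phenotype, LOW)
    )
    if prior is None:
        try:
            if mode == "genome_only":
                prior = average_prevalence(kb.prevalence)
            else:
                prior = kb.prevalence.lookup(
                    phenotype, genome.ancestry, genome.gender, genome.age
                )
        except NoPrevalence:
            if not has_annotations:
                raise NotPredictable(
                    f"phenotype {phenotype!r} has no annotations and no "
                    f"prevalence"
                ) from None
            raise

    evidence = collect_evidence(
        genome, phenotype, kb, scores, prior, alteration_params
    )
    return posterior(
        evidence,
        params,
        prior,
        mode=mode,
        participant_id=genome.participant_id,
        phenotype=phenotype,
    )


def predict_cohort(
    genomes: Sequence[PersonalGenome],
    phenotypes: Sequence[str],
    kb: AnnotationKB,
    scores: Mapping[VariantKey, float],
    params: ModelParams = ModelParams(),
    mode: str = "full",
    alteration_params: AlterationModelParams = AlterationModelParams(),
):
    """Posterior matrix (participants × phenotypes) as a DataFrame.

    Phenotypes that are not predictable for the whole cohort are dropped;
    per-individual prior failures propagate.
    """
    import pandas as pd

    data: dict[str, dict[str, float]] = {}
    for pheno in phenotypes:
        column = {}
        try:
            for g in genomes:
                column[g.participant_id] = predict(
                    g, pheno, kb, scores, params, mode, alteration_params
                ).posterior
        except NotPredictable:
            continue
        data[pheno] = column
    frame = pd.DataFrame(data)
    return frame.reindex([g.participant_id for g in genomes])
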