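"""Gene-level functional impact from per-variant significance values.

Any variant-effect predictor that emits a p-value per variant can plug in:
scores are just a mapping ``(chrom, pos, ref, alt) -> p``. Per gene, the
p-values of the individual's rare non-silent variants are combined with
Fisher's method into T = −2 Σ ln p, and a posterior probability that the
gene product is functionally altered is obtained by Bayes' rule.

The alternative model takes truly damaging variants' p-values as
Beta(a, 1) with shape a in (0, 1]; −2 ln p is then Exponential(a/2), so T
over k variants is Gamma(k, rate a/2), while under the null (uniform
p-values) T is chi-square with 2k degrees of freedom — i.e. Gamma(k,
rate 1/2). The likelihood ratio therefore has the closed form

    LR(T; k, a) = a^k · exp((1 − a) T / 2)

and the posterior is expit(logit(rho) + ln LR). With a = 1 the
alternative collapses onto the null and the posterior reduces to the
prior rho for every T; for a < 1 it is strictly increasing in T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.special import expit, logit

from .annotation_kb import AnnotationKB
from .exceptions import MalformedInput, NoEvidence
from .genome_io import PersonalGenome, select_rare_nonsilent

#: p-values are floored here before taking logs, so T stays finite
P_FLOOR = 1e-10

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class GeneStatistic:
    """Fisher's-method statistic over one gene's variant p-values."""

    gene: str
    T: float
    k: int

    def __post_init__(self) -> None:
        if self.T < 0 or self.k < 1:
            raise ValueError(f"invalid gene statistic T={self.T}, k={self.k}")


@dataclass(frozen=True)
class AlterationModelParams:
    """Parameters of the gene-alteration posterior.

    ``prior_altered`` (rho) is the prior probability that a
    phenotype-associated gene carrying rare non-silent variants is
    functionally altered; ``beta_shape`` (a) governs how concentrated near
    zero damaging variants' p-values are. Both are deliberately exposed:
    they encode beliefs about the variant scorer, not about any cohort.
    """

    prior_altered: float = 0.05
    beta_shape: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.prior_altered < 1.0:
            raise ValueError("prior_altered must lie in (0,1)")
        if not 0.0 < self.beta_shape <= 1.0:
            raise ValueError("beta_shape must lie in (0,1]")


def combine_fisher(pvalues: Iterable[float], gene: str = "") -> GeneStatistic:
    """Fisher's method: T = −2 Σ ln p over k p-values."""
    ps = list(pvalues)
    if not ps:
        raise NoEvidence(f"no p-values to combine for gene {gene!r}")
    for p in ps:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-value out of (0,1]: {p}")
    T = -2.0 * sum(math.log(max(p, P_FLOOR)) for p in ps)
    return GeneStatistic(gene=gene, T=T, k=len(ps))


def gene_alteration_posterior(
    stat: GeneStatistic, params: AlterationModelParams
) -> float:
    """P(gene altered | T, k) under the Beta(a,1) alternative."""
    log_lr = stat.k * math.log(params.beta_shape) + 0.5 * (
        1.0 - params.beta_shape
    ) * stat.T
    return float(expit(logit(params.prior_altered) + log_lr))


def score_gene(
    genome: PersonalGenome,
    gene: str,
    phenotype: str,
    kb: AnnotationKB,
    scores: Mapping[VariantKey, float],
    params: AlterationModelParams = AlterationModelParams(),
    missing_score: str = "skip",
) -> float:
    """Probability that a gene is functionally altered in this individual.

    Composition: select the rare non-silent calls in the gene, look up
    their functional p-values, combine with Fisher's method, apply the
    alteration posterior. A gene with no qualifying scored variant
    contributes 0 (no evidence of alteration).
    """
    calls = select_rare_nonsilent(genome, gene, kb)
    pvalues = []
    for call in calls:
        key = (call.chrom, call.pos, call.ref_allele, call.alt_allele)
        p = scores.get(key)
        if p is None:
            if missing_score == "skip":
                continue
            raise KeyError(f"no functional score for variant {key}")
        pvalues.append(p)
    if not pvalues:
        return 0.0
    stat = combine_fisher(pvalues, gene=gene)
    return gene_alteration_posterior(stat, params)


def load_scores(path: str | Path) -> dict[VariantKey, float]:
    """Read a variant-score table: chrom, pos, ref, alt, p_value."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["chrom", "pos", "ref", "alt", "p_value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedInput(f"{path}: missing columns {missing}")
    scores: dict[VariantKey, float] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            p = float(row.p_value)
        except ValueError as exc:
            raise MalformedInput(
                f"{path}: line {i}: column 'p_value': not a number: "
                f"{row.p_value!r}"
            ) from exc
        if not 0.0 < p <= 1.0:
            raise MalformedInput(
                f"{path}: line {i}: column 'p_value': out of (0,1]: {p}"
            )
        scores[(row.chrom, int(row.pos), row.ref, row.alt)] = p
    return scores


def write_scores(scores: Mapping[VariantKey, float], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"chrom": c, "pos": pos, "ref": r, "alt": a, "p_value": repr(p)}
            for (c, pos, r, a), p in scores.items()
        ],
        columns=["chrom", "pos", "ref", "alt", "p_value"],
    ).to_csv(Path(path), sep="\t", index=False)
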