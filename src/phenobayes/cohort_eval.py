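"""Cohort-level evaluation: ranking, AUC, permutation significance, FDR,
and a rare-allele burden baseline.

Per phenotype, participants are ranked by descending posterior probability
and the ranking is scored with the Mann–Whitney AUC (probability that a
random case outranks a random control, half credit for ties). Participants
with unknown status, and participants of a gender to which the phenotype
does not apply, are excluded from the evaluation.

Two permutation nulls are provided: shuffling participant identities (one
permutation applied simultaneously to every phenotype column, preserving
the correlation structure of phenotypes within a participant) and
shuffling one phenotype's status labels (treating phenotypes as
independent and exchangeable). Multiple testing is handled with
Benjamini–Hochberg q-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_kb import AnnotationKB, HIGH, LOW
from .exceptions import UndefinedAUC
from .functional_scoring import VariantKey
from .genome_io import (
    ABSENT,
    PRESENT,
    RARE_MAF,
    CohortPhenotypes,
    PersonalGenome,
)


@dataclass
class EvalResult:
    phenotype: str
    auc: float
    p_value: float
    fdr: float
    n_cases: int
    n_controls: int
    n_excluded: int


@dataclass
class EvalConfig:
    n_perm: int = 10_000
    seed: int = 0
    test: str = "participants"  # or "labels"
    #: phenotype -> gender to which it applies; others are excluded
    gender_specific: dict[str, str] = field(default_factory=dict)


def _rank_auc(ranks: np.ndarray, y: np.ndarray) -> float:
    """AUC from midranks: (Σ ranks of cases − n1(n1+1)/2) / (n1·n0)."""
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedAUC(f"need at least one case and one control "
                           f"(cases={n1}, controls={n0})")
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auc(
    scores: Sequence[float],
    statuses: Sequence[int],
    exclusions: Sequence[bool] | None = None,
) -> float:
    """Mann–Whitney AUC with half credit per tied case–control pair.

    ``statuses`` are 1 (case) / 0 (control); ``exclusions`` marks
    participants to drop (unknown status, gender-inapplicable) before
    scoring.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(statuses)
    if exclusions is not None:
        keep = ~np.asarray(exclusions, dtype=bool)
        s, y = s[keep], y[keep]
    ranks = stats.rankdata(s)
    return _rank_auc(ranks, y.astype(int))


def _status_arrays(
    status_col: pd.Series,
    genders: Mapping[str, str] | None,
    applicable_gender: str | None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """(mask of evaluated participants, 0/1 statuses, n_excluded)."""
    known = status_col.isin([PRESENT, ABSENT]).to_numpy()
    eligible = np.ones(len(status_col), dtype=bool)
    if applicable_gender is not None and genders is not None:
        eligible = np.array(
            [genders.get(pid) == applicable_gender for pid in status_col.index]
        )
    mask = known & eligible
    y = (status_col.to_numpy() == PRESENT).astype(int)
    n_excluded = int(len(status_col) - mask.sum())
    return mask, y, n_excluded


def permutation_test_participants(
    score_matrix: pd.DataFrame,
    status_matrix: pd.DataFrame,
    n_perm: int,
    seed: int,
    genders: Mapping[str, str] | None = None,
    gender_specific: Mapping[str, str] | None = None,
) -> pd.Series:
    """Participant-identity permutation p-values, one per phenotype.

    Each of the ``n_perm`` permutations reassigns whole score vectors
    among participants — the same permutation for every phenotype column —
    and the p-value is (1 + #{permuted AUC ≥ observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(score_matrix)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    pvals = {}
    gender_specific = gender_specific or {}
    for pheno in score_matrix.columns:
        s = score_matrix[pheno].to_numpy(dtype=float)
        mask, y, _ = _status_arrays(
            status_matrix[pheno].reindex(score_matrix.index),
            genders,
            gender_specific.get(pheno),
        )
        y_m = y[mask]
        if y_m.sum() == 0 or y_m.sum() == len(y_m):
            pvals[pheno] = np.nan
            continue
        obs = _rank_auc(stats.rankdata(s[mask]), y_m)
        # permuted scores restricted to the evaluated participants
        perm_scores = s[perms[:, mask]]
        perm_ranks = stats.rankdata(perm_scores, axis=1)
        n1 = y_m.sum()
        n0 = len(y_m) - n1
        perm_auc = (perm_ranks[:, y_m == 1].sum(axis=1) - n1 * (n1 + 1) / 2) / (
            n1 * n0
        )
        pvals[pheno] = (1 + int((perm_auc >= obs - 1e-12).sum())) / (1 + n_perm)
    return pd.Series(pvals, name="p_value")


def permutation_test_labels(
    scores: Sequence[float],
    statuses: Sequence[int],
    n_perm: int = 10_000,
    seed: int = 0,
    method: str = "mc",
) -> float:
    """Label-shuffle p-value for one phenotype.

    ``method='mc'``: Monte-Carlo shuffles with the add-one estimator
    p = (1 + #{perm AUC ≥ observed}) / (1 + n_perm). ``method='exact'``
    enumerates all placements of the case set (currently supported for a
    single case, where the null is uniform over the n possible ranks and
    the p-value is exactly rank/n).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(statuses, dtype=int)
    ranks = stats.rankdata(s)
    obs = _rank_auc(ranks, y)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if method == "exact":
        if n1 != 1:
            raise ValueError("exact enumeration implemented for a single case")
        # the single case may sit at any of the n positions, all equally
        # likely; AUC >= observed iff its rank-from-top is <= observed rank
        auc_all = (ranks - 1) / n0  # AUC when the case is participant i
        return float((auc_all >= obs - 1e-12).sum() / len(y))
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        perm_auc = (ranks[y_perm == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        if perm_auc >= obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)


def fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    return stats.false_discovery_control(p, method="bh")


def burden_baseline(
    genomes: Sequence[PersonalGenome],
    kb: AnnotationKB,
    phenotype: str,
    scores: Mapping[VariantKey, float],
    damaging_threshold: float = 0.05,
) -> pd.Series:
    """Rare damaging-allele burden per participant in a phenotype's genes.

    Counts alleles (het = 1, hom = 2) of variants with MAF < 0.01 in every
    recorded population and functional p-value below the threshold, summed
    over the phenotype's annotated gene set. The returned Series is
    ordered by descending burden, ties broken by ascending participant id.
    """
    genes = set(kb.genes_for(phenotype, HIGH)) | set(kb.genes_for(phenotype, LOW))
    regions = {g: kb.gene_regions[g] for g in genes if g in kb.gene_regions}
    counts = {}
    for genome in genomes:
        burden = 0
        for call in genome.calls:
            in_gene = any(
                call.chrom == chrom and start <= call.pos <= end
                for chrom, start, end in regions.values()
            )
            if not in_gene:
                continue
            freqs = kb.allele_freqs.get((call.chrom, call.pos, call.alt_allele))
            if freqs and not all(v < RARE_MAF for v in freqs.values()):
                continue
            p = scores.get((call.chrom, call.pos, call.ref_allele, call.alt_allele))
            if p is not None and p < damaging_threshold:
                burden += call.allele_count
        counts[genome.participant_id] = burden
    series = pd.Series(counts, name="burden")
    return series.sort_index().sort_values(ascending=False, kind="stable")


def evaluate_cohort(
    posteriors: pd.DataFrame,
    phenotype_matrix: CohortPhenotypes,
    config: EvalConfig = EvalConfig(),
    genders: Mapping[str, str] | None = None,
) -> tuple[list[EvalResult], pd.DataFrame]:
    """Per-phenotype AUC, permutation p-value and BH FDR, plus a report.

    The report has one row per phenotype with the rank-ordered status
    string ('+' case, '-' control, '?' unknown, 'x' gender-excluded),
    ranked by descending posterior, ties broken by ascending participant
    id. Phenotypes with an undefined AUC (no cases or no controls after
    exclusion) are reported with NaN statistics rather than aborting.
    """
    statuses = phenotype_matrix.frame.reindex(posteriors.index)
    if config.test == "participants":
        pvals = permutation_test_participants(
            posteriors,
            statuses,
            config.n_perm,
            config.seed,
            genders,
            config.gender_specific,
        )
    elif config.test == "labels":
        pvals = {}
        for pheno in posteriors.columns:
            mask, y, _ = _status_arrays(
                statuses[pheno], genders, config.gender_specific.get(pheno)
            )
            y_m = y[mask]
            if 0 < y_m.sum() < len(y_m):
                pvals[pheno] = permutation_test_labels(
                    posteriors[pheno].to_numpy()[mask],
                    y_m,
                    config.n_perm,
                    config.seed,
                )
            else:
                pvals[pheno] = np.nan
        pvals = pd.Series(pvals)
    else:
        raise ValueError(f"unknown permutation test {config.test!r}")

    defined = [p for p in posteriors.columns if not math.isnan(pvals[p])]
    qvals = pd.Series(np.nan, index=posteriors.columns)
    if defined:
        qvals[defined] = fdr(pvals[defined].to_numpy())

    results = []
    report_rows = []
    for pheno in posteriors.columns:
        col = statuses[pheno]
        mask, y, n_excluded = _status_arrays(
            col, genders, config.gender_specific.get(pheno)
        )
        scores_col = posteriors[pheno]
        order = sorted(
            posteriors.index, key=lambda pid: (-scores_col[pid], pid)
        )
        symbols = []
        for pid in order:
            i = posteriors.index.get_loc(pid)
            if not mask[i]:
                symbols.append("?" if col[pid] not in (PRESENT, ABSENT) else "x")
            else:
                symbols.append("+" if col[pid] == PRESENT else "-")
        y_m = y[mask]
        try:
            value = auc(scores_col.to_numpy()[mask], y_m)
        except UndefinedAUC:
            value = float("nan")
        results.append(
            EvalResult(
                phenotype=pheno,
                auc=value,
                p_value=float(pvals[pheno]),
                fdr=float(qvals[pheno]),
                n_cases=int(y_m.sum()),
                n_controls=int(len(y_m) - y_m.sum()),
                n_excluded=n_excluded,
            )
        )
        report_rows.append(
            {
                "phenotype": pheno,
                "auc": value,
                "p_value": float(pvals[pheno]),
                "fdr": float(qvals[pheno]),
                "n_cases": int(y_m.sum()),
                "ranked_statuses": "".join(symbols),
            }
        )
    return results, pd.DataFrame(report_rows)
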