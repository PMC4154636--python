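"""Matching genomes to phenotypic profiles by Bernoulli likelihood.

A phenotypic profile is a questionnaire vector of present/absent/unknown
statuses over dichotomous traits. Given a genome's per-phenotype posterior
probabilities, the match to a profile is scored with an independent
Bernoulli likelihood over the phenotypes whose status is known; profiles
are ranked from most to least probable, and profiles known to belong to no
sequenced sample (ineligible decoys) are excluded up front.

Significance of a matching result is judged against the uniformly-random
null in which each genome's top-ranked profile is equally likely to be any
eligible profile; the count of correct top-1 matches is then
Binomial(n_genomes, 1/n_profiles), which supplies an exact companion to
the Monte-Carlo estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import MalformedInput, NoOverlap
from .genome_io import ABSENT, PRESENT, UNKNOWN


@dataclass
class PhenotypeProfile:
    profile_id: str
    statuses: dict[str, str]
    eligible: bool = True

    def __post_init__(self) -> None:
        if not self.statuses:
            raise ValueError(f"profile {self.profile_id}: empty status map")
        bad = set(self.statuses.values()) - {PRESENT, ABSENT, UNKNOWN}
        if bad:
            raise ValueError(
                f"profile {self.profile_id}: invalid statuses {sorted(bad)}"
            )


@dataclass
class MatchResult:
    genome_id: str
    ranking: list[tuple[str, float]]  # (profile_id, log-likelihood), best first
    rank_of_truth: int | None = None

    @property
    def top_profile(self) -> str:
        return self.ranking[0][0]


def match_loglik(
    posteriors: Mapping[str, float],
    profile: PhenotypeProfile,
    eps: float = 1e-6,
) -> float:
    """Bernoulli log-likelihood of the profile given the posteriors.

    Sums ln p for phenotypes marked present and ln(1−p) for absent, with
    each posterior clamped into [eps, 1−eps] so that hard 0/1 posteriors
    cannot produce infinite log-likelihoods; unknown statuses contribute
    nothing (an all-unknown overlap yields 0, the empty product).
    """
    if not 0.0 < eps < 0.5:
        raise ValueError(f"eps must lie in (0, 0.5), got {eps}")
    shared = [
        pheno
        for pheno, status in profile.statuses.items()
        if pheno in posteriors
    ]
    if not shared:
        raise NoOverlap(
            f"profile {profile.profile_id} shares no phenotype with the "
            f"posterior map"
        )
    total = 0.0
    for pheno in shared:
        status = profile.statuses[pheno]
        if status == UNKNOWN:
            continue
        p = min(max(posteriors[pheno], eps), 1.0 - eps)
        total += math.log(p) if status == PRESENT else math.log(1.0 - p)
    return total


def rank_profiles(
    genome_id: str,
    posteriors: Mapping[str, float],
    profiles: Sequence[PhenotypeProfile],
    eps: float = 1e-6,
) -> MatchResult:
    """Rank eligible profiles by descending log-likelihood, ties by id."""
    eligible = [p for p in profiles if p.eligible]
    if not eligible:
        raise ValueError("no eligible profiles to rank")
    scored = [
        (p.profile_id, match_loglik(posteriors, p, eps)) for p in eligible
    ]
    scored.sort(key=lambda item: (-item[1], item[0]))
    return MatchResult(genome_id=genome_id, ranking=scored)


def evaluate_matching(
    results: Sequence[MatchResult], truth: Mapping[str, str]
) -> tuple[int, float | None]:
    """(number of correct top-1 matches, mean rank of the true profile).

    Every genome in ``results`` must appear in the truth map. An empty
    result set yields (0, None).
    """
    if not results:
        return 0, None
    n_top1 = 0
    ranks = []
    for res in results:
        if res.genome_id not in truth:
            raise KeyError(f"genome {res.genome_id!r} missing from truth map")
        true_profile = truth[res.genome_id]
        rank = next(
            (
                i
                for i, (pid, _) in enumerate(res.ranking, start=1)
                if pid == true_profile
            ),
            None,
        )
        if rank is None:
            raise KeyError(
                f"true profile {true_profile!r} absent from ranking of "
                f"{res.genome_id!r}"
            )
        res.rank_of_truth = rank
        ranks.append(rank)
        if rank == 1:
            n_top1 += 1
    return n_top1, float(np.mean(ranks))


@dataclass
class NullMatchingResult:
    empirical_significance: float
    exact_binomial_tail: float
    n_trials: int
    max_correct_observed: int


def null_matching_significance(
    n_genomes: int,
    n_profiles: int,
    threshold: int,
    n_trials: int = 10_000,
    seed: int = 0,
    permutation_null: bool = False,
) -> NullMatchingResult:
    """Probability of ≥ threshold correct top-1 matches under random matching.

    Per trial each genome's top profile is drawn independently and
    uniformly over the eligible profiles (with ``permutation_null`` the
    trial instead assigns profiles without replacement). Returns both the
    Monte-Carlo fraction of trials reaching the threshold and the exact
    Binomial(n_genomes, 1/n_profiles) upper tail for the independent null.
    """
    if n_genomes < 1 or n_profiles < 1 or n_trials < 1:
        raise ValueError("n_genomes, n_profiles, n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    if threshold <= 0:
        empirical = 1.0
        max_correct = n_genomes
    elif permutation_null:
        if n_profiles < n_genomes:
            raise ValueError("permutation null needs n_profiles >= n_genomes")
        correct = np.empty(n_trials, dtype=int)
        truth = np.arange(n_genomes)
        for t in range(n_trials):
            assignment = rng.permutation(n_profiles)[:n_genomes]
            correct[t] = int((assignment == truth).sum())
        empirical = float((correct >= threshold).mean())
        max_correct = int(correct.max())
    else:
        draws = rng.integers(0, n_profiles, size=(n_trials, n_genomes))
        truth = np.arange(n_genomes) % n_profiles
        correct = (draws == truth).sum(axis=1)
        empirical = float((correct >= threshold).mean())
        max_correct = int(correct.max())
    exact = float(stats.binom.sf(threshold - 1, n_genomes, 1.0 / n_profiles))
    return NullMatchingResult(
        empirical_significance=empirical,
        exact_binomial_tail=min(exact, 1.0),
        n_trials=n_trials,
        max_correct_observed=max_correct,
    )


# ---------------------------------------------------------------------------
# TSV persistence
# ---------------------------------------------------------------------------

_STATUS_TO_TSV = {PRESENT: "1", ABSENT: "0", UNKNOWN: "NA"}
_TSV_TO_STATUS = {v: k for k, v in _STATUS_TO_TSV.items()}


def read_profiles_tsv(
    profiles_path: str | Path, eligibility_path: str | Path | None = None
) -> list[PhenotypeProfile]:
    """Read profiles (profile_id, phenotype, status) plus eligibility flags."""
    path = Path(profiles_path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    eligible: dict[str, bool] = {}
    if eligibility_path is not None:
        edf = pd.read_csv(
            Path(eligibility_path), sep="\t", dtype=str, keep_default_na=False
        )
        eligible = {
            row.profile_id: row.eligible == "1"
            for row in edf.itertuples(index=False)
        }
    statuses: dict[str, dict[str, str]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.status not in _TSV_TO_STATUS:
            raise MalformedInput(
                f"{path}: line {i}: column 'status': expected 1/0/NA, got "
                f"{row.status!r}"
            )
        statuses.setdefault(row.profile_id, {})[row.phenotype] = _TSV_TO_STATUS[
            row.status
        ]
    return [
        PhenotypeProfile(pid, st, eligible.get(pid, True))
        for pid, st in sorted(statuses.items())
    ]


def write_profiles_tsv(
    profiles: Sequence[PhenotypeProfile],
    profiles_path: str | Path,
    eligibility_path: str | Path | None = None,
) -> None:
    rows = [
        {
            "profile_id": p.profile_id,
            "phenotype": pheno,
            "status": _STATUS_TO_TSV[status],
        }
        for p in profiles
        for pheno, status in p.statuses.items()
    ]
    pd.DataFrame(rows, columns=["profile_id", "phenotype", "status"]).to_csv(
        Path(profiles_path), sep="\t", index=False
    )
    if eligibility_path is not None:
        pd.DataFrame(
            [
                {"profile_id": p.profile_id, "eligible": int(p.eligible)}
                for p in profiles
            ],
            columns=["profile_id", "eligible"],
        ).to_csv(Path(eligibility_path), sep="\t", index=False)
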