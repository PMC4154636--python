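import itertools
import math

import numpy as np
import pytest

from phenobayes import (
    MechanismEvidence,
    ModelParams,
    NoPrevalence,
    NotPredictable,
    category_activation,
    gwas_genotype_penetrance,
    gwas_update,
    posterior,
    predict,
)
from phenobayes.genome_io import GenotypeCall, PersonalGenome


def bisect_o0(odds_ratio, f, prior):
    """Independent plain-bisection oracle for the baseline odds."""
    def hwe_mean(o0):
        r = [o0 * odds_ratio**g / (1 + o0 * odds_ratio**g) for g in range(3)]
        return (1 - f) ** 2 * r[0] + 2 * f * (1 - f) * r[1] + f**2 * r[2]

    lo, hi = 1e-12, 1e3
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if hwe_mean(mid) < prior:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def enumeration_posterior(pi_vl, q_vh, q_gh, q_gl, params):
    """Exhaustive 16-state oracle: independent Bernoulli mechanism
    activations with a noisy-OR conditional for the phenotype. The
    low-penetrance-variant mechanism is always active with weight pi_vl."""
    qs = (1.0, q_vh, q_gh, q_gl)
    weights = (pi_vl, params.rho_vh, params.rho_gh, params.rho_gl)
    total = 0.0
    for states in itertools.product([0, 1], repeat=4):
        p_state = 1.0
        for s, q in zip(states, qs):
            p_state *= q if s else 1.0 - q
        p_y = 1.0 - math.prod((1.0 - w) ** s for s, w in zip(states, weights))
        total += p_state * p_y
    return total


class TestGwasGenotypePenetrance:
    def test_or_near_one_risks_approach_prior(self):
        r = gwas_genotype_penetrance(1.0 + 1e-9, 0.3, 0.1)
        for g in range(3):
            assert r[g] == pytest.approx(0.1, abs=1e-8)

    def test_against_independent_bisection_oracle(self):
        o0 = bisect_o0(2.0, 0.3, 0.1)
        expected = [o0 * 2.0**g / (1 + o0 * 2.0**g) for g in range(3)]
        r = gwas_genotype_penetrance(2.0, 0.3, 0.1)
        for g in range(3):
            assert r[g] == pytest.approx(expected[g], abs=1e-8)
        assert r.r2 == pytest.approx(0.2125, abs=1e-3)

    def test_hwe_mean_constraint_on_random_grid(self, rng):
        """(1-f)^2 r0 + 2f(1-f) r1 + f^2 r2 = prior to 1e-8, and
        r0 < prior < r2, over randomized (OR, f, prior)."""
        for _ in range(200):
            odds = float(np.exp(rng.uniform(np.log(1.01), np.log(20.0))))
            f = float(rng.uniform(0.01, 0.99))
            prior = float(rng.uniform(0.001, 0.9))
            r = gwas_genotype_penetrance(odds, f, prior)
            mean = (
                (1 - f) ** 2 * r.r0 + 2 * f * (1 - f) * r.r1 + f**2 * r.r2
            )
            assert mean == pytest.approx(prior, abs=1e-8)
            assert r.r0 < prior < r.r2

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            gwas_genotype_penetrance(0.9, 0.3, 0.1)
        with pytest.raises(ValueError):
            gwas_genotype_penetrance(2.0, 0.0, 0.1)
        with pytest.raises(ValueError):
            gwas_genotype_penetrance(2.0, 0.3, 1.0)


class TestGwasUpdate:
    def test_no_hits_returns_prior(self):
        assert gwas_update(0.1, []) == 0.1

    def test_dose_zero_is_protective(self):
        r = gwas_genotype_penetrance(2.0, 0.3, 0.1)
        assert gwas_update(0.1, [(0, r)]) < 0.1

    def test_cap_never_exceeded(self):
        r = gwas_genotype_penetrance(20.0, 0.4, 0.3)
        updated = gwas_update(0.3, [(2, r)] * 10, cap=0.99)
        assert updated == 0.99

    def test_mismatched_prior_rejected(self):
        r = gwas_genotype_penetrance(2.0, 0.3, 0.1)
        with pytest.raises(ValueError, match="prior"):
            gwas_update(0.2, [(1, r)])


class TestCategoryActivation:
    @pytest.mark.parametrize(
        "ps,expected",
        [([], 0.0), ([0.5, 0.5], 0.75), ([0.3], 0.3), ([1.0, 0.1], 1.0)],
    )
    def test_noisy_or(self, ps, expected):
        assert category_activation(ps) == pytest.approx(expected)


class TestPosterior:
    def test_no_evidence_returns_prior(self):
        res = posterior(MechanismEvidence(), ModelParams(), prior=0.1)
        assert res.posterior == pytest.approx(0.1)

    def test_high_penetrance_dominance(self):
        params = ModelParams(rho_vh=1.0)
        res = posterior(
            MechanismEvidence(q_vh=1.0, q_gh=0.2, q_gl=0.1),
            params, prior=0.05,
        )
        assert res.posterior == pytest.approx(1.0)

    def test_single_category_gh_matches_enumeration(self):
        params = ModelParams(rho_gh=0.5)
        res = posterior(
            MechanismEvidence(q_gh=0.6), params, prior=0.1, mode="gh"
        )
        expected = enumeration_posterior(0.1, 0.0, 0.6, 0.0, params)
        assert res.posterior == pytest.approx(expected, abs=1e-12)

    def test_closed_form_equals_enumeration_randomized(self, rng):
        """Closed form == 16-state enumeration to 1e-12 over 1000 draws."""
        for _ in range(1000):
            params = ModelParams(
                rho_vh=float(rng.uniform()),
                rho_gh=float(rng.uniform()),
                rho_gl=float(rng.uniform()),
            )
            prior = float(rng.uniform(0.01, 0.5))
            lrs = list(rng.uniform(0.2, 2.0, size=rng.integers(0, 4)))
            evidence = MechanismEvidence(
                q_vh=float(rng.uniform()),
                q_gh=float(rng.uniform()),
                q_gl=float(rng.uniform()),
                gwas_lr=lrs,
            )
            res = posterior(evidence, params, prior)
            pi_vl = min(params.posterior_cap, prior * float(np.prod(lrs)))
            expected = enumeration_posterior(
                pi_vl, evidence.q_vh, evidence.q_gh, evidence.q_gl, params
            )
            assert abs(res.posterior - expected) < 1e-12
            assert 0.0 <= res.posterior <= 1.0

    def test_monotone_in_each_activation(self):
        params = ModelParams()
        base = posterior(
            MechanismEvidence(q_gh=0.2, q_gl=0.2), params, 0.1
        ).posterior
        for bump in ({"q_vh": 0.5}, {"q_gh": 0.5}, {"q_gl": 0.5}):
            ev = MechanismEvidence(q_gh=0.2, q_gl=0.2)
            for key, val in bump.items():
                setattr(ev, key, val)
            assert posterior(ev, params, 0.1).posterior >= base

    def test_prevalence_only_mode(self):
        res = posterior(
            MechanismEvidence(q_vh=1.0), ModelParams(), 0.1,
            mode="prevalence_only",
        )
        assert res.posterior == 0.1

    def test_missing_prior_propagates(self):
        with pytest.raises(NoPrevalence):
            posterior(MechanismEvidence(), ModelParams(), prior=0.0)


class TestPredict:
    def test_no_relevant_annotations_sits_at_prior(self, empty_genome, kb, scores):
        """A phenotype with a prior but no genetic annotations posts at the
        prior; with GWAS hits annotated, a non-carrier is protective
        (dose 0 risk is below the prevalence by the HWE constraint)."""
        from phenobayes import ALL, PrevalenceEntry

        kb.prevalence.add(
            PrevalenceEntry("pheno_b", ALL, ALL, None, None, 0.2, "global")
        )
        res = predict(empty_genome, "pheno_b", kb, scores)
        assert res.posterior == pytest.approx(res.prior) == pytest.approx(0.2)
        protective = predict(empty_genome, "pheno_a", kb, scores)
        assert protective.posterior < protective.prior

    def test_hp_carrier_dominates(self, genome, kb, scores):
        res = predict(genome, "pheno_a", kb, scores)
        assert res.breakdown["q_vh"] == 1.0
        assert res.posterior >= 0.95

    def test_extra_risk_allele_strictly_raises_posterior(self, kb, scores):
        calls = [GenotypeCall("chr1", 1000, "A", "G", 1)]
        het = PersonalGenome("S1", calls, age=45, gender="F", ancestry="EUR")
        hom = PersonalGenome(
            "S2", [GenotypeCall("chr1", 1000, "A", "G", 2)],
            age=45, gender="F", ancestry="EUR",
        )
        p_het = predict(het, "pheno_a", kb, scores).posterior
        p_hom = predict(hom, "pheno_a", kb, scores).posterior
        p_none = predict(
            PersonalGenome("S0", [], age=45, gender="F", ancestry="EUR"),
            "pheno_a", kb, scores,
        ).posterior
        assert p_none < p_het < p_hom

    def test_unannotated_phenotype_not_predictable(self, empty_genome, kb, scores):
        with pytest.raises(NotPredictable):
            predict(empty_genome, "no_such_phenotype", kb, scores)

    def test_genome_only_uses_average_prevalence(self, empty_genome, kb, scores):
        res = predict(empty_genome, "pheno_a", kb, scores, mode="genome_only")
        # single phenotype -> average equals its global prevalence
        assert res.prior == pytest.approx(0.1)
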