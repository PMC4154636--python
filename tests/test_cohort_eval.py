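import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenobayes import (
    EvalConfig,
    UndefinedAUC,
    auc,
    burden_baseline,
    evaluate_cohort,
    fdr,
    permutation_test_labels,
    permutation_test_participants,
)
from phenobayes.genome_io import (
    ABSENT,
    CohortPhenotypes,
    GenotypeCall,
    PRESENT,
    PersonalGenome,
    UNKNOWN,
)


def brute_force_auc(scores, statuses):
    """Pair-counting oracle: P(case > control) + half credit for ties."""
    cases = [s for s, y in zip(scores, statuses) if y == 1]
    controls = [s for s, y in zip(scores, statuses) if y == 0]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_interleaved_example(self):
        assert auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75

    def test_all_ties_is_half(self):
        assert auc([0.5] * 6, [1, 1, 0, 0, 0, 1]) == 0.5

    def test_matches_brute_force_on_random_cohorts(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 51))
            scores = np.round(rng.uniform(size=n), 2)  # rounding forces ties
            statuses = rng.integers(0, 2, size=n)
            if statuses.sum() in (0, n):
                continue
            assert auc(scores, statuses) == pytest.approx(
                brute_force_auc(scores, statuses), abs=1e-12
            )

    def test_monotone_transform_invariance(self, rng):
        scores = rng.uniform(size=30)
        statuses = rng.integers(0, 2, size=30)
        if statuses.sum() in (0, 30):
            statuses[0] = 1 - statuses[0]
        base = auc(scores, statuses)
        assert auc(np.exp(5 * scores), statuses) == pytest.approx(base)
        assert auc(np.log(scores + 1e-9), statuses) == pytest.approx(base)

    def test_exclusions_applied_before_scoring(self):
        # excluded participant would otherwise flip the ranking
        value = auc(
            [0.9, 0.5, 0.1], [0, 1, 0], exclusions=[True, False, False]
        )
        assert value == 1.0

    def test_no_cases_signals(self):
        with pytest.raises(UndefinedAUC):
            auc([0.3, 0.2], [0, 0])

    def test_single_case_rank_formula(self, rng):
        """With one case among n and no ties, AUC = (n - rank)/(n - 1)."""
        n = 20
        scores = rng.permutation(n).astype(float)
        case = int(rng.integers(n))
        statuses = np.zeros(n, dtype=int)
        statuses[case] = 1
        rank = int((scores > scores[case]).sum()) + 1  # rank from the top
        assert auc(scores, statuses) == pytest.approx((n - rank) / (n - 1))


class TestPermutationTests:
    def test_participant_permutation_detects_signal(self, rng):
        n = 40
        y = np.array([1] * 8 + [0] * 32)
        scores = y + rng.normal(0, 0.05, size=n)  # near-perfect separation
        sm = pd.DataFrame({"p1": scores}, index=[f"S{i}" for i in range(n)])
        st = pd.DataFrame(
            {"p1": np.where(y == 1, PRESENT, ABSENT)}, index=sm.index
        )
        pvals = permutation_test_participants(sm, st, n_perm=200, seed=1)
        assert pvals["p1"] <= 0.05
        assert pvals["p1"] >= 1 / 201  # add-one estimator floor

    def test_same_permutation_across_phenotypes(self):
        """Identical score/status columns must get identical p-values:
        one participant shuffle drives all columns simultaneously."""
        idx = [f"S{i}" for i in range(30)]
        scores = np.linspace(0, 1, 30)
        sm = pd.DataFrame({"a": scores, "b": scores}, index=idx)
        st_col = np.where(scores > 0.8, PRESENT, ABSENT)
        st = pd.DataFrame({"a": st_col, "b": st_col}, index=idx)
        pvals = permutation_test_participants(sm, st, n_perm=100, seed=7)
        assert pvals["a"] == pvals["b"]

    def test_label_permutation_pvalue_bounds(self, rng):
        scores = rng.uniform(size=25)
        y = rng.integers(0, 2, size=25)
        if y.sum() in (0, 25):
            y[0] = 1 - y[0]
        p = permutation_test_labels(scores, y, n_perm=99, seed=3)
        assert 1 / 100 <= p <= 1.0

    def test_exact_single_case_null_is_rank_over_n(self):
        """Enumerating the n equally likely case positions gives p = r/n."""
        n = 10
        scores = np.arange(n, dtype=float)  # participant i has score i
        for rank in range(1, n + 1):
            y = np.zeros(n, dtype=int)
            y[n - rank] = 1  # score n-rank is the rank-th from the top
            p = permutation_test_labels(scores, y, method="exact")
            assert p == pytest.approx(rank / n)

    def test_exact_requires_single_case(self):
        with pytest.raises(ValueError):
            permutation_test_labels([1.0, 2.0, 3.0], [1, 1, 0], method="exact")


class TestFdr:
    def test_single_p_identity(self):
        assert fdr([0.01])[0] == pytest.approx(0.01)

    def test_step_up_hand_computed(self):
        qs = fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(qs, [0.04, 0.04, 0.04, 0.04])

    def test_q_at_least_p(self, rng):
        ps = rng.uniform(0.001, 1.0, size=20)
        assert (fdr(ps) >= ps - 1e-12).all()


class TestBurdenBaseline:
    def _genomes(self, kb):
        g1 = PersonalGenome(  # two het damaging + one hom damaging = 4
            "S1",
            [
                GenotypeCall("chr1", 6100, "A", "G", 1),
                GenotypeCall("chr1", 6150, "A", "G", 1),
                GenotypeCall("chr1", 6160, "A", "G", 2),
            ],
            age=40, gender="F", ancestry="EUR",
        )
        g2 = PersonalGenome("S2", [], age=40, gender="F", ancestry="EUR")
        g3 = PersonalGenome(  # common variant: excluded from the count
            "S3", [GenotypeCall("chr1", 6200, "A", "G", 1)],
            age=40, gender="F", ancestry="EUR",
        )
        kb.allele_freqs[("chr1", 6150, "G")] = {"EA": 0.001}
        kb.allele_freqs[("chr1", 6160, "G")] = {"EA": 0.002}
        return [g1, g2, g3]

    def test_counts_and_ranking(self, kb):
        genomes = self._genomes(kb)
        scores = {
            ("chr1", 6100, "A", "G"): 0.01,
            ("chr1", 6150, "A", "G"): 0.04,
            ("chr1", 6160, "A", "G"): 0.02,
            ("chr1", 6200, "A", "G"): 0.001,  # common -> never counted
        }
        burden = burden_baseline(genomes, kb, "pheno_a", scores,
                                 damaging_threshold=0.05)
        assert burden["S1"] == 4
        assert burden["S2"] == 0
        assert burden["S3"] == 0  # MAF 0.02 in one population excludes it
        assert list(burden.index) == ["S1", "S2", "S3"]  # ties by id

    def test_benign_scores_not_counted(self, kb):
        genomes = self._genomes(kb)
        scores = {("chr1", 6100, "A", "G"): 0.5}
        burden = burden_baseline(genomes, kb, "pheno_a", scores)
        assert burden["S1"] == 0


class TestEvaluateCohort:
    def _cohort(self, scores_by_pheno, statuses_by_pheno, ids):
        posteriors = pd.DataFrame(scores_by_pheno, index=ids)
        cohort = CohortPhenotypes(pd.DataFrame(statuses_by_pheno, index=ids))
        return posteriors, cohort

    def test_perfect_separation_auc_one(self):
        ids = [f"S{i}" for i in range(8)]
        post, cohort = self._cohort(
            {"p1": [0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.1]},
            {"p1": [PRESENT] * 3 + [ABSENT] * 5},
            ids,
        )
        results, report = evaluate_cohort(
            post, cohort, EvalConfig(n_perm=50, seed=0)
        )
        assert results[0].auc == 1.0
        assert report["ranked_statuses"][0] == "+++-----"

    def test_unknowns_marked_and_excluded(self):
        ids = [f"S{i}" for i in range(5)]
        post, cohort = self._cohort(
            {"p1": [0.9, 0.7, 0.5, 0.3, 0.1]},
            {"p1": [PRESENT, UNKNOWN, ABSENT, ABSENT, ABSENT]},
            ids,
        )
        results, report = evaluate_cohort(
            post, cohort, EvalConfig(n_perm=50, seed=0)
        )
        assert report["ranked_statuses"][0] == "+?---"
        assert results[0].n_cases == 1 and results[0].n_controls == 3
        assert results[0].n_excluded == 1

    def test_gender_specific_exclusion(self):
        ids = ["S0", "S1", "S2", "S3"]
        post, cohort = self._cohort(
            {"p1": [0.9, 0.7, 0.5, 0.3]},
            {"p1": [PRESENT, ABSENT, ABSENT, ABSENT]},
            ids,
        )
        genders = {"S0": "F", "S1": "M", "S2": "F", "S3": "F"}
        config = EvalConfig(n_perm=50, seed=0,
                            gender_specific={"p1": "F"})
        results, report = evaluate_cohort(post, cohort, config, genders)
        assert results[0].n_excluded == 1
        assert report["ranked_statuses"][0] == "+x--"

    def test_undefined_auc_does_not_abort(self):
        ids = ["S0", "S1"]
        post, cohort = self._cohort(
            {"all_ctrl": [0.9, 0.1], "ok": [0.8, 0.2]},
            {"all_ctrl": [ABSENT, ABSENT], "ok": [PRESENT, ABSENT]},
            ids,
        )
        results, _ = evaluate_cohort(post, cohort, EvalConfig(n_perm=50, seed=0))
        by_pheno = {r.phenotype: r for r in results}
        assert np.isnan(by_pheno["all_ctrl"].auc)
        assert by_pheno["ok"].auc == 1.0

    def test_shuffled_statuses_auc_near_half(self, rng):
        """Statuses independent of scores: mean AUC across phenotypes
        should sit near 0.5 (±0.05 at n=200)."""
        n = 200
        ids = [f"S{i}" for i in range(n)]
        scores_by = {f"p{j}": rng.uniform(size=n) for j in range(20)}
        status_by = {
            f"p{j}": np.where(rng.uniform(size=n) < 0.3, PRESENT, ABSENT)
            for j in range(20)
        }
        post, cohort = self._cohort(scores_by, status_by, ids)
        results, _ = evaluate_cohort(post, cohort, EvalConfig(n_perm=20, seed=0))
        mean_auc = np.mean([r.auc for r in results])
        assert abs(mean_auc - 0.5) < 0.05
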