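import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathsurv import evaluation as ev
from pathsurv import pathway_activity as pa
from pathsurv import survival_stats as ss
from pathsurv.errors import UndefinedSignalError, ValidationError
from pathsurv.io_formats import ExpressionMatrix, GeneSet, SurvivalData

from oracles import brute_force_concordance


def _surv(time, event):
    return SurvivalData([f"s{i}" for i in range(len(time))],
                        np.asarray(time, float), np.asarray(event, int))


class TestConcordanceIndex:
    def test_perfect_ranking(self):
        assert ev.concordance_index([1, 2, 3], [1, 1, 1], [3, 2, 1]) == 1.0

    def test_total_discordance(self):
        assert ev.concordance_index([1, 2, 3], [1, 1, 1], [1, 2, 3]) == 0.0

    def test_censored_pair_enumeration_by_hand(self):
        # comparable pairs (earlier subject's event observed): (1,2) is
        # discordant (eta 2 < 9), (1,3) concordant (2 > 1); pair (2,3) is
        # not comparable because the earlier subject is censored -> c = 1/2
        assert ev.concordance_index([1, 2, 3], [1, 0, 1], [2, 9, 1]) == 0.5

    def test_score_ties_count_half(self):
        assert ev.concordance_index([1, 2], [1, 1], [5, 5]) == 0.5

    def test_equals_brute_force_on_random_instances(self, rng):
        for _ in range(60):
            n = int(rng.integers(3, 31))
            time = rng.integers(1, 10, n).astype(float)   # ties in time
            event = rng.integers(0, 2, n)
            eta = rng.integers(-3, 4, n).astype(float)    # ties in eta
            try:
                expected = brute_force_concordance(time, event, eta)
            except ZeroDivisionError:
                with pytest.raises(UndefinedSignalError):
                    ev.concordance_index(time, event, eta)
                continue
            assert ev.concordance_index(time, event, eta) == expected

    def test_complement_symmetry_without_ties(self, rng):
        time = rng.exponential(1.0, 25)
        event = rng.integers(0, 2, 25)
        event[0] = 1
        eta = rng.standard_normal(25)
        c1 = ev.concordance_index(time, event, eta)
        c2 = ev.concordance_index(time, event, -eta)
        assert c1 + c2 == pytest.approx(1.0, abs=1e-12)

    def test_no_comparable_pairs_error(self):
        with pytest.raises(UndefinedSignalError):
            ev.concordance_index([5, 5], [1, 1], [1, 2])


class TestCrossValidatedCindex:
    def test_perfect_signal_every_fold(self):
        n = 50
        time = np.arange(1.0, n + 1)
        surv = _surv(time, np.ones(n, int))
        result = ev.cross_validated_cindex(-time, surv, seed=0)
        assert result.per_fold_c == [1.0] * 5

    def test_deterministic_given_seed(self, rng):
        n = 80
        act = rng.standard_normal(n)
        surv = _surv(rng.exponential(1.0, n), np.ones(n, int))
        a = ev.cross_validated_cindex(act, surv, seed=11)
        b = ev.cross_validated_cindex(act, surv, seed=11)
        assert a.per_fold_c == b.per_fold_c

    def test_full_data_fold_reproduces_in_sample_c(self, rng):
        n = 60
        act = rng.standard_normal(n)
        time = rng.exponential(np.exp(-act))
        surv = _surv(time, np.ones(n, int))
        idx = np.arange(n)
        result = ev.cross_validated_cindex(act, surv, folds=[(idx, idx)])
        fit = ss.fit_cox(act, surv)
        in_sample = ev.concordance_index(time, surv.event, act * fit.beta[0])
        assert result.per_fold_c[0] == pytest.approx(in_sample, abs=1e-12)

    def test_null_signal_near_half(self, rng):
        n = 2000
        surv = _surv(rng.exponential(1.0, n),
                     (rng.uniform(size=n) < 0.7).astype(int))
        result = ev.cross_validated_cindex(rng.standard_normal(n), surv, seed=2)
        assert 0.45 <= result.mean_c <= 0.55


class TestStability:
    def test_noiseless_rank_one_is_exactly_stable(self, rng):
        m, p = 200, 12
        z = rng.standard_normal(m)
        w = rng.standard_normal(p)
        x = ExpressionMatrix([f"g{i}" for i in range(p)],
                             [f"s{j}" for j in range(m)],
                             np.outer(w, z))
        std = pa.preprocess(x)
        report = ev.stability_analysis(std, GeneSet("PW", "", std.gene_ids),
                                       n_rep=20, seed=0)
        assert report.pairwise_distances.max() < 1e-6

    def test_random_direction_background_mean(self, rng):
        # mean(1 - |cos|) for random unit vectors in R^50 is about
        # 1 - sqrt(2/(50 pi)); check against a direct Monte-Carlo
        dim, n = 50, 400
        vecs = rng.standard_normal((n, dim))
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        pairs = rng.integers(0, n, (3000, 2))
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        mc = np.mean(1 - np.abs(np.sum(vecs[pairs[:, 0]] * vecs[pairs[:, 1]], axis=1)))
        analytic = 1 - np.sqrt(2 / (dim * np.pi))
        assert mc == pytest.approx(analytic, abs=0.01)
        assert ev._pairwise_abs_cosine_distances(vecs).mean() == pytest.approx(mc, abs=0.01)

    def test_structured_pathway_beats_background(self, planted_standardized):
        x, sets, _, _ = planted_standardized
        report = ev.stability_analysis(x, sets["PLANTED"], n_rep=30, seed=5)
        u = stats.mannwhitneyu(report.pairwise_distances,
                               report.background_distances, alternative="less")
        assert u.pvalue < 0.01

    def test_subsample_size_floor(self, planted_standardized):
        x, sets, _, _ = planted_standardized
        report = ev.stability_analysis(x, sets["PLANTED"], n_rep=5,
                                       fraction=0.2, seed=1)
        assert report.subsample_size == int(np.floor(0.2 * x.n_samples))


@pytest.fixture(scope="module")
def small_scan():
    rng = np.random.default_rng(13)
    m = 100
    act = pd.DataFrame(rng.standard_normal((6, m)),
                       index=[f"PW{i}" for i in range(6)],
                       columns=[f"s{i}" for i in range(m)])
    surv = SurvivalData(list(act.columns), rng.exponential(1.0, m),
                        np.ones(m, int))
    results = ss.pathway_scan(act, surv)
    return act, surv, results


class TestPermutationCalibration:
    def test_permutation_count_rule(self, small_scan):
        import copy
        act, surv, results = small_scan
        results = copy.deepcopy(results)
        for r in results:
            r.p = 0.5   # force the 100/p rule to request exactly 200
        records = ev.permutation_calibration(act, surv, results, n_select=2,
                                             max_perms=10_000, seed=0)
        assert all(rec.n_permutations == 200 for rec in records)
        assert not any(rec.capped for rec in records)

    def test_cap_contract(self, small_scan):
        import copy
        act, surv, results = small_scan
        results = copy.deepcopy(results)
        for r in results:
            r.p = 1e-5
        records = ev.permutation_calibration(act, surv, results, n_select=1,
                                             max_perms=500, seed=0)
        assert records[0].n_permutations == 500 and records[0].capped

    def test_selection_without_replacement(self, small_scan):
        act, surv, results = small_scan
        records = ev.permutation_calibration(act, surv, results, n_select=6,
                                             max_perms=300, seed=3)
        ids = [rec.pathway_id for rec in records]
        assert len(set(ids)) == 6
        assert all(-5.0 <= rec.a <= 0.0 for rec in records)

    def test_too_few_pathways_rejected(self, small_scan):
        act, surv, results = small_scan
        with pytest.raises(ValidationError):
            ev.permutation_calibration(act, surv, results, n_select=7)


class TestGeneSetNull:
    def test_zero_draws_empty(self, planted_standardized):
        x, _, surv, _ = planted_standardized
        assert len(ev.gene_set_null(x, surv, set_size=10, n_draws=0)) == 0

    def test_set_size_bounds(self, planted_standardized):
        x, _, surv, _ = planted_standardized
        with pytest.raises(ValidationError):
            ev.gene_set_null(x, surv, set_size=2, n_draws=1)
        with pytest.raises(ValidationError):
            ev.gene_set_null(x, surv, set_size=x.n_genes + 1, n_draws=1)

    def test_planted_pathway_beats_size_matched_null(self, planted_standardized):
        x, sets, surv, _ = planted_standardized
        planted = sets["PLANTED"]
        b, genes, _ = pa.subset_pathway(x, planted)
        d = pa.decompose(b, k=1)[0]
        p_planted = ss.fit_cox(d.eigengene, surv).p_values[0]
        null_ps = ev.gene_set_null(x, surv, set_size=len(genes), n_draws=60, seed=4)
        assert p_planted < np.percentile(null_ps, 5)


class TestTranscriptScan:
    def test_constant_transcript_skipped(self, rng):
        m = 40
        values = rng.standard_normal((3, m))
        x = ExpressionMatrix(["g0", "g1", "FLAT"], [f"s{j}" for j in range(m)],
                             values, is_standardized=False)
        x.values[2] = 0.0
        x.is_standardized = False
        surv = _surv(rng.exponential(1.0, m), np.ones(m, int))
        results, skipped = ev.transcript_scan(x, surv, n_folds=3)
        assert skipped == ["FLAT"]
        assert {r.pathway_id for r in results} == {"g0", "g1"}

    def test_planted_pathway_outranks_median_transcript(self, planted_standardized):
        x, sets, surv, _ = planted_standardized
        folds = ev.make_folds(surv.n_samples, seed=0)
        b, _, _ = pa.subset_pathway(x, sets["PLANTED"])
        d = pa.decompose(b, k=1)[0]
        pathway_c = ev.cross_validated_cindex(d.eigengene, surv, folds=folds).mean_c
        sub = ExpressionMatrix(x.gene_ids[:120], x.sample_ids, x.values[:120],
                               is_standardized=True)
        results, _ = ev.transcript_scan(sub, surv, seed=0)
        transcript_cs = [r.mean_c for r in results if r.status == "ok"]
        assert pathway_c > np.median(transcript_cs)
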