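import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from pathsurv import survival_stats as ss
from pathsurv.errors import NonIdentifiableError, ValidationError
from pathsurv.io_formats import SurvivalData

from oracles import grid_search_cox_beta, naive_cox_loglik


def _surv(time, event):
    ids = [f"s{i}" for i in range(len(time))]
    return SurvivalData(ids, np.asarray(time, float), np.asarray(event, int))


@pytest.fixture(scope="module")
def toy():
    # 6 samples, binary covariate, all events observed, groups interleaved
    # in time so the partial-likelihood maximum is finite
    time = [2.0, 5.0, 1.0, 7.0, 3.0, 9.0]
    event = [1, 1, 1, 1, 1, 1]
    x = np.array([1.0, 0.0, 1.0, 0.0, 0.0, 1.0])
    return x, _surv(time, event)


class TestFitCox:
    def test_matches_grid_search_oracle(self, toy):
        x, surv = toy
        fit = ss.fit_cox(x, surv)
        beta_grid = grid_search_cox_beta(x, surv.time, surv.event)
        assert fit.beta[0] == pytest.approx(beta_grid, abs=1e-3)
        assert fit.converged and fit.n_events == 6

    def test_loglik_matches_naive_formula_with_ties(self, rng):
        n = 40
        x = rng.standard_normal(n)
        time = np.round(rng.exponential(1.0, n), 1) + 0.1  # induces ties
        event = (rng.uniform(size=n) < 0.7).astype(int)
        fit = ss.fit_cox(x, _surv(time, event))
        ll_naive = naive_cox_loglik(fit.beta[0], x, time, event)
        assert fit.log_partial_likelihood == pytest.approx(ll_naive, abs=1e-8)

    def test_agrees_with_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 150
        x = rng.standard_normal((n, 2))
        time = np.round(rng.exponential(np.exp(-0.7 * x[:, 0]), n), 1) + 0.05
        event = (rng.uniform(size=n) < 0.7).astype(int)
        fit = ss.fit_cox(x, _surv(time, event))
        frame = pd.DataFrame({"t": time, "e": event, "x0": x[:, 0], "x1": x[:, 1]})
        cph = lifelines.CoxPHFitter().fit(frame, "t", "e")
        np.testing.assert_allclose(fit.beta, cph.params_.to_numpy(), atol=1e-4)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.to_numpy(), atol=1e-4)

    def test_breslow_option(self, rng):
        n = 30
        x = rng.standard_normal(n)
        time = np.round(rng.exponential(1.0, n), 1) + 0.1
        event = np.ones(n, int)
        efron = ss.fit_cox(x, _surv(time, event), ties="efron")
        breslow = ss.fit_cox(x, _surv(time, event), ties="breslow")
        assert efron.beta[0] != pytest.approx(breslow.beta[0], abs=1e-12)
        ll = naive_cox_loglik(breslow.beta[0], x, time, event, ties="breslow")
        assert breslow.log_partial_likelihood == pytest.approx(ll, abs=1e-8)

    def test_constant_covariate_non_identifiable(self, toy):
        _, surv = toy
        with pytest.raises(NonIdentifiableError, match="constant"):
            ss.fit_cox(np.ones(6), surv)

    def test_zero_events_rejected(self):
        with pytest.raises(NonIdentifiableError, match="no observed events"):
            ss.fit_cox(np.arange(4.0), _surv([1, 2, 3, 4], [0, 0, 0, 0]))

    def test_shift_invariance_and_inverse_scaling(self, toy):
        x, surv = toy
        base = ss.fit_cox(x, surv)
        shifted = ss.fit_cox(x + 10.0, surv)
        scaled = ss.fit_cox(3.0 * x, surv)
        assert shifted.beta[0] == pytest.approx(base.beta[0], abs=1e-6)
        assert scaled.beta[0] == pytest.approx(base.beta[0] / 3.0, abs=1e-6)
        assert shifted.p_values[0] == pytest.approx(base.p_values[0], rel=1e-6)
        assert scaled.p_values[0] == pytest.approx(base.p_values[0], rel=1e-6)

    def test_sample_permutation_invariance(self, rng):
        n = 50
        x = rng.standard_normal(n)
        time = rng.exponential(1.0, n)
        event = (rng.uniform(size=n) < 0.8).astype(int)
        base = ss.fit_cox(x, _surv(time, event))
        perm = rng.permutation(n)
        permuted = ss.fit_cox(x[perm], _surv(time[perm], event[perm]))
        assert permuted.beta[0] == pytest.approx(base.beta[0], abs=1e-9)

    def test_grid_oracle_on_random_small_instances(self, rng):
        # no censoring, binary covariate, n <= 12
        for _ in range(30):
            n = int(rng.integers(4, 13))
            x = rng.integers(0, 2, n).astype(float)
            if x.std() == 0:
                continue
            time = rng.exponential(1.0, n)
            fit = ss.fit_cox(x, _surv(time, np.ones(n, int)))
            beta_grid = grid_search_cox_beta(x, time, np.ones(n, int))
            if abs(beta_grid) > 4.9:   # optimum outside the oracle's range
                continue
            assert fit.beta[0] == pytest.approx(beta_grid, abs=1e-3)


class TestQValues:
    def test_all_ones(self):
        np.testing.assert_allclose(ss.compute_qvalues([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_pi0_one_equals_benjamini_hochberg(self, rng):
        p = rng.uniform(size=200)
        q = ss.compute_qvalues(p, pi0=1.0)
        _, bh, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_pi0_estimate_on_uniform_pvalues(self):
        for seed in (0, 1, 2):
            p = np.random.default_rng(seed).uniform(size=1000)
            assert 0.8 <= ss.estimate_pi0(p) <= 1.2

    def test_pi0_detects_signal(self, rng):
        p = np.concatenate([rng.uniform(size=500),
                            rng.uniform(0, 1e-4, size=500)])
        assert ss.estimate_pi0(p) < 0.8

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=300)
        q = ss.compute_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_never_below_min_p_times_pi0(self, rng):
        p = rng.uniform(size=500)
        pi0 = ss.estimate_pi0(p)
        q = ss.compute_qvalues(p)
        assert q.min() >= p.min() * pi0 - 1e-12

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [np.nan, 0.5]])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValidationError):
            ss.compute_qvalues(bad)


@pytest.fixture(scope="module")
def scan_inputs():
    rng = np.random.default_rng(3)
    m = 120
    act = pd.DataFrame(rng.standard_normal((6, m)),
                       index=[f"PW{i}" for i in range(6)],
                       columns=[f"s{i}" for i in range(m)])
    time = rng.exponential(np.exp(-1.2 * act.loc["PW0"].to_numpy()))
    surv = SurvivalData(list(act.columns), time, np.ones(m, int))
    return act, surv


@pytest.fixture(scope="module")
def components():
    rng = np.random.default_rng(9)
    m = 100
    a = rng.standard_normal((3, m))
    time = rng.exponential(np.exp(-0.8 * a[0]))
    surv = SurvivalData([f"s{i}" for i in range(m)], time, np.ones(m, int))
    return a, surv


class TestPathwayScan:
    def test_smallest_p_gets_smallest_q(self, scan_inputs):
        act, surv = scan_inputs
        results = ss.pathway_scan(act, surv)
        ok = [r for r in results if r.status == "ok"]
        best = min(ok, key=lambda r: r.p)
        assert best.q == min(r.q for r in ok)
        assert best.pathway_id == "PW0"

    def test_collinear_confounder_flagged(self, scan_inputs):
        act, surv = scan_inputs
        conf = act.loc["PW0"].to_numpy()
        results = ss.pathway_scan(act.loc[["PW0"]], surv, confounder=conf)
        assert results[0].status.startswith("non_identifiable")

    def test_failed_fits_excluded_from_fdr(self, scan_inputs):
        act, surv = scan_inputs
        broken = act.copy()
        broken.loc["FLAT"] = 1.0
        results = ss.pathway_scan(broken, surv)
        flat = next(r for r in results if r.pathway_id == "FLAT")
        assert flat.status.startswith("non_identifiable") and np.isnan(flat.q)
        assert all(np.isfinite(r.q) for r in results if r.status == "ok")

    def test_empty_table_rejected(self, scan_inputs):
        _, surv = scan_inputs
        with pytest.raises(ValidationError, match="empty"):
            ss.pathway_scan(pd.DataFrame(columns=list(surv.sample_ids)), surv)


class TestMultiEigengene:
    def test_k1_joint_equals_scan_fit(self, components):
        a, surv = components
        joint = ss.multi_eigengene_fit(a[:1], surv, mode="joint")
        act = pd.DataFrame(a[:1], index=["PW"], columns=surv.sample_ids)
        scan = ss.pathway_scan(act, surv)[0]
        assert joint.beta[0] == pytest.approx(scan.beta, abs=1e-10)
        assert joint.p_values[0] == pytest.approx(scan.p, abs=1e-10)

    def test_joint_loglik_dominates_nested_singles(self, components):
        a, surv = components
        joint = ss.multi_eigengene_fit(a, surv, mode="joint")
        singles = ss.multi_eigengene_fit(a, surv, mode="separate")
        for single in singles:
            assert joint.log_partial_likelihood >= single.log_partial_likelihood - 1e-8

    def test_separate_mode_returns_k_fits(self, components):
        a, surv = components
        singles = ss.multi_eigengene_fit(a, surv, mode="separate")
        assert len(singles) == 3
        assert all(len(f.beta) == 1 for f in singles)

    def test_joint_null_false_positive_rate_exceeds_single(self):
        # more coefficients per pathway => more chances of a small p under
        # the null (the degrees-of-freedom cost of the multi-component model)
        rng = np.random.default_rng(21)
        m, reps, k = 80, 150, 3
        joint_hit = single_hit = 0
        for _ in range(reps):
            a = rng.standard_normal((k, m))
            surv = SurvivalData([f"s{i}" for i in range(m)],
                                rng.exponential(1.0, m), np.ones(m, int))
            joint = ss.multi_eigengene_fit(a, surv, mode="joint")
            joint_hit += bool((joint.p_values < 0.05).any())
            single = ss.multi_eigengene_fit(a[:1], surv, mode="joint")
            single_hit += bool(single.p_values[0] < 0.05)
        assert joint_hit > single_hit
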