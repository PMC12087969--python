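import numpy as np
import pytest
from scipy import stats

from paleoniche import phylo
from paleoniche.niche_omi import BinScheme
from paleoniche.phylo import AsrResult
from paleoniche.synthgen import (SimConfig, simulate_bm_trait,
                                 simulate_fbd_tree, simulate_mk_states)
from paleoniche.trees import TimeTree


def _gls_oracle(C, x):
    """Independent small-matrix GLS: root estimate and ML sigma^2."""
    n = x.size
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    mu = (one @ Ci @ x) / (one @ Ci @ one)
    s2 = (x - mu) @ Ci @ (x - mu) / n
    return mu, s2


class TestAsrBm:
    def test_constant_trait_reconstructs_constant(self, five_tip_tree):
        res = phylo.asr_bm(five_tip_tree, np.full(5, 3.3))
        assert np.allclose(res.node_values, 3.3, atol=1e-6)

    def test_three_tip_gls_closed_form(self, three_tip_tree):
        """Conditional-MVN algebra done independently with dense matrices."""
        t = three_tip_tree
        x = np.array([1.0, 2.0, -0.5])
        res = phylo.asr_bm(t, x)
        internals = [i for i in range(t.n_nodes) if t.children[i]]
        nodes = np.concatenate([t.tips, internals])
        Cfull = t.mrca_depth_matrix(nodes)
        Ctt = Cfull[:3, :3] + 1e-12 * np.eye(3)
        Cit = Cfull[3:, :3]
        mu, _ = _gls_oracle(Ctt, x)
        pred = mu + Cit @ np.linalg.solve(Ctt, x - mu)
        order = [list(res.node_ids).index(i) for i in internals]
        assert np.allclose(res.node_values[order], pred, atol=1e-10)

    def test_ci_calibration_on_bm_simulations(self):
        """~95% of true node values fall inside the 95% CI."""
        cfg = SimConfig(seed=21, n_extant=48, n_fossil=8, root_age=100.0,
                        birth_rate=0.06, death_rate=0.02)
        tree = simulate_fbd_tree(cfg)
        rng = np.random.default_rng(3)
        hits = tot = 0
        for _ in range(40):
            truth = simulate_bm_trait(tree, 0.2, 0.0, rng=rng)
            res = phylo.asr_bm(tree, truth[tree.tips])
            inside = (truth[res.node_ids] >= res.ci95[:, 0]) & \
                     (truth[res.node_ids] <= res.ci95[:, 1])
            hits += inside.sum()
            tot += inside.size
        assert 0.92 <= hits / tot <= 0.98


class TestAsrMk:
    def test_single_state_root_posterior_is_one(self, five_tip_tree):
        res = phylo.asr_mk(five_tip_tree, np.zeros(5, dtype=int), 2)
        root_row = list(res.node_ids).index(five_tip_tree.root)
        assert res.state_posterior[root_row, 0] == pytest.approx(1.0, abs=1e-6)

    def test_posteriors_sum_to_one(self, medium_tree):
        states = simulate_mk_states(medium_tree, 0.02, 2, seed=5)
        res = phylo.asr_mk(medium_tree, states[medium_tree.tips], 2)
        assert np.allclose(res.state_posterior.sum(axis=1), 1.0, atol=1e-12)

    def test_two_tip_enumeration_oracle(self):
        """Marginal root posterior equals exhaustive enumeration."""
        t = TimeTree.from_newick("(a:1.5,b:0.7);")
        states = {t.labels[i]: s for i, s in zip(t.tips, [0, 1])}
        res = phylo.asr_mk(t, states, 2)
        q = res.rate
        k = 2

        def ptrans(i, j, bl):
            e = np.exp(-k * q * bl)
            return 1 / k + (k - 1) / k * e if i == j else 1 / k - e / k

        tipst = [states[t.labels[i]] for i in t.tips]
        bls = [t.blen[i] for i in t.tips]
        joint = np.array([0.5 * ptrans(r, tipst[0], bls[0])
                          * ptrans(r, tipst[1], bls[1]) for r in range(2)])
        root_row = list(res.node_ids).index(t.root)
        assert np.allclose(res.state_posterior[root_row],
                           joint / joint.sum(), atol=1e-12)


class TestPagelLambda:
    def test_lambda_one_reproduces_bm_likelihood(self, medium_tree, rng):
        x = simulate_bm_trait(medium_tree, 0.1, 0.0, rng=rng)[medium_tree.tips]
        C = medium_tree.vcv()
        mu, s2 = _gls_oracle(C + 1e-12 * np.eye(len(x)), x)
        direct = stats.multivariate_normal.logpdf(x, mean=np.full(len(x), mu),
                                                  cov=s2 * C + 1e-10 * np.eye(len(x)))
        res = phylo.pagel_lambda(medium_tree, x)
        # evaluate the profile at lambda = 1 via the fit on BM data
        assert res.extras["logL_hat"] >= direct - 1e-6

    def test_five_tip_grid_search_oracle(self, five_tip_tree):
        x = np.array([0.3, 0.5, -1.2, -0.8, 2.0])
        res = phylo.pagel_lambda(five_tip_tree, x)
        C = five_tip_tree.vcv()
        lmax = res.extras["lambda_max"]

        def prof(lam):
            Cl = C * lam
            np.fill_diagonal(Cl, np.diag(C))
            mu, s2 = _gls_oracle(Cl + 1e-12 * np.eye(5), x)
            return stats.multivariate_normal.logpdf(
                x, mean=np.full(5, mu), cov=s2 * Cl + 1e-12 * np.eye(5))

        grid = np.arange(0.0, lmax, 1e-4)
        best = grid[np.argmax([prof(g) for g in grid])]
        assert abs(res.lambda_hat - best) <= 2e-4

    def test_affine_invariance(self, medium_tree, rng):
        x = simulate_bm_trait(medium_tree, 0.2, 0.0, rng=rng)[medium_tree.tips]
        a = phylo.pagel_lambda(medium_tree, x)
        b = phylo.pagel_lambda(medium_tree, 5.0 * x - 3.0)
        assert a.lambda_hat == pytest.approx(b.lambda_hat, abs=1e-6)


class TestBlombergK:
    def test_affine_invariance(self, medium_tree, rng):
        x = simulate_bm_trait(medium_tree, 0.2, 0.0, rng=rng)[medium_tree.tips]
        a = phylo.blomberg_k(medium_tree, x, n_perm=50, seed=1)
        b = phylo.blomberg_k(medium_tree, -2.0 * x + 10.0, n_perm=50, seed=1)
        assert a.K == pytest.approx(b.K, abs=1e-8)

    def test_shuffling_destroys_signal(self, medium_tree):
        rng = np.random.default_rng(8)
        wins = 0
        for _ in range(10):
            x = simulate_bm_trait(medium_tree, 0.2, 0.0, rng=rng)[medium_tree.tips]
            k0 = phylo.blomberg_k(medium_tree, x, n_perm=10, seed=1).K
            ks = phylo.blomberg_k(medium_tree, rng.permutation(x),
                                  n_perm=10, seed=1).K
            wins += ks < k0
        assert wins >= 9

    def test_constant_trait_rejected(self, medium_tree):
        with pytest.raises(ValueError, match="constant"):
            phylo.blomberg_k(medium_tree, np.ones(medium_tree.n_tips))

    def test_permutation_floor_with_default_count(self, five_tip_tree):
        res = phylo.blomberg_k(five_tip_tree, np.array([0.1, 0.2, 5, 6, 3.0]),
                               n_perm=100, seed=0)
        assert res.p_K >= 1.0 / 101


class TestEvoModels:
    def test_transform_models_nest_bm(self, medium_tree, rng):
        """LB/DT/KP/EB/OU all contain BM, so their logL can't be worse."""
        x = simulate_bm_trait(medium_tree, 0.1, 2.0, rng=rng)[medium_tree.tips]
        tab = phylo.fit_evo_models(medium_tree, x)
        for m in ["LB", "DT", "KP", "OU", "RT", "MT"]:
            assert tab.loc[m, "logL"] >= tab.loc["BM", "logL"] - 1e-3
        expected = (-2 * tab["logL"] + 2 * tab["k"]
                    + 2 * tab["k"] * (tab["k"] + 1)
                    / (medium_tree.n_tips - tab["k"] - 1))
        assert np.allclose(tab["AICc"].to_numpy(), expected.to_numpy())

    def test_bm_recovered_on_bm_data(self):
        cfg = SimConfig(seed=11, n_extant=50, n_fossil=None,
                        fossil_sampling_rate=0.0, death_rate=0.0,
                        birth_rate=0.05, root_age=100.0)
        tree = simulate_fbd_tree(cfg)
        rng = np.random.default_rng(17)
        good = 0
        for _ in range(20):
            x = simulate_bm_trait(tree, 0.1, 0.0, rng=rng)[tree.tips]
            tab = phylo.fit_evo_models(tree, x)
            good += tab.loc["BM", "dAICc"] <= 2.0
        assert good >= 16

    def test_ou_alpha_limit_is_bm(self, five_tip_tree):
        x = np.array([0.3, 0.5, -1.2, -0.8, 2.0])
        C = five_tip_tree.vcv()
        D = np.add.outer(np.diag(C), np.diag(C)) - 2 * C
        al = 1e-8
        R = np.exp(-al * D) * (1 - np.exp(-2 * al * C)) / (2 * al)
        mu_b, s_b = _gls_oracle(C + 1e-12 * np.eye(5), x)
        mu_o, s_o = _gls_oracle(R + 1e-12 * np.eye(5), x)
        ll_b = stats.multivariate_normal.logpdf(x, np.full(5, mu_b), s_b * C)
        ll_o = stats.multivariate_normal.logpdf(x, np.full(5, mu_o), s_o * R)
        assert abs(ll_b - ll_o) < 1e-4


class TestPgls:
    def test_star_tree_equals_ols(self, star_tree, rng):
        y = rng.normal(size=star_tree.n_tips)
        x = rng.normal(size=star_tree.n_tips)
        res = phylo.pgls(star_tree, y, x)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(res["coef"], beta, atol=1e-10)

    def test_four_tip_gls_oracle(self):
        t = TimeTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        y = np.array([1.0, 1.4, -0.2, 0.3])
        x = np.array([0.0, 1.0, 0.0, 1.0])
        res = phylo.pgls(t, y, x)
        C = t.vcv()
        X = np.column_stack([np.ones(4), x])
        Ci = np.linalg.inv(C + 1e-12 * np.eye(4))
        beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
        assert np.allclose(res["coef"], beta, atol=1e-9)

    def test_collinear_predictors_rejected(self, star_tree, rng):
        x = rng.normal(size=star_tree.n_tips)
        with pytest.raises(ValueError, match="collinear"):
            phylo.pgls(star_tree, x, np.column_stack([x, 2 * x]))

    def test_planted_shape_shift_recovered(self):
        rng = np.random.default_rng(6)
        good = 0
        for rep in range(10):
            cfg = SimConfig(seed=200 + rep, n_extant=25, n_fossil=5,
                            root_age=80.0, birth_rate=0.06, death_rate=0.02)
            t = simulate_fbd_tree(cfg)
            shape = simulate_mk_states(t, 0.01, 2, rng=rng)
            wl = simulate_bm_trait(t, 0.05, 5.0, rng=rng) + 2.0 * shape
            st = shape[t.tips]
            if st.min() == st.max():
                good += 1  # no variation to test against
                continue
            res = phylo.pgls(t, wl[t.tips], st.astype(float))
            good += res["coef"][1] > 0
        assert good >= 9


class TestBinnedBranches:
    def _asr_const(self, tree, value):
        internals = np.array([i for i in range(tree.n_nodes)
                              if tree.children[i]])
        return AsrResult(node_ids=internals,
                         node_values=np.full(internals.size, value))

    def test_constant_trait_gives_constant_bin_means(self, medium_tree):
        scheme = BinScheme([100.0, 50.0, 0.0])
        asr = self._asr_const(medium_tree, 4.2)
        tab = phylo.branch_bin_means(medium_tree, asr,
                                     np.full(medium_tree.n_tips, 4.2), scheme)
        assert np.allclose(tab["mean"].dropna(), 4.2)

    def test_single_branch_hand_integration(self):
        # root at 10 Ma, two tips at 0; one branch's values go 0 -> 10
        t = TimeTree.from_newick("(a:10,b:10);")
        internals = np.array([t.root])
        asr = AsrResult(node_ids=internals, node_values=np.array([0.0]))
        tips_vals = {"a": 10.0, "b": 0.0}
        tab = phylo.branch_bin_means(t, asr, tips_vals, BinScheme([10.0, 5.0, 0.0]))
        # branch a: linear 0->10; bin 10-5 mean 2.5, bin 5-0 mean 7.5
        # branch b: constant 0; bins average the two branches equally
        assert tab["mean"].iloc[0] == pytest.approx((2.5 + 0) / 2)
        assert tab["mean"].iloc[1] == pytest.approx((7.5 + 0) / 2)

    def test_bins_beyond_root_flagged_empty(self, medium_tree):
        scheme = BinScheme([250.0, 150.0, 0.0])
        asr = self._asr_const(medium_tree, 1.0)
        tab = phylo.branch_bin_means(medium_tree, asr,
                                     np.ones(medium_tree.n_tips), scheme)
        assert bool(tab["empty"].iloc[0])

    def test_thresholds_match_segment_endpoints(self):
        t = TimeTree.from_newick("((a:5,b:5):5,(c:5,d:5):5);")
        internals = np.array([i for i in range(t.n_nodes) if t.children[i]])
        node_vals = dict(zip(internals, [0.0, 4.0, -2.0]))
        asr = AsrResult(node_ids=internals,
                        node_values=np.array([node_vals[i] for i in internals]))
        tips_vals = {"a": 8.0, "b": 2.0, "c": -6.0, "d": 1.0}
        scheme = BinScheme([10.0, 5.0, 0.0])
        tab = phylo.niche_thresholds_by_bin(t, asr, tips_vals, scheme)
        # older bin holds the two internal branches: values 0->4 and 0->-2
        assert tab["vmin"].iloc[0] == pytest.approx(-2.0)
        assert tab["vmax"].iloc[0] == pytest.approx(4.0)
        # younger bin: pendant branches span {4->8, 4->2, -2->-6, -2->1}
        assert tab["vmin"].iloc[1] == pytest.approx(-6.0)
        assert tab["vmax"].iloc[1] == pytest.approx(8.0)

    def test_constant_trait_thresholds_collapse(self, medium_tree):
        asr = self._asr_const(medium_tree, 2.0)
        tab = phylo.niche_thresholds_by_bin(
            medium_tree, asr, np.full(medium_tree.n_tips, 2.0),
            BinScheme([100.0, 0.0]))
        assert tab["vmin"].iloc[0] == pytest.approx(2.0)
        assert tab["vmax"].iloc[0] == pytest.approx(2.0)


class TestLtt:
    def test_two_tip_single_step(self):
        t = TimeTree.from_newick("(a:4,b:4);")
        ages, counts = phylo.ltt(t)
        assert list(counts) == [2]
        assert ages[0] == pytest.approx(4.0)

    def test_counts_positive_and_stepwise(self, medium_tree):
        ages, counts = phylo.ltt(medium_tree)
        assert counts.min() >= 1
        assert np.all(np.diff(ages) <= 0)

    def test_pure_birth_slope_near_birth_rate(self):
        cfg = SimConfig(seed=31, n_extant=200, n_fossil=None, birth_rate=0.08,
                        death_rate=0.0, fossil_sampling_rate=0.0,
                        root_age=60.0)
        t = simulate_fbd_tree(cfg)
        ages, counts = phylo.ltt(t)
        time_fw = t.root_age - ages
        slope = np.polyfit(time_fw, np.log(counts), 1)[0]
        assert abs(slope - 0.08) <= 0.2 * 0.08


class TestRateProxy:
    def test_single_bin_equals_mean_squared_contrast(self, medium_tree, rng):
        x = simulate_bm_trait(medium_tree, 0.3, 0.0, rng=rng)[medium_tree.tips]
        _, con = phylo.independent_contrasts(medium_tree, x)
        tab = phylo.rate_through_time_proxy(medium_tree, x,
                                            BinScheme([100.0, 0.0]), seed=1)
        assert tab["rate"].iloc[0] == pytest.approx((con ** 2).mean())

    def test_contrasts_estimate_sigma2(self, medium_tree):
        rng = np.random.default_rng(9)
        ms = [np.mean(phylo.independent_contrasts(
            medium_tree, simulate_bm_trait(medium_tree, 0.3, 0.0,
                                           rng=rng)[medium_tree.tips])[1] ** 2)
            for _ in range(50)]
        assert np.mean(ms) == pytest.approx(0.3, rel=0.15)

    def test_early_burst_declines(self):
        rng = np.random.default_rng(14)
        neg = 0
        for rep in range(10):
            cfg = SimConfig(seed=400 + rep, n_extant=40, n_fossil=5,
                            root_age=80.0, birth_rate=0.07, death_rate=0.02)
            t = simulate_fbd_tree(cfg)
            # planted early burst: rate decays toward the present
            vals = np.zeros(t.n_nodes)
            for i in t.preorder:
                if i != t.root:
                    mid_age = 0.5 * (t.age[t.parent[i]] + t.age[i])
                    rate = 0.5 * np.exp(-0.05 * (t.root_age - mid_age))
                    vals[i] = vals[t.parent[i]] + rng.normal(
                        0, np.sqrt(rate * t.blen[i]))
            scheme = BinScheme([80.0, 60.0, 40.0, 20.0, 0.0])
            tab = phylo.rate_through_time_proxy(t, vals[t.tips], scheme, seed=rep)
            ok = tab.dropna(subset=["rate"])
            mids = 0.5 * (ok["bin_older"] + ok["bin_younger"])
            rho = stats.spearmanr(mids, ok["rate"]).statistic
            neg += rho > 0  # rate increases with age = declines toward present
        assert neg >= 9
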