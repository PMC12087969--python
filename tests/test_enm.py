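import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from paleoniche import enm
from paleoniche.rasters import ClimateSlice
from paleoniche.synthgen import simulate_climate_history


class TestScreening:
    def test_uncorrelated_variables_all_retained(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 5)),
                         columns=list("abcde"))
        out = enm.screen_variables(X, threshold=0.8)
        assert sorted(out["selected"]) == list("abcde")

    def test_collinear_pair_resolved_by_pc_contribution(self):
        """PCA contributions recomputed independently via eigh on the
        correlation matrix pick the same representative."""
        rng = np.random.default_rng(4)
        v1 = rng.normal(size=40)
        v3 = rng.normal(size=40)
        X = pd.DataFrame({"v1": v1, "v2": v1 + 0.05 * rng.normal(size=40),
                          "v3": v3})
        out = enm.screen_variables(X, threshold=0.8)
        assert len(out["selected"]) == 2 and "v3" in out["selected"]
        # independent oracle: eigendecomposition of the correlation matrix,
        # contributions over the leading components covering 80% of variance
        Z = (X - X.mean()) / X.std(ddof=0)
        S = np.corrcoef(Z.to_numpy().T)
        evals, evecs = np.linalg.eigh(S)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        evr = evals / evals.sum()
        m = int(np.searchsorted(np.cumsum(evr), 0.80)) + 1
        contrib = (evecs[:, :m] ** 2 * evr[:m]).sum(axis=1) / evr[:m].sum()
        pair = [list(X.columns).index(v) for v in ("v1", "v2")]
        oracle = ("v1", "v2")[int(contrib[pair[1]] > contrib[pair[0]])]
        assert oracle in out["selected"]

    def test_constant_variable_excluded_with_warning(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20),
                          "b": np.full(20, 7.0),
                          "c": rng.normal(size=20)})
        with pytest.warns(UserWarning, match="constant"):
            out = enm.screen_variables(X)
        assert "b" in out["excluded_constant"]
        assert "b" not in out["selected"]


class TestThinning:
    def _records(self, lons, lats):
        return pd.DataFrame({"lon": lons, "lat": lats})

    def test_zero_radius_keeps_everything(self):
        r = self._records([0, 0.01, 0.02], [0, 0, 0])
        assert len(enm.thin_records(r, 0.0)) == 3

    def test_close_pair_thinned(self):
        # ~5 km apart at the equator (0.045 degrees)
        r = self._records([0.0, 0.045], [0.0, 0.0])
        assert len(enm.thin_records(r, 6.0)) == 1
        assert len(enm.thin_records(r, 4.0)) == 2

    def test_matches_brute_force_greedy(self, rng):
        lons = rng.uniform(0, 0.3, 10)
        lats = rng.uniform(0, 0.3, 10)
        r = self._records(lons, lats)
        kept = enm.thin_records(r, 8.0)
        expected = []
        for i in range(10):
            if all(enm.great_circle_km(lons[i], lats[i], lons[k], lats[k]) >= 8.0
                   for k in expected):
                expected.append(i)
        assert list(kept.index) == expected


class TestMaxEnt:
    def test_matched_means_give_zero_weights(self):
        bg = np.array([[0.0], [0.5], [1.0]])
        pres = np.array([[0.5], [0.5]])
        m = enm.fit_maxent_linear(pres, bg, reg_multiplier=1.0)
        assert np.allclose(m.weights_, 0.0, atol=1e-8)
        assert np.allclose(m.raw_density(bg), 1 / 3, atol=1e-8)

    def test_one_variable_weight_matches_stationarity_oracle(self):
        """The L1 optimum solves E_q[z] = pbar - beta exactly (active KKT);
        solved independently by scalar optimization of the objective."""
        bg = np.array([[0.0], [0.25], [0.5], [0.75], [1.0]])
        pres = np.array([[0.7], [0.9], [0.8]])
        m = enm.fit_maxent_linear(pres, bg, reg_multiplier=0.5)
        z = bg.ravel()
        pbar = pres.mean()
        beta = m.beta_[0]

        def obj(w):
            return logsumexp(z * w) - w * pbar + beta * abs(w)

        res = minimize_scalar(obj, bounds=(-50, 50), method="bounded",
                              options={"xatol": 1e-12})
        assert m.weights_[0] == pytest.approx(res.x, abs=1e-6)

    def test_kkt_gaps_within_regularization(self, rng):
        bg = rng.uniform(size=(50, 4))
        pres = rng.uniform(0.3, 1.0, size=(12, 4))
        m = enm.fit_maxent_linear(pres, bg, reg_multiplier=1.5)
        assert np.all(m.kkt_gaps(bg) <= m.beta_ + 1e-7)

    def test_gibbs_distribution_normalizes(self, rng):
        bg = rng.uniform(size=(80, 3))
        pres = rng.uniform(0.4, 1.0, size=(10, 3))
        m = enm.fit_maxent_linear(pres, bg)
        assert m.background_density_.sum() == pytest.approx(1.0, abs=1e-12)

    def test_shrinkage_monotone_in_regularization(self, rng):
        bg = rng.uniform(size=(40, 2))
        pres = rng.uniform(0.5, 1.0, size=(8, 2))
        prev = None
        for reg in [0.5, 1.0, 1.5, 2.5, 4.0]:
            w = np.abs(enm.fit_maxent_linear(pres, bg, reg).weights_)
            if prev is not None:
                assert np.all(w <= prev + 1e-8)
            prev = w


class TestProjection:
    def test_class_boundaries(self):
        P = np.array([[0.6, 0.4, 0.2]])
        assert list(enm.classify(P)[0]) == \
            ["suitable", "less_suitable", "unsuitable"]
        edge = np.array([[0.5, 0.3]])
        assert list(enm.classify(edge)[0]) == ["less_suitable", "unsuitable"]

    def test_zero_weights_give_constant_map(self):
        slices = simulate_climate_history(2, 0.0, seed=1, nlat=4, nlon=8)
        bg = slices[-1].table(["MAT"])
        m = enm.fit_maxent_linear(np.array([[bg.mean()], [bg.mean()]]), bg,
                                  variable_names=["MAT"])
        smap = enm.project(m, slices[0], ["MAT"])
        assert np.allclose(smap.P, smap.P.flat[0])

    def test_projecting_training_slice_reproduces_training_p(self, rng):
        slices = simulate_climate_history(2, 0.0, seed=2, nlat=4, nlon=8)
        slc = slices[-1]
        bg = slc.table(["MAT", "TS"])
        pres = bg[rng.choice(len(bg), 6, replace=False)]
        m = enm.fit_maxent_linear(pres, bg, variable_names=["MAT", "TS"])
        smap = enm.project(m, slc, ["MAT", "TS"])
        assert np.allclose(smap.P.ravel(), m.predict(bg), atol=1e-12)

    def test_missing_variable_named_in_error(self):
        slc = ClimateSlice(0.0, np.array([10.0]), np.array([0.0]),
                           {"MAT": np.array([[1.0]])})
        m = enm.LinearMaxEnt()
        m.selected_variables_ = ["MAT", "EL"]
        with pytest.raises(ValueError, match="EL"):
            enm.project(m, slc)

    def test_replicates_averaged_cellwise(self, rng):
        slices = simulate_climate_history(2, 0.0, seed=3, nlat=4, nlon=8)
        slc = slices[-1]
        bg = slc.table(["MAT"])
        models = [enm.fit_maxent_linear(
            bg[rng.choice(len(bg), 5, replace=False)], bg,
            variable_names=["MAT"]) for _ in range(3)]
        avg = enm.project(models, slc, ["MAT"])
        singles = [enm.project(m, slc, ["MAT"]).P for m in models]
        assert np.allclose(avg.P, np.mean(singles, axis=0), atol=1e-12)


class TestEvaluate:
    def test_strong_separation_drives_auc_toward_one(self, rng):
        # presences at the top of the background's feature range: the fitted
        # monotone model scores nearly every presence above the background
        bg = np.column_stack([rng.uniform(0, 1, 200)])
        pres = np.column_stack([rng.uniform(0.96, 1.0, 15)])
        ev = enm.evaluate(pres, bg, test_fraction=0.2,
                          n_replicates=3, seed=0, reg_multiplier=0.5)
        assert ev.auc_train > 0.95

    def test_presences_outside_background_hull_fail_with_gradient(self, rng):
        # the L1-regularized objective is unbounded when presence means lie
        # outside the attainable background feature expectations
        bg = np.column_stack([rng.uniform(0, 0.3, 60)])
        pres = np.column_stack([rng.uniform(0.8, 1.0, 15)])
        with pytest.raises(RuntimeError, match="grad norm"):
            enm.fit_maxent_linear(pres, bg, reg_multiplier=0.5)

    def test_reproducible_with_seed(self, rng):
        bg = rng.uniform(size=(50, 2))
        pres = rng.uniform(0.3, 1.0, size=(12, 2))
        a = enm.evaluate(pres, bg, 0.2, 5, seed=7)
        b = enm.evaluate(pres, bg, 0.2, 5, seed=7)
        assert a.auc_test == b.auc_test

    def test_uninformative_model_near_half(self, rng):
        # presences drawn from the background itself: no signal
        bg = rng.uniform(size=(500, 1))
        pres = bg[rng.choice(500, 40, replace=False)]
        ev = enm.evaluate(pres, bg, 0.25, 5, seed=3)
        assert abs(ev.auc_test - 0.5) < 0.1

    def test_too_few_presences_fail(self, rng):
        with pytest.raises(ValueError, match="too few"):
            enm.evaluate(rng.uniform(size=(2, 1)), rng.uniform(size=(10, 1)),
                         0.2, 3, seed=1)

    def test_training_auc_on_planted_loglinear_niche(self):
        """Power property: a loglinear planted suitability (the matched
        generator/model pair) yields training AUC above 0.8."""
        rng = np.random.default_rng(9)
        slices = simulate_climate_history(2, 0.0, seed=9, nlat=10, nlon=20)
        slc = slices[-1]
        bg = slc.table(["MAT"])
        w = np.exp(0.5 * (bg.ravel() - bg.mean()))
        cells = rng.choice(len(bg), size=60, p=w / w.sum())
        pres = bg[cells]
        ev = enm.evaluate(pres, bg, 0.2, 5, seed=2, reg_multiplier=1.5)
        assert ev.auc_train > 0.8
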