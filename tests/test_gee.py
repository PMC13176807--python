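import numpy as np
import pandas as pd
import pytest

from bchgee import classify, datagen, gee, zip_lca
from bchgee.classify import bch_weights
from bchgee.gee import (bootstrap_se, expand_data, fit_naive_gee,
                        fit_weighted_gee, wald_test)


def _toy_children(n_schools=3, T=2, n_per=4, seed=0, betas=(2.0, 1.0, 0.5),
                  sigma=0.5):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_schools):
        for t in range(1, T + 1):
            for k in range(1, n_per + 1):
                z = rng.integers(0, 2)
                cls = (i + t) % len(betas)
                rows.append({"school_id": i, "time": t, "child": k,
                             "y": betas[cls] + 0.2 * z
                             + sigma * rng.normal(),
                             "z": float(z), "_cls": cls + 1})
    return pd.DataFrame(rows)


def _toy_assign(children):
    return (children[["school_id", "time", "_cls"]]
            .drop_duplicates()
            .rename(columns={"_cls": "assigned"})
            .reset_index(drop=True))


class TestExpandData:
    def test_dimensions(self):
        # 2 children, L = 3, one covariate: 6 x 4 block per school-time
        children = _toy_children(n_schools=1, T=1, n_per=2)
        assign = _toy_assign(children)
        w = bch_weights(np.eye(3), assign)
        design = expand_data(children, assign, w)
        assert design.X.shape == (6, 4)
        assert design.y.shape == (6,)
        # class block is one indicator per row
        np.testing.assert_allclose(design.X[:, :3].sum(axis=1), 1.0)
        np.testing.assert_allclose(design.X[:3, :3], np.eye(3))

    def test_weights_follow_assigned_class(self):
        children = _toy_children(n_schools=2, T=2, n_per=3, seed=1)
        assign = _toy_assign(children)
        D = np.array([[0.8, 0.1, 0.05], [0.15, 0.8, 0.15], [0.05, 0.1, 0.8]])
        w = bch_weights(D, assign)
        design = expand_data(children, assign, w)
        # every child-time carries the weight vector of its school's class
        Dstar = w.Dstar
        for r in assign.itertuples():
            mask = ((children["school_id"] == r.school_id)
                    & (children["time"] == r.time))
            n_kids = int(mask.sum())
            rows = design.w[np.repeat(mask.to_numpy(), 3)]
            np.testing.assert_allclose(
                rows.reshape(n_kids, 3), np.tile(Dstar.T[r.assigned - 1],
                                                 (n_kids, 1)))

    def test_single_class_expansion_is_identity(self):
        children = _toy_children(betas=(1.5,))
        assign = _toy_assign(children)
        w = bch_weights(np.eye(1), assign)
        design = expand_data(children, assign, w)
        assert design.L == 1
        assert len(design.y) == len(children)
        np.testing.assert_allclose(design.w, 1.0)

    def test_unmatched_keys_reported(self):
        children = _toy_children()
        assign = _toy_assign(children).iloc[:-1]
        w = bch_weights(np.eye(3), assign)
        with pytest.raises(ValueError, match="no class assignment"):
            expand_data(children, assign, w)


class TestWeightedGee:
    def test_identity_weights_match_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        children = _toy_children(n_schools=6, T=2, n_per=5, seed=2)
        assign = _toy_assign(children)
        w = bch_weights(np.eye(3), assign)
        design = expand_data(children, assign, w)
        fit = fit_weighted_gee(design, "independence")
        naive = fit_naive_gee(children, assign, 3)

        X = np.zeros((len(children), 4))
        X[np.arange(len(children)),
          children["_cls"].to_numpy() - 1] = 1.0
        X[:, 3] = children["z"]
        ols = sm.OLS(children["y"].to_numpy(), X).fit()
        np.testing.assert_allclose(fit.beta, ols.params, atol=1e-8)
        np.testing.assert_allclose(naive.beta, ols.params, atol=1e-8)
        np.testing.assert_allclose(fit.beta, naive.beta, atol=1e-10)

    @pytest.mark.filterwarnings("ignore:estimated scale parameter")
    def test_closed_form_weighted_solve(self):
        # independence estimate equals the brute-force weighted LS formula
        children = _toy_children(n_schools=2, T=1, n_per=3, seed=3,
                                 betas=(2.0, 1.0))
        assign = _toy_assign(children)
        D = np.array([[0.85, 0.2], [0.15, 0.8]])
        w = bch_weights(D, assign)
        design = expand_data(children, assign, w)
        fit = fit_weighted_gee(design, "independence")
        X, y, wt = design.X, design.y, design.w
        oracle = np.linalg.solve(X.T @ (wt[:, None] * X), X.T @ (wt * y))
        np.testing.assert_allclose(fit.beta, oracle, atol=1e-10)

    def test_score_identity_at_convergence(self, small_dataset,
                                           fitted_pipeline):
        _, children, _ = small_dataset
        design = expand_data(children, fitted_pipeline["assign"],
                             fitted_pipeline["weights"])
        for structure in ("independence", "exchangeable2"):
            fit = fit_weighted_gee(design, structure)
            assert fit.converged
            assert fit.score_norm < 1e-6

    def test_fixed_zero_alphas_equal_independence(self, small_dataset,
                                                  fitted_pipeline):
        _, children, _ = small_dataset
        design = expand_data(children, fitted_pipeline["assign"],
                             fitted_pipeline["weights"])
        ind = fit_weighted_gee(design, "independence")
        exch0 = fit_weighted_gee(design, "exchangeable2",
                                 fixed_alphas=(0.0, 0.0))
        np.testing.assert_allclose(exch0.beta, ind.beta, atol=1e-8)
        np.testing.assert_allclose(exch0.cov, ind.cov, atol=1e-8)

    def test_school_order_invariance(self):
        children = _toy_children(n_schools=5, T=2, n_per=4, seed=4)
        assign = _toy_assign(children)
        D = np.array([[0.8, 0.1, 0.05], [0.15, 0.8, 0.15], [0.05, 0.1, 0.8]])
        w = bch_weights(D, assign)
        fit1 = fit_weighted_gee(expand_data(children, assign, w),
                                "exchangeable2")
        relabel = {0: 4, 1: 2, 2: 0, 3: 1, 4: 3}
        children2 = children.assign(
            school_id=children["school_id"].map(relabel))
        assign2 = assign.assign(school_id=assign["school_id"].map(relabel))
        fit2 = fit_weighted_gee(expand_data(children2, assign2, w),
                                "exchangeable2")
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-9)
        np.testing.assert_allclose(fit1.alpha_w, fit2.alpha_w, atol=1e-12)

    def test_attenuation_direction_low_entropy(self):
        # misclassification attenuates the naive extreme-class contrast
        cfg = datagen.make_scenario(entropy="low", effect_size=0.25,
                                    n_schools=400, children_range=(5, 10),
                                    seed=17)
        panel, children, _ = datagen.simulate_dataset(cfg)
        model = zip_lca.fit_zip_lca(panel, 3, n_starts=2, seed=0)
        post = classify.posterior_probs(model, panel)
        assign = classify.modal_assign(post)
        D = classify.classification_error(post, assign)
        w = classify.bch_weights(D, assign)
        bch = fit_weighted_gee(expand_data(children, assign, w))
        naive = fit_naive_gee(children, assign, 3)
        c13 = np.array([1.0, 0.0, -1.0, 0.0])
        assert abs(c13 @ naive.beta) < abs(c13 @ bch.beta)


class TestSandwich:
    def test_reduces_to_cluster_robust_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        children = _toy_children(n_schools=8, T=2, n_per=4, seed=6)
        assign = _toy_assign(children)
        naive = fit_naive_gee(children, assign, 3)

        X = np.zeros((len(children), 4))
        X[np.arange(len(children)), children["_cls"].to_numpy() - 1] = 1.0
        X[:, 3] = children["z"]
        ols = sm.OLS(children["y"].to_numpy(), X).fit(
            cov_type="cluster",
            cov_kwds={"groups": children["school_id"], "use_correction": False})
        np.testing.assert_allclose(naive.cov, ols.cov_params(), atol=1e-8)

    def test_matches_dense_assembly(self):
        # independently coded bread/meat with dense per-school matrices
        children = _toy_children(n_schools=3, T=2, n_per=3, seed=7)
        assign = _toy_assign(children)
        D = np.array([[0.8, 0.1, 0.05], [0.15, 0.8, 0.15], [0.05, 0.1, 0.8]])
        w = bch_weights(D, assign)
        design = expand_data(children, assign, w)
        aw, ab = 0.07, 0.04
        fit = fit_weighted_gee(design, "exchangeable2",
                               fixed_alphas=(aw, ab))
        M = len(design.y)
        R = np.eye(M)
        for i in range(M):
            for j in range(M):
                if i == j or design.school[i] != design.school[j]:
                    continue
                if design.st_seg[i] == design.st_seg[j]:
                    if design.copy[i] == design.copy[j]:
                        R[i, j] = aw
                else:
                    R[i, j] = ab
        V = fit.phi * R
        bread = np.zeros((4, 4))
        meat = np.zeros((4, 4))
        Vinv = np.linalg.inv(V)
        for i in np.unique(design.school):
            m = design.school == i
            Xi, yi, wi = design.X[m], design.y[m], design.w[m]
            Vi_inv = np.linalg.inv(V[np.ix_(m, m)])
            bread += Xi.T @ Vi_inv @ np.diag(wi) @ Xi
            Si = Xi.T @ Vi_inv @ np.diag(wi) @ (yi - Xi @ fit.beta)
            meat += np.outer(Si, Si)
        expected = np.linalg.inv(bread) @ meat @ np.linalg.inv(bread).T
        np.testing.assert_allclose(fit.cov, expected, atol=1e-8)

    def test_diagonal_nonnegative(self, small_dataset, fitted_pipeline):
        _, children, _ = small_dataset
        design = expand_data(children, fitted_pipeline["assign"],
                             fitted_pipeline["weights"])
        fit = fit_weighted_gee(design, "exchangeable2")
        assert np.all(np.diag(fit.cov) >= 0)
        eigvals = np.linalg.eigvalsh(fit.cov)
        assert eigvals.min() > -1e-12


class TestWald:
    def test_normal_tail_arithmetic(self):
        fit = gee.GeeFit(beta=np.array([0.2, 0.0]),
                         cov=np.array([[0.01, 0.0], [0.0, 1.0]]),
                         phi=1.0, alpha_w=0.0, alpha_b=0.0,
                         structure="independence", colnames=["a", "b"],
                         n_iter=1, converged=True, score_norm=0.0,
                         N_total=10, n_schools=5)
        res = wald_test(fit, [1.0, 0.0])
        assert res.z == pytest.approx(2.0)
        assert res.pvalue == pytest.approx(0.0455, abs=2e-4)

    def test_zero_contrast_rejected(self):
        fit = gee.GeeFit(beta=np.zeros(2), cov=np.eye(2), phi=1.0,
                         alpha_w=0.0, alpha_b=0.0, structure="independence",
                         colnames=["a", "b"], n_iter=1, converged=True,
                         score_norm=0.0, N_total=10, n_schools=5)
        with pytest.raises(ValueError, match="zero"):
            wald_test(fit, [0.0, 0.0])

    def test_pvalue_sign_invariant(self):
        fit = gee.GeeFit(beta=np.array([0.3, -0.1]), cov=np.eye(2) * 0.04,
                         phi=1.0, alpha_w=0.0, alpha_b=0.0,
                         structure="independence", colnames=["a", "b"],
                         n_iter=1, converged=True, score_norm=0.0,
                         N_total=10, n_schools=5)
        c = np.array([1.0, -1.0])
        assert wald_test(fit, c).pvalue == pytest.approx(
            wald_test(fit, -c).pvalue, rel=1e-12)


class TestBootstrap:
    def test_single_replicate_rejected(self, small_dataset, fitted_pipeline):
        panel, children, _ = small_dataset
        with pytest.raises(ValueError, match="B >= 2"):
            bootstrap_se(panel, children, fitted_pipeline["model"], B=1)

    @pytest.mark.filterwarnings("ignore:estimated scale parameter")
    def test_noiseless_outcomes_give_zero_se(self):
        # perfectly separated classes and noise-free outcomes
        cfg = datagen.make_scenario(entropy="high", effect_size=0.25,
                                    n_schools=60, children_range=(3, 5),
                                    seed=5)
        from dataclasses import replace
        cfg = replace(cfg, var_between=0.0, var_within_time=0.0,
                      var_child=1e-12, beta_z=0.0,
                      zip_lambda=cfg.zip_lambda * 5,
                      zip_p=np.full((3, 3), 1e-6))
        panel, children, paths = datagen.simulate_dataset(cfg)
        model = zip_lca.fit_zip_lca(panel, 3, n_starts=2, seed=0)
        res = bootstrap_se(panel, children, model, B=10, seed=0)
        assert res["n_success"] >= 8
        assert np.all(res["se"][:3] < 0.05)

    def test_bootstrap_se_tracks_sampling_variability(self, small_dataset,
                                                      fitted_pipeline):
        panel, children, _ = small_dataset
        res = bootstrap_se(panel, children, fitted_pipeline["model"], B=30,
                           seed=1)
        design = expand_data(children, fitted_pipeline["assign"],
                             fitted_pipeline["weights"])
        fit = fit_weighted_gee(design)
        sandwich_se = np.sqrt(np.diag(fit.cov))
        ratio = res["se"] / sandwich_se
        assert np.all(ratio[:3] > 0.4) and np.all(ratio[:3] < 2.5)
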