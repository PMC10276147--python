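import numpy as np
import pytest

import mtlassosum as mt
from _oracles import convex_oracle, dense_quadratic


def _fit(inst, lams, cross=1.0, tol=1e-12, **kw):
    pen = mt.PenaltySpec(lambdas=np.atleast_1d(lams), s=0.5, **kw)
    return pen, mt.fit((inst["r"], inst["n"]), inst["blocks"], inst["model"], pen,
                       tol=tol, max_iter=2000, cross_term_factor=cross)


class TestCoordinateUpdate:
    @pytest.fixture()
    def scalar_instance(self, sd_panel_blocks):
        panel, blocks = sd_panel_blocks
        sub = blocks.subset(np.arange(panel.n_snps) < 1)
        model = mt.constant_model((0.5,), 0.0, 1)
        return sub, model

    def test_soft_threshold_kills_small_terms(self, scalar_instance):
        sub, model = scalar_instance
        # A = n * r / sigma2_e = 1 * 0.15 * 2 = 0.3 <= lambda * w = 0.5
        pen = mt.PenaltySpec(lambdas=[0.5], s=0.5)
        beta = np.zeros((1, 1))
        val = mt.coordinate_update(0, 0, beta, (np.array([[0.15]]), [1.0]),
                                   sub, model, pen, lam=0.5)
        assert val == 0.0

    def test_unpenalized_ratio(self, scalar_instance):
        sub, model = scalar_instance
        # D = n*(X'X+s)/sigma2_e + omega = 1*1*2 + 2 = 4; A = 2*0.2 = 0.4
        pen = mt.PenaltySpec(lambdas=[1e-300], s=0.5)
        beta = np.zeros((1, 1))
        val = mt.coordinate_update(0, 0, beta, (np.array([[0.2]]), [1.0]),
                                   sub, model, pen, lam=1e-300)
        assert val == pytest.approx(0.4 / 4.0)

    def test_fit_is_coordinate_fixed_point(self, tiny_sd_instance):
        pen, res = _fit(tiny_sd_instance, 0.5)
        beta = res.beta[0]
        for j in range(beta.shape[0]):
            for k in range(beta.shape[1]):
                new = mt.coordinate_update(
                    j, k, beta, (tiny_sd_instance["r"], tiny_sd_instance["n"]),
                    tiny_sd_instance["blocks"], tiny_sd_instance["model"], pen, lam=0.5,
                )
                assert new == pytest.approx(beta[j, k], abs=1e-9)


class TestConvexOracleEquivalence:
    @pytest.mark.parametrize("cross", [1.0, 0.5])
    @pytest.mark.parametrize("lam", [0.5, 5.0])
    def test_matches_generic_convex_minimizer(self, tiny_sd_instance, cross, lam):
        inst = tiny_sd_instance
        _, res = _fit(inst, lam, cross=cross)
        Q = dense_quadratic(inst["blocks"], inst["model"], inst["n"], 0.5, cross)
        v = (inst["n"] / inst["model"].residual * inst["r"]).reshape(-1)
        expected = convex_oracle(Q, v, lam, np.ones(Q.shape[0]))
        np.testing.assert_allclose(res.beta[0].reshape(-1), expected, atol=1e-6)

    def test_oracle_with_weights(self, tiny_sd_instance):
        inst = tiny_sd_instance
        rng = np.random.default_rng(3)
        W = rng.uniform(0.5, 2.0, inst["r"].shape)
        _, res = _fit(inst, 1.0, weights=W)
        Q = dense_quadratic(inst["blocks"], inst["model"], inst["n"], 0.5, 1.0)
        v = (inst["n"] / inst["model"].residual * inst["r"]).reshape(-1)
        expected = convex_oracle(Q, v, 1.0, W.reshape(-1))
        np.testing.assert_allclose(res.beta[0].reshape(-1), expected, atol=1e-6)


class TestFitProperties:
    def test_full_shrinkage_above_lambda_max(self, reference_sim):
        sim = reference_sim
        lmax = mt.lambda_max(sim["ss"], sim["model"])
        res = mt.fit(sim["ss"], sim["blocks"], sim["model"],
                     mt.PenaltySpec(lambdas=[lmax * 1.001], s=0.5))
        assert not res.beta.any()

    def test_objective_trace_non_increasing(self, reference_sim):
        sim = reference_sim
        lmax = mt.lambda_max(sim["ss"], sim["model"])
        pen = mt.PenaltySpec(lambdas=np.geomspace(lmax * 0.8, lmax * 0.05, 5), s=0.5)
        res = mt.fit(sim["ss"], sim["blocks"], sim["model"], pen)
        for trace in res.objective:
            assert np.all(np.diff(trace) <= 1e-8 * np.maximum(1.0, np.abs(trace[:-1])))

    def test_decoupling_matches_univariate_fits(self, reference_sim):
        sim = reference_sim
        model = sim["model"].diagonalized()
        lmax = mt.lambda_max(sim["ss"], model)
        pen = mt.PenaltySpec(lambdas=np.geomspace(lmax * 0.8, lmax * 0.05, 4), s=0.5)
        res_mv = mt.fit(sim["ss"], sim["blocks"], model, pen, tol=1e-8, max_iter=500)
        for k in range(2):
            res_k = mt.fit(
                (sim["ss"].r[:, k : k + 1], sim["ss"].n[k : k + 1]),
                sim["blocks"], model.subset_trait(k), pen, tol=1e-8, max_iter=500,
            )
            np.testing.assert_allclose(res_mv.beta[:, :, k], res_k.beta[:, :, 0],
                                       atol=1e-8)

    def test_permutation_invariance(self, reference_sim):
        sim = reference_sim
        blocks = sim["blocks"]
        order = np.arange(len(blocks.blocks))[::-1]
        perm = np.concatenate([np.arange(a, b) for a, b in [blocks.blocks[i] for i in order]])
        panel_p = blocks.panel.subset(perm)
        sizes = [blocks.blocks[i][1] - blocks.blocks[i][0] for i in order]
        spans, off = [], 0
        for m in sizes:
            spans.append((off, off + m))
            off += m
        blocks_p = mt.LDBlockSet(panel=panel_p, blocks=spans, s=blocks.s)
        model_p = mt.GeneticCovarianceModel(sigma_b=sim["model"].sigma_b[perm])
        lmax = mt.lambda_max(sim["ss"], sim["model"])
        pen = mt.PenaltySpec(lambdas=[lmax * 0.2], s=0.5)
        res = mt.fit(sim["ss"], sim["blocks"], sim["model"], pen, tol=1e-10, max_iter=500)
        res_p = mt.fit((sim["ss"].r[perm], sim["ss"].n), blocks_p, model_p, pen,
                       tol=1e-10, max_iter=500)
        np.testing.assert_allclose(res_p.beta[0], res.beta[0][perm], atol=1e-8)

    def test_infinite_weights_pin_coefficients(self, reference_sim):
        sim = reference_sim
        p, q = sim["ss"].r.shape
        W = np.ones((p, q))
        rng = np.random.default_rng(8)
        pinned = rng.choice(p, 50, replace=False)
        W[pinned, 0] = np.inf
        lmax = mt.lambda_max(sim["ss"], sim["model"])
        pen = mt.PenaltySpec(lambdas=[lmax * 0.05], s=0.5, weights=W)
        res = mt.fit(sim["ss"], sim["blocks"], sim["model"], pen)
        assert not res.beta[0][pinned, 0].any()
        assert res.beta[0].any()


class TestKKT:
    def test_converged_fit_has_no_violations(self, tiny_sd_instance):
        inst = tiny_sd_instance
        pen, res = _fit(inst, 0.5)
        report = mt.kkt_check(res.beta[0], (inst["r"], inst["n"]), inst["blocks"],
                              inst["model"], lam=0.5, tol=1e-6)
        assert report["n_violations"] == 0

    def test_perturbed_solution_is_flagged(self, tiny_sd_instance):
        inst = tiny_sd_instance
        pen, res = _fit(inst, 0.5)
        beta = res.beta[0].copy()
        beta[0, 0] += 0.01
        report = mt.kkt_check(beta, (inst["r"], inst["n"]), inst["blocks"],
                              inst["model"], lam=0.5, tol=1e-6)
        assert report["n_violations"] > 0

    def test_all_zero_at_lambda_max_flags_boundary(self, tiny_sd_instance):
        inst = tiny_sd_instance
        lmax = mt.lambda_max((inst["r"], inst["n"]), inst["model"])
        beta = np.zeros_like(inst["r"])
        report = mt.kkt_check(beta, (inst["r"], inst["n"]), inst["blocks"],
                              inst["model"], lam=lmax, tol=1e-9)
        assert report["n_violations"] == 0
        assert report["active_at_threshold"].any()


class TestAdaptiveWeights:
    def test_inverse_magnitude(self):
        w = mt.adaptive_weights(np.array([[0.1, -0.2]]), gamma=1.0)
        np.testing.assert_allclose(w, [[10.0, 5.0]])

    def test_zero_source_pins_coefficient(self, reference_sim):
        sim = reference_sim
        source = np.zeros_like(sim["ss"].r)
        source[0, 0] = 0.1
        w = mt.adaptive_weights(source)
        assert np.isinf(w[1, 0]) and w[0, 0] == 10.0
        lmax = mt.lambda_max(sim["ss"], sim["model"])
        pen = mt.PenaltySpec(lambdas=[lmax * 1e-4], s=0.5, weights=w)
        res = mt.fit(sim["ss"], sim["blocks"], sim["model"], pen)
        assert not res.beta[0][np.isinf(w)].any()
        assert res.beta[0][0, 0] != 0.0

    def test_unit_source_reproduces_constant_weight_fit(self, tiny_sd_instance):
        inst = tiny_sd_instance
        w = mt.adaptive_weights(np.ones_like(inst["r"]), gamma=1.0)
        _, res_w = _fit(inst, 0.5, weights=w)
        _, res_c = _fit(inst, 0.5)
        np.testing.assert_allclose(res_w.beta, res_c.beta, atol=1e-12)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            mt.adaptive_weights(np.ones((2, 2)), gamma=-1.0)
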