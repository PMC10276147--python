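import numpy as np
import pytest
from scipy import stats

import mtlassosum as mt
from mtlassosum.simulate import STATUS_BOTH, STATUS_NONE, STATUS_T1, STATUS_T2


class TestScenario:
    def test_reference_causal_probabilities(self):
        probs = mt.SimulationScenario.reference().causal_probs
        assert probs == pytest.approx(
            {"both": 0.35, "t1": 0.14, "t2": 0.12, "none": 0.39}
        )

    def test_low_polygenicity_causal_probabilities(self):
        probs = mt.SimulationScenario.low_polygenicity().causal_probs
        assert probs == pytest.approx(
            {"both": 0.08, "t1": 0.04, "t2": 0.02, "none": 0.86}
        )

    def test_inconsistent_probabilities_rejected(self):
        with pytest.raises(ValueError):
            mt.SimulationScenario(polygenicity=(0.2, 0.2), p_causal_both=0.3)

    def test_overlap_settings(self):
        assert mt.SimulationScenario.overlap_sensitivity().rho_o == 0.16
        assert mt.SimulationScenario.overlap_sensitivity(doubled=True).rho_o == 0.32


class TestCausalAssignment:
    def test_multinomial_proportions(self):
        scn = mt.SimulationScenario.reference()
        status = mt.assign_causal_status(40000, scn, np.random.default_rng(1))
        frac_both = (status == STATUS_BOTH).mean()
        assert frac_both == pytest.approx(0.35, abs=3 * np.sqrt(0.35 * 0.65 / 40000))

    def test_annotation_demotion(self):
        scn = mt.SimulationScenario.reference()
        p = 5000
        h1 = np.full(p, 1e-5)
        h1[: p // 2] = -1e-6
        h2 = np.full(p, 1e-5)
        status = mt.assign_causal_status(p, scn, np.random.default_rng(2),
                                         predictions=(h1, h2))
        causal1 = (status == STATUS_T1) | (status == STATUS_BOTH)
        assert not causal1[: p // 2].any()
        assert causal1[p // 2 :].any()


class TestEffects:
    def test_noncausal_rows_exactly_zero(self):
        scn = mt.SimulationScenario.reference()
        rng = np.random.default_rng(3)
        status = mt.assign_causal_status(2000, scn, rng)
        eff = mt.draw_effects(status, scn, rng)
        assert not eff.beta[status == STATUS_NONE].any()
        assert not eff.beta[status == STATUS_T1, 1].any()
        assert not eff.beta[status == STATUS_T2, 0].any()

    def test_realized_heritability_four_matrix(self):
        scn = mt.SimulationScenario.reference()
        rng = np.random.default_rng(4)
        status = mt.assign_causal_status(20000, scn, rng)
        eff = mt.draw_effects(status, scn, rng)
        m1 = ((status == STATUS_T1) | (status == STATUS_BOTH)).sum()
        h2_hat = (eff.beta[:, 0] ** 2).sum()
        assert h2_hat == pytest.approx(0.47, abs=3 * 0.47 * np.sqrt(2 / m1))

    def test_realized_genetic_correlation(self):
        scn = mt.SimulationScenario.reference()
        rng = np.random.default_rng(5)
        status = mt.assign_causal_status(20000, scn, rng)
        eff = mt.draw_effects(status, scn, rng)
        b = eff.beta
        rg = (b[:, 0] * b[:, 1]).sum() / np.sqrt((b[:, 0] ** 2).sum() * (b[:, 1] ** 2).sum())
        mb = (status == STATUS_BOTH).sum()
        assert rg == pytest.approx(0.59, abs=3 * (1 - 0.59**2) / np.sqrt(mb))

    def test_annotation_mode_scaling(self):
        scn = mt.SimulationScenario.reference()
        rng = np.random.default_rng(6)
        p = 20000
        h1 = rng.uniform(0.5, 1.5, p)
        h2 = rng.uniform(0.5, 1.5, p)
        rho = 0.5 * np.sqrt(h1 * h2)
        status = mt.assign_causal_status(p, scn, rng, predictions=(h1, h2))
        eff = mt.draw_effects(status, scn, rng, contributions=(h1, h2, rho))
        m1 = ((status == STATUS_T1) | (status == STATUS_BOTH)).sum()
        assert (eff.beta[:, 0] ** 2).sum() == pytest.approx(
            0.47, abs=3 * 0.47 * np.sqrt(2 / m1)
        )


class TestRegionSumstats:
    def test_moments_match_dense_mvn_oracle(self, sd_panel_blocks):
        panel, blocks = sd_panel_blocks
        sub = blocks.subset(np.arange(panel.n_snps) < 8)
        R = sub.ld[0]
        m = 8
        beta = np.zeros((m, 2))
        beta[2, 0] = 0.1
        n = np.array([2000.0, 2000.0])
        reps = 2000
        rng = np.random.default_rng(7)
        draws = np.array([mt.draw_region_sumstats(beta, sub, n, rng) for _ in range(reps)])
        oracle_rng = np.random.default_rng(8)
        oracle = oracle_rng.multivariate_normal(R @ beta[:, 0], R / n[0], size=reps)
        mean_se = np.sqrt(np.diag(R) / n[0] / reps)
        np.testing.assert_allclose(draws[:, :, 0].mean(0), R @ beta[:, 0],
                                   atol=(4 * mean_se).max())
        cov_hat = np.cov(draws[:, :, 0].T)
        cov_oracle = np.cov(oracle.T)
        assert np.abs(cov_hat - R / n[0]).max() < 5 * (R.max() / n[0]) * np.sqrt(2 / reps) + 1e-5
        assert np.abs(cov_hat - cov_oracle).max() < 1e-4

    def test_overlap_induces_noise_correlation(self, sd_panel_blocks):
        panel, blocks = sd_panel_blocks
        sub = blocks.subset(np.arange(panel.n_snps) < 8)
        beta = np.zeros((8, 2))
        n = np.array([3000.0, 3000.0])
        rng = np.random.default_rng(9)
        reps = 1500
        draws = np.array(
            [mt.draw_region_sumstats(beta, sub, n, rng, rho_o=0.3) for _ in range(reps)]
        )
        # whiten by the block eigenstructure and correlate the components
        R = sub.ld[0]
        w, V = np.linalg.eigh(R)
        keep = w > 1e-8
        white = np.einsum("e,je,rjk->rek", 1 / np.sqrt(w[keep]), V[:, keep], draws)
        c = np.corrcoef(white[:, :, 0].ravel(), white[:, :, 1].ravel())[0, 1]
        assert c == pytest.approx(0.3, abs=3 / np.sqrt(reps * keep.sum()))

    def test_reproducible_under_seed(self, sd_panel_blocks):
        panel, blocks = sd_panel_blocks
        beta = np.zeros((panel.n_snps, 2))
        r1 = mt.draw_region_sumstats(beta, blocks, (1000, 1000), np.random.default_rng(10))
        r2 = mt.draw_region_sumstats(beta, blocks, (1000, 1000), np.random.default_rng(10))
        np.testing.assert_array_equal(r1, r2)


class TestLiabilityCohort:
    def test_threshold_is_upper_quantile(self):
        scn = mt.SimulationScenario.reference()
        beta = np.zeros((10, 2))
        beta[0] = 0.1
        cohort = mt.simulate_liability_cohort(beta, scn, np.random.default_rng(11),
                                              n_subjects=100)
        assert cohort.thresholds[0] == pytest.approx(stats.norm.isf(0.01))
        assert cohort.thresholds[1] == pytest.approx(stats.norm.isf(0.02))

    def test_prevalence_within_binomial_error(self):
        scn = mt.SimulationScenario.reference(p_snps=2000)
        rng = np.random.default_rng(12)
        status = mt.assign_causal_status(2000, scn, rng)
        eff = mt.draw_effects(status, scn, rng)
        n = 50000
        cohort = mt.simulate_liability_cohort(eff.beta, scn, rng, n_subjects=n)
        for k, K in enumerate(scn.prevalence):
            se = np.sqrt(K * (1 - K) / n)
            assert cohort.affected[:, k].mean() == pytest.approx(K, abs=3 * se + 0.002)

    def test_vanishing_heritability_decouples_genotype(self):
        scn = mt.SimulationScenario.reference(h2=(0.001, 0.001))
        rng = np.random.default_rng(13)
        status = mt.assign_causal_status(500, scn, rng)
        eff = mt.draw_effects(status, scn, rng)
        cohort = mt.simulate_liability_cohort(eff.beta, scn, rng, n_subjects=20000)
        c = np.corrcoef(cohort.G[:, 0], cohort.affected[:, 0])[0, 1]
        assert abs(c) < 0.05


class TestEvaluate:
    def _cohort(self, G, affected):
        return mt.LiabilityCohort(G=G, liability=G, affected=affected,
                                  thresholds=np.full(G.shape[1], np.nan))

    def test_perfect_prs_correlation_one(self):
        rng = np.random.default_rng(14)
        G = rng.standard_normal((100, 1))
        cohort = self._cohort(G, G > 1.0)
        out = mt.evaluate(G, cohort)
        assert out["cor_with_G"][0] == pytest.approx(1.0)

    def test_auc_pair_enumeration(self):
        prs = np.array([2.0, 3.0, 0.0, 1.0, 2.0])[:, None]
        affected = np.array([True, True, False, False, False])[:, None]
        G = prs.copy()
        out = mt.evaluate(prs, self._cohort(G, affected))
        assert out["auc"][0] == pytest.approx(11 / 12)

    def test_independent_prs_auc_half(self):
        rng = np.random.default_rng(15)
        n = 20000
        G = rng.standard_normal((n, 1))
        prs = rng.standard_normal((n, 1))
        out = mt.evaluate(prs, self._cohort(G, G > 1.5))
        assert out["auc"][0] == pytest.approx(0.5, abs=0.02)

    def test_zero_variance_prs_is_nan(self):
        G = np.random.default_rng(16).standard_normal((50, 1))
        out = mt.evaluate(np.zeros((50, 1)), self._cohort(G, G > 0))
        assert np.isnan(out["cor_with_G"][0])


class TestFixturePanel:
    def test_zero_decay_gives_no_ld(self):
        panel, blocks = mt.make_fixture_panel(800, 60, block_size=20, ld_decay=0.0,
                                              seed=17)
        off = [np.abs(R - np.diag(np.diag(R)))[np.triu_indices(len(R), 1)].mean()
               for R in blocks.ld]
        assert np.mean(off) < 3 / np.sqrt(800)

    def test_adjacent_ld_increases_with_decay(self):
        adj = []
        for decay in (0.3, 0.9):
            panel, blocks = mt.make_fixture_panel(600, 60, block_size=20,
                                                  ld_decay=decay, seed=18)
            adj.append(np.mean([R[0, 1] for R in blocks.ld]))
        assert adj[1] > adj[0]

    def test_emitted_plink_roundtrips(self, tmp_path):
        panel, blocks = mt.make_fixture_panel(
            120, 50, block_size=25, seed=19, out_prefix=tmp_path / "fix"
        )
        back = mt.read_plink(tmp_path / "fix", maf_min=0.0)
        flipped = back.a1 != panel.a1
        np.testing.assert_array_equal(back.genotypes[:, ~flipped],
                                      panel.genotypes[:, ~flipped])
        np.testing.assert_array_equal(back.genotypes[:, flipped],
                                      2 - panel.genotypes[:, flipped])
        assert (tmp_path / "fix.blocks.tsv").exists()

    def test_population_reproducibility(self):
        pop1 = mt.SyntheticPopulation(100, seed=20)
        pop2 = mt.SyntheticPopulation(100, seed=20)
        g1 = pop1.sample_panel(50, np.random.default_rng(21)).genotypes
        g2 = pop2.sample_panel(50, np.random.default_rng(21)).genotypes
        np.testing.assert_array_equal(g1, g2)
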