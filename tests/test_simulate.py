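import numpy as np
import pytest
from scipy.special import expit, logit

import ctmix
from ctmix.errors import ConfigurationError
from ctmix.simulate import realize_sigma_jk


class TestSelectDms:
    def test_edge_counts(self):
        assert ctmix.select_dms(10, 0, seed=0).size == 0
        assert np.array_equal(ctmix.select_dms(10, 10, seed=0), np.arange(10))

    def test_full_array_scale_draw(self):
        dms = ctmix.select_dms(375_639, 500, seed=1)
        assert len(dms) == 500
        assert len(np.unique(dms)) == 500

    def test_too_many_requested(self):
        with pytest.raises(ConfigurationError):
            ctmix.select_dms(10, 11, seed=0)


class TestPhenotype:
    def test_binary_support_and_mean(self):
        z = ctmix.generate_phenotype(100_000, "binary", seed=2)
        assert set(np.unique(z)) <= {0.0, 1.0}
        assert abs(z.mean() - 0.5) < 0.005  # 99% binomial interval

    def test_continuous_sd(self):
        z = ctmix.generate_phenotype(100_000, "continuous", seed=3)
        assert abs(z.std(ddof=1) - 1.0) < 0.01  # chi-square interval

    def test_unknown_kind(self):
        with pytest.raises(ConfigurationError):
            ctmix.generate_phenotype(10, "ordinal", seed=0)


class TestEffectMeans:
    def test_degenerate_sd_gives_exact_means(self):
        sc = ctmix.ScenarioConfig(
            name="t", s=50, mu_k=(0.3, -0.2), sigma_k=(0.0, 0.0),
            sigma_jk=0.1, rho=100,
        )
        mu = ctmix.sample_effect_means(sc, seed=0)
        assert np.allclose(mu[:, 0], 0.3) and np.allclose(mu[:, 1], -0.2)

    def test_scenario1_mean_locations(self, scenario1_small):
        mu = ctmix.sample_effect_means(scenario1_small, seed=4)
        assert abs(mu[:, 0].mean() - (-0.05)) < 0.01  # sd 0.05/sqrt(500)
        assert abs(mu[:, 1].mean() - 0.5) < 0.15  # sd 0.75/sqrt(500)

    def test_block_equicorrelation(self):
        """Within-block pairwise correlation of effect means matches the
        configured background correlation (Monte-Carlo oracle)."""
        block = ctmix.BlockSpec(
            size=40, background_correlation=0.4, mu_k=(0.1, 0.4),
            sigma_k=(1.0, 1.0),
        )
        sc = ctmix.ScenarioConfig(
            name="b", s=40, mu_k=(0.1, 0.4), sigma_k=(1.0, 1.0),
            sigma_jk=0.1, rho=100, blocks=(block,),
        )
        draws = np.array(
            [ctmix.sample_effect_means(sc, seed=s)[:, 0] for s in range(4000)]
        )
        corr = np.corrcoef(draws.T)
        off = corr[np.triu_indices(40, k=1)]
        assert abs(off.mean() - 0.4) < 0.02

    def test_blocks_independent_of_each_other(self):
        blocks = (
            ctmix.BlockSpec(20, 0.5, (0.0, 0.0), (1.0, 1.0)),
            ctmix.BlockSpec(20, 0.5, (0.0, 0.0), (1.0, 1.0)),
        )
        sc = ctmix.ScenarioConfig(
            name="b2", s=40, mu_k=(0.0, 0.0), sigma_k=(1.0, 1.0),
            sigma_jk=0.1, rho=100, blocks=blocks,
        )
        draws = np.array(
            [ctmix.sample_effect_means(sc, seed=s)[:, 0] for s in range(4000)]
        )
        cross = np.corrcoef(draws[:, 5], draws[:, 25])[0, 1]
        assert abs(cross) < 0.05

    def test_invalid_block_correlation(self):
        with pytest.raises(ConfigurationError):
            ctmix.BlockSpec(10, 1.0, (0.0, 0.0), (1.0, 1.0))


class TestIndividualEffects:
    def test_zero_sd_reproduces_means(self):
        mu = np.array([[0.5, -0.5], [1.0, 2.0]])
        e = ctmix.sample_individual_effects(mu, 0.0, n=4, seed=0)
        assert e.shape == (2, 2, 4)
        assert np.allclose(e[0, :, :], mu[:, 0:1])
        assert np.allclose(e[1, :, :], mu[:, 1:2])

    def test_clt_mean(self):
        mu = np.zeros((1, 2))
        e = ctmix.sample_individual_effects(mu, 1.0, n=100_000, seed=1)
        assert abs(e.mean()) < 0.01

    def test_uniform_range_realization(self):
        sc = ctmix.ScenarioConfig(
            name="u", s=1000, mu_k=(0, 0), sigma_k=(0.1, 0.1),
            sigma_jk=(0.1, 2.0), rho=100,
        )
        sigma = realize_sigma_jk(sc, seed=0)
        assert sigma.shape == (1000, 2)
        assert (sigma >= 0.1).all() and (sigma <= 2.0).all()
        assert sigma.std() > 0

    def test_negative_sd_rejected(self):
        with pytest.raises(ConfigurationError):
            ctmix.sample_individual_effects(np.zeros((2, 2)), -1.0, n=3)


class TestApplyDmsEffect:
    @pytest.mark.parametrize(
        "beta,z,e,expected",
        [
            (0.37, 0.0, 2.5, 0.37),  # zero phenotype passes through
            (0.5, 1.0, np.log(3.0), 0.75),  # logit(0.5)=0 -> invlogit(ln 3)
            (0.2, 1.0, 1.0, 0.40460968),  # closed form invlogit(logit(.2)+1)
        ],
    )
    def test_closed_form(self, beta, z, e, expected):
        assert ctmix.apply_dms_effect(beta, z, e) == pytest.approx(
            expected, abs=1e-6
        )

    def test_monotone_increase_for_positive_effect(self):
        rng = np.random.default_rng(0)
        beta = rng.uniform(0.05, 0.95, size=50)
        out = ctmix.apply_dms_effect(beta, 1.0, 0.8)
        assert (out > beta).all()

    def test_rejects_out_of_range_beta(self):
        with pytest.raises(ValueError):
            ctmix.apply_dms_effect(1.2, 1.0, 0.0)


class TestMixtureProportions:
    def test_rows_on_simplex(self):
        p = ctmix.sample_mixture_proportions(
            np.zeros(100), (0.57, 0.43), (0.08, -0.08), 100.0, seed=0
        )
        assert np.allclose(p.sum(axis=1), 1.0)
        assert ((p >= 0) & (p <= 1)).all()

    def test_baseline_mean_matches_alpha0(self):
        p = ctmix.sample_mixture_proportions(
            np.zeros(100_000), (0.57, 0.43), (0.08, -0.08), 100.0, seed=1
        )
        assert abs(p[:, 0].mean() - 0.57) < 0.002

    def test_precision_controls_variance(self):
        """Dirichlet variance law: var(p1) = a1 a2 / (rho + 1)."""
        kw = dict(alpha0=(0.57, 0.43), delta_alpha=(0.0, 0.0))
        p_hi = ctmix.sample_mixture_proportions(
            np.zeros(100_000), kw["alpha0"], kw["delta_alpha"], 100.0, seed=2
        )
        p_lo = ctmix.sample_mixture_proportions(
            np.zeros(100_000), kw["alpha0"], kw["delta_alpha"], 10.0, seed=3
        )
        assert p_lo[:, 0].var() > p_hi[:, 0].var()
        for p, rho in ((p_hi, 100.0), (p_lo, 10.0)):
            theory = 0.57 * 0.43 / (rho + 1.0)
            assert p[:, 0].var(ddof=1) == pytest.approx(theory, rel=0.05)

    def test_confounding_by_construction(self):
        """Group difference in mean p1 approaches delta_alpha_1."""
        p1 = ctmix.sample_mixture_proportions(
            np.ones(5000), (0.57, 0.43), (0.08, -0.08), 100.0, seed=4
        )
        p0 = ctmix.sample_mixture_proportions(
            np.zeros(5000), (0.57, 0.43), (0.08, -0.08), 100.0, seed=5
        )
        assert p1[:, 0].mean() - p0[:, 0].mean() == pytest.approx(0.08, abs=0.01)

    def test_extreme_continuous_z_stays_valid(self):
        p = ctmix.sample_mixture_proportions(
            np.array([-50.0, 50.0]), (0.57, 0.43), (0.08, -0.08), 100.0, seed=6
        )
        assert np.allclose(p.sum(axis=1), 1.0)
        assert ((p >= 0) & (p <= 1)).all()

    def test_invalid_precision(self):
        with pytest.raises(ConfigurationError):
            ctmix.sample_mixture_proportions(0.0, (0.5, 0.5), (0, 0), -1.0)


class TestMixProfiles:
    def test_pure_celltype(self):
        rng = np.random.default_rng(0)
        bp = rng.uniform(0.1, 0.9, size=(2, 5, 3))
        p = np.tile([1.0, 0.0], (3, 1))
        assert np.array_equal(ctmix.mix_profiles(bp, p), bp[0])

    def test_half_half_average(self):
        bp = np.full((2, 1, 1), 0.2)
        bp[1] = 0.6
        out = ctmix.mix_profiles(bp, np.array([[0.5, 0.5]]))
        assert out[0, 0] == pytest.approx(0.4)

    def test_limit_profiles_give_proportion(self):
        bp = np.zeros((2, 1, 1)) + 1e-12
        bp[1] = 1.0 - 1e-12
        out = ctmix.mix_profiles(bp, np.array([[0.57, 0.43]]))
        assert out[0, 0] == pytest.approx(0.43, abs=1e-9)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            ctmix.mix_profiles(np.zeros((2, 4, 3)), np.zeros((4, 2)))


class TestRunScenario:
    def test_non_dms_values_are_convex_combinations(self, sim1, base_small):
        truth = sim1.truth
        mask = np.ones(base_small.n_probes, dtype=bool)
        mask[truth.dms_indices] = False
        lo = np.minimum(base_small.beta[0], base_small.beta[1])[mask]
        hi = np.maximum(base_small.beta[0], base_small.beta[1])[mask]
        mixed = sim1.mixed_beta[mask]
        assert (mixed >= lo - 1e-12).all() and (mixed <= hi + 1e-12).all()

    def test_dms_count_matches_scenario(self, sim1, scenario1_small):
        assert len(sim1.truth.dms_indices) == scenario1_small.s

    def test_seeded_determinism(self, base_small, scenario1_small):
        a = ctmix.run_scenario(base_small, scenario1_small, seed=99)
        b = ctmix.run_scenario(base_small, scenario1_small, seed=99)
        assert np.array_equal(a.mixed_beta, b.mixed_beta)
        assert np.array_equal(a.truth.p_ik, b.truth.p_ik)
        assert np.array_equal(a.truth.dms_indices, b.truth.dms_indices)

    def test_pure_null_gif_near_one(self, null_sim):
        fit = ctmix.probewise_lm(null_sim.mixed_beta, null_sim.truth.z)
        res = ctmix.ebayes_moderate(fit)
        gif = ctmix.genomic_inflation(res.p)
        assert 0.8 < gif < 1.3

    def test_scenario7_preset_has_50_dms(self):
        sc = ctmix.load_scenario("scenario7")
        assert sc.s == 50 and sc.n_replications == 10
        base = ctmix.generate_base_profiles(
            ctmix.BaseProfileConfig(n_probes=500, seed=1)
        )
        sim = ctmix.run_scenario(base, sc, seed=0)
        assert len(sim.truth.dms_indices) == 50

    def test_scenario8_preset_blocks(self):
        sc = ctmix.load_scenario("scenario8")
        assert sc.s == 10_000
        assert tuple(b.size for b in sc.blocks) == (5000, 5000)
        assert tuple(b.background_correlation for b in sc.blocks) == (0.4, 0.5)

    def test_replications_redraw_dms(self, base_small):
        sc = ctmix.load_scenario("scenario7", seed=5)
        sims = list(ctmix.run_replications(base_small, sc))
        assert len(sims) == 10
        assert not np.array_equal(
            sims[0].truth.dms_indices, sims[1].truth.dms_indices
        )
        sigmas = {tuple(s.truth.sigma_jk[:2, 0]) for s in sims}
        assert len(sigmas) == 10  # sigma_jk re-realized per replication


class TestScenarioConfigValidation:
    def test_alpha0_must_sum_to_one(self):
        with pytest.raises(ConfigurationError, match="sum to 1"):
            ctmix.ScenarioConfig(
                name="x", s=1, mu_k=(0, 0), sigma_k=(0, 0), sigma_jk=0.1,
                rho=100, alpha0=(0.6, 0.6),
            )

    def test_delta_alpha_must_sum_to_zero(self):
        with pytest.raises(ConfigurationError):
            ctmix.ScenarioConfig(
                name="x", s=1, mu_k=(0, 0), sigma_k=(0, 0), sigma_jk=0.1,
                rho=100, delta_alpha=(0.08, 0.08),
            )

    def test_block_sizes_must_sum_to_s(self):
        with pytest.raises(ConfigurationError):
            ctmix.ScenarioConfig(
                name="x", s=10, mu_k=(0, 0), sigma_k=(0, 0), sigma_jk=0.1,
                rho=100,
                blocks=(ctmix.BlockSpec(4, 0.4, (0, 0), (1, 1)),),
            )
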