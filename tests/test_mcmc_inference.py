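import math

import numpy as np
import pytest
from scipy import stats

from linkdfe.likelihood import total_loglik
from linkdfe.mcmc_inference import (
    ChainConfig,
    ModelState,
    adapt_scales,
    bic,
    compare_models,
    init_state,
    kde_mode,
    metropolis_chain,
    mh_sweep,
    run_chain,
    summarize,
    summarize_param,
)


class TestInitState:
    def test_neutral_data_initialises_near_zero(self, small_loaded):
        # the fixture's data carry real effects, so build a neutral version:
        # read counts at half depth
        import copy
        from linkdfe.likelihood import ReadCountTable

        reads = [
            ReadCountTable(x=np.round(rt.d / 2), d=rt.d) for rt in small_loaded.reads
        ]
        cfg = ChainConfig(seed=1)
        state = init_state(small_loaded.blocks, reads, cfg)
        s_all = np.concatenate(state.s)
        assert np.all(np.abs(s_all) < 0.05)

    def test_variant_constraints_respected(self, small_loaded):
        for variant in ("shared", "shared_shape", "full"):
            cfg = ChainConfig(seed=1, variant=variant)
            state = init_state(small_loaded.blocks, small_loaded.reads, cfg)
            if variant in ("shared", "shared_shape"):
                assert state.dfe.shape_neg == state.dfe.shape_pos
            if variant == "shared":
                assert state.dfe.rate_neg == state.dfe.rate_pos
            assert state.dfe.variant == variant

    def test_deterministic_under_seed(self, small_loaded):
        cfg = ChainConfig(seed=7)
        a = init_state(small_loaded.blocks, small_loaded.reads, cfg)
        b = init_state(small_loaded.blocks, small_loaded.reads, cfg)
        assert all(np.array_equal(x, y) for x, y in zip(a.s, b.s))
        assert all(np.array_equal(x, y) for x, y in zip(a.dev, b.dev))
        assert a.dfe == b.dfe

    def test_initial_state_within_prior_support(self, small_loaded):
        cfg = ChainConfig(seed=2)
        state = init_state(small_loaded.blocks, small_loaded.reads, cfg)
        assert np.isfinite(
            total_loglik(state, small_loaded.blocks, small_loaded.reads,
                         cfg.t_generations)
        )


class TestAdaptScales:
    def test_persistent_acceptance_grows_scales(self):
        cfg = ChainConfig()
        scale = 0.1
        for _ in range(50):
            scale = adapt_scales(scale, True, cfg)
        assert scale > 0.1 * cfg.adapt_factor**10

    def test_persistent_rejection_shrinks_scales(self):
        cfg = ChainConfig()
        scale = 0.1
        for _ in range(50):
            scale = adapt_scales(scale, False, cfg)
        assert scale < 0.1 / cfg.adapt_factor**10

    def test_stationary_at_target_acceptance(self):
        # a sequence accepting exactly the target fraction of updates
        # leaves the scale unchanged on net
        cfg = ChainConfig(target_acceptance=0.25)
        scale = 0.1
        for i in range(1000):
            scale = adapt_scales(scale, i % 4 == 0, cfg)
        assert scale == pytest.approx(0.1, rel=1e-9)

    def test_clamped_to_bounds(self):
        cfg = ChainConfig()
        assert adapt_scales(1e9, True, cfg) == cfg.scale_max
        assert adapt_scales(1e-12, False, cfg) == cfg.scale_min


class TestMetropolisKernel:
    def test_standard_normal_target_moments(self):
        rng = np.random.default_rng(0)
        chain = metropolis_chain(
            lambda x: -0.5 * x * x, x0=0.0, scale=2.4, n_steps=40_000, rng=rng
        )
        chain = chain[2_000:]
        batches = chain[: len(chain) // 20 * 20].reshape(20, -1).mean(axis=1)
        se_mean = batches.std(ddof=1) / math.sqrt(20)
        assert abs(chain.mean()) < 3 * se_mean
        var_batches = chain[: len(chain) // 20 * 20].reshape(20, -1).var(axis=1)
        se_var = var_batches.std(ddof=1) / math.sqrt(20)
        assert abs(chain.var() - 1.0) < 3 * se_var + 0.02

    def test_three_state_discretised_target_stationary(self):
        # piecewise-constant density on [0, 3) with bin masses 0.2/0.5/0.3
        weights = np.array([0.2, 0.5, 0.3])

        def logpdf(x):
            if not 0.0 <= x < 3.0:
                return -np.inf
            return math.log(weights[int(x)])

        rng = np.random.default_rng(1)
        chain = metropolis_chain(logpdf, x0=1.5, scale=1.5, n_steps=100_000, rng=rng)
        thinned = chain[5_000::10]
        counts = np.bincount(thinned.astype(int), minlength=3)
        chi2, p = stats.chisquare(counts, weights * counts.sum())
        assert p > 0.01


class TestMhSweep:
    def test_tiny_proposal_scales_leave_state_nearly_fixed(self, small_loaded):
        cfg = ChainConfig(seed=3, block_pair_moves=False)
        state = init_state(small_loaded.blocks, small_loaded.reads, cfg)
        scales = {
            "s": np.full(20, 1e-12), "dev": np.full((20, 3), 1e-12),
            "sigma": 1e-12, "q": 1e-12, "shape": 1e-12, "rate": 1e-12,
        }
        new_state, acc = mh_sweep(
            state, small_loaded.blocks, small_loaded.reads, cfg, scales=scales,
            rng=np.random.default_rng(0),
        )
        s_old = np.concatenate(state.s)
        s_new = np.concatenate(new_state.s)
        # acceptance approaches 1 and the state is essentially unchanged
        assert np.mean(acc["s"]) > 0.95
        assert np.allclose(s_old, s_new, atol=1e-10)

    def test_sweep_keeps_prior_support(self, small_loaded):
        cfg = ChainConfig(seed=3)
        state = init_state(small_loaded.blocks, small_loaded.reads, cfg)
        rng = np.random.default_rng(9)
        for _ in range(20):
            state, _ = mh_sweep(state, small_loaded.blocks, small_loaded.reads,
                                cfg, rng=rng, adapt=True)
        s_all = np.concatenate(state.s)
        assert np.all(np.abs(s_all) < 1.0) and np.all(s_all != 0.0)
        assert 0 < state.dfe.q < 1
        assert state.sigma_delta > 0


class TestRunChain:
    def test_reproducible_and_bookkeeping(self, small_loaded):
        cfg = ChainConfig(burn_in=60, total=260, thin=4, seed=11)
        a = run_chain(small_loaded.blocks, small_loaded.reads, cfg)
        b = run_chain(small_loaded.blocks, small_loaded.reads, cfg)
        assert np.array_equal(a.samples["q"], b.samples["q"])
        assert np.array_equal(a.s_samples, b.s_samples)
        assert len(a.samples["q"]) == (260 - 60) // 4
        assert a.samples["loglik"].shape == a.samples["q"].shape

    def test_trace_matches_reference_loglik(self, small_loaded):
        # the engine's incremental bookkeeping must agree with the plain
        # reference evaluation of the composite likelihood
        cfg = ChainConfig(burn_in=30, total=60, thin=29, seed=5)
        res = run_chain(small_loaded.blocks, small_loaded.reads, cfg)
        state = res.final_state
        ref = total_loglik(state, small_loaded.blocks, small_loaded.reads,
                           cfg.t_generations)
        assert res.samples["loglik"][-1] == pytest.approx(ref, abs=1e-6)

    def test_posterior_matches_numerical_quadrature_on_one_mutation(self):
        # single mutation, one replicate, DFE term disabled, the replicate
        # deviation (in its standardised log scale) and sigma conditioned
        # at zero via frozen proposals: the posterior of s is then a clean
        # 1-D profile proportional to binomial(x; d, p(s)), available by
        # quadrature over s
        from linkdfe.dfe_model import TwoSidedGammaDFE
        from linkdfe.likelihood import ReadCountTable
        from linkdfe.selection_model import ChromosomeBlock

        block = ChromosomeBlock("L01", "chr1", ("m0",), np.array([]))
        x, d, t = 130.0, 200.0, 60.0
        sigma = 0.05
        reads = ReadCountTable(x=np.array([[x]]), d=np.array([[d]]))
        state = ModelState(
            s=[np.array([0.005])], dev=[np.array([[0.0]])],
            sigma_delta=sigma, dfe=TwoSidedGammaDFE.shared(0.5, 0.53, 0.022),
        )
        cfg = ChainConfig(burn_in=3_000, total=30_000, thin=30, seed=21,
                          include_dfe_term=False, t_generations=t)
        frozen = 1e-13
        scales = {"s": np.full(1, 0.01), "dev": np.full((1, 1), frozen),
                  "sigma": frozen, "q": 0.05, "shape": frozen, "rate": frozen}
        res = run_chain([block], [reads], cfg, state=state,
                        initial_scales=scales, adapt=False)
        s_samp = res.s_samples[:, 0]

        s_grid = np.linspace(-0.2, 0.2, 8001)
        p_grid = (1 + s_grid) ** t / ((1 + s_grid) ** t + 1)
        logpost = x * np.log(p_grid) + (d - x) * np.log1p(-p_grid)
        w = np.exp(logpost - logpost.max())
        cdf = np.cumsum(w) / w.sum()
        ecdf = np.arange(1, s_samp.size + 1) / s_samp.size
        cdf_at = np.interp(np.sort(s_samp), s_grid, cdf)
        ks = np.max(np.abs(ecdf - cdf_at))
        assert ks < 0.05

    def test_abort_on_invalid_initial_state(self, small_loaded):
        cfg = ChainConfig(burn_in=10, total=20, seed=0)
        state = init_state(small_loaded.blocks, small_loaded.reads, cfg)
        state.dev[0][0, 0] = 0.999  # pushes p + delta out of (0, 1)
        with pytest.raises(RuntimeError, match="non-finite|outside"):
            run_chain(small_loaded.blocks, small_loaded.reads, cfg, state=state)


class TestSummarize:
    def test_constant_samples(self):
        s = summarize_param(np.full(200, 3.14))
        assert (s.mode, s.lower95, s.upper95) == (3.14, 3.14, 3.14)

    def test_ranked_quantiles_order_statistics(self):
        s = summarize_param(np.arange(1.0, 1001.0))
        assert s.lower95 == pytest.approx(25.5, abs=1.0)
        assert s.upper95 == pytest.approx(975.5, abs=1.0)

    def test_skewed_samples_mode_below_mean(self):
        rng = np.random.default_rng(3)
        draws = rng.gamma(0.5, 1.0, size=5_000)
        assert kde_mode(draws) < draws.mean()

    def test_mode_within_interval(self):
        rng = np.random.default_rng(4)
        draws = rng.normal(0, 1, 1_000)
        s = summarize_param(draws)
        assert s.lower95 <= s.mode <= s.upper95


class TestModelComparison:
    def test_bic_formula(self):
        assert bic(2, 254, -100.0) == pytest.approx(2 * math.log(254) + 200, abs=1e-9)

    def test_penalty_monotone_in_k(self):
        assert bic(4, 254, -100.0) > bic(3, 254, -100.0) > bic(2, 254, -100.0)

    def test_variant_parameter_counts(self):
        table, preferred = compare_models(
            {"shared": -100.0, "shared_shape": -100.0, "full": -100.0}, n_obs=254
        )
        assert dict(zip(table["variant"], table["k"])) == {
            "shared": 2, "shared_shape": 3, "full": 4,
        }
        # equal likelihoods: the smallest model wins on BIC
        assert preferred == "shared"

    def test_strong_evidence_rule(self):
        table, preferred = compare_models(
            {"shared": -100.0, "full": -80.0}, n_obs=254
        )
        assert preferred == "full"
        delta = bic(2, 254, -100.0) - bic(4, 254, -80.0)
        assert bool(table.loc[table["variant"] == "full",
                              "strong_evidence"].iloc[0]) == (delta > 10)
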