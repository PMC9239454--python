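import math

import numpy as np
import pytest

from linkdfe.dfe_model import TwoSidedGammaDFE
from linkdfe.likelihood import (
    NoiseModel,
    ReadCountTable,
    ReplicateDeviations,
    block_expected_freqs,
    loglik_dfe_block,
    loglik_freq_block,
    loglik_sign_counts,
    total_loglik,
)
from linkdfe.mcmc_inference import ModelState
from linkdfe.selection_model import ChromosomeBlock

SHARED = TwoSidedGammaDFE.shared(q=0.5, shape=0.53, mean_abs=0.022)
EXP_DFE = TwoSidedGammaDFE(q=1.0, shape_neg=1.0, shape_pos=1.0,
                           rate_neg=10.0, rate_pos=10.0, variant="shared")


def _single_block():
    return ChromosomeBlock("L01", "chr1", ("m0",), np.array([]))


class TestFreqTerm:
    def test_lognormal_at_median(self):
        reads = ReadCountTable(x=np.array([[5.0]]), d=np.array([[10.0]]))
        ll = loglik_freq_block(
            np.array([0.5]), ReplicateDeviations(np.array([[0.0]])),
            NoiseModel(0.1), reads,
        )
        lognorm_part = math.log(1.0 / (0.5 * 0.1 * math.sqrt(2 * math.pi)))
        binom_part = math.log(252 / 1024)
        assert lognorm_part == pytest.approx(2.07679, abs=1e-5)
        assert binom_part == pytest.approx(-1.40204, abs=1e-5)
        assert ll == pytest.approx(lognorm_part + binom_part, abs=1e-9)

    def test_degenerate_binomial_probability_one(self):
        # as p + delta -> 1 with x = d the binomial part tends to log(1) = 0
        from linkdfe.likelihood import binomial_logpmf

        assert binomial_logpmf(10.0, 10.0, 1.0 - 1e-14) == pytest.approx(0.0, abs=1e-12)
        assert binomial_logpmf(10.0, 10.0, 1.0) == 0.0

    def test_support_violation_is_minus_infinity(self):
        reads = ReadCountTable(x=np.array([[5.0]]), d=np.array([[10.0]]))
        ll = loglik_freq_block(
            np.array([0.5]), ReplicateDeviations(np.array([[0.6]])),
            NoiseModel(0.1), reads,
        )
        assert ll == -np.inf

    def test_maximised_near_empirical_frequency(self):
        # profile over delta on a 1-mutation toy: at high depth and weak
        # lognormal penalty the freq term peaks where p + delta is close
        # to the empirical read frequency x/d
        reads = ReadCountTable(x=np.array([[1500.0]]), d=np.array([[2000.0]]))
        deltas = np.linspace(-0.4, 0.45, 1701)
        lls = [
            loglik_freq_block(np.array([0.5]),
                              ReplicateDeviations(np.array([[d_]])),
                              NoiseModel(0.3), reads)
            for d_ in deltas
        ]
        best = deltas[int(np.argmax(lls))]
        assert 0.5 + best == pytest.approx(0.75, abs=0.02)


class TestDfeTerm:
    def test_exponential_oracle(self):
        ll = loglik_dfe_block(np.array([0.2]), EXP_DFE)
        assert ll == pytest.approx(math.log(10 * math.exp(-2)), abs=1e-9)
        assert ll == pytest.approx(0.30259, abs=1e-5)

    def test_symmetric_dfe_sign_invariance(self):
        s = np.array([0.01, 0.05, -0.002])
        assert loglik_dfe_block(s, SHARED) == pytest.approx(
            loglik_dfe_block(-s, SHARED), abs=1e-12
        )

    def test_small_effect_singularity_integrable_but_divergent_pointwise(self):
        # shape < 1: the log density grows without bound as |s| -> 0
        small = loglik_dfe_block(np.array([1e-12]), SHARED)
        smaller = loglik_dfe_block(np.array([1e-15]), SHARED)
        assert smaller > small > loglik_dfe_block(np.array([0.01]), SHARED)

    def test_exact_zero_rejected(self):
        with pytest.raises(ValueError):
            loglik_dfe_block(np.array([0.0]), SHARED)


class TestSignTerm:
    def test_even_split(self):
        assert loglik_sign_counts(1, 1, 0.5) == pytest.approx(math.log(0.5), abs=1e-9)

    def test_certain_positive(self):
        assert loglik_sign_counts(5, 0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_mode_property(self):
        n = 254
        at_mode = loglik_sign_counts(127, 127, 0.5)
        for n1 in (0, 50, 126, 128, 200, 254):
            assert loglik_sign_counts(n1, n - n1, 0.5) <= at_mode + 1e-12


class TestTotalLoglik:
    def _state(self, s, dev, sigma=0.1, dfe=EXP_DFE):
        return ModelState(s=[np.asarray(s)], dev=[np.asarray(dev)],
                          sigma_delta=sigma, dfe=dfe)

    def test_composes_single_term_oracles(self):
        block = _single_block()
        reads = ReadCountTable(x=np.array([[5.0]]), d=np.array([[10.0]]))
        s = np.array([0.2])
        state = self._state(s, np.array([[0.0]]))
        # at s = 0.2 the expected frequency after t generations
        p = block_expected_freqs(block, s, 0.0)
        assert p[0] == pytest.approx(0.5)
        ll = total_loglik(state, [block], [reads], t_generations=0.0)
        expected = (
            loglik_freq_block(p, ReplicateDeviations(np.array([[0.0]])),
                              NoiseModel(0.1), reads)
            + loglik_dfe_block(s, EXP_DFE)
            + loglik_sign_counts(1, 0, 1.0)
        )
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_doubling_data_doubles_block_terms(self):
        block = _single_block()
        block2 = ChromosomeBlock("L02", "chr1", ("m1",), np.array([]))
        reads = ReadCountTable(x=np.array([[30.0]]), d=np.array([[100.0]]))
        s = np.array([0.05])
        one = ModelState(s=[s], dev=[np.array([[0.0]])], sigma_delta=0.1, dfe=EXP_DFE)
        two = ModelState(s=[s, s.copy()], dev=[np.array([[0.0]])] * 2,
                         sigma_delta=0.1, dfe=EXP_DFE)
        ll1 = total_loglik(one, [block], [reads], 60.0)
        ll2 = total_loglik(two, [block, block2], [reads, reads], 60.0)
        sign1 = loglik_sign_counts(1, 0, 1.0)
        sign2 = loglik_sign_counts(2, 0, 1.0)
        assert ll2 - sign2 == pytest.approx(2 * (ll1 - sign1), abs=1e-9)

    def test_block_order_invariance(self):
        rng = np.random.default_rng(5)
        blocks = [
            ChromosomeBlock("L01", "chr1", ("a", "b"), np.array([0.1])),
            ChromosomeBlock("L01", "chr2", ("c",), np.array([])),
        ]
        reads = [
            ReadCountTable(x=np.array([[40.0, 42], [60, 61]]),
                           d=np.array([[100.0, 100], [100, 100]])),
            ReadCountTable(x=np.array([[55.0, 50]]), d=np.array([[90.0, 95]])),
        ]
        s = [np.array([0.02, -0.01]), np.array([0.005])]
        dev = [rng.normal(0, 0.01, (2, 2)), rng.normal(0, 0.01, (1, 2))]
        fwd = ModelState(s=s, dev=dev, sigma_delta=0.08, dfe=SHARED)
        rev = ModelState(s=s[::-1], dev=dev[::-1], sigma_delta=0.08, dfe=SHARED)
        assert total_loglik(fwd, blocks, reads, 60.0) == pytest.approx(
            total_loglik(rev, blocks[::-1], reads[::-1], 60.0), abs=1e-10
        )

    def test_out_of_support_state_is_minus_infinity(self):
        block = _single_block()
        reads = ReadCountTable(x=np.array([[5.0]]), d=np.array([[10.0]]))
        state = self._state(np.array([0.2]), np.array([[0.9]]))
        assert total_loglik(state, [block], [reads], 0.0) == -np.inf

    def test_profile_recovers_generating_effect_at_high_depth(self):
        # simulate from the model at depth 1e5 and profile the total log
        # likelihood over a grid of s: the optimum sits at the truth
        s_true = 0.03
        t = 60.0
        block = _single_block()
        p_true = float(block_expected_freqs(block, np.array([s_true]), t)[0])
        rng = np.random.default_rng(42)
        d = 100_000
        x = rng.binomial(d, p_true)
        reads = ReadCountTable(x=np.array([[float(x)]]), d=np.array([[float(d)]]))
        grid = np.linspace(0.02, 0.04, 801)
        lls = []
        for s in grid:
            p = block_expected_freqs(block, np.array([s]), t)
            state = ModelState(s=[np.array([s])],
                               dev=[np.array([[float(x) / d - p[0]]])],
                               sigma_delta=0.05, dfe=EXP_DFE)
            lls.append(total_loglik(state, [block], [reads], t,
                                    include_dfe_term=False))
        best = grid[int(np.argmax(lls))]
        assert abs(best - s_true) < 0.002
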