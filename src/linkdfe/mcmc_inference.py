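"""Adaptive Metropolis-Hastings inference of the DFE and per-mutation effects.

The sampler performs one Metropolis-Hastings update per scalar parameter per
sweep, with symmetric normal proposals, in systematic order: every selection
coefficient s_j (block by block), every replicate deviation delta_jk (these
are conditionally independent given the rest and are updated as one
vectorised batch), the replicate noise sigma_delta, the free gamma
parameters of the DFE variant, and the positive-mass weight q.

During burn-in each parameter's proposal scale is multiplied by
``adapt_factor ** (accepted - target_acceptance)`` after its update, so the
stationary acceptance proportion is the target (0.234 by default).  Scales
freeze at the end of burn-in, preserving detailed balance in the sampling
phase.

Priors are uniform: s_j on (-1, 1), q on (0, 1), sigma_delta, shapes and
rates on (0, large bound); replicate deviations are constrained only by
|delta| < 1 and the support requirement 0 < p_j + delta_jk < 1.
Out-of-support proposals are rejected outright.

"Iterations" here are full sweeps over all scalar parameters.  The
equivalent single-parameter-update count is ``sweeps * n_parameters`` and
is reported in the run log.  Default chain lengths are sized so that a full
fit of a seven-cross dataset completes in minutes.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, log_ndtr

from .dfe_model import N_DFE_PARAMS, VARIANTS, TwoSidedGammaDFE
from .likelihood import ReadCountTable, block_expected_freqs, total_loglik
from .selection_model import ChromosomeBlock, carrier_matrix, meiosis_freqs

logger = logging.getLogger("linkdfe")

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class ChainConfig:
    """Configuration of one MCMC run.

    ``burn_in`` and ``total`` count full sweeps; ``thin`` is the sweep
    interval between retained samples of the post-burn-in phase.
    """

    burn_in: int = 2_000
    total: int = 10_000
    thin: int = 10
    seed: int = 0
    target_acceptance: float = 0.234
    adapt_factor: float = 1.2
    variant: str = "shared"
    t_generations: float = 60.0
    include_dfe_term: bool = True
    block_pair_moves: bool = True
    sigma_max: float = 10.0
    shape_max: float = 100.0
    rate_max: float = 1e4
    scale_min: float = 1e-8
    scale_max: float = 1e2

    def __post_init__(self) -> None:
        if not self.burn_in < self.total:
            raise ValueError("burn_in must be < total")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0.0 < self.target_acceptance < 1.0:
            raise ValueError("target_acceptance must be in (0, 1)")
        if self.adapt_factor <= 1.0:
            raise ValueError("adapt_factor must be > 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


@dataclass
class ModelState:
    """All sampled parameters: per-block effects and deviations, the
    replicate noise, and the DFE parameters."""

    s: list
    dev: list
    sigma_delta: float
    dfe: TwoSidedGammaDFE

    def copy(self) -> "ModelState":
        return ModelState(
            s=[np.array(x) for x in self.s],
            dev=[np.array(x) for x in self.dev],
            sigma_delta=self.sigma_delta,
            dfe=self.dfe,
        )


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------


def init_state(
    blocks: Sequence[ChromosomeBlock],
    reads: Sequence[ReadCountTable],
    config: ChainConfig,
    seed: int | None = None,
) -> ModelState:
    """Initial state from naive single-locus estimates.

    Each s_j starts at the value that would carry a frequency of 0.5 to the
    mutation's empirical mean frequency in t generations of independent
    single-locus selection, clipped to (-0.5, 0.5).  Deviations start at the
    gap between each replicate's (clipped) empirical frequency and the
    model's expectation, sigma_delta at 0.05, and the DFE parameters at
    moment estimates from the initial effects.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t = config.t_generations
    s_list: list[np.ndarray] = []
    dev_list: list[np.ndarray] = []
    clipped_any = False
    for block, rt in zip(blocks, reads):
        p_hat = np.mean(rt.x / rt.d, axis=1)
        if np.any((p_hat <= 0.01) | (p_hat >= 0.99)):
            clipped_any = True
        p_hat = np.clip(p_hat, 0.01, 0.99)
        s0 = (p_hat / (1.0 - p_hat)) ** (1.0 / t) - 1.0
        s0 = np.clip(s0, -0.5, 0.5)
        zero = s0 == 0.0
        if np.any(zero):
            s0[zero] = 1e-6 * np.where(rng.random(zero.sum()) < 0.5, -1.0, 1.0)
        s_list.append(s0)
        p_model = block_expected_freqs(block, s0, t)
        emp = np.clip(rt.x / rt.d, 1e-4, 1.0 - 1e-4)
        dev_list.append(emp - p_model[:, None])
    if clipped_any:
        logger.warning(
            "some empirical frequencies at or beyond 0.01/0.99 were clipped "
            "for initialisation"
        )

    all_s = np.concatenate(s_list)
    q0 = float(np.clip(np.mean(all_s > 0), 0.05, 0.95))

    def _moments(mags: np.ndarray) -> tuple[float, float]:
        mean = float(np.mean(mags)) if mags.size else 0.01
        mean = max(mean, 1e-3)
        var = float(np.var(mags)) if mags.size > 1 else 0.0
        shape = mean**2 / var if var > 0 else 1.0
        shape = float(np.clip(shape, 0.1, 5.0))
        return shape, shape / mean

    pos = np.abs(all_s[all_s > 0])
    neg = np.abs(all_s[all_s < 0])
    if config.variant == "shared":
        shape, rate = _moments(np.abs(all_s))
        dfe = TwoSidedGammaDFE(q0, shape, shape, rate, rate, "shared")
    elif config.variant == "shared_shape":
        shape, _ = _moments(np.abs(all_s))
        _, rate_n = _moments(neg)
        _, rate_p = _moments(pos)
        # rates rescaled so the side means match under the pooled shape
        mean_n = max(float(np.mean(neg)) if neg.size else 0.01, 1e-3)
        mean_p = max(float(np.mean(pos)) if pos.size else 0.01, 1e-3)
        dfe = TwoSidedGammaDFE(
            q0, shape, shape, shape / mean_n, shape / mean_p, "shared_shape"
        )
    else:
        shape_n, rate_n = _moments(neg)
        shape_p, rate_p = _moments(pos)
        dfe = TwoSidedGammaDFE(q0, shape_n, shape_p, rate_n, rate_p, "full")
    return ModelState(s=s_list, dev=dev_list, sigma_delta=0.05, dfe=dfe)


# ---------------------------------------------------------------------------
# Sampling engine
# ---------------------------------------------------------------------------

# Free DFE parameters per variant: (parameter name, target array, side indices)
_DFE_PARAM_SPECS = {
    "shared": [("shape", "shape", (0, 1)), ("rate", "rate", (0, 1))],
    "shared_shape": [
        ("shape", "shape", (0, 1)),
        ("rate_neg", "rate", (0,)),
        ("rate_pos", "rate", (1,)),
    ],
    "full": [
        ("shape_neg", "shape", (0,)),
        ("shape_pos", "shape", (1,)),
        ("rate_neg", "rate", (0,)),
        ("rate_pos", "rate", (1,)),
    ],
}


class _Engine:
    """Flat-array sampling engine with incremental likelihood bookkeeping."""

    def __init__(
        self,
        blocks: Sequence[ChromosomeBlock],
        reads: Sequence[ReadCountTable],
        config: ChainConfig,
        state: ModelState,
    ) -> None:
        if len(blocks) != len(reads):
            raise ValueError("blocks and reads must align")
        self.cfg = config
        self.t = config.t_generations
        self.blocks = list(blocks)
        n_rep = {rt.n_replicates for rt in reads}
        if len(n_rep) != 1:
            raise ValueError("all blocks must have the same replicate count")
        self.r = n_rep.pop()

        offsets = np.cumsum([0] + [b.m for b in blocks])
        self.M = int(offsets[-1])
        self.slices = [slice(int(a), int(b)) for a, b in zip(offsets[:-1], offsets[1:])]
        self.carriers = [carrier_matrix(b.m) for b in blocks]
        self.log_pi0 = []
        for b in blocks:
            with np.errstate(divide="ignore"):
                self.log_pi0.append(np.log(meiosis_freqs(b).freqs))

        self.x = np.concatenate([rt.x for rt in reads], axis=0)
        self.d = np.concatenate([rt.d for rt in reads], axis=0)
        self.dmx = self.d - self.x
        self.lgam = gammaln(self.d + 1) - gammaln(self.x + 1) - gammaln(self.dmx + 1)

        # state.  Replicate deviations are carried non-centrally as
        # z_jk = log((p_j + delta_jk) / p_j) / sigma, i.e. the standardised
        # log-scale deviation: the lognormal layer then contributes a
        # standard-normal term in z and the sigma updates do not drag the
        # whole deviation field with them (no funnel).  The sampled
        # posterior over (s, delta, sigma, ...) is unchanged.
        self.s = np.concatenate([np.asarray(v, float) for v in state.s])
        self.sigma = float(state.sigma_delta)
        dev = np.concatenate([np.asarray(v, float) for v in state.dev], axis=0)
        self.q = float(state.dfe.q)
        self.shape = np.array([state.dfe.shape_neg, state.dfe.shape_pos])
        self.rate = np.array([state.dfe.rate_neg, state.dfe.rate_pos])

        # caches: per-block t*log-fitness vectors support rank-1 updates when
        # a single effect changes (no matmul per proposal)
        self.u = np.log1p(self.s)
        self.tlogw = [
            self.t * (self.carriers[b] @ self.u[sl])
            for b, sl in enumerate(self.slices)
        ]
        self.p = np.empty(self.M)
        for b_idx, sl in enumerate(self.slices):
            self.p[sl] = self._p_from_tlogw(b_idx, self.tlogw[b_idx])
        v0 = self.p[:, None] + dev
        if np.any(v0 <= 0.0) or np.any(v0 >= 1.0):
            raise RuntimeError(
                "initial state has replicate frequencies outside (0, 1); "
                "log likelihood is non-finite at initialisation"
            )
        self.z = np.log(v0 / self.p[:, None]) / self.sigma
        T = self._freq_terms(slice(0, self.M), self.p)
        if T is None:
            raise RuntimeError(
                "initial state has replicate frequencies outside (0, 1); "
                "log likelihood is non-finite at initialisation"
            )
        self.T = T
        self.dfe_terms = self._dfe_term_vector(self.s, self.shape, self.rate)
        self.dfe_sum = float(self.dfe_terms.sum())
        self.n1 = int(np.sum(self.s > 0))
        self._lchoose = (
            gammaln(self.M + 1)
            - gammaln(np.arange(self.M + 1) + 1)
            - gammaln(self.M - np.arange(self.M + 1) + 1)
        )
        self.sign_ll = self._sign_loglik(self.n1, self.q)

        # proposal scales and acceptance bookkeeping
        self.scales: dict = {
            "s": np.full(self.M, 0.02),
            "dev": np.full((self.M, self.r), 0.5),
            "sigma": 0.05,
            "q": 0.05,
        }
        self.dfe_param_specs = _DFE_PARAM_SPECS[config.variant]
        for name, kind, _ in self.dfe_param_specs:
            self.scales[name] = 0.05 if kind == "shape" else 2.0
        # within-block pair-move scales (exchange along the linkage ridge)
        self.scales["pair"] = np.full(len(self.blocks), 0.01)
        self.reset_counters()

    # -- bookkeeping helpers -------------------------------------------------

    def reset_counters(self) -> None:
        self.n_prop = {k: np.zeros_like(np.asarray(v, float)) for k, v in self.scales.items()}
        self.n_acc = {k: np.zeros_like(np.asarray(v, float)) for k, v in self.scales.items()}

    def acceptance_rates(self) -> dict:
        out = {}
        for k in self.scales:
            prop = self.n_prop[k]
            with np.errstate(invalid="ignore", divide="ignore"):
                out[k] = np.where(prop > 0, self.n_acc[k] / np.maximum(prop, 1), np.nan)
            if np.ndim(out[k]) == 0:
                out[k] = float(out[k])
        return out

    def mean_acceptance(self) -> float:
        """Average realised acceptance over all scalar parameters (the
        block pair/swap moves are supplementary and excluded)."""
        acc = 0.0
        prop = 0.0
        for k in self.scales:
            if k == "pair":
                continue
            acc += float(np.sum(self.n_acc[k]))
            prop += float(np.sum(self.n_prop[k]))
        return acc / prop if prop > 0 else math.nan

    @property
    def n_parameters(self) -> int:
        return self.M + self.M * self.r + 2 + len(self.dfe_param_specs)

    def current_dev(self) -> np.ndarray:
        """Additive replicate deviations delta_jk implied by the z state."""
        p = self.p[:, None]
        return p * np.expm1(self.sigma * self.z)

    def total_loglik(self) -> float:
        """Composite log likelihood of the current state (reported form:
        lognormal density of the replicate frequencies, not the z-space
        sampling target)."""
        p = self.p[:, None]
        v = p * np.exp(self.sigma * self.z)
        logv = np.log(v)
        zstd = (logv - np.log(p)) / self.sigma
        ln_part = (
            -logv - math.log(self.sigma) - 0.5 * LOG_2PI - 0.5 * zstd**2
            - log_ndtr(-np.log(p) / self.sigma)
        )
        bin_part = self.lgam + self.x * logv + self.dmx * np.log1p(-v)
        dfe_part = self.dfe_sum if self.cfg.include_dfe_term else 0.0
        return float(ln_part.sum() + bin_part.sum() + dfe_part + self.sign_ll)

    def to_state(self) -> ModelState:
        dfe = TwoSidedGammaDFE(
            q=self.q,
            shape_neg=float(self.shape[0]),
            shape_pos=float(self.shape[1]),
            rate_neg=float(self.rate[0]),
            rate_pos=float(self.rate[1]),
            variant=self.cfg.variant,
        )
        dev = self.current_dev()
        return ModelState(
            s=[np.array(self.s[sl]) for sl in self.slices],
            dev=[np.array(dev[sl]) for sl in self.slices],
            sigma_delta=self.sigma,
            dfe=dfe,
        )

    # -- likelihood pieces ---------------------------------------------------

    def _p_from_tlogw(self, b_idx: int, tlogw: np.ndarray) -> np.ndarray:
        z = self.log_pi0[b_idx] + tlogw
        z = np.exp(z - z.max())
        return self.carriers[b_idx].T @ (z / z.sum())

    def _freq_terms(self, sl: slice, p_slice: np.ndarray, sigma: float | None = None):
        """z-space frequency terms for a slice: truncated standard-normal
        penalty on z (normalised by the mass below the v < 1 boundary) plus
        the binomial read likelihood at v = p * exp(sigma z).  Returns None
        if any replicate frequency leaves (0, 1)."""
        sigma = self.sigma if sigma is None else sigma
        z = self.z[sl]
        logp = np.log(p_slice)[:, None]
        logv = logp + sigma * z
        if logv.max() >= 0.0:
            return None
        v = np.exp(logv)
        return (
            -0.5 * z * z
            - log_ndtr(-logp / sigma)
            + self.lgam[sl] + self.x[sl] * logv + self.dmx[sl] * np.log1p(-v)
        )

    def _freq_terms_new_p(self, sl: slice, p_slice: np.ndarray):
        """Frequency terms for a proposed p with z and sigma unchanged
        (uses the per-sweep caches of sigma*z and -z^2/2)."""
        logp = np.log(p_slice)[:, None]
        logv = logp + self._sz[sl]
        if logv.max() >= 0.0:
            return None
        v = np.exp(logv)
        return (
            self._zz[sl]
            - log_ndtr(-logp / self.sigma)
            + self.lgam[sl] + self.x[sl] * logv + self.dmx[sl] * np.log1p(-v)
        )

    def _dfe_term_vector(
        self, s: np.ndarray, shape: np.ndarray, rate: np.ndarray
    ) -> np.ndarray:
        pos = (s > 0).astype(int)
        sh = shape[pos]
        rt = rate[pos]
        a = np.abs(s)
        return (sh - 1.0) * np.log(a) - rt * a + sh * np.log(rt) - gammaln(sh)

    def _dfe_term_scalar(self, s: float) -> float:
        side = 1 if s > 0 else 0
        sh = float(self.shape[side])
        rt = float(self.rate[side])
        a = abs(s)
        return (sh - 1.0) * math.log(a) - rt * a + sh * math.log(rt) - math.lgamma(sh)

    def _sign_loglik(self, n1: int, q: float) -> float:
        return float(
            self._lchoose[n1] + n1 * math.log(q) + (self.M - n1) * math.log1p(-q)
        )

    def _adapt(self, key: str, accepted, idx=None) -> None:
        cfg = self.cfg
        if np.ndim(accepted) == 0 and (idx is None or np.ndim(idx) == 0):
            # scalar fast path (hot: one call per single-parameter update)
            f = cfg.adapt_factor ** (
                (1.0 if accepted else 0.0) - cfg.target_acceptance
            )
            if idx is None:
                self.scales[key] = min(
                    max(self.scales[key] * f, cfg.scale_min), cfg.scale_max
                )
            else:
                arr = self.scales[key]
                arr[idx] = min(max(arr[idx] * f, cfg.scale_min), cfg.scale_max)
            return
        factor = cfg.adapt_factor ** (np.asarray(accepted, float) - cfg.target_acceptance)
        self.scales[key][idx] = np.clip(
            self.scales[key][idx] * factor, cfg.scale_min, cfg.scale_max
        )

    # -- parameter family updates -------------------------------------------

    def _update_s(self, rng: np.random.Generator, adapt: bool) -> None:
        norm = rng.standard_normal(self.M)
        logu = np.log(rng.random(self.M))
        scales = self.scales["s"]
        include_dfe = self.cfg.include_dfe_term
        for b_idx, sl in enumerate(self.slices):
            for jl in range(sl.stop - sl.start):
                g = sl.start + jl
                self.n_prop["s"][g] += 1
                old = self.s[g]
                new = old + scales[g] * norm[g]
                accepted = False
                if -1.0 < new < 1.0 and new != 0.0:
                    u_new = math.log1p(new)
                    tlogw_try = self.tlogw[b_idx] + (
                        self.t * (u_new - self.u[g])
                    ) * self.carriers[b_idx][:, jl]
                    p_new = self._p_from_tlogw(b_idx, tlogw_try)
                    T_new = self._freq_terms_new_p(sl, p_new)
                    if T_new is not None:
                        delta = float(T_new.sum() - self.T[sl].sum())
                        new_dfe_term = 0.0
                        if include_dfe:
                            new_dfe_term = self._dfe_term_scalar(new)
                            delta += new_dfe_term - self.dfe_terms[g]
                        flip = (new > 0) != (old > 0)
                        if flip:
                            n1_new = self.n1 + (1 if new > 0 else -1)
                            sign_new = self._sign_loglik(n1_new, self.q)
                            delta += sign_new - self.sign_ll
                        if logu[g] < delta:
                            accepted = True
                            self.s[g] = new
                            self.u[g] = u_new
                            self.tlogw[b_idx] = tlogw_try
                            self.p[sl] = p_new
                            self.T[sl] = T_new
                            if include_dfe:
                                self.dfe_sum += new_dfe_term - self.dfe_terms[g]
                                self.dfe_terms[g] = new_dfe_term
                            if flip:
                                self.n1 = n1_new
                                self.sign_ll = sign_new
                if accepted:
                    self.n_acc["s"][g] += 1
                if adapt:
                    self._adapt("s", accepted, idx=g)

    def _try_block_pair(self, b_idx: int, jl_i: int, jl_j: int,
                        si: float, sj: float, logu: float) -> bool:
        """Attempt replacing two effects of one block; returns acceptance."""
        sl = self.slices[b_idx]
        gi, gj = sl.start + jl_i, sl.start + jl_j
        old_i, old_j = self.s[gi], self.s[gj]
        if not (-1.0 < si < 1.0 and -1.0 < sj < 1.0) or si == 0.0 or sj == 0.0:
            return False
        ui_new, uj_new = math.log1p(si), math.log1p(sj)
        c = self.carriers[b_idx]
        tlogw_try = (
            self.tlogw[b_idx]
            + (self.t * (ui_new - self.u[gi])) * c[:, jl_i]
            + (self.t * (uj_new - self.u[gj])) * c[:, jl_j]
        )
        p_new = self._p_from_tlogw(b_idx, tlogw_try)
        T_new = self._freq_terms_new_p(sl, p_new)
        if T_new is None:
            return False
        delta = float(T_new.sum() - self.T[sl].sum())
        term_i = term_j = 0.0
        if self.cfg.include_dfe_term:
            term_i = self._dfe_term_scalar(si)
            term_j = self._dfe_term_scalar(sj)
            delta += term_i + term_j - self.dfe_terms[gi] - self.dfe_terms[gj]
        dn1 = int(si > 0) + int(sj > 0) - int(old_i > 0) - int(old_j > 0)
        sign_new = self.sign_ll
        if dn1 != 0:
            sign_new = self._sign_loglik(self.n1 + dn1, self.q)
            delta += sign_new - self.sign_ll
        if logu >= delta:
            return False
        self.s[gi], self.s[gj] = si, sj
        self.u[gi], self.u[gj] = ui_new, uj_new
        self.tlogw[b_idx] = tlogw_try
        self.p[sl] = p_new
        self.T[sl] = T_new
        if self.cfg.include_dfe_term:
            self.dfe_sum += term_i + term_j - self.dfe_terms[gi] - self.dfe_terms[gj]
            self.dfe_terms[gi] = term_i
            self.dfe_terms[gj] = term_j
        if dn1 != 0:
            self.n1 += dn1
            self.sign_ll = sign_new
        return True

    def _update_block_pairs(self, rng: np.random.Generator, adapt: bool) -> None:
        """Supplementary within-block moves for linked mutations.

        Tightly linked mutations leave only their combined effect well
        identified; single-coordinate updates crawl along that ridge.  Two
        symmetric moves fix the mixing: an exchange that shifts log(1+s) of
        a random adjacent pair by +/-eps (sum-preserving; the s-space
        Jacobian of the paired translation is exactly 1) and a swap of two
        effects within the block (an involution).  Both target the same
        posterior.
        """
        for b_idx, sl in enumerate(self.slices):
            m = sl.stop - sl.start
            if m < 2:
                continue
            # exchange move on a random adjacent pair
            jl = int(rng.integers(0, m - 1))
            eps = float(self.scales["pair"][b_idx] * rng.standard_normal())
            gi, gj = sl.start + jl, sl.start + jl + 1
            si = math.expm1(math.log1p(self.s[gi]) + eps)
            sj = math.expm1(math.log1p(self.s[gj]) - eps)
            self.n_prop["pair"][b_idx] += 1
            accepted = self._try_block_pair(
                b_idx, jl, jl + 1, si, sj, math.log(rng.random())
            )
            if accepted:
                self.n_acc["pair"][b_idx] += 1
            if adapt:
                self._adapt("pair", accepted, idx=b_idx)
            # swap move on a random pair (likelihood term changes only)
            ja, jb = rng.choice(m, size=2, replace=False)
            self._try_block_pair(
                b_idx, int(ja), int(jb),
                self.s[sl.start + jb], self.s[sl.start + ja],
                math.log(rng.random()),
            )

    def _update_dev(self, rng: np.random.Generator, adapt: bool) -> None:
        # the z_jk are conditionally independent given everything else, so
        # one vectorised elementwise Metropolis step is exact
        shape = self.z.shape
        prop = self.z + self.scales["dev"] * rng.standard_normal(shape)
        logv = np.log(self.p)[:, None] + self.sigma * prop
        ok = logv < 0.0
        logv_safe = np.where(ok, logv, -1.0)
        v = np.exp(logv_safe)
        T_new = (
            -0.5 * prop * prop
            + self.lgam + self.x * logv_safe + self.dmx * np.log1p(-v)
        )
        logu = np.log(rng.random(shape))
        accept = ok & (logu < T_new - self.T)
        self.z = np.where(accept, prop, self.z)
        self.T = np.where(accept, T_new, self.T)
        self.n_prop["dev"] += 1
        self.n_acc["dev"] += accept
        if adapt:
            self._adapt("dev", accept, idx=slice(None))

    def _update_sigma(self, rng: np.random.Generator, adapt: bool) -> None:
        self.n_prop["sigma"] += 1
        new = self.sigma + self.scales["sigma"] * rng.standard_normal()
        accepted = False
        if 0.0 < new <= self.cfg.sigma_max:
            T_new = self._freq_terms(slice(0, self.M), self.p, sigma=new)
            if T_new is not None:
                if math.log(rng.random()) < float(T_new.sum() - self.T.sum()):
                    accepted = True
                    self.sigma = new
                    self.T = T_new
        if accepted:
            self.n_acc["sigma"] += 1
        if adapt:
            self._adapt("sigma", accepted)

    def _update_dfe_params(self, rng: np.random.Generator, adapt: bool) -> None:
        if not self.cfg.include_dfe_term:
            return
        for name, kind, sides in self.dfe_param_specs:
            self.n_prop[name] += 1
            arr = self.shape if kind == "shape" else self.rate
            bound = self.cfg.shape_max if kind == "shape" else self.cfg.rate_max
            old = float(arr[sides[0]])
            new = old + self.scales[name] * rng.standard_normal()
            accepted = False
            if 0.0 < new <= bound:
                shape_try = self.shape.copy()
                rate_try = self.rate.copy()
                target = shape_try if kind == "shape" else rate_try
                for side in sides:
                    target[side] = new
                terms_new = self._dfe_term_vector(self.s, shape_try, rate_try)
                delta = float(terms_new.sum()) - self.dfe_sum
                if math.log(rng.random()) < delta:
                    accepted = True
                    self.shape = shape_try
                    self.rate = rate_try
                    self.dfe_terms = terms_new
                    self.dfe_sum = float(terms_new.sum())
            if accepted:
                self.n_acc[name] += 1
            if adapt:
                self._adapt(name, accepted)

    def _update_q(self, rng: np.random.Generator, adapt: bool) -> None:
        self.n_prop["q"] += 1
        new = self.q + self.scales["q"] * rng.standard_normal()
        accepted = False
        if 0.0 < new < 1.0:
            sign_new = self._sign_loglik(self.n1, new)
            if math.log(rng.random()) < sign_new - self.sign_ll:
                accepted = True
                self.q = new
                self.sign_ll = sign_new
        if accepted:
            self.n_acc["q"] += 1
        if adapt:
            self._adapt("q", accepted)

    def sweep(self, rng: np.random.Generator, adapt: bool) -> None:
        # z and sigma are fixed during the s-layer updates: cache their
        # contributions to the frequency terms for the proposal evaluations
        self._sz = self.sigma * self.z
        self._zz = -0.5 * self.z * self.z
        self._update_s(rng, adapt)
        if self.cfg.block_pair_moves:
            self._update_block_pairs(rng, adapt)
        self._update_dev(rng, adapt)
        self._update_sigma(rng, adapt)
        self._update_dfe_params(rng, adapt)
        self._update_q(rng, adapt)


def mh_sweep(
    state: ModelState,
    blocks: Sequence[ChromosomeBlock],
    reads: Sequence[ReadCountTable],
    config: ChainConfig,
    scales: dict | None = None,
    rng: np.random.Generator | None = None,
    adapt: bool = False,
) -> tuple[ModelState, dict]:
    """One full Metropolis-Hastings sweep over all scalar parameters.

    Returns the updated state and the per-parameter acceptance flags (as
    rates over this single sweep).  For long runs use :func:`run_chain`,
    which keeps the engine's caches alive between sweeps.
    """
    rng = rng or np.random.default_rng(config.seed)
    engine = _Engine(blocks, reads, config, state)
    if scales is not None:
        for k, v in scales.items():
            engine.scales[k] = v
    engine.sweep(rng, adapt)
    return engine.to_state(), engine.acceptance_rates()


def adapt_scales(
    scales: np.ndarray | float,
    accepted: np.ndarray | bool,
    config: ChainConfig,
) -> np.ndarray | float:
    """Burn-in proposal-scale update rule.

    Multiplies each scale by ``adapt_factor ** (accepted - target)`` so that
    the stationary acceptance proportion equals the target: at equilibrium,
    up-moves of ``factor^(1-target)`` after acceptances balance down-moves
    of ``factor^(-target)`` after rejections exactly when the acceptance
    rate is the target.
    """
    factor = config.adapt_factor ** (
        np.asarray(accepted, dtype=float) - config.target_acceptance
    )
    out = np.clip(np.asarray(scales) * factor, config.scale_min, config.scale_max)
    return float(out) if np.ndim(scales) == 0 else out


def metropolis_chain(
    logpdf,
    x0: float,
    scale: float,
    n_steps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Scalar random-walk Metropolis kernel with symmetric normal proposals.

    The same accept rule the main sampler applies per parameter, exposed on
    an arbitrary 1-D log density for kernel validation and quick posterior
    explorations.  Returns the chain including the start value.
    """
    x = float(x0)
    lp = logpdf(x)
    out = np.empty(n_steps + 1)
    out[0] = x
    for i in range(1, n_steps + 1):
        prop = x + scale * rng.standard_normal()
        lp_prop = logpdf(prop)
        if math.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
        out[i] = x
    return out


@dataclass
class ChainResult:
    """Thinned posterior samples and run metadata."""

    samples: dict
    s_samples: np.ndarray
    dev_samples: np.ndarray
    acceptance: dict
    mean_acceptance: float
    final_state: ModelState
    config: ChainConfig
    n_parameters: int
    scales: dict = field(default_factory=dict)


def run_chain(
    blocks: Sequence[ChromosomeBlock],
    reads: Sequence[ReadCountTable],
    config: ChainConfig,
    state: ModelState | None = None,
    initial_scales: dict | None = None,
    adapt: bool = True,
) -> ChainResult:
    """Run the adaptive MH chain and return thinned samples.

    Fully reproducible under ``config.seed``.  Proposal scales adapt during
    burn-in and are frozen afterwards; acceptance rates are reported for
    the sampling phase only.  Pass ``initial_scales`` (and ``adapt=False``
    to pin them) to resume a tuned chain or to condition on parameters by
    freezing their proposals.
    """
    t_start = time.perf_counter()
    rng = np.random.default_rng(config.seed)
    if state is None:
        state = init_state(blocks, reads, config, seed=config.seed)
    engine = _Engine(blocks, reads, config, state)
    if initial_scales is not None:
        for key, value in initial_scales.items():
            engine.scales[key] = value
    if not np.isfinite(engine.total_loglik()):
        raise RuntimeError(
            "non-finite log likelihood at initialisation; check read counts "
            "and the initial state"
        )
    n_samples = (config.total - config.burn_in) // config.thin + (
        1 if (config.total - config.burn_in) % config.thin else 0
    )
    keys = [
        "q",
        "sigma_delta",
        "shape_neg",
        "shape_pos",
        "rate_neg",
        "rate_pos",
        "mean_neg",
        "mean_pos",
        "loglik",
    ]
    samples = {k: np.empty(n_samples) for k in keys}
    s_samples = np.empty((n_samples, engine.M))
    dev_samples = np.empty((n_samples, engine.M, engine.r))
    idx = 0
    for i in range(config.total):
        adapt_now = adapt and i < config.burn_in
        engine.sweep(rng, adapt_now)
        if i == config.burn_in - 1:
            engine.reset_counters()
        if i >= config.burn_in and (i - config.burn_in) % config.thin == 0:
            samples["q"][idx] = engine.q
            samples["sigma_delta"][idx] = engine.sigma
            samples["shape_neg"][idx] = engine.shape[0]
            samples["shape_pos"][idx] = engine.shape[1]
            samples["rate_neg"][idx] = engine.rate[0]
            samples["rate_pos"][idx] = engine.rate[1]
            samples["mean_neg"][idx] = engine.shape[0] / engine.rate[0]
            samples["mean_pos"][idx] = engine.shape[1] / engine.rate[1]
            samples["loglik"][idx] = engine.total_loglik()
            s_samples[idx] = engine.s
            dev_samples[idx] = engine.current_dev()
            idx += 1
    logger.info(
        "chain finished: seed %d, %d sweeps (%d parameter updates), "
        "%d samples, mean acceptance %.3f, %.1f s",
        config.seed,
        config.total,
        config.total * engine.n_parameters,
        idx,
        engine.mean_acceptance(),
        time.perf_counter() - t_start,
    )
    return ChainResult(
        samples={k: v[:idx] for k, v in samples.items()},
        s_samples=s_samples[:idx],
        dev_samples=dev_samples[:idx],
        acceptance=engine.acceptance_rates(),
        mean_acceptance=engine.mean_acceptance(),
        final_state=engine.to_state(),
        config=config,
        n_parameters=engine.n_parameters,
        scales=engine.scales,
    )


# ---------------------------------------------------------------------------
# Posterior summaries and model comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamSummary:
    mode: float
    lower95: float
    upper95: float


@dataclass(frozen=True)
class PosteriorSummary:
    params: dict
    modal_loglik: float | None = None
    acceptance: dict | None = None


def kde_mode(x: np.ndarray, n_grid: int = 512) -> float:
    """Posterior mode via Gaussian KDE (Silverman bandwidth) on a grid.

    The grid spans the sample range padded by one bandwidth; ties in the
    density argmax resolve to the lowest grid value.
    """
    x = np.asarray(x, dtype=float)
    if x.std(ddof=0) == 0.0:
        return float(x[0])
    kde = stats.gaussian_kde(x, bw_method="silverman")
    bw = float(kde.factor * x.std(ddof=1))
    grid = np.linspace(x.min() - bw, x.max() + bw, n_grid)
    dens = kde(grid)
    return float(grid[int(np.argmax(dens))])


def summarize_param(x: np.ndarray) -> ParamSummary:
    """Mode (KDE) and equal-tail 95% credible interval (ranked quantiles)."""
    x = np.asarray(x, dtype=float)
    if x.size < 100:
        raise ValueError("at least 100 samples are required to summarise")
    lo, hi = np.quantile(x, [0.025, 0.975], method="midpoint")
    mode = kde_mode(x)
    if not lo <= mode <= hi:
        logger.warning(
            "KDE mode %.6g outside credible interval [%.6g, %.6g]; clipping",
            mode, lo, hi,
        )
        mode = float(np.clip(mode, lo, hi))
    return ParamSummary(mode=float(mode), lower95=float(lo), upper95=float(hi))


def summarize(
    samples: Mapping[str, np.ndarray],
    acceptance: dict | None = None,
) -> PosteriorSummary:
    """Summarise every sampled parameter; 'loglik' yields the modal value."""
    params = {
        k: summarize_param(v) for k, v in samples.items() if k != "loglik"
    }
    modal_ll = float(np.max(samples["loglik"])) if "loglik" in samples else None
    return PosteriorSummary(params=params, modal_loglik=modal_ll, acceptance=acceptance)


#: BIC difference below which evidence for the lower-BIC model is "strong".
STRONG_EVIDENCE_DELTA_BIC = -10.0


def bic(k: int, n_obs: int, loglik: float) -> float:
    """Bayesian Information Criterion with natural logarithms."""
    return k * math.log(n_obs) - 2.0 * loglik


def compare_models(
    fits: Mapping[str, float],
    n_obs: int,
    k_dfe: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, str]:
    """BIC table over DFE variants and the preferred (lowest-BIC) variant.

    ``fits`` maps variant name to modal log likelihood.  ``k_dfe`` defaults
    to the number of free gamma parameters per variant (2, 3, 4).  The
    ``strong_evidence`` column records whether the preferred model beats
    each alternative by more than 10 BIC units.
    """
    k_dfe = dict(k_dfe) if k_dfe is not None else {v: N_DFE_PARAMS[v] for v in fits}
    rows = []
    for variant, ll in fits.items():
        rows.append(
            {"variant": variant, "k": k_dfe[variant], "loglik": ll,
             "BIC": bic(k_dfe[variant], n_obs, ll)}
        )
    table = pd.DataFrame(rows)
    best_idx = int(table["BIC"].idxmin())
    preferred = str(table.loc[best_idx, "variant"])
    table["delta_BIC"] = table["BIC"] - table["BIC"].min()
    # strong evidence for the preferred model iff it beats every other
    # variant by more than 10 BIC units
    others = table.drop(index=best_idx)["delta_BIC"]
    strong = bool((others > -STRONG_EVIDENCE_DELTA_BIC).all()) if len(table) > 1 else False
    table["strong_evidence"] = False
    table.loc[best_idx, "strong_evidence"] = strong
    return table, preferred
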