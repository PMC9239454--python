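"""Composite log likelihood of observed read counts given the model.

The log likelihood is the sum of three terms:

1. A frequency term per chromosome block (summed over mutations j and
   time-t replicates k): the replicate frequency ``p_j + delta_jk`` is
   modelled as a lognormal deviate with median ``p_j`` and log-scale
   standard deviation ``sigma_delta``, truncated to (0, 1) and renormalised
   (a frequency cannot exceed 1; for expected frequencies near 1 the
   truncated mass is substantial, and dropping the normalisation would
   spuriously penalise strong positive effects), and the mutant read count
   ``x_jk`` as binomial(``d_jk``, ``p_j + delta_jk``).
2. A DFE term: each selection coefficient's magnitude is gamma-distributed
   with the side-specific shape and rate.  The positive-mass weight ``q``
   is deliberately NOT part of this term.
3. A sign-count term: the total number of positive-effect mutations is
   binomial(n_pos + n_neg, q).  This is where ``q`` enters.

Only time-t replicates enter the likelihood; the model's initial condition
is frequency 0.5 at the cross, and inferred effects absorb the whole
frequency change over the assumed t generations.  Replicate frequencies
must lie strictly inside (0, 1); states violating that have log likelihood
-inf and are rejected by the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, log_ndtr

from .dfe_model import TwoSidedGammaDFE
from .selection_model import (
    ChromosomeBlock,
    carrier_matrix,
    evolve_closed,
    meiosis_freqs,
)

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ReadCountTable:
    """Mutant-supporting read counts and depths for one block's mutations.

    ``x`` and ``d`` are (m, r) arrays over mutations (block order) and
    time-t replicates.
    """

    x: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "d", d)
        if x.shape != d.shape or x.ndim != 2:
            raise ValueError("x and d must be 2-D arrays of identical shape")
        if np.any(d < 1):
            raise ValueError("all depths must be >= 1")
        if np.any(x < 0) or np.any(x > d):
            raise ValueError("mutant read counts must satisfy 0 <= x <= d")

    @property
    def n_replicates(self) -> int:
        return self.x.shape[1]


@dataclass(frozen=True)
class ReplicateDeviations:
    """Additive deviations delta_jk of replicate frequencies from p_j."""

    delta: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta", np.asarray(self.delta, dtype=float))


@dataclass(frozen=True)
class NoiseModel:
    """Log-scale standard deviation of the between-replicate lognormal."""

    sigma_delta: float

    def __post_init__(self) -> None:
        if self.sigma_delta <= 0:
            raise ValueError("sigma_delta must be > 0")


def lognormal_logpdf(
    v: np.ndarray | float, median: np.ndarray | float, sigma: float
) -> np.ndarray | float:
    """Log density of a lognormal with given median and log-scale sd."""
    v = np.asarray(v, dtype=float)
    z = (np.log(v) - np.log(median)) / sigma
    return -np.log(v) - np.log(sigma) - 0.5 * LOG_2PI - 0.5 * z * z


def binomial_logpmf(
    x: np.ndarray | float, d: np.ndarray | float, prob: np.ndarray | float
) -> np.ndarray | float:
    """Exact binomial log PMF via log-gamma, stable at prob near 0 or 1."""
    x = np.asarray(x, dtype=float)
    d = np.asarray(d, dtype=float)
    prob = np.asarray(prob, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = x * np.log(prob) + (d - x) * np.log1p(-prob)
    # 0*log(0) -> 0 by convention
    term = np.where((x == 0) & (prob == 0), 0.0, term)
    term = np.where((x == d) & (prob == 1), 0.0, term)
    return gammaln(d + 1) - gammaln(x + 1) - gammaln(d - x + 1) + term


def truncation_logmass(p: np.ndarray | float, sigma: float) -> np.ndarray | float:
    """Log probability that a lognormal(median p, log-sd sigma) deviate
    stays below 1, i.e. the normaliser of the truncated replicate-frequency
    distribution.  Essentially 0 unless p is close to 1."""
    return log_ndtr(-np.log(p) / sigma)


def loglik_freq_block(
    p: np.ndarray,
    dev: ReplicateDeviations | np.ndarray,
    noise: NoiseModel | float,
    reads: ReadCountTable,
) -> float:
    """Frequency term of one block: truncated lognormal deviation +
    binomial reads.

    Returns -inf if any replicate frequency ``p_j + delta_jk`` falls outside
    the open interval (0, 1).
    """
    delta = dev.delta if isinstance(dev, ReplicateDeviations) else np.asarray(dev)
    sigma = noise.sigma_delta if isinstance(noise, NoiseModel) else float(noise)
    p = np.asarray(p, dtype=float)
    v = p[:, None] + delta
    if np.any(v <= 0.0) or np.any(v >= 1.0):
        return -np.inf
    terms = (
        lognormal_logpdf(v, p[:, None], sigma)
        - truncation_logmass(p[:, None], sigma)
        + binomial_logpmf(reads.x, reads.d, v)
    )
    return float(np.sum(terms))


def loglik_dfe_block(s: np.ndarray, dfe: TwoSidedGammaDFE) -> float:
    """DFE term of one block: sum of side-specific gamma log densities of |s|.

    The mixture weight q is excluded; it enters through the sign-count term.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s == 0.0):
        raise ValueError("selection coefficients of exactly 0 are not in the support")
    pos = s > 0
    shape = np.where(pos, dfe.shape_pos, dfe.shape_neg)
    rate = np.where(pos, dfe.rate_pos, dfe.rate_neg)
    a = np.abs(s)
    return float(
        np.sum((shape - 1.0) * np.log(a) - rate * a + shape * np.log(rate) - gammaln(shape))
    )


def loglik_sign_counts(n_pos: int, n_neg: int, q: float) -> float:
    """Binomial log likelihood of the split into positive/negative effects."""
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be non-negative")
    n = n_pos + n_neg
    return float(binomial_logpmf(n_pos, n, q))


def block_expected_freqs(
    block: ChromosomeBlock, s: np.ndarray, t: float
) -> np.ndarray:
    """Expected mutation frequencies of a block after t generations.

    Composes one round of meiosis with the closed-form selection recursion.
    """
    pool = meiosis_freqs(block)
    log_w = carrier_matrix(block.m) @ np.log1p(np.asarray(s, dtype=float))
    freqs_t = evolve_closed(pool.freqs, log_w, t)
    return carrier_matrix(block.m).T @ freqs_t


def total_loglik(
    state,
    blocks: Sequence[ChromosomeBlock],
    reads: Sequence[ReadCountTable],
    t_generations: float = 60.0,
    include_dfe_term: bool = True,
) -> float:
    """Total composite log likelihood over independent chromosome blocks.

    ``state`` must expose per-block effect vectors ``state.s`` and deviation
    arrays ``state.dev`` (lists aligned with ``blocks``), plus
    ``state.sigma_delta`` and ``state.dfe``.  This is the reference
    implementation; the MCMC engine evaluates the same quantity
    incrementally.
    """
    total = 0.0
    all_s = np.concatenate([np.asarray(sb, dtype=float) for sb in state.s])
    for block, s_block, dev_block, rt in zip(blocks, state.s, state.dev, reads):
        p = block_expected_freqs(block, s_block, t_generations)
        term = loglik_freq_block(p, np.asarray(dev_block), state.sigma_delta, rt)
        if not np.isfinite(term):
            return -np.inf
        total += term
        if include_dfe_term:
            total += loglik_dfe_block(np.asarray(s_block), state.dfe)
    n_pos = int(np.sum(all_s > 0))
    n_neg = int(np.sum(all_s < 0))
    total += loglik_sign_counts(n_pos, n_neg, state.dfe.q)
    return float(total)
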