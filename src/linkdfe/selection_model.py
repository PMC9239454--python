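"""Deterministic linked-selection dynamics of recombinant haplotype pools.

One cross between a mutation-bearing haploid line and its unmutated ancestor
produces, per chromosome, a pool of 2^m recombinant haplotypes over the m
linked mutations on that chromosome.  A single round of meiosis sets the
initial haplotype frequencies (each mutation marginally at 0.5); the pool
then competes asexually, so haplotype frequencies change deterministically
under multiplicative selection with no further recombination:

    pi_{i,t+1} = pi_{i,t} * w_i / wbar_t,     w_i = prod_j (1 + delta_ij s_j)

Blocks on different chromosomes, and blocks from different crosses, evolve
independently.  Haplotypes are encoded as integer bitmasks in genome order:
bit j of haplotype index i is 1 iff the haplotype carries mutation j.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Hard cap on mutations per block (2^20 haplotypes); real blocks are far
#: smaller (about 2 mutations per chromosome per line on average).
MAX_BLOCK_MUTATIONS = 20


class BlockTooLargeError(ValueError):
    """A chromosome block exceeds the haplotype enumeration cap."""


class FitnessNonPositiveError(ValueError):
    """A selection coefficient <= -1 would give non-positive fitness."""


@dataclass(frozen=True)
class ChromosomeBlock:
    """Ordered linked mutations of one cross on one chromosome.

    ``rec_fractions`` holds the m-1 recombination fractions between adjacent
    mutations (genome order), each in [0, 0.5).
    """

    cross_id: str
    chromosome_id: str
    mutation_ids: tuple
    rec_fractions: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "rec_fractions", np.asarray(self.rec_fractions, dtype=float)
        )
        object.__setattr__(self, "mutation_ids", tuple(self.mutation_ids))
        m = len(self.mutation_ids)
        if m < 1:
            raise ValueError("a block needs at least one mutation")
        if m > MAX_BLOCK_MUTATIONS:
            raise BlockTooLargeError(
                f"block {self.cross_id}/{self.chromosome_id} has {m} mutations; "
                f"the cap is {MAX_BLOCK_MUTATIONS} (2^{MAX_BLOCK_MUTATIONS} haplotypes)"
            )
        if self.rec_fractions.shape != (m - 1,):
            raise ValueError(
                f"expected {m - 1} recombination fractions, got "
                f"{self.rec_fractions.shape}"
            )
        if np.any(self.rec_fractions < 0) or np.any(self.rec_fractions >= 0.5):
            raise ValueError("recombination fractions must lie in [0, 0.5)")

    @property
    def m(self) -> int:
        return len(self.mutation_ids)


@dataclass(frozen=True)
class HaplotypePool:
    """Frequencies of the 2^m haplotypes of one block.

    Haplotype i carries mutation j iff bit j of i is set.
    """

    n_mutations: int
    freqs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        if self.freqs.shape != (2**self.n_mutations,):
            raise ValueError(
                f"expected {2**self.n_mutations} frequencies, got {self.freqs.shape}"
            )
        if np.any(self.freqs < 0):
            raise ValueError("haplotype frequencies must be non-negative")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")


def carrier_matrix(m: int) -> np.ndarray:
    """(2^m, m) 0/1 matrix: entry (i, j) = 1 iff haplotype i carries mutation j."""
    idx = np.arange(2**m)
    return ((idx[:, None] >> np.arange(m)[None, :]) & 1).astype(float)


def meiosis_freqs(block: ChromosomeBlock) -> HaplotypePool:
    """Expected haplotype frequencies after one round of meiosis.

    The mutant parent carries all m mutations in coupling, the ancestor
    none.  The frequency of a haplotype is 0.5 times the product over
    adjacent intervals of r (pattern switches parental origin) or 1 - r
    (pattern stays), so every mutation is marginally at frequency 0.5.
    """
    m = block.m
    bits = carrier_matrix(m).astype(int)
    freqs = np.full(2**m, 0.5)
    for k, r in enumerate(block.rec_fractions):
        switch = bits[:, k] != bits[:, k + 1]
        freqs *= np.where(switch, r, 1.0 - r)
    return HaplotypePool(n_mutations=m, freqs=freqs)


def haplotype_fitness(pool: HaplotypePool, s: Sequence[float] | np.ndarray) -> np.ndarray:
    """Multiplicative fitness of each haplotype: w_i = prod_j (1 + s_j)^{bit_ij}."""
    s_arr = np.asarray(s, dtype=float)
    if s_arr.shape != (pool.n_mutations,):
        raise ValueError(
            f"expected {pool.n_mutations} selection coefficients, got {s_arr.shape}"
        )
    if np.any(s_arr <= -1.0):
        raise FitnessNonPositiveError("selection coefficients must exceed -1")
    carriers = carrier_matrix(pool.n_mutations)
    return np.exp(carriers @ np.log1p(s_arr))


def evolve(pool: HaplotypePool, fitness: np.ndarray, t: int) -> HaplotypePool:
    """Iterate the deterministic selection recursion for ``t`` generations."""
    if t < 0 or int(t) != t:
        raise ValueError("t must be a non-negative integer")
    w = np.asarray(fitness, dtype=float)
    freqs = pool.freqs.copy()
    for _ in range(int(t)):
        freqs = freqs * w
        freqs = freqs / freqs.sum()
    return HaplotypePool(n_mutations=pool.n_mutations, freqs=freqs)


def evolve_closed(freqs: np.ndarray, log_fitness: np.ndarray, t: float) -> np.ndarray:
    """Closed form of the selection recursion: pi_t ∝ pi_0 * w^t.

    Mathematically identical to iterating :func:`evolve` ``t`` times (the
    mean-fitness normalisers telescope); used as the fast path in
    likelihood evaluation.
    """
    with np.errstate(divide="ignore"):
        z = np.log(freqs) + t * log_fitness
    z = np.exp(z - z.max())
    return z / z.sum()


def expected_allele_freqs(pool: HaplotypePool) -> np.ndarray:
    """Marginal frequency of each mutation: p_j = sum of freqs of carriers."""
    return carrier_matrix(pool.n_mutations).T @ pool.freqs


def write_trajectory_tsv(
    block: ChromosomeBlock,
    s: Sequence[float] | np.ndarray,
    t: int,
    path,
) -> None:
    """Dump the per-generation expected mutation frequencies of one block
    as TSV (generation, mutation_id, frequency) for debugging."""
    pool = meiosis_freqs(block)
    w = haplotype_fitness(pool, s)
    with open(path, "w") as fh:
        fh.write("generation\tmutation_id\tfrequency\n")
        for gen in range(int(t) + 1):
            p = expected_allele_freqs(pool)
            for mid, pj in zip(block.mutation_ids, p):
                fh.write(f"{gen}\t{mid}\t{pj:.10g}\n")
            pool = evolve(pool, w, 1)
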