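"""Synthetic datasets with the statistical structure the inference assumes.

The generator emulates the experimental design end to end: seven crosses of
mutation-bearing haploid lines to their unmutated ancestor, 254 mutations
spread over 17 chromosomes, recombinant haplotype pools founded by a finite
number of germinating zygotes, a few generations of pre-assay growth before
the time-0 sample, about 60 generations of serial-transfer evolution, and
pool sequencing with lognormal between-replicate frequency noise, binomial
read sampling, and negative-binomial depth variation (time-0 mean depth
about 521x, time-t about 222x, coefficient of variation about 0.43).

Defaults reproduce the study conditions; every stochastic element is driven
by a single seed so datasets are exactly reproducible.  A ``truth`` table
records all latent values (true effects, haplotype trajectories' marginal
frequencies) for parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dfe_model import TwoSidedGammaDFE, dfe_sample
from .genetic_map import (
    DEFAULT_GENOME_AVG_BP_PER_CM,
    DEFAULT_SLOPE_BP_PER_CM_PER_BP,
    ChromosomeSpec,
    build_map,
    map_positions,
    recomb_fractions,
)
from .selection_model import (
    ChromosomeBlock,
    HaplotypePool,
    carrier_matrix,
    evolve_closed,
    haplotype_fitness,
    meiosis_freqs,
)

#: Per-line mutation counts of the default seven-cross design (254 total).
DEFAULT_MUTATIONS_PER_CROSS = (25, 15, 47, 52, 41, 36, 38)

#: Mutation class mix of the default design: 232 SNPs, 13 insertions,
#: 9 deletions out of 254.
DEFAULT_CLASS_PROBS = {"SNP": 232 / 254, "INS": 13 / 254, "DEL": 9 / 254}


def default_chromosomes(n: int = 17) -> list[ChromosomeSpec]:
    """Synthetic chromosome lengths: ``n`` chromosomes spanning 1-10 Mb."""
    lengths = np.linspace(1e6, 1e7, n).round().astype(int)
    return [
        ChromosomeSpec(id=f"chr{i + 1:02d}", length_bp=int(L))
        for i, L in enumerate(lengths)
    ]


def default_true_dfe() -> TwoSidedGammaDFE:
    """Two-sided gamma with q=0.5, shape 0.53, mean |s| 0.022 (shared)."""
    return TwoSidedGammaDFE.shared(q=0.5, shape=0.53, mean_abs=0.022)


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of one simulated experiment.

    ``zygote_pool_size`` is the number of germinating zygotes founding each
    cross's recombinant pool; ``None`` means an infinite (deterministic)
    pool.  ``t_pre`` is the number of pre-assay growth generations before
    the time-0 sample, during which selection already operates; the paper
    design cannot pin this number down, so it is a free knob (default 5).
    """

    n_crosses: int = 7
    mutations_per_cross: tuple = DEFAULT_MUTATIONS_PER_CROSS
    chromosomes: tuple = tuple(default_chromosomes())
    true_dfe: TwoSidedGammaDFE = field(default_factory=default_true_dfe)
    t_evolution: int = 60
    t_pre: int = 5
    replicates: int = 3
    depth_mean_t0: float = 520.7
    depth_mean_tt: float = 221.6
    depth_cv: float = 0.43
    sigma_delta_true: float = 0.05
    zygote_pool_size: int | None = 10_000
    mode: str = "deterministic"
    wf_population_size: int = 1_000_000
    n_transfers: int = 9
    genome_avg_bp_per_cM: float = DEFAULT_GENOME_AVG_BP_PER_CM
    map_slope: float = DEFAULT_SLOPE_BP_PER_CM_PER_BP
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.mutations_per_cross) != self.n_crosses:
            raise ValueError(
                "mutations_per_cross must have one entry per cross "
                f"({self.n_crosses}), got {len(self.mutations_per_cross)}"
            )
        if any(m < 1 for m in self.mutations_per_cross):
            raise ValueError("every cross needs at least one mutation")
        if self.replicates < 1 or self.t_evolution < 0 or self.t_pre < 0:
            raise ValueError("counts must be non-negative (replicates >= 1)")
        if min(self.depth_mean_t0, self.depth_mean_tt) < 1:
            raise ValueError("depth means must be >= 1")
        if self.mode not in ("deterministic", "wright_fisher"):
            raise ValueError("mode must be 'deterministic' or 'wright_fisher'")


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated dataset plus its latent truth."""

    mutations: pd.DataFrame
    reads: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir: str | Path, header_lines: Sequence[str] = ()) -> None:
        """Write mutation, read-count, truth and chromosome-length TSVs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

        def _dump(df: pd.DataFrame, name: str) -> None:
            path = outdir / name
            with open(path, "w") as fh:
                for line in header_lines:
                    fh.write(f"# {line}\n")
                df.to_csv(fh, sep="\t", index=False)

        _dump(self.mutations, "mutations.tsv")
        _dump(self.reads, "reads.tsv")
        _dump(self.truth, "truth.tsv")
        with open(outdir / "chromosomes.tsv", "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            for c in self.config.chromosomes:
                fh.write(f"{c.id}\t{c.length_bp}\n")


# ---------------------------------------------------------------------------
# Generator stages
# ---------------------------------------------------------------------------


def simulate_lines(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Place mutations on chromosomes and draw their true effects.

    Each mutation is assigned a chromosome uniformly at random and a
    position uniform over that chromosome's length; positions are sorted in
    genome order within each cross.  Effects come from the configured DFE
    (clipped just inside (-1, 1) so fitnesses stay positive).
    """
    chroms = list(config.chromosomes)
    rows = []
    for c_idx, n_mut in enumerate(config.mutations_per_cross):
        cross = f"L{c_idx + 1:02d}"
        chrom_idx = rng.integers(0, len(chroms), size=n_mut)
        positions = np.array(
            [rng.integers(1, chroms[i].length_bp + 1) for i in chrom_idx]
        )
        classes = rng.choice(
            list(DEFAULT_CLASS_PROBS), size=n_mut, p=list(DEFAULT_CLASS_PROBS.values())
        )
        annotation = np.where(rng.random(n_mut) < 0.5, "exonic", "non-exonic")
        for j in range(n_mut):
            rows.append(
                {
                    "cross": cross,
                    "chromosome": chroms[chrom_idx[j]].id,
                    "position": int(positions[j]),
                    "mut_class": classes[j],
                    "annotation": annotation[j],
                }
            )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["cross", "chromosome", "position"], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "mutation_id", [f"mut{i + 1:04d}" for i in range(len(df))])
    effects = np.clip(dfe_sample(config.true_dfe, len(df), rng), -0.999, 0.999)
    # the DFE is continuous: an exact zero has probability 0, but guard anyway
    effects[effects == 0.0] = 1e-9
    return df, effects


def simulate_pool(
    block: ChromosomeBlock,
    zygote_pool_size: int | None,
    rng: np.random.Generator,
) -> HaplotypePool:
    """Realised founding pool: multinomial draw of zygotes from the meiosis
    expectation, or the exact expectation for an infinite pool."""
    expected = meiosis_freqs(block)
    if zygote_pool_size is None or np.isinf(zygote_pool_size):
        return expected
    if zygote_pool_size < 1:
        raise ValueError("zygote_pool_size must be >= 1")
    counts = rng.multinomial(int(zygote_pool_size), expected.freqs)
    return HaplotypePool(
        n_mutations=block.m, freqs=counts / counts.sum()
    )


def _wright_fisher(
    freqs: np.ndarray,
    fitness: np.ndarray,
    t: int,
    n_pop: int,
    rng: np.random.Generator,
    bottleneck_gens: frozenset = frozenset(),
    bottleneck_size: int | None = None,
) -> np.ndarray:
    """Multinomial resampling of N haplotypes per generation, with optional
    serial-transfer bottlenecks at the given generation indices."""
    f = freqs.copy()
    for g in range(t):
        w = f * fitness
        f = rng.multinomial(n_pop, w / w.sum()) / n_pop
        if g in bottleneck_gens and bottleneck_size:
            f = rng.multinomial(bottleneck_size, f) / bottleneck_size
    return f


def simulate_trajectory(
    pool: HaplotypePool,
    effects: np.ndarray,
    t_pre: int,
    t_evolution: int,
    mode: str = "deterministic",
    n_replicates: int = 3,
    rng: np.random.Generator | None = None,
    wf_population_size: int = 1_000_000,
    n_transfers: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Evolve a pool and report mutation frequencies at the assay timepoints.

    Returns ``(p0, pt)``: the time-0 marginal frequencies after ``t_pre``
    generations (shape (m,)) and the per-replicate expected frequencies
    after ``t_evolution`` further generations (shape (m, n_replicates)),
    before any measurement noise.  In ``wright_fisher`` mode replicates
    drift independently after time 0 and pass through ``n_transfers``
    bottlenecks at 1/100 of the census size.
    """
    w = haplotype_fitness(pool, effects)
    if mode == "deterministic":
        # same closed-form selection core as the likelihood module, so the
        # generated expectations coincide exactly with the model's
        carriers = carrier_matrix(pool.n_mutations)
        log_w = carriers @ np.log1p(np.asarray(effects, dtype=float))
        p0 = carriers.T @ evolve_closed(pool.freqs, log_w, t_pre)
        pt_once = carriers.T @ evolve_closed(pool.freqs, log_w, t_pre + t_evolution)
        pt = np.tile(pt_once[:, None], (1, n_replicates))
        return p0, pt
    if mode != "wright_fisher":
        raise ValueError("mode must be 'deterministic' or 'wright_fisher'")
    if rng is None:
        raise ValueError("wright_fisher mode needs an rng")
    carriers = carrier_matrix(pool.n_mutations)
    f0 = _wright_fisher(pool.freqs, w, t_pre, wf_population_size, rng)
    p0 = carriers.T @ f0
    if n_transfers > 0:
        step = max(t_evolution // n_transfers, 1)
        bottlenecks = frozenset(range(step - 1, t_evolution, step))
    else:
        bottlenecks = frozenset()
    pt = np.empty((pool.n_mutations, n_replicates))
    for k in range(n_replicates):
        fk = _wright_fisher(
            f0, w, t_evolution, wf_population_size, rng,
            bottleneck_gens=bottlenecks,
            bottleneck_size=max(wf_population_size // 100, 1),
        )
        pt[:, k] = carriers.T @ fk
    return p0, pt


def sample_depths(
    mean: float, cv: float, size, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial depths matched to a mean and coefficient of variation.

    The NB dispersion k solves cv^2 = 1/mean + 1/k; if the requested cv is
    at or below the Poisson floor the depths are Poisson.  Depths are
    floored at 1 so every mutation stays observable.
    """
    mean = float(mean)
    if cv <= 0:
        return np.maximum(np.full(size, round(mean), dtype=int), 1)
    excess = cv**2 - 1.0 / mean
    if excess <= 0:
        draws = rng.poisson(mean, size=size)
    else:
        k = 1.0 / excess
        p = k / (k + mean)
        draws = rng.negative_binomial(k, p, size=size)
    return np.maximum(draws, 1)


def simulate_reads(
    freqs: np.ndarray,
    depth_mean: float,
    sigma_delta: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Read counts for an (m, r) array of underlying frequencies.

    Each replicate frequency is perturbed lognormally (median = the true
    frequency, log-sd ``sigma_delta``, redrawn until inside (0, 1)), a depth
    is drawn from the negative binomial, and mutant reads are binomial.
    With ``sigma_delta = 0`` the frequency is used as is.
    """
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
        raise ValueError("underlying frequencies must lie strictly in (0, 1)")
    if sigma_delta > 0:
        v = freqs * np.exp(sigma_delta * rng.standard_normal(freqs.shape))
        bad = v >= 1.0
        while np.any(bad):
            v[bad] = freqs[bad] * np.exp(
                sigma_delta * rng.standard_normal(int(bad.sum()))
            )
            bad = v >= 1.0
    else:
        v = freqs
    d = sample_depths(depth_mean, config.depth_cv, freqs.shape, rng)
    x = rng.binomial(d.astype(int), v)
    return x.astype(float), d.astype(float)


def blocks_from_mutations(
    mutations: pd.DataFrame,
    chromosomes: Sequence[ChromosomeSpec],
    genome_avg: float = DEFAULT_GENOME_AVG_BP_PER_CM,
    slope: float = DEFAULT_SLOPE_BP_PER_CM_PER_BP,
) -> list[tuple[ChromosomeBlock, np.ndarray]]:
    """Group a mutation table into chromosome blocks with recombination
    fractions attached; returns (block, row-index array) pairs in the
    table's (cross, chromosome) order."""
    gmap = build_map(list(chromosomes), genome_avg=genome_avg, slope=slope)
    out = []
    for (cross, chrom), grp in mutations.groupby(["cross", "chromosome"], sort=True):
        grp = grp.sort_values("position", kind="mergesort")
        cm = map_positions(grp["position"].to_numpy(), chrom, gmap)
        block = ChromosomeBlock(
            cross_id=str(cross),
            chromosome_id=str(chrom),
            mutation_ids=tuple(grp["mutation_id"]),
            rec_fractions=recomb_fractions(cm),
        )
        out.append((block, grp.index.to_numpy()))
    return out


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate a full dataset under the configured study conditions."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    mutations, effects = simulate_lines(config, rng)
    block_index = blocks_from_mutations(
        mutations, config.chromosomes, config.genome_avg_bp_per_cM, config.map_slope
    )

    read_rows = []
    truth_rows = []
    for block, rows in block_index:
        s_block = effects[rows]
        pool = simulate_pool(block, config.zygote_pool_size, rng)
        p0, pt = simulate_trajectory(
            pool,
            s_block,
            config.t_pre,
            config.t_evolution,
            mode=config.mode,
            n_replicates=config.replicates,
            rng=rng,
            wf_population_size=config.wf_population_size,
            n_transfers=config.n_transfers if config.mode == "wright_fisher" else 0,
        )
        p0c = np.clip(p0, 1e-9, 1.0 - 1e-9)
        ptc = np.clip(pt, 1e-9, 1.0 - 1e-9)
        x0, d0 = simulate_reads(p0c[:, None], config.depth_mean_t0, 0.0, config, rng)
        xt, dt = simulate_reads(
            ptc, config.depth_mean_tt, config.sigma_delta_true, config, rng
        )
        for j, row_idx in enumerate(rows):
            mut = mutations.loc[row_idx]
            base = {
                "cross": mut["cross"],
                "mutation_id": mut["mutation_id"],
                "chromosome": mut["chromosome"],
                "position": mut["position"],
            }
            read_rows.append(
                dict(base, replicate=0, timepoint="t0",
                     mutant_reads=int(x0[j, 0]), depth=int(d0[j, 0]))
            )
            for k in range(config.replicates):
                read_rows.append(
                    dict(base, replicate=k + 1, timepoint="tt",
                         mutant_reads=int(xt[j, k]), depth=int(dt[j, k]))
                )
            truth_rows.append(
                dict(base, s_true=effects[row_idx], p0_true=p0[j],
                     pt_true=float(np.mean(pt[j])))
            )
    reads = pd.DataFrame(read_rows)
    truth = pd.DataFrame(truth_rows)
    return SyntheticDataset(
        mutations=mutations, reads=reads, truth=truth, config=config
    )
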