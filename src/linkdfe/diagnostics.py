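"""Pre-inference summaries of the experiment.

Covers the descriptive statistics computed before (and independently of)
the Bayesian fit: the repeatability of mutation frequencies among
replicates, the reconstruction of generation counts from serial-transfer
culture densities, the implied initial zygote population size, and
bootstrap contrasts of effect sizes between annotation categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("linkdfe")


@dataclass(frozen=True)
class VarianceComponents:
    """Nested variance decomposition of replicate mutation frequencies.

    ``v_ma`` is the among-cross variance, ``v_m`` the among-mutation
    variance within crosses, ``v_e`` the residual among-replicate variance.
    Repeatability is ``v_m / (v_m + v_e)``; the among-cross component is
    deliberately excluded from the denominator.
    """

    v_ma: float
    v_m: float
    v_e: float

    @property
    def repeatability(self) -> float:
        denom = self.v_m + self.v_e
        return self.v_m / denom if denom > 0 else 0.0


def repeatability(freqs: pd.DataFrame) -> VarianceComponents:
    """Method-of-moments nested variance components of replicate frequencies.

    ``freqs`` needs columns ``cross``, ``mutation_id``, ``freq`` with one
    row per replicate measurement (time-t replicates).  The decomposition
    is the standard two-level nested ANOVA (mutations nested in crosses,
    replicates nested in mutations); negative moment estimates are
    truncated to zero with a log entry.
    """
    required = {"cross", "mutation_id", "freq"}
    missing = required - set(freqs.columns)
    if missing:
        raise ValueError(f"frequency table lacks columns: {sorted(missing)}")
    counts = freqs.groupby(["cross", "mutation_id"])["freq"].count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(
            f"every mutation needs >= 2 replicates to estimate V_E; offending: {bad[:5]}"
        )

    y = freqs["freq"].to_numpy(dtype=float)
    grand = y.mean()
    n_total = y.size

    mut_stats = freqs.groupby(["cross", "mutation_id"])["freq"].agg(["mean", "count"])
    cross_stats = freqs.groupby("cross")["freq"].agg(["mean", "count"])
    a = len(cross_stats)

    # residual (within-mutation) sum of squares
    mut_mean_per_row = freqs.set_index(["cross", "mutation_id"]).index.map(
        mut_stats["mean"]
    )
    ss_e = float(np.sum((y - np.asarray(mut_mean_per_row)) ** 2))
    df_e = n_total - len(mut_stats)

    # among mutations within crosses
    cross_mean_per_mut = mut_stats.index.get_level_values("cross").map(
        cross_stats["mean"]
    )
    ss_m = float(
        np.sum(
            mut_stats["count"].to_numpy()
            * (mut_stats["mean"].to_numpy() - np.asarray(cross_mean_per_mut)) ** 2
        )
    )
    df_m = len(mut_stats) - a

    # among crosses
    ss_ma = float(
        np.sum(
            cross_stats["count"].to_numpy()
            * (cross_stats["mean"].to_numpy() - grand) ** 2
        )
    )
    df_ma = a - 1

    ms_e = ss_e / df_e
    ms_m = ss_m / df_m if df_m > 0 else ms_e

    # expected-mean-square coefficients (balanced-design forms evaluated
    # with the average counts; exact when the design is balanced)
    r_bar = float(mut_stats["count"].mean())
    b_bar = float(mut_stats.groupby(level="cross").size().mean())

    v_e = ms_e
    v_m = (ms_m - ms_e) / r_bar
    if df_ma > 0:
        ms_ma = ss_ma / df_ma
        v_ma = (ms_ma - ms_m) / (r_bar * b_bar)
    else:
        v_ma = 0.0

    if v_m < 0 or v_ma < 0:
        logger.info(
            "negative variance component estimate truncated to 0 "
            "(V_M=%.3g, V_MA=%.3g)", v_m, v_ma,
        )
    return VarianceComponents(v_ma=max(v_ma, 0.0), v_m=max(v_m, 0.0), v_e=max(v_e, 0.0))


def generations_from_density(
    n_start: float | np.ndarray, n_end: float | np.ndarray
) -> float | np.ndarray:
    """Generations of growth implied by a density change: g = log2(end/start).

    Densities may be any proportional proxy (OD, cells/ml).  A decline gives
    a negative count with a warning rather than an error.
    """
    n_start = np.asarray(n_start, dtype=float)
    n_end = np.asarray(n_end, dtype=float)
    if np.any(n_start <= 0) or np.any(n_end <= 0):
        raise ValueError("densities must be > 0")
    if np.any(n_end < n_start):
        logger.warning("culture density declined; negative generation count")
    g = np.log2(n_end / n_start)
    return float(g) if g.ndim == 0 else g


def total_generations(transfers: Sequence[tuple[float, float]]) -> float:
    """Sum per-transfer generation counts over consecutive serial transfers."""
    return float(sum(generations_from_density(n0, nt) for n0, nt in transfers))


def initial_population_size(g: float, n_end: float) -> float:
    """Initial population size from generations of doubling growth.

    Inverts N_t = N_0 * 2^g, i.e. N_0 = N_t / 2^g.
    """
    if g < 0:
        raise ValueError("g must be >= 0")
    if n_end <= 0:
        raise ValueError("n_end must be > 0")
    return n_end / 2.0**g


@dataclass(frozen=True)
class BootstrapContrast:
    """Group contrast of per-mutation effect sizes with bootstrap p-values."""

    diff_mean: float
    diff_mean_sq: float
    p_mean: float
    p_mean_sq: float
    n_boot: int


def bootstrap_contrast(
    values: np.ndarray,
    labels: Sequence,
    group_a,
    group_b,
    n_boot: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> BootstrapContrast:
    """Bootstrap test of the difference in mean (and mean squared) effect
    between two annotation categories.

    The null distribution resamples mutations with replacement from the
    pooled set and reallocates the original group sizes, so labels carry no
    information under the null.  Two-sided p-values use the standard
    ``(1 + #extreme) / (n_boot + 1)`` correction and are exactly invariant
    under swapping the two group labels (the contrast signs flip).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    # canonical group order so the resampling stream is label-order free
    swapped = str(group_a) > str(group_b)
    if swapped:
        group_a, group_b = group_b, group_a
    va = values[labels == group_a]
    vb = values[labels == group_b]
    if va.size == 0 or vb.size == 0:
        raise ValueError(f"both groups must be non-empty ({group_a}: {va.size}, "
                         f"{group_b}: {vb.size})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    sign = -1.0 if swapped else 1.0
    obs_mean = va.mean() - vb.mean()
    obs_sq = np.mean(va**2) - np.mean(vb**2)

    pooled = np.concatenate([va, vb])
    na = va.size
    n = pooled.size
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = pooled[idx]
    boot_a = boot[:, :na]
    boot_b = boot[:, na:]
    boot_mean = boot_a.mean(axis=1) - boot_b.mean(axis=1)
    boot_sq = np.mean(boot_a**2, axis=1) - np.mean(boot_b**2, axis=1)

    p_mean = (1 + np.sum(np.abs(boot_mean) >= abs(obs_mean))) / (n_boot + 1)
    p_sq = (1 + np.sum(np.abs(boot_sq) >= abs(obs_sq))) / (n_boot + 1)
    return BootstrapContrast(
        diff_mean=float(sign * obs_mean),
        diff_mean_sq=float(sign * obs_sq),
        p_mean=float(p_mean),
        p_mean_sq=float(p_sq),
        n_boot=n_boot,
    )
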