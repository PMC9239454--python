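"""Per-chromosome genetic map for a genome with a uniform within-chromosome
recombination rate.

The map assumes a genome-wide average inverse recombination rate (bp/cM) and
lets the per-chromosome inverse rate ``y_i`` increase linearly with
chromosome length ``x_i``::

    y_i = slope * x_i + k,      k = genome_avg - slope * (sum x_i^2 / sum x_i)

so that the length-weighted mean of ``y_i`` equals the genome-wide average
exactly.  Longer chromosomes therefore recombine less per base, reflecting
the requirement of roughly one obligate chiasma per chromosome per meiosis.

Map distances are converted to recombination fractions with the Haldane map
function (no crossover interference), ``r = (1 - exp(-2 d)) / 2`` with ``d``
in Morgans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

#: Genome-wide average inverse recombination rate, bases per centimorgan.
DEFAULT_GENOME_AVG_BP_PER_CM = 87_000.0

#: Increase of bp/cM per base pair of chromosome length.  An alternative,
#: ten-fold smaller slope (0.000616) is sometimes quoted for the same
#: regression; pass it explicitly to :func:`build_map` if preferred.
DEFAULT_SLOPE_BP_PER_CM_PER_BP = 0.00616


class InvalidMapError(ValueError):
    """The requested map parameters produce a non-positive bp/cM value."""


class PositionOutOfRangeError(ValueError):
    """A base-pair position falls outside its chromosome."""


@dataclass(frozen=True)
class ChromosomeSpec:
    """A chromosome identifier and its physical length in base pairs."""

    id: str
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(
                f"chromosome {self.id!r}: length_bp must be > 0, got {self.length_bp}"
            )


@dataclass(frozen=True)
class GeneticMap:
    """Linear length-dependent genetic map.

    Attributes
    ----------
    genome_avg_bp_per_cM:
        Length-weighted mean of the per-chromosome inverse rates.
    slope:
        bp/cM increase per bp of chromosome length.
    intercept_k:
        Intercept of the linear relation (bp/cM).
    per_chromosome_bp_per_cM:
        Mapping chromosome id -> y_i.
    chromosome_lengths:
        Mapping chromosome id -> length in bp (used for range checks).
    """

    genome_avg_bp_per_cM: float
    slope: float
    intercept_k: float
    per_chromosome_bp_per_cM: Mapping[str, float]
    chromosome_lengths: Mapping[str, int] = field(default_factory=dict)

    def bp_per_cM(self, chromosome_id: str) -> float:
        return self.per_chromosome_bp_per_cM[chromosome_id]


def build_map(
    chromosomes: Sequence[ChromosomeSpec],
    genome_avg: float = DEFAULT_GENOME_AVG_BP_PER_CM,
    slope: float = DEFAULT_SLOPE_BP_PER_CM_PER_BP,
) -> GeneticMap:
    """Build the per-chromosome genetic map from chromosome lengths.

    The intercept is chosen so that the length-weighted mean of ``y_i``
    equals ``genome_avg``.

    Raises
    ------
    InvalidMapError
        If any chromosome receives a non-positive bp/cM.
    """
    if not chromosomes:
        raise ValueError("at least one chromosome is required")
    ids = [c.id for c in chromosomes]
    if len(set(ids)) != len(ids):
        raise ValueError("chromosome ids must be unique")
    if genome_avg <= 0:
        raise ValueError("genome_avg must be > 0")
    if slope < 0:
        raise ValueError("slope must be >= 0")

    x = np.array([float(c.length_bp) for c in chromosomes])
    k = genome_avg - slope * (np.sum(x**2) / np.sum(x))
    y = slope * x + k
    for c, yi in zip(chromosomes, y):
        if yi <= 0:
            raise InvalidMapError(
                f"chromosome {c.id!r} receives non-positive bp/cM ({yi:.3f}); "
                "reduce the slope or the spread of chromosome lengths"
            )
    return GeneticMap(
        genome_avg_bp_per_cM=float(genome_avg),
        slope=float(slope),
        intercept_k=float(k),
        per_chromosome_bp_per_cM={c.id: float(yi) for c, yi in zip(chromosomes, y)},
        chromosome_lengths={c.id: c.length_bp for c in chromosomes},
    )


def map_positions(
    positions_bp: Sequence[float] | np.ndarray,
    chromosome_id: str,
    gmap: GeneticMap,
) -> np.ndarray:
    """Convert sorted 1-based bp positions on one chromosome to cM positions.

    cM_j = position_bp / y_i with y_i the chromosome's bp/cM.
    """
    pos = np.asarray(positions_bp, dtype=float)
    if pos.ndim != 1:
        raise ValueError("positions must be one-dimensional")
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted ascending")
    length = gmap.chromosome_lengths.get(chromosome_id)
    if length is not None and (np.any(pos < 0) or np.any(pos > length)):
        raise PositionOutOfRangeError(
            f"position outside [0, {length}] on chromosome {chromosome_id!r}"
        )
    return pos / gmap.bp_per_cM(chromosome_id)


def haldane(d_morgans: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: recombination fraction for map distance in Morgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_morgans, dtype=float)))


def recomb_fractions(cm_positions: Sequence[float] | np.ndarray) -> np.ndarray:
    """Recombination fractions between adjacent sorted cM positions.

    Returns an array of length ``len(cm_positions) - 1`` with each fraction in
    [0, 0.5) under the Haldane map function.
    """
    cm = np.asarray(cm_positions, dtype=float)
    if cm.size < 1:
        raise ValueError("at least one position is required")
    d = np.diff(cm)
    if np.any(d < 0):
        raise ValueError("cM positions must be sorted ascending")
    return np.asarray(haldane(d / 100.0))


def read_chromosome_lengths(path: str | Path) -> list[ChromosomeSpec]:
    """Read chromosome lengths from a two-column TSV (id, length) or a
    FASTA index (``.fai``, where length is the second column)."""
    path = Path(path)
    specs: list[ChromosomeSpec] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: expected at least two tab-separated columns")
            specs.append(ChromosomeSpec(id=parts[0], length_bp=int(parts[1])))
    if not specs:
        raise ValueError(f"{path}: no chromosomes found")
    return specs
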