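"""Two-sided gamma distribution of fitness effects (DFE).

The DFE places probability mass ``q`` on positive selection coefficients and
``1 - q`` on negative ones; the magnitude ``|s|`` on each side follows a
gamma distribution with its own shape and rate.  Three constraint variants
are supported:

``shared``
    One shape and one rate for both sides (2 free gamma parameters).
``shared_shape``
    One shape, side-specific rates, i.e. side-specific means (3 parameters).
``full``
    Side-specific shapes and rates (4 parameters).

Parameterisation note: the rate parameters here are RATES, so the mean
absolute effect on a side is ``shape / rate``.  Field descriptions of this
model sometimes label the same quantity "scale"; to avoid shape/scale
confusion every constructor in this module takes either a rate or a mean,
never a scale.

The module also implements the correction for selection during the
mutation-accumulation (MA) phase.  Mutations arise during clonal colony
growth between single-cell transfers; a mutation with effect ``s`` arising
while the colony doubles for ``t`` generations is over- or under-represented
in the cells available at transfer by the deterministic weight

    w(s, t) = (2^(s t) - 1) / (t (2^s - 1)),       w(0, t) = 1,

the expected representation of the mutant relative to a neutral mutation
when lineage growth rates scale multiplicatively with ``1 + s`` and
mutations arise at cell divisions in proportion to the number of divisions
per generation.  Dividing the observed DFE density by ``w`` and
renormalising yields the DFE of mutations as they arose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import stats

VARIANTS = ("shared", "shared_shape", "full")

#: Number of free gamma parameters per variant (the positive-mass weight q
#: is counted separately in model comparison).
N_DFE_PARAMS = {"shared": 2, "shared_shape": 3, "full": 4}


class WeightDivergenceError(ValueError):
    """The MA-phase representation weight is non-finite over the support."""


@dataclass(frozen=True)
class TwoSidedGammaDFE:
    """Two-sided gamma distribution of selection coefficients.

    Attributes
    ----------
    q:
        Probability that a mutation's effect is positive.
    shape_neg, shape_pos:
        Gamma shape parameters of the negative and positive side.
    rate_neg, rate_pos:
        Gamma rate parameters; mean |s| on a side equals shape / rate.
    variant:
        Constraint mode, one of ``shared``, ``shared_shape``, ``full``.
    """

    q: float
    shape_neg: float
    shape_pos: float
    rate_neg: float
    rate_pos: float
    variant: str = "full"

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q must be in [0, 1], got {self.q}")
        for name in ("shape_neg", "shape_pos", "rate_neg", "rate_pos"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.variant == "shared" and (
            self.shape_neg != self.shape_pos or self.rate_neg != self.rate_pos
        ):
            raise ValueError("variant='shared' requires equal shapes and rates")
        if self.variant == "shared_shape" and self.shape_neg != self.shape_pos:
            raise ValueError("variant='shared_shape' requires equal shapes")

    # -- convenience constructors -------------------------------------------

    @classmethod
    def shared(cls, q: float, shape: float, mean_abs: float) -> "TwoSidedGammaDFE":
        """Shared-parameter variant from (q, shape, mean |s|)."""
        rate = mean_to_rate(mean_abs, shape)
        return cls(q=q, shape_neg=shape, shape_pos=shape,
                   rate_neg=rate, rate_pos=rate, variant="shared")

    @classmethod
    def from_means(
        cls,
        q: float,
        shape_neg: float,
        shape_pos: float,
        mean_neg: float,
        mean_pos: float,
        variant: str = "full",
    ) -> "TwoSidedGammaDFE":
        return cls(
            q=q,
            shape_neg=shape_neg,
            shape_pos=shape_pos,
            rate_neg=mean_to_rate(mean_neg, shape_neg),
            rate_pos=mean_to_rate(mean_pos, shape_pos),
            variant=variant,
        )

    # -- derived quantities --------------------------------------------------

    @property
    def mean_neg(self) -> float:
        """Mean |s| of negative-effect mutations (shape/rate)."""
        return self.shape_neg / self.rate_neg

    @property
    def mean_pos(self) -> float:
        """Mean |s| of positive-effect mutations (shape/rate)."""
        return self.shape_pos / self.rate_pos

    def to_dict(self) -> dict:
        return {
            "q": self.q,
            "shape_neg": self.shape_neg,
            "shape_pos": self.shape_pos,
            "rate_neg": self.rate_neg,
            "rate_pos": self.rate_pos,
            "variant": self.variant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TwoSidedGammaDFE":
        return cls(**{k: (v if k == "variant" else float(v)) for k, v in d.items()})


def mean_to_rate(mean_abs_effect: float, shape: float) -> float:
    """Convert a mean absolute effect and a gamma shape to the gamma rate."""
    if mean_abs_effect <= 0 or shape <= 0:
        raise ValueError("mean and shape must both be > 0")
    return shape / mean_abs_effect


def dfe_density(s: np.ndarray | float, dfe: TwoSidedGammaDFE) -> np.ndarray | float:
    """Density of the two-sided gamma DFE at signed effect(s) ``s``.

    For s > 0 the density is ``q * gammaPDF(s; shape_pos, rate_pos)``; for
    s < 0 it is ``(1-q) * gammaPDF(-s; shape_neg, rate_neg)``.  The density
    at exactly 0 is returned as the limit through the positive side (it is
    infinite for shapes < 1 and the point has measure zero).
    """
    s_arr = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s_arr)):
        raise ValueError("selection coefficients must be finite")
    pos = s_arr > 0
    with np.errstate(invalid="ignore"):
        out = np.where(
            pos,
            dfe.q
            * stats.gamma.pdf(np.abs(s_arr), dfe.shape_pos, scale=1.0 / dfe.rate_pos),
            (1.0 - dfe.q)
            * stats.gamma.pdf(np.abs(s_arr), dfe.shape_neg, scale=1.0 / dfe.rate_neg),
        )
    if np.isscalar(s):
        return float(out)
    return out


def dfe_cdf(s: np.ndarray | float, dfe: TwoSidedGammaDFE) -> np.ndarray | float:
    """CDF of the two-sided gamma DFE (analytic)."""
    s_arr = np.asarray(s, dtype=float)
    neg_part = (1.0 - dfe.q) * stats.gamma.sf(
        -s_arr, dfe.shape_neg, scale=1.0 / dfe.rate_neg
    )
    pos_part = (1.0 - dfe.q) + dfe.q * stats.gamma.cdf(
        s_arr, dfe.shape_pos, scale=1.0 / dfe.rate_pos
    )
    out = np.where(s_arr < 0, neg_part, pos_part)
    if np.isscalar(s):
        return float(out)
    return out


def dfe_sample(
    dfe: TwoSidedGammaDFE,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` signed selection coefficients from the DFE."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positive = rng.random(n) < dfe.q
    mag_pos = rng.gamma(dfe.shape_pos, 1.0 / dfe.rate_pos, size=n)
    mag_neg = rng.gamma(dfe.shape_neg, 1.0 / dfe.rate_neg, size=n)
    return np.where(positive, mag_pos, -mag_neg)


# ---------------------------------------------------------------------------
# MA-phase selection-bias correction
# ---------------------------------------------------------------------------


def wahl_agashe_weight(s: np.ndarray | float, t_growth: float) -> np.ndarray | float:
    """Relative representation of a mutation with effect ``s`` after
    ``t_growth`` generations of deterministic colony doubling.

    ``w(s, t) = (2^(s t) - 1) / (t (2^s - 1))`` with the neutral limit
    ``w(0, t) = 1``.  ``w`` is strictly increasing in ``s``.
    """
    if t_growth < 1:
        raise ValueError("t_growth must be >= 1")
    s_arr = np.asarray(s, dtype=float)
    out = np.ones_like(s_arr)
    nz = s_arr != 0.0
    sz = s_arr[nz]
    out[nz] = np.expm1(sz * t_growth * math.log(2.0)) / (
        t_growth * np.expm1(sz * math.log(2.0))
    )
    if np.isscalar(s):
        return float(out)
    return out


def representation_weight_bruteforce(s: float, t_growth: int) -> float:
    """Brute-force oracle for :func:`wahl_agashe_weight`.

    Sums over the generation at which the mutation arises: the number of
    cell divisions in generation ``g`` of deterministic doubling growth is
    ``2^(g-1)``; a mutant arising then grows for ``t - g`` further
    generations with its per-generation growth factor scaled by ``1 + s``
    (i.e. ``2^(1+s)`` instead of 2).  The weight is the expected final mutant
    cell count relative to the neutral case.
    """
    t = int(t_growth)
    num = 0.0
    den = 0.0
    for g in range(1, t + 1):
        divisions = 2.0 ** (g - 1)
        num += divisions * 2.0 ** ((1.0 + s) * (t - g))
        den += divisions * 2.0 ** (t - g)
    return num / den


@dataclass(frozen=True)
class MABiasCorrection:
    """Result of the MA-phase selection-bias correction."""

    q_corrected: float
    s_grid: np.ndarray
    density_corrected: np.ndarray
    density_uncorrected: np.ndarray
    t_growth: float


def ma_bias_correct(
    dfe: TwoSidedGammaDFE,
    t_growth: float,
    s_min: float = -0.3,
    s_max: float = 0.3,
    n_grid: int = 2001,
) -> MABiasCorrection:
    """Correct an observed DFE for selection during MA colony growth.

    Divides the observed two-sided gamma density by the representation
    weight ``w(s, t_growth)``, renormalises by numerical quadrature on a
    fixed grid of ``s``, and returns the corrected positive mass ``q'`` and
    the corrected density on the grid.  Since ``w`` increases in ``s``,
    ``q' <= q`` for any DFE with mass on both sides.

    The default grid spans s in [-0.3, 0.3] with 2,001 points, covering
    essentially all mass of DFEs with mean |s| of a few percent.
    """
    s = np.linspace(s_min, s_max, n_grid)
    dens = np.asarray(dfe_density(s, dfe))
    w = np.asarray(wahl_agashe_weight(s, t_growth))
    corrected = dens / w
    if not np.all(np.isfinite(corrected[s != 0])):
        raise WeightDivergenceError(
            "corrected density is non-finite over the grid; the gamma tail "
            "outruns the representation weight (positive-side rate too small "
            f"for t_growth={t_growth})"
        )
    # The density is infinite at s=0 for shapes < 1; the singularity is
    # integrable and the trapezoid rule on a grid that brackets 0 without
    # hitting it exactly remains accurate.  Guard against an exact-zero node.
    corrected = np.where(np.isfinite(corrected), corrected, 0.0)
    dens_f = np.where(np.isfinite(dens), dens, 0.0)
    norm = np.trapezoid(corrected, s)
    corrected = corrected / norm
    pos_mass = np.trapezoid(np.where(s > 0, corrected, 0.0), s)
    return MABiasCorrection(
        q_corrected=float(pos_mass),
        s_grid=s,
        density_corrected=corrected,
        density_uncorrected=dens_f,
        t_growth=float(t_growth),
    )


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------


def write_dfe_config(dfe: TwoSidedGammaDFE, path: str | Path) -> None:
    """Write DFE parameters as a flat key=value file."""
    with open(path, "w") as fh:
        for key, value in dfe.to_dict().items():
            fh.write(f"{key}={value}\n")


def read_dfe_config(path: str | Path) -> TwoSidedGammaDFE:
    d: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            d[key.strip()] = value.strip()
    return TwoSidedGammaDFE.from_dict(d)


def write_density_tsv(
    path: str | Path,
    s_grid: np.ndarray,
    density: np.ndarray,
    header_lines: Iterable[str] = (),
) -> None:
    """Write a (s, density) table as two-column TSV with '#' headers."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("s\tdensity\n")
        for si, di in zip(s_grid, density):
            fh.write(f"{si:.10g}\t{di:.10g}\n")
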