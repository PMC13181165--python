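"""Synthetic weighted bipartite matrices with planted structure.

Three structures:

* ``Modular(k, mu_in, mu_out, sigma)`` — k contiguous row blocks matched to
  k contiguous column blocks; weights ~ Normal(mu_in, sigma) within a
  planted block pair and Normal(mu_out, sigma) between, clipped at 0 so the
  matrices stay CA-compatible.  All cells start observed.
* ``Nested(fill)`` — a perfect staircase: the fixed point of the isocline
  construction used by the temperature metric, so the generated mask scores
  T = 0 exactly.  Present cells carry Uniform(0.5, 1.5) weights; absent
  cells are missing.
* ``RandomFill(fill)`` — i.i.d. Bernoulli(fill) presences with
  Uniform(0.5, 1.5) weights.

Three missingness mechanisms applied on top of observed cells:

* ``MCAR(rate)`` — each observed cell masked independently;
* ``BlockMissing(regions)`` — listed rectangular regions masked entirely
  (block-MNAR, emulating the block-like gaps seen in survey/retail-style
  data);
* ``ThresholdMissing(tau)`` — cells with weight < tau masked
  (value-dependent, i.e. MNAR censoring).

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .incidence import IncidenceMatrix
from .structure import isocline_shape


# ----------------------------------------------------------------- structures
@dataclass
class Modular:
    k: int = 2
    mu_in: float = 10.0
    mu_out: float = 1.0
    sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not self.mu_in > self.mu_out >= 0:
            raise ValueError("need mu_in > mu_out >= 0")


@dataclass
class Nested:
    fill: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.fill < 1.0:
            raise ValueError("fill must be in (0, 1)")


@dataclass
class RandomFill:
    fill: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.fill < 1.0:
            raise ValueError("fill must be in (0, 1)")


Structure = Union[Modular, Nested, RandomFill]


# ---------------------------------------------------------------- missingness
@dataclass
class MCAR:
    rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate < 1.0:
            raise ValueError("rate must be in [0, 1)")


@dataclass
class BlockMissing:
    #: list of (row_start, row_stop, col_start, col_stop), stop exclusive
    regions: list[tuple[int, int, int, int]] = field(default_factory=list)


@dataclass
class ThresholdMissing:
    tau: float


Missingness = Union[MCAR, BlockMissing, ThresholdMissing]


def nested_mask(m: int, n: int, fill: float, max_iter: int = 100) -> np.ndarray:
    """Perfectly nested presence mask: fixed point of the isocline at its fill.

    Starting from the requested fill, the mask induced by the isocline is
    recomputed at its own empirical fill until stable; at the fixed point
    every presence lies on or above the isocline of the mask's own fill, so
    the nestedness temperature is exactly zero.
    """
    x = (np.arange(n) + 0.5) / n
    y = 1.0 - (np.arange(m) + 0.5) / m
    X, Y = np.meshgrid(x, y)
    f = float(fill)
    P = None
    for _ in range(max_iter):
        a = isocline_shape(f)
        P = (1.0 - X) ** a + Y**a >= 1.0
        new_f = float(P.mean())
        if new_f == f:
            break
        if new_f in (0.0, 1.0):
            raise ValueError("requested fill collapses to an empty/full mask")
        f = new_f
    return P


def simulate_bipartite(
    m: int,
    n: int,
    structure: Structure,
    missingness: Optional[Missingness] = None,
    seed: int = 0,
) -> tuple[IncidenceMatrix, dict]:
    """Generate an incidence matrix with planted structure and truth labels."""
    if m < 2 or n < 2:
        raise ValueError("need m >= 2 and n >= 2")
    rng = np.random.default_rng(seed)
    rows = [f"r{i:03d}" for i in range(m)]
    cols = [f"c{j:03d}" for j in range(n)]

    if isinstance(structure, Modular):
        row_blocks = np.minimum(np.arange(m) * structure.k // m, structure.k - 1)
        col_blocks = np.minimum(np.arange(n) * structure.k // n, structure.k - 1)
        same = row_blocks[:, None] == col_blocks[None, :]
        mu = np.where(same, structure.mu_in, structure.mu_out)
        A = np.clip(rng.normal(mu, structure.sigma), 0.0, None)
        mask = np.ones((m, n), dtype=bool)
        truth = {"row_blocks": row_blocks, "col_blocks": col_blocks}
    elif isinstance(structure, Nested):
        mask = nested_mask(m, n, structure.fill)
        A = np.where(mask, rng.uniform(0.5, 1.5, size=(m, n)), np.nan)
        truth = {"row_order": np.arange(m), "col_order": np.arange(n)}
    elif isinstance(structure, RandomFill):
        mask = rng.random((m, n)) < structure.fill
        if not mask.any():
            mask[0, 0] = True
        A = np.where(mask, rng.uniform(0.5, 1.5, size=(m, n)), np.nan)
        truth = {}
    else:
        raise TypeError(f"unknown structure {structure!r}")

    M = IncidenceMatrix(A=A, mask=mask, row_names=rows, col_names=cols, weighted=True)
    if missingness is not None:
        M = apply_missingness(M, missingness, seed=seed + 1)
    return M, truth


def apply_missingness(
    M: IncidenceMatrix, mechanism: Missingness, seed: int = 0
) -> IncidenceMatrix:
    """Mask observed cells according to the given mechanism (seeded)."""
    rng = np.random.default_rng(seed)
    mask = M.mask.copy()
    if isinstance(mechanism, MCAR):
        drop = (rng.random(mask.shape) < mechanism.rate) & mask
        mask &= ~drop
    elif isinstance(mechanism, BlockMissing):
        for r0, r1, c0, c1 in mechanism.regions:
            mask[r0:r1, c0:c1] = False
    elif isinstance(mechanism, ThresholdMissing):
        vals = np.nan_to_num(M.A, nan=np.inf)
        mask &= ~(vals < mechanism.tau)
    else:
        raise TypeError(f"unknown missingness mechanism {mechanism!r}")
    if not mask.any():
        raise ValueError("mechanism would mask every observed cell")
    return IncidenceMatrix(
        A=M.A,
        mask=mask,
        row_names=list(M.row_names),
        col_names=list(M.col_names),
        weighted=M.weighted,
    )
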