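"""Structure metrics for bipartite presence/absence patterns.

Three complementary views of how a boolean presence matrix (typically the
*observedness* mask of an incidence matrix) deviates from randomness:

* **Nestedness temperature** (Atmar–Patterson style): after canonical packing,
  each matrix cell is mapped into the unit square and scored by how far it
  sits on the wrong side of an *isocline* — the boundary of the perfectly
  nested arrangement with the same fill.  T = 0 for a perfectly nested
  staircase, up to 100 for maximally disordered patterns.

* **Modularity** Q of a node partition on a weighted graph (Newman–Girvan,
  weighted degrees): Q = sum_c (e_cc - a_c^2).

* **Runs-based permutation randomness test** on a categorical label sequence:
  the number of maximal constant-label runs is compared against random
  permutations of the same sequence (marginal label frequencies preserved);
  few runs mean clustered, non-random ordering.  The test is one-sided
  (lower tail) and p-values are corrected with Benjamini–Hochberg FDR.

Isocline geometry
-----------------
Cell (i, j) of the packed m x n matrix (1-based, row 1 on top) maps to
(x, y) = ((j - 0.5)/n, 1 - (i - 0.5)/m).  The isocline is the increasing
curve y = (1 - (1 - x)^a)^(1/a) from (0, 0) to (1, 1); the presence region
of a perfectly nested matrix is the area above it, which equals
1 - Gamma(1 + 1/a)^2 / Gamma(1 + 2/a), so the shape parameter ``a`` is
solved from the fill.  An *unexpected* cell is a presence strictly below the
curve or an absence strictly above it.  Its unexpectedness is
u = (d / D)^2 where d is the distance from the cell's point to the isocline
along the diagonal of slope -1 through the point and D is the length of that
diagonal inside the unit square.  U is the mean of u over *all* cells and
T = 100 * U / 0.04145, clipped to [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

#: classic Atmar-Patterson scaling constant: maximal attainable mean
#: unexpectedness, so that T spans [0, 100].
U_MAX = 0.04145

_SQRT2 = np.sqrt(2.0)


# --------------------------------------------------------------------- types
@dataclass
class PackedMatrix:
    row_order: np.ndarray
    col_order: np.ndarray
    fill: float


@dataclass
class TemperatureResult:
    T: float
    U: float
    fill: float
    unexpected_cells: list[tuple[int, int, float]] = field(default_factory=list)


@dataclass
class PermTestResult:
    observed_runs: int
    n_perm: int
    p_empirical: float
    seed: int
    p_adjusted: Optional[float] = None


# ------------------------------------------------------------------- packing
def pack_matrix(presence: np.ndarray, max_passes: int = 20) -> PackedMatrix:
    """Canonical packing: rows and columns sorted by decreasing presence count.

    Ties are broken by the summed opposite-margin counts over the line's
    presences, then by the line's presence pattern in the current opposite
    order (strong positions first), then by original index.  The pattern key
    makes the packed matrix invariant under row/column permutation of the
    input up to identical lines.  Sorting is iterated until both orders are
    stable or ``max_passes`` elapse.
    """
    P = np.asarray(presence, dtype=bool)
    if P.ndim != 2:
        raise ValueError("presence must be a 2-D boolean matrix")
    if not P.any():
        raise ValueError("cannot pack an all-empty presence matrix")
    m, n = P.shape
    rcnt = P.sum(axis=1)
    ccnt = P.sum(axis=0)
    rsec = P @ ccnt  # summed column counts over this row's presences
    csec = rcnt @ P

    def _order_lines(cnt, sec, patterns):
        # patterns: lines x opposite-dim booleans in current opposite order
        keys = [
            (-int(cnt[i]), -int(sec[i]), tuple(0 if v else 1 for v in patterns[i]), i)
            for i in range(len(cnt))
        ]
        return np.array(sorted(range(len(cnt)), key=lambda i: keys[i]), dtype=int)

    row_order = np.arange(m)
    col_order = np.arange(n)
    for _ in range(max_passes):
        new_rows = _order_lines(rcnt, rsec, P[:, col_order])
        new_cols = _order_lines(ccnt, csec, P[new_rows, :].T)
        if np.array_equal(new_rows, row_order) and np.array_equal(new_cols, col_order):
            break
        row_order, col_order = new_rows, new_cols
    return PackedMatrix(row_order=row_order, col_order=col_order, fill=float(P.mean()))


# --------------------------------------------------------------- temperature
def isocline_shape(fill: float) -> float:
    """Shape parameter ``a`` with area above the isocline equal to ``fill``."""
    if not 0.0 < fill < 1.0:
        raise ValueError("fill must lie strictly between 0 and 1")

    def area_below(a: float) -> float:
        # integral_0^1 (1-(1-x)^a)^(1/a) dx = Gamma(1+1/a)^2 / Gamma(1+2/a)
        return float(np.exp(2.0 * gammaln(1.0 + 1.0 / a) - gammaln(1.0 + 2.0 / a)))

    def f(log_a: float) -> float:
        return (1.0 - area_below(np.exp(log_a))) - fill

    lo, hi = np.log(1e-6), np.log(1e6)
    return float(np.exp(brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)))


def isocline_y(x: np.ndarray, a: float) -> np.ndarray:
    """Isocline height y = (1-(1-x)^a)^(1/a)."""
    x = np.asarray(x, dtype=float)
    return (1.0 - (1.0 - x) ** a) ** (1.0 / a)


def _diagonal_crossing(a: float, c: np.ndarray, iters: int = 80) -> np.ndarray:
    """x-coordinate where the isocline meets the diagonal x + y = c.

    The isocline increases from (0,0) to (1,1), so g(x) = F(x) + x - c is
    strictly increasing and each diagonal has exactly one crossing; solved by
    vectorised bisection.
    """
    c = np.asarray(c, dtype=float)
    lo = np.maximum(0.0, c - 1.0)
    hi = np.minimum(1.0, c)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        g = isocline_y(mid, a) + mid - c
        take_lo = g < 0.0
        lo = np.where(take_lo, mid, lo)
        hi = np.where(take_lo, hi, mid)
    return 0.5 * (lo + hi)


def nestedness_temperature(
    presence: np.ndarray, on_curve_tol: float = 1e-12
) -> TemperatureResult:
    """Atmar–Patterson-style nestedness temperature of a presence matrix.

    The matrix is packed first, so the result is invariant under row/column
    permutation of the input.  Fully empty or fully full matrices return
    T = 0 by convention.  Cells whose centre lies on the isocline (within
    ``on_curve_tol`` in the signed superellipse residual) are not unexpected.
    """
    P = np.asarray(presence, dtype=bool)
    if P.ndim != 2 or min(P.shape) < 2:
        raise ValueError("temperature needs a matrix of at least 2x2")
    m, n = P.shape
    fill = float(P.mean())
    if fill in (0.0, 1.0):
        return TemperatureResult(T=0.0, U=0.0, fill=fill)
    packed = pack_matrix(P)
    Pp = P[np.ix_(packed.row_order, packed.col_order)]
    a = isocline_shape(fill)

    x = (np.arange(n) + 0.5) / n
    y = 1.0 - (np.arange(m) + 0.5) / m
    X, Y = np.meshgrid(x, y)
    # signed residual: s > 0 above the curve, s < 0 below
    s = (1.0 - X) ** a + Y**a - 1.0
    above = s > on_curve_tol
    below = s < -on_curve_tol
    unexpected = (Pp & below) | (~Pp & above)

    C = X + Y
    xc = _diagonal_crossing(a, C)
    d = np.abs(X - xc) * _SQRT2
    D = np.where(C <= 1.0, C, 2.0 - C) * _SQRT2
    u = np.where(unexpected, (d / D) ** 2, 0.0)
    U = float(u.mean())
    T = float(np.clip(100.0 * U / U_MAX, 0.0, 100.0))
    cells = [
        (int(i), int(j), float(u[i, j]))
        for i, j in zip(*np.nonzero(unexpected))
    ]
    return TemperatureResult(T=T, U=U, fill=fill, unexpected_cells=cells)


# ---------------------------------------------------------------- modularity
def modularity(graph, membership: Sequence[int]) -> float:
    """Newman–Girvan modularity Q = sum_c (e_cc - a_c^2) with edge weights.

    ``graph`` is an undirected igraph Graph (optionally with a ``weight``
    edge attribute); ``membership`` assigns every vertex a community id.
    """
    if graph.ecount() == 0:
        raise ValueError("modularity needs a graph with at least one edge")
    if len(membership) != graph.vcount():
        raise ValueError("membership must cover every node")
    mem = np.asarray(membership)
    if "weight" in graph.es.attributes():
        w = np.asarray(graph.es["weight"], dtype=float)
    else:
        w = np.ones(graph.ecount())
    src = np.array([e.source for e in graph.es])
    tgt = np.array([e.target for e in graph.es])
    total = w.sum()  # sum of edge weights; 2*total = total degree
    comms = np.unique(mem)
    Q = 0.0
    for cid in comms:
        in_c = (mem[src] == cid) & (mem[tgt] == cid)
        e_cc = w[in_c].sum() / total
        # weighted degree of the community / total degree
        deg = w[(mem[src] == cid)].sum() + w[(mem[tgt] == cid)].sum()
        a_c = deg / (2.0 * total)
        Q += e_cc - a_c**2
    return float(Q)


# ----------------------------------------------------------------- runs test
def count_runs(labels: Sequence) -> int:
    """Number of maximal constant-label runs in a sequence."""
    arr = np.asarray(labels)
    if arr.size == 0:
        raise ValueError("empty label sequence")
    if arr.size == 1:
        return 1
    return int(1 + np.sum(arr[1:] != arr[:-1]))


def runs_permutation_test(
    labels: Sequence, n_perm: int = 5000, seed: int = 0
) -> PermTestResult:
    """Lower-tail permutation test on the number of label runs.

    The observed sequence is compared against ``n_perm`` uniform random
    permutations of itself (marginal label frequencies preserved).  Fewer
    runs than expected indicate clustered, non-random label order, so the
    empirical p-value is p = (1 + #{runs_perm <= runs_obs}) / (n_perm + 1);
    its floor is 1/(n_perm+1).
    """
    arr = np.asarray(labels)
    if arr.size < 2:
        raise ValueError("runs test needs a sequence of length >= 2")
    _, codes = np.unique(arr, return_inverse=True)
    observed = count_runs(codes)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)
    runs = 1 + (perms[:, 1:] != perms[:, :-1]).sum(axis=1)
    p = (1 + int((runs <= observed).sum())) / (n_perm + 1)
    return PermTestResult(
        observed_runs=observed, n_perm=n_perm, p_empirical=float(p), seed=seed
    )


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return [float(v) for v in multipletests(p, method="fdr_bh")[1]]


def significance_code(p: float) -> str:
    """Conventional significance stars: *** <0.001, ** <0.01, * <0.05, ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
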