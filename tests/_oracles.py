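"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths of the package: the temperature
oracle solves the isocline shape by bisection on a numerically integrated
area (scipy.integrate.quad, not the closed form) and walks every cell with
scalar bisection; the submatrix oracles enumerate subsets exhaustively; the
pair-counting oracle enumerates node pairs one by one.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import quad

U_MAX = 0.04145


def _curve(x: float, a: float) -> float:
    return (1.0 - (1.0 - x) ** a) ** (1.0 / a)


def _fill_of_shape(a: float) -> float:
    below, _ = quad(lambda t: _curve(t, a), 0.0, 1.0, epsabs=1e-13, epsrel=1e-13)
    return 1.0 - below


def _solve_shape(fill: float) -> float:
    lo, hi = math.log(1e-6), math.log(1e6)
    # fill decreases with a, so _fill_of_shape(exp(lo)) > fill > at exp(hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _fill_of_shape(math.exp(mid)) > fill:
            lo = mid
        else:
            hi = mid
    return math.exp(0.5 * (lo + hi))


def _crossing(a: float, c: float) -> float:
    lo = max(0.0, c - 1.0)
    hi = min(1.0, c)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _curve(mid, a) + mid - c < 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def pack_counts(P: np.ndarray) -> np.ndarray:
    """Plain count-sorted packing (stable): enough for oracle geometry when
    combined with the same tie rules as the implementation is not required —
    the oracle receives the *packed* matrix from the caller."""
    return P


def temperature_oracle(packed: np.ndarray) -> float:
    """Temperature of an already-packed presence matrix, cell by cell."""
    P = np.asarray(packed, dtype=bool)
    m, n = P.shape
    fill = float(P.mean())
    if fill in (0.0, 1.0):
        return 0.0
    a = _solve_shape(fill)
    total = 0.0
    for i in range(m):
        for j in range(n):
            x = (j + 0.5) / n
            y = 1.0 - (i + 0.5) / m
            s = (1.0 - x) ** a + y**a - 1.0
            if abs(s) <= 1e-12:
                continue
            above = s > 0.0
            if P[i, j] == above:
                continue  # expected cell
            c = x + y
            xc = _crossing(a, c)
            d = abs(x - xc) * math.sqrt(2.0)
            D = (c if c <= 1.0 else 2.0 - c) * math.sqrt(2.0)
            total += (d / D) ** 2
    U = total / (m * n)
    return float(min(100.0, max(0.0, 100.0 * U / U_MAX)))


def exhaustive_element_max(mask: np.ndarray) -> int:
    """Exact largest complete block (cells) by row-subset enumeration."""
    m, n = mask.shape
    best = 0
    for r in range(1, 2**m):
        rows = [i for i in range(m) if r >> i & 1]
        cols = int(mask[rows].all(axis=0).sum())
        best = max(best, len(rows) * cols)
    return best


def exhaustive_square(mask: np.ndarray) -> int:
    """Exact largest complete square block (cells)."""
    m, n = mask.shape
    best = 0
    for r in range(1, 2**m):
        rows = [i for i in range(m) if r >> i & 1]
        cols = int(mask[rows].all(axis=0).sum())
        best = max(best, min(len(rows), cols) ** 2)
    return best


def brute_force_pair_counts(labels1, labels2) -> tuple[int, int, int, int]:
    """(a, b, c, d) by explicit enumeration of all unordered node pairs."""
    n = len(labels1)
    a = b = c = d = 0
    for i, j in itertools.combinations(range(n), 2):
        same1 = labels1[i] == labels1[j]
        same2 = labels2[i] == labels2[j]
        if same1 and same2:
            a += 1
        elif same1:
            b += 1
        elif same2:
            c += 1
        else:
            d += 1
    return a, b, c, d


def brute_force_silhouette(D: np.ndarray, labels) -> float:
    """Average silhouette width straight from the definition."""
    labels = np.asarray(labels)
    n = len(labels)
    vals = []
    for i in range(n):
        own = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not own:
            vals.append(0.0)
            continue
        a = float(np.mean([D[i, j] for j in own]))
        bs = []
        for other in set(labels.tolist()) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == other]
            bs.append(float(np.mean([D[i, j] for j in members])))
        b = min(bs)
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def exact_runs_lower_tail_p(labels) -> float:
    """Exact lower-tail probability of the run count over all distinct
    arrangements of the multiset of labels (small sequences only)."""
    labels = list(labels)

    def runs(seq):
        return 1 + sum(1 for x, y in zip(seq, seq[1:]) if x != y)

    observed = runs(labels)
    arrangements = set(itertools.permutations(labels))
    le = sum(1 for arr in arrangements if runs(list(arr)) <= observed)
    return le / len(arrangements)
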