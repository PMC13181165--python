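"""Pair-counting contingency shared by internal and external validation.

For two partitions of the same n nodes, every unordered node pair falls in
one of four bins: a — co-clustered in both; b — co-clustered in the first
only; c — co-clustered in the second only; d — separated in both.  All
pair-counting agreement indices (Rand, Jaccard, Dice, Fowlkes–Mallows,
Minkowski) derive from these counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics.cluster import pair_confusion_matrix


@dataclass
class PairCounts:
    a: int
    b: int
    c: int
    d: int

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def pair_counts_from_labels(first: Sequence, second: Sequence) -> PairCounts:
    """Pair counts with the *first* partition as reference (rows of b/c)."""
    if len(first) != len(second):
        raise ValueError("partitions must label the same nodes")
    if len(first) < 2:
        raise ValueError("need at least two nodes to count pairs")
    _, f = np.unique(np.asarray(first, dtype=object), return_inverse=True)
    _, s = np.unique(np.asarray(second, dtype=object), return_inverse=True)
    # sklearn counts ordered pairs: halve to get unordered pair counts
    C = pair_confusion_matrix(f, s)
    return PairCounts(
        a=int(C[1, 1] // 2),
        b=int(C[1, 0] // 2),
        c=int(C[0, 1] // 2),
        d=int(C[0, 0] // 2),
    )
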