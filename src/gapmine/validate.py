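"""Structure-preservation scoring of imputation methods.

An imputation method is judged not by reconstruction error but by whether
the clustering of the *imputed* network reproduces the clustering of the
complete-submatrix benchmark — the largest missing-free block of the input,
whose projection is clustered once (same algorithm and seed for benchmark
and candidates, so score differences reflect imputation alone).  Agreement
is measured on the benchmark's node set with five pair-counting indices:

    rand      = (a + d) / (a + b + c + d)
    jaccard   = a / (a + b + c)
    dice      = 2a / (2a + b + c)
    fowlkes_mallows = a / sqrt((a + b)(a + c))
    minkowski = sqrt((b + c) / (a + b))          (lower is better)

Methods are ranked by the chosen index (default Jaccard; Minkowski is
inverted for ranking).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from ._pairs import PairCounts, pair_counts_from_labels
from .impute import METHODS, impute
from .incidence import IncidenceMatrix
from .projection import _normalize_part, _run_method, project
from .submatrix import extract_submatrix

INDEX_NAMES = ("dice", "fowlkes_mallows", "jaccard", "minkowski", "rand")


def pair_counts(
    membership1: dict[str, int],
    membership2: dict[str, int],
    shared_nodes: Sequence[str],
) -> PairCounts:
    """Pair counts over ``shared_nodes`` (membership1 is the benchmark)."""
    nodes = list(shared_nodes)
    if len(nodes) < 2:
        raise ValueError("need at least two shared nodes")
    m1 = [membership1[v] for v in nodes]
    m2 = [membership2[v] for v in nodes]
    return pair_counts_from_labels(m1, m2)


def comparison_indices(pc: PairCounts) -> dict[str, float]:
    """The five pair-counting indices, with degenerate denominators handled."""
    a, b, c, d = pc.a, pc.b, pc.c, pc.d
    rand = (a + d) / pc.total
    jaccard = a / (a + b + c) if (a + b + c) else 0.0
    dice = 2 * a / (2 * a + b + c) if (2 * a + b + c) else 0.0
    fm = a / math.sqrt((a + b) * (a + c)) if a else 0.0
    minkowski = math.sqrt((b + c) / (a + b)) if (a + b) else float("nan")
    return {
        "dice": dice,
        "fowlkes_mallows": fm,
        "jaccard": jaccard,
        "minkowski": minkowski,
        "rand": rand,
    }


@dataclass
class ValidationReport:
    per_method: dict[str, dict[str, float]]
    ranking: Optional[list[str]]
    benchmark: dict
    seed: int

    def to_json(self) -> str:
        payload = {
            "benchmark": self.benchmark,
            "per_method": self.per_method,
            "ranking": self.ranking,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)


def validate_edge_prediction(
    M: IncidenceMatrix,
    methods: Sequence[str] = METHODS,
    part: str = "V",
    cluster_method: str = "multilevel",
    seed: int = 0,
    ranking_index: str = "jaccard",
    impute_kwargs: Optional[dict[str, dict]] = None,
) -> ValidationReport:
    """Score imputation methods by clustering agreement with the benchmark.

    Pipeline: (1) extract the element-max complete submatrix; (2) project
    its chosen part and cluster it — the benchmark membership; (3) impute
    the full matrix with each method, project, cluster with the same
    algorithm and seed, restrict to the benchmark node set; (4) pair-count
    agreement; (5) rank.  A degenerate benchmark (single cluster) yields a
    report with NaN indices and no ranking.
    """
    if ranking_index not in INDEX_NAMES:
        raise ValueError(f"ranking_index must be one of {INDEX_NAMES}")
    impute_kwargs = impute_kwargs or {}
    sub = extract_submatrix(M, "Rectangular_element_max")
    bench_M = sub.block(M)
    part_key = _normalize_part(part)
    bench_nodes = (
        sub.row_names(M) if part_key == "V" else sub.col_names(M)
    )
    if len(bench_nodes) < 3:
        raise ValueError("benchmark submatrix too small (< 3 nodes in the part)")
    bench_G = project(bench_M, part_key)
    bench_mem_list = _run_method(bench_G.graph, cluster_method, seed)
    bench_mem = {bench_G.names[i]: int(c) for i, c in enumerate(bench_mem_list)}
    benchmark_info = {
        "mode": sub.mode,
        "n_rows": int(sub.rows.size),
        "n_cols": int(sub.cols.size),
        "part": part_key,
        "cluster_method": cluster_method,
        "n_clusters": len(set(bench_mem.values())),
    }
    degenerate = len(set(bench_mem.values())) < 2

    per_method: dict[str, dict[str, float]] = {}
    for name in methods:
        kwargs = dict(impute_kwargs.get(name, {}))
        if name == "als":
            kwargs.setdefault("seed", seed)
        completed = impute(M, name, **kwargs)
        full = completed.to_incidence(M)
        G = project(full, part_key)
        mem_list = _run_method(G.graph, cluster_method, seed)
        mem = {G.names[i]: int(c) for i, c in enumerate(mem_list)}
        if degenerate:
            per_method[name] = {k: float("nan") for k in INDEX_NAMES}
            continue
        pc = pair_counts(bench_mem, mem, bench_nodes)
        per_method[name] = comparison_indices(pc)

    if degenerate:
        ranking = None
    else:
        sign = 1.0 if ranking_index == "minkowski" else -1.0

        def _key(name: str):
            v = per_method[name][ranking_index]
            if math.isnan(v):
                v = math.inf if ranking_index == "minkowski" else -math.inf
            return (sign * v, list(methods).index(name))

        ranking = sorted(methods, key=_key)
    return ValidationReport(
        per_method=per_method,
        ranking=list(ranking) if ranking is not None else None,
        benchmark=benchmark_info,
        seed=seed,
    )
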