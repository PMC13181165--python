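"""Nominal long tables and bipartite incidence matrices.

A dataset of paired nominal observations ``(x_i, y_i)`` — optionally carrying a
numeric weight — is modelled as a bipartite network over two disjoint node sets
``V`` (rows) and ``W`` (columns).  Its connectivity is stored in a biadjacency
(incidence) matrix ``A`` together with an explicit boolean mask distinguishing
*observed* cells from *missing* ones.  Missing cells are unknown interactions,
never true zeros: a zero weight is a valid observation and is kept distinct
from a missing cell throughout the package.

This module covers the plumbing around that central object: reading long
CSV/TSV tables, aggregating them into an incidence matrix, summarising the
missingness, degree filtering, and on-disk round trips (TSV with empty cells
for missing values, or MatrixMarket plus a sidecar mask).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

#: weight tokens treated as missing; such records are dropped (the pair is
#: treated as unobserved, not as an unweighted observation).
NA_TOKENS = {"", "na", "nan", "null", "none", "n/a"}

AGGREGATIONS = ("mean", "median", "sum", "first")


@dataclass
class NominalTable:
    """Long-format list of nominal pairs with optional numeric weights."""

    records: list[tuple[str, str, Optional[float]]]
    weighted: bool

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("a nominal table needs at least one record")
        for r, c, w in self.records:
            if not r or not c:
                raise ValueError("labels must be non-empty strings")
            if self.weighted and (w is None or not np.isfinite(w)):
                raise ValueError("weighted table with non-finite weight")


@dataclass
class IncidenceSummary:
    n_rows: int
    n_cols: int
    n_observed: int
    n_missing: int
    prop_nonmissing: float
    weighted: bool
    weight_range: Optional[tuple[float, float]] = None

    def to_dict(self) -> dict:
        d = {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "n_observed": self.n_observed,
            "n_missing": self.n_missing,
            "prop_nonmissing": self.prop_nonmissing,
            "weighted": self.weighted,
        }
        if self.weight_range is not None:
            d["weight_min"], d["weight_max"] = self.weight_range
        return d


@dataclass
class IncidenceMatrix:
    """Biadjacency matrix ``A`` over row set V and column set W with a mask.

    ``A[i, j]`` is meaningful only where ``mask[i, j]`` is True; unobserved
    cells hold NaN.  Row and column names are unique and keep first-appearance
    order so that all outputs are reproducible byte for byte.
    """

    A: np.ndarray
    mask: np.ndarray
    row_names: list[str]
    col_names: list[str]
    weighted: bool = True

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.A.ndim != 2 or self.A.shape != self.mask.shape:
            raise ValueError("A and mask must be 2-D arrays of equal shape")
        m, n = self.A.shape
        if m < 1 or n < 1:
            raise ValueError("incidence matrix must be at least 1x1")
        if len(self.row_names) != m or len(self.col_names) != n:
            raise ValueError("name lengths must match the matrix shape")
        if len(set(self.row_names)) != m or len(set(self.col_names)) != n:
            raise ValueError("row and column names must be unique")
        if not self.mask.any():
            raise ValueError("incidence matrix must have at least one observed cell")
        # unobserved cells are excluded from all statistics: pin them to NaN
        self.A = np.where(self.mask, self.A, np.nan)

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape

    def presence(self, criterion: str = "observed") -> np.ndarray:
        """Boolean presence matrix used by the structure metrics.

        ``observed`` — presence means the cell is not missing (the default:
        the metrics then characterise the missingness pattern itself);
        ``positive`` — presence means an observed, strictly positive weight
        (ecological binary use).
        """
        if criterion == "observed":
            return self.mask.copy()
        if criterion == "positive":
            return self.mask & (np.nan_to_num(self.A, nan=0.0) > 0)
        raise ValueError(f"unknown presence criterion: {criterion!r}")

    def values_filled(self, fill: float = 0.0) -> np.ndarray:
        """Dense weight matrix with missing cells replaced by ``fill``."""
        return np.where(self.mask, np.nan_to_num(self.A, nan=fill), fill)

    def to_table(self) -> NominalTable:
        """Long-table view of the observed cells (inverse of build_incidence)."""
        recs = []
        for i, j in zip(*np.nonzero(self.mask)):
            w = float(self.A[i, j]) if self.weighted else None
            recs.append((self.row_names[i], self.col_names[j], w))
        return NominalTable(records=recs, weighted=self.weighted)

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.A, index=self.row_names, columns=self.col_names)
        df.to_csv(path, sep="\t", na_rep="")

    @classmethod
    def from_tsv(cls, path: str | Path, weighted: bool = True) -> "IncidenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        A = df.to_numpy(dtype=float)
        mask = np.isfinite(A)
        return cls(
            A=A,
            mask=mask,
            row_names=[str(x) for x in df.index],
            col_names=[str(x) for x in df.columns],
            weighted=weighted,
        )

    def to_mtx(self, path: str | Path, mask_path: str | Path) -> None:
        """MatrixMarket export: values (missing as 0) plus a 0/1 sidecar mask.

        The sidecar mask is what preserves observed zero weights across the
        sparse round trip.
        """
        vals = scipy.sparse.coo_matrix(self.values_filled(0.0))
        scipy.io.mmwrite(str(path), vals)
        scipy.io.mmwrite(str(mask_path), scipy.sparse.coo_matrix(self.mask.astype(int)))

    @classmethod
    def from_mtx(
        cls,
        path: str | Path,
        mask_path: str | Path,
        row_names: Optional[Sequence[str]] = None,
        col_names: Optional[Sequence[str]] = None,
        weighted: bool = True,
    ) -> "IncidenceMatrix":
        A = np.asarray(scipy.io.mmread(str(path)).todense(), dtype=float)
        mask = np.asarray(scipy.io.mmread(str(mask_path)).todense()) != 0
        m, n = A.shape
        rows = list(row_names) if row_names is not None else [f"r{i}" for i in range(m)]
        cols = list(col_names) if col_names is not None else [f"c{j}" for j in range(n)]
        return cls(A=A, mask=mask, row_names=rows, col_names=cols, weighted=weighted)


def read_nominal_table(
    path: str | Path,
    col_spec: Optional[Sequence] = None,
    delimiter: Optional[str] = None,
    header: bool = False,
) -> NominalTable:
    """Read a 2- or 3-column long-format nominal table.

    The first two resolved columns are the nominal labels; an optional third
    column is a numeric edge weight.  Lines whose weight token is an NA
    sentinel ("", "NA", "NaN", "null", ...) are dropped: the pair is treated
    as unobserved rather than as an observed unweighted edge.  Lines with a
    missing label are likewise dropped.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(
        path,
        sep=delimiter,
        header=0 if header else None,
        dtype=str,
        keep_default_na=False,
        skip_blank_lines=True,
    )
    if col_spec is not None:
        if all(isinstance(c, int) for c in col_spec):
            df = df.iloc[:, list(col_spec)]
        else:
            df = df.loc[:, list(col_spec)]
    if df.shape[1] < 2:
        raise ValueError("need at least two nominal columns")
    if df.shape[1] > 3:
        raise ValueError(
            "more than three columns: pass col_spec to pick the two label "
            "columns and the optional weight column"
        )
    weighted = df.shape[1] == 3
    records: list[tuple[str, str, Optional[float]]] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        r, c = str(row[0]).strip(), str(row[1]).strip()
        if r.lower() in NA_TOKENS or c.lower() in NA_TOKENS:
            n_dropped += 1
            continue
        if weighted:
            tok = str(row[2]).strip()
            if tok.lower() in NA_TOKENS:
                n_dropped += 1
                continue
            try:
                w = float(tok)
            except ValueError as exc:
                raise ValueError(f"weight token {tok!r} is not numeric") from exc
            if not np.isfinite(w):
                n_dropped += 1
                continue
            records.append((r, c, w))
        else:
            records.append((r, c, None))
    if n_dropped:
        logger.info("dropped %d record(s) with missing label or weight", n_dropped)
    if not records:
        raise ValueError("all rows dropped; no observed pairs remain")
    return NominalTable(records=records, weighted=weighted)


def build_incidence(table: NominalTable, agg: str = "mean") -> IncidenceMatrix:
    """Aggregate a nominal table into an incidence matrix.

    Rows/columns appear in first-appearance order.  Duplicated (row, col)
    pairs are combined by ``agg`` (default mean, with the duplicate count
    logged); unweighted tables produce a binary matrix with 1 on observed
    cells.
    """
    if agg not in AGGREGATIONS:
        raise ValueError(f"agg must be one of {AGGREGATIONS}")
    rows = list(dict.fromkeys(r for r, _, _ in table.records))
    cols = list(dict.fromkeys(c for _, c, _ in table.records))
    ri = {r: i for i, r in enumerate(rows)}
    ci = {c: j for j, c in enumerate(cols)}
    m, n = len(rows), len(cols)
    mask = np.zeros((m, n), dtype=bool)
    if not table.weighted:
        for r, c, _ in table.records:
            mask[ri[r], ci[c]] = True
        A = np.where(mask, 1.0, np.nan)
        return IncidenceMatrix(A, mask, rows, cols, weighted=False)

    buckets: dict[tuple[int, int], list[float]] = {}
    for r, c, w in table.records:
        buckets.setdefault((ri[r], ci[c]), []).append(float(w))
    n_dup = sum(len(v) - 1 for v in buckets.values())
    if n_dup:
        logger.info("aggregated %d duplicate pair(s) with agg=%s", n_dup, agg)
    A = np.full((m, n), np.nan)
    for (i, j), vals in buckets.items():
        mask[i, j] = True
        if agg == "mean":
            A[i, j] = float(np.mean(vals))
        elif agg == "median":
            A[i, j] = float(np.median(vals))
        elif agg == "sum":
            A[i, j] = float(np.sum(vals))
        else:  # first
            A[i, j] = vals[0]
    return IncidenceMatrix(A, mask, rows, cols, weighted=True)


def summarize_incidence(M: IncidenceMatrix) -> IncidenceSummary:
    m, n = M.shape
    n_obs = int(M.mask.sum())
    wr = None
    if M.weighted:
        obs = M.A[M.mask]
        wr = (float(np.min(obs)), float(np.max(obs)))
    return IncidenceSummary(
        n_rows=m,
        n_cols=n,
        n_observed=n_obs,
        n_missing=m * n - n_obs,
        prop_nonmissing=n_obs / (m * n),
        weighted=M.weighted,
        weight_range=wr,
    )


def filter_by_degree(
    M: IncidenceMatrix,
    min_row_deg: int = 0,
    min_col_deg: int = 0,
    iterative: bool = True,
) -> IncidenceMatrix:
    """Drop low-degree rows/columns (degree = count of observed cells).

    One pass removes, simultaneously, every row below ``min_row_deg`` and
    every column below ``min_col_deg``.  With ``iterative=True`` (default)
    passes repeat, with degrees recomputed, until the surviving core is
    stable — removal of a column can push a row below its threshold, so the
    two modes genuinely differ.  Raises if filtering empties the matrix.
    """
    if min_row_deg < 0 or min_col_deg < 0:
        raise ValueError("degree thresholds must be non-negative")
    keep_r = np.arange(M.shape[0])
    keep_c = np.arange(M.shape[1])
    while True:
        sub = M.mask[np.ix_(keep_r, keep_c)]
        ok_r = sub.sum(axis=1) >= min_row_deg
        ok_c = sub.sum(axis=0) >= min_col_deg
        if ok_r.all() and ok_c.all():
            break
        keep_r = keep_r[ok_r]
        keep_c = keep_c[ok_c]
        if keep_r.size == 0 or keep_c.size == 0:
            raise ValueError("degree filtering emptied the matrix")
        if not iterative:
            break
    return IncidenceMatrix(
        A=M.A[np.ix_(keep_r, keep_c)],
        mask=M.mask[np.ix_(keep_r, keep_c)],
        row_names=[M.row_names[i] for i in keep_r],
        col_names=[M.col_names[j] for j in keep_c],
        weighted=M.weighted,
    )


def write_summary_json(summary: IncidenceSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n")
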