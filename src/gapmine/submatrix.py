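"""Approximate largest complete (missing-free) submatrix extraction.

Finding the largest row/column submatrix without missing values is NP-hard,
so a deterministic heuristic portfolio is used, combining two iterative
reordering strategies driven by row/column missing counts:

* **greedy peel** — lines (rows/columns) containing missing cells are
  removed one at a time, most-missing first, preferring the removal that
  keeps the shape objective largest, until the working block is complete;
* **forward selection** — lines are added one at a time in the order that
  maximises the resulting complete block, sweeping both orientations and
  keeping the best prefix.

Every candidate then goes through a fixpoint *re-add* pass that restores any
removed line fully observed on the surviving block, so results are always
missing-free and maximal (no single removed line can be re-added), and
identical inputs yield identical outputs.

Four shape objectives are supported:

* ``Rectangular_element_max`` — maximise the number of cells (either
  dimension may shrink);
* ``Square`` — maximise the side of a square block;
* ``Rectangular_row`` — keep *all* columns, drop incomplete rows;
* ``Rectangular_col`` — keep *all* rows, drop incomplete columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .incidence import IncidenceMatrix

MODES = ("Square", "Rectangular_row", "Rectangular_col", "Rectangular_element_max")


@dataclass
class SubmatrixResult:
    mode: str
    rows: np.ndarray  # original row indices, packed order
    cols: np.ndarray  # original column indices, packed order
    n_cells: int
    proportion_of_rows: float

    def row_names(self, M: IncidenceMatrix) -> list[str]:
        return [M.row_names[i] for i in self.rows]

    def col_names(self, M: IncidenceMatrix) -> list[str]:
        return [M.col_names[j] for j in self.cols]

    def block(self, M: IncidenceMatrix) -> IncidenceMatrix:
        return IncidenceMatrix(
            A=M.A[np.ix_(self.rows, self.cols)],
            mask=M.mask[np.ix_(self.rows, self.cols)],
            row_names=self.row_names(M),
            col_names=self.col_names(M),
            weighted=M.weighted,
        )


# ------------------------------------------------------------------ internals
def _score(mode: str, r: int, c: int) -> int:
    return min(r, c) ** 2 if mode == "Square" else r * c


def _peel(mask: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Most-missing-first peeling until the alive block is complete."""
    m, n = mask.shape
    alive_r = np.ones(m, dtype=bool)
    alive_c = np.ones(n, dtype=bool)
    while True:
        sub_missing = ~mask[np.ix_(alive_r, alive_c)]
        if not sub_missing.any():
            break
        r, c = sub_missing.shape
        row_ids = np.flatnonzero(alive_r)
        col_ids = np.flatnonzero(alive_c)
        row_miss = sub_missing.sum(axis=1)
        col_miss = sub_missing.sum(axis=0)
        candidates = []
        # key: most missing; largest post-removal objective; remove from the
        # larger dimension; rows before columns; lowest original index
        if r > 1:
            for k in np.flatnonzero(row_miss > 0):
                candidates.append(
                    (-int(row_miss[k]), -_score(mode, r - 1, c), -r, 0,
                     int(row_ids[k]), "row")
                )
        if c > 1:
            for k in np.flatnonzero(col_miss > 0):
                candidates.append(
                    (-int(col_miss[k]), -_score(mode, r, c - 1), -c, 1,
                     int(col_ids[k]), "col")
                )
        if not candidates:
            # degenerate 1x1 corner still missing: fall back to the first
            # observed cell of the matrix
            oi, oj = np.argwhere(mask)[0]
            alive_r[:] = False
            alive_c[:] = False
            alive_r[oi] = True
            alive_c[oj] = True
            break
        candidates.sort()
        _, _, _, _, idx, kind = candidates[0]
        if kind == "row":
            alive_r[idx] = False
        else:
            alive_c[idx] = False
    return alive_r, alive_c


def _forward(mask: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Forward line selection, both orientations; best prefix block wins."""
    best = (-1, None, None)
    for transposed in (False, True):
        W = mask.T if transposed else mask
        m, n = W.shape
        avail = np.ones(m, dtype=bool)
        chosen: list[int] = []
        cum = np.ones(n, dtype=bool)
        while avail.any() and cum.any():
            ids = np.flatnonzero(avail)
            gains = (W[ids] & cum).sum(axis=1)
            k = ids[int(np.argmax(gains))]  # argmax takes the lowest index on ties
            chosen.append(int(k))
            avail[k] = False
            cum = cum & W[k]
            cols = np.flatnonzero(cum)
            score = _score(mode, len(chosen), cols.size)
            if score > best[0]:
                rows_sel = np.zeros(m, dtype=bool)
                rows_sel[chosen] = True
                cols_sel = np.zeros(n, dtype=bool)
                cols_sel[cols] = True
                if transposed:
                    best = (score, cols_sel, rows_sel)
                else:
                    best = (score, rows_sel, cols_sel)
    if best[1] is None:  # no observed cell reachable; caller guards this
        raise ValueError("matrix has no observed cell")
    return best[1].copy(), best[2].copy()


def _readd(mask, alive_r, alive_c) -> None:
    """Fixpoint restoration of removed lines complete on the survivors."""
    changed = True
    while changed:
        changed = False
        for i in np.flatnonzero(~alive_r):
            if mask[i, alive_c].all():
                alive_r[i] = True
                changed = True
        for j in np.flatnonzero(~alive_c):
            if mask[alive_r, j].all():
                alive_c[j] = True
                changed = True


def _squarify(mask, alive_r, alive_c) -> None:
    """Trim the larger dimension to a square, then re-add in (row, col) pairs.

    Trimming keeps lines with more observed cells in the original matrix
    (ties by lowest index); pair re-adds keep the block square and maximal
    in the paired sense.
    """

    def _trim(alive, counts, side):
        ids = sorted(np.flatnonzero(alive), key=lambda i: (-int(counts[i]), i))
        for i in ids[side:]:
            alive[i] = False

    side = int(min(alive_r.sum(), alive_c.sum()))
    _trim(alive_r, mask.sum(axis=1), side)
    _trim(alive_c, mask.sum(axis=0), side)
    changed = True
    while changed:
        changed = False
        for i in np.flatnonzero(~alive_r):
            if not mask[i, alive_c].all():
                continue
            for j in np.flatnonzero(~alive_c):
                if mask[alive_r, j].all() and mask[i, j]:
                    alive_r[i] = True
                    alive_c[j] = True
                    changed = True
                    break
            if changed:
                break


def extract_submatrix(
    M: IncidenceMatrix, mode: str = "Rectangular_element_max", max_passes: int = 50
) -> SubmatrixResult:
    """Best complete block found by the deterministic heuristic portfolio."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    mask = M.mask
    m, n = mask.shape
    if not mask.any():
        raise ValueError("matrix has no observed cell")

    if mode in ("Rectangular_row", "Rectangular_col"):
        return _finalize(M, mode, *_fixed_dimension(mask, mode))

    candidates = []
    for ar, ac in (_peel(mask, mode), _forward(mask, mode)):
        ar, ac = ar.copy(), ac.copy()
        if mode == "Square":
            _squarify(mask, ar, ac)
        else:
            _readd(mask, ar, ac)
        candidates.append((ar, ac))
    # deterministic winner: largest objective, then first candidate in order
    best = max(
        enumerate(candidates),
        key=lambda t: (_score(mode, int(t[1][0].sum()), int(t[1][1].sum())), -t[0]),
    )[1]
    return _finalize(M, mode, *best)


def _fixed_dimension(mask: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Keep one dimension whole; peel the other down to its complete lines.

    When no line of the peelable dimension is complete (e.g. some column is
    missing in every row for ``Rectangular_row``), the mode is infeasible as
    stated: fall back, with a warning, to dropping the most-missing opposite
    lines until a complete line exists.
    """
    work = mask if mode == "Rectangular_row" else mask.T
    alive_opp = np.ones(work.shape[1], dtype=bool)
    warned = False
    while True:
        complete = work[:, alive_opp].all(axis=1)
        if complete.any():
            break
        if not warned:
            warnings.warn(
                f"{mode} infeasible on the full opposite dimension; dropping "
                "the most-missing opposite line(s) first",
                stacklevel=3,
            )
            warned = True
        miss = (~work[:, alive_opp]).sum(axis=0)
        opp_ids = np.flatnonzero(alive_opp)
        alive_opp[opp_ids[int(np.argmax(miss))]] = False
        if not alive_opp.any():
            raise ValueError("matrix has no observed cell in any line")
    if mode == "Rectangular_row":
        return complete, alive_opp
    return alive_opp, complete


def _finalize(
    M: IncidenceMatrix, mode: str, alive_r: np.ndarray, alive_c: np.ndarray
) -> SubmatrixResult:
    mask = M.mask
    m = mask.shape[0]
    rows = np.flatnonzero(alive_r)
    cols = np.flatnonzero(alive_c)
    block = mask[np.ix_(rows, cols)]
    assert block.all(), "internal error: extracted block contains missing cells"
    # report in packed order: by observed count in the original matrix, desc
    rows = np.array(sorted(rows, key=lambda i: (-int(mask[i].sum()), i)), dtype=int)
    cols = np.array(sorted(cols, key=lambda j: (-int(mask[:, j].sum()), j)), dtype=int)
    return SubmatrixResult(
        mode=mode,
        rows=rows,
        cols=cols,
        n_cells=int(rows.size * cols.size),
        proportion_of_rows=float(rows.size / m),
    )


def submatrix_report(M: IncidenceMatrix, results: list[SubmatrixResult]) -> dict:
    """Per-mode block dimensions plus the two completeness proportions.

    Proportion (a) is the overall observedness of the input matrix
    (observed cells / total cells); proportion (b) is the row-wise share
    retained by the block, |rows| * n / (m * n).
    """
    m, n = M.shape
    n_obs = int(M.mask.sum())
    report: dict = {
        "n_rows": m,
        "n_cols": n,
        "n_observed": n_obs,
        "prop_nonmissing": n_obs / (m * n),
        "modes": {},
    }
    for res in results:
        report["modes"][res.mode] = {
            "block_rows": int(res.rows.size),
            "block_cols": int(res.cols.size),
            "n_cells": res.n_cells,
            "prop_total_observed": n_obs / (m * n),
            "prop_rows_retained": res.rows.size * n / (m * n),
        }
    return report
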