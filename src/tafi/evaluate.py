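"""Consistency analysis: contingency tables and forecast-verification skill.

Predicted subtrees are compared against reference modules (pathways,
complexes) through a k x k contingency table whose cell (i, j) counts the
genes shared by reference set i and predicted set j.  Columns are matched
to rows by maximum-weight bipartite assignment so that a perfect
prediction yields a diagonal table.  Agreement is then summarized by three
chance-corrected skill scores — Heidke, Peirce and Gerrity — all of which
equal 1 exactly on a positive diagonal table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ContingencyTable",
    "EvaluationError",
    "build_contingency",
    "heidke_score",
    "peirce_score",
    "gerrity_score",
]


class EvaluationError(ValueError):
    """Raised for degenerate contingency inputs."""


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray  # k x k, rows = reference, columns = matched prediction
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        return self.counts.shape[0]


def build_contingency(
    reference: Sequence[Iterable[str]],
    predicted: Sequence[Iterable[str]],
    *,
    matching: str = "optimal",
    row_labels: Sequence[str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate reference modules against predicted subtrees.

    Cell (i, j) = |reference_i ∩ predicted_j|.  A gene belonging to
    several predicted sets (fuzzy membership) is counted in each.  Columns
    are permuted so the diagonal carries the maximum total overlap —
    optimal assignment by default, greedy (largest cell first) with
    ``matching="greedy"``.
    """
    k = len(reference)
    if len(predicted) != k:
        raise EvaluationError(
            f"reference has {k} sets but prediction has {len(predicted)}"
        )
    if k == 0:
        raise EvaluationError("empty partition")
    ref = [frozenset(s) for s in reference]
    pred = [frozenset(s) for s in predicted]
    counts = np.zeros((k, k), dtype=int)
    for i, r in enumerate(ref):
        for j, p in enumerate(pred):
            counts[i, j] = len(r & p)
    if counts.sum() == 0:
        raise EvaluationError("reference and prediction share no genes")

    if matching == "optimal":
        _, cols = linear_sum_assignment(counts, maximize=True)
    elif matching == "greedy":
        cols = np.full(k, -1)
        used_r, used_c = set(), set()
        order = np.argsort(counts, axis=None)[::-1]
        for flat in order:
            i, j = divmod(int(flat), k)
            if i in used_r or j in used_c:
                continue
            cols[i] = j
            used_r.add(i)
            used_c.add(j)
            if len(used_r) == k:
                break
    else:
        raise EvaluationError(f"unknown matching {matching!r}")

    counts = counts[:, cols]
    rl = tuple(row_labels) if row_labels else tuple(f"ref{i}" for i in range(k))
    cl = tuple(f"pred{j}" for j in cols)
    return ContingencyTable(counts=counts, row_labels=rl, col_labels=cl)


def _as_array(table: ContingencyTable | np.ndarray) -> np.ndarray:
    arr = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise EvaluationError("contingency table must be square")
    if arr.sum() <= 0:
        raise EvaluationError("contingency table is empty")
    if (arr < 0).any():
        raise EvaluationError("negative counts")
    return arr.astype(float)


def heidke_score(table: ContingencyTable | np.ndarray) -> float:
    """Heidke skill score: (PC - E) / (1 - E).

    PC is the proportion on the diagonal; E the agreement expected by
    chance from the product of row and column marginals.  1 for a perfect
    diagonal, 0 when agreement is exactly at chance level.
    """
    arr = _as_array(table)
    n = arr.sum()
    pc = np.trace(arr) / n
    e = float((arr.sum(axis=1) / n) @ (arr.sum(axis=0) / n))
    if e >= 1.0:
        raise EvaluationError("degenerate marginals: chance agreement is 1")
    return (pc - e) / (1 - e)


def peirce_score(table: ContingencyTable | np.ndarray) -> float:
    """Peirce (Hanssen–Kuipers) skill score: (PC - E) / (1 - E_ref).

    Same numerator as Heidke but normalized by the chance term built from
    the reference (row) marginals alone, making the score insensitive to
    prediction bias.
    """
    arr = _as_array(table)
    n = arr.sum()
    pc = np.trace(arr) / n
    p_row = arr.sum(axis=1) / n
    p_col = arr.sum(axis=0) / n
    e = float(p_row @ p_col)
    e_ref = float(p_row @ p_row)
    if e_ref >= 1.0:
        raise EvaluationError("degenerate reference marginals")
    return (pc - e) / (1 - e_ref)


def gerrity_score(table: ContingencyTable | np.ndarray) -> float:
    """Gerrity equitable skill score.

    Uses the standard Gerrity reward/penalty matrix derived from the
    reference (row) marginals: correct assignments in rare categories earn
    more, and any constant prediction scores exactly 0.  1 on a perfect
    diagonal; requires k >= 2 and no empty reference category.
    """
    arr = _as_array(table)
    k = arr.shape[0]
    if k < 2:
        raise EvaluationError("Gerrity score needs at least 2 categories")
    n = arr.sum()
    p = arr.sum(axis=1) / n
    if (p == 0).any():
        raise EvaluationError("empty reference category")
    cum = np.cumsum(p)
    a = (1 - cum[:-1]) / cum[:-1]  # a_r for r = 1..k-1 (0-indexed 0..k-2)
    inv_a = 1 / a
    b = 1 / (k - 1)
    s = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            s_ij = b * (inv_a[:i].sum() - (j - i) + a[j:].sum())
            s[i, j] = s[j, i] = s_ij
    return float((arr / n * s).sum())
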