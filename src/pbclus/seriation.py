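"""Block-diagonal reordering of a binary matrix by greedy Tanimoto chaining.

Columns of the binary matrix are treated as set indicators; two columns are
similar when their supports overlap (Tanimoto coefficient > 0). The
reordering (a) drops all-zero columns (the "ousted" observations), (b)
splits the rest into connected components of the overlap graph, (c) inside
each component grows a chain greedily from a central seed, appending at each
step the unplaced column most similar to the last placed one, and (d)
concatenates the components. The result is a permutation that exposes the
diagonal block structure of the matrix, plus the series of consecutive
similarities along the chain whose zeros mark block boundaries.

All tie-breaks are on the smallest original column index, so the procedure
is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components as _cc
from scipy.sparse import csr_matrix

__all__ = [
    "Permutation",
    "OrderingResult",
    "tanimoto",
    "tanimoto_matrix",
    "split_components",
    "select_seed",
    "reorder",
]


@dataclass
class Permutation:
    """Seriated order over retained columns plus the set of ousted columns."""

    order: list[int]
    ousted: list[int]

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("order contains duplicate indices")
        if set(self.order) & set(self.ousted):
            raise ValueError("order and ousted overlap")

    @property
    def n_retained(self) -> int:
        return len(self.order)

    def full_order(self) -> list[int]:
        """Retained columns in seriated order, then ousted columns."""
        return list(self.order) + sorted(self.ousted)


@dataclass
class OrderingResult:
    """Outcome of one reordering.

    ``ordered`` is the full n×n input conjugated by the permutation with the
    ousted (all-zero) columns appended last; ``consecutive`` holds the
    Tanimoto similarity of adjacent retained columns (length n_retained − 1),
    zero exactly where the order crosses a connected-component boundary;
    ``objective`` is their sum.
    """

    permutation: Permutation
    ordered: np.ndarray
    objective: float
    consecutive: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_retained(self) -> int:
        return self.permutation.n_retained

    def retained_block(self) -> np.ndarray:
        k = self.n_retained
        return self.ordered[:k, :k]


def tanimoto(u: np.ndarray, v: np.ndarray) -> float:
    """Tanimoto coefficient of two binary vectors: |u∩v| / |u∪v|.

    Computed from dot products as u·v / (u·u + v·v − u·v); equals 1 iff the
    supports coincide (and are non-empty), 0 iff they are disjoint.
    """
    u = np.asarray(u, dtype=np.int64)
    v = np.asarray(v, dtype=np.int64)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    dot = int(u @ v)
    denom = int(u @ u) + int(v @ v) - dot
    if denom == 0:
        raise ValueError("Tanimoto undefined: both vectors are zero")
    return dot / denom


def tanimoto_matrix(cols: np.ndarray) -> np.ndarray:
    """All-pairs Tanimoto similarities between the columns of a binary matrix.

    Every column must be non-zero.
    """
    m = np.asarray(cols, dtype=np.int64)
    gram = m.T @ m
    sizes = np.diag(gram)
    if (sizes == 0).any():
        raise ValueError("all-zero column passed to tanimoto_matrix")
    denom = sizes[:, None] + sizes[None, :] - gram
    return gram / denom


def _retained_columns(B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    B = np.asarray(B)
    nonzero = B.any(axis=0)
    return np.flatnonzero(nonzero), np.flatnonzero(~nonzero)


def split_components(B_lambda: np.ndarray) -> list[list[int]]:
    """Connected components of the column-overlap graph.

    Vertices are the non-zero columns; an edge joins columns whose supports
    intersect (Tanimoto > 0). Components are returned sorted by their
    smallest member index, members sorted ascending. All-zero columns are
    excluded (they are the ousted set).
    """
    B = np.asarray(B_lambda, dtype=np.int64)
    retained, _ = _retained_columns(B)
    if retained.size == 0:
        return []
    sub = B[:, retained]
    overlap = (sub.T @ sub) > 0
    n_comp, labels = _cc(csr_matrix(overlap), directed=False)
    groups = [retained[labels == c].tolist() for c in range(n_comp)]
    groups.sort(key=lambda g: g[0])
    return groups


def select_seed(
    group: list[int], B_lambda: np.ndarray, strong_threshold: float = 0.5
) -> int:
    """Central member of a component: most "strongly correlated" neighbors.

    Returns the member maximizing the number of other members whose Tanimoto
    similarity reaches ``strong_threshold``; ties go to the smallest original
    index.
    """
    if not group:
        raise ValueError("empty group")
    if len(group) == 1:
        return group[0]
    B = np.asarray(B_lambda, dtype=np.int64)
    t = tanimoto_matrix(B[:, group])
    strong = (t >= strong_threshold).sum(axis=1) - 1  # exclude self
    best = int(np.argmax(strong))  # argmax takes first maximum: smallest index
    return group[best]


def reorder(B_lambda: np.ndarray, strong_threshold: float = 0.5) -> OrderingResult:
    """Seriate a square binary matrix into block-diagonal form.

    Within each connected component a chain is grown greedily from the seed
    column; components are concatenated in order of smallest member index and
    ousted (all-zero) columns are appended last. The objective is the sum of
    consecutive Tanimoto similarities along the retained chain.
    """
    B = np.asarray(B_lambda, dtype=np.int64)
    n = B.shape[0]
    if B.ndim != 2 or B.shape[1] != n:
        raise ValueError("matrix must be square")
    retained, ousted = _retained_columns(B)
    if retained.size == 0:
        raise ValueError("matrix is entirely zero: nothing to order")

    t_full = np.full((n, n), -1.0)
    t_sub = tanimoto_matrix(B[:, retained])
    t_full[np.ix_(retained, retained)] = t_sub

    order: list[int] = []
    for group in split_components(B):
        seed = select_seed(group, B, strong_threshold)
        placed = [seed]
        remaining = [g for g in group if g != seed]
        while remaining:
            sims = t_full[placed[-1], remaining]
            nxt = remaining[int(np.argmax(sims))]  # first max = smallest index
            placed.append(nxt)
            remaining.remove(nxt)
        order.extend(placed)

    perm = Permutation(order=order, ousted=sorted(int(i) for i in ousted))
    full = perm.full_order()
    ordered = B[np.ix_(full, full)]
    if len(order) > 1:
        consecutive = np.array(
            [max(t_full[a, b], 0.0) for a, b in zip(order, order[1:])]
        )
    else:
        consecutive = np.empty(0)
    return OrderingResult(
        permutation=perm,
        ordered=ordered,
        objective=float(consecutive.sum()),
        consecutive=consecutive,
    )
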