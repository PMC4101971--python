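"""Quality measures for orderings and partitions.

- Niermann-style seriation stress: each matrix cell is compared with its
  window neighbors (Moore 3x3 ring or von Neumann 4-cross) via squared
  differences; a well-seriated dissimilarity matrix has smooth local
  structure, hence low stress.
- Fisher index: trace ratio of within-cluster to between-cluster scatter;
  lower means compact, well-separated clusters.
- Contingency-table classification rate: best one-to-one matching of
  clusters to reference classes, matched count over table total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .neighborhood import FeatureTable
from .partition import OUSTED, Partition

__all__ = [
    "ClusterStats",
    "ContingencyTable",
    "stress",
    "cluster_stats",
    "fisher_index",
    "contingency_table",
    "classification_rate",
]


@dataclass
class ClusterStats:
    means: dict[int, np.ndarray]
    grand_mean: np.ndarray
    sizes: dict[int, int]
    S_w: np.ndarray
    S_B: np.ndarray
    F_index: float


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("contingency counts must be non-negative")
        r, c = self.counts.shape
        if not self.row_labels:
            self.row_labels = [str(i + 1) for i in range(r)]
        if not self.col_labels:
            self.col_labels = [str(j + 1) for j in range(c)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


def stress(M: np.ndarray, mode: str = "moore") -> float:
    """Local-window seriation stress of a (reordered) matrix.

    For every cell, sum the squared differences with the cells of its window
    — the 8 surrounding cells for ``moore``, the 4-cross for ``neumann`` —
    truncated at the matrix edges, and sum over all cells. Each unordered
    neighbor pair is therefore counted twice (once from each end), matching
    the double-sum definition.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("stress expects a 2-d matrix")
    if mode == "moore":
        offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    elif mode == "neumann":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        raise ValueError(f"unknown stress mode {mode!r}")
    n, m = M.shape
    total = 0.0
    for di, dj in offsets:
        src = M[max(di, 0): n + min(di, 0), max(dj, 0): m + min(dj, 0)]
        dst = M[max(-di, 0): n + min(-di, 0), max(-dj, 0): m + min(-dj, 0)]
        total += float(((src - dst) ** 2).sum())
    return total


def cluster_stats(X: FeatureTable, partition: Partition) -> ClusterStats:
    """Within/between scatter matrices of a partition (OUSTED excluded)."""
    clusters = sorted(k for k in set(partition.labels.values()) if k != OUSTED)
    if len(clusters) < 2:
        raise ValueError("Fisher index needs at least 2 clusters")
    id_to_row = {rid: i for i, rid in enumerate(X.row_ids)}
    p = X.p
    means: dict[int, np.ndarray] = {}
    sizes: dict[int, int] = {}
    S_w = np.zeros((p, p))
    S_B = np.zeros((p, p))
    all_rows = []
    groups = {}
    for k in clusters:
        rows = [id_to_row[i] for i in partition.members(k)]
        pts = X.values[rows]
        groups[k] = pts
        means[k] = pts.mean(axis=0)
        sizes[k] = len(rows)
        all_rows.append(pts)
    stacked = np.vstack(all_rows)
    grand = stacked.mean(axis=0)
    for k in clusters:
        centered = groups[k] - means[k]
        S_w += centered.T @ centered
        dm = (means[k] - grand)[:, None]
        S_B += sizes[k] * (dm @ dm.T)
    tr_b = float(np.trace(S_B))
    if tr_b == 0:
        raise ValueError("all cluster means coincide: Fisher index undefined")
    f = float(np.trace(S_w)) / tr_b
    return ClusterStats(means=means, grand_mean=grand, sizes=sizes, S_w=S_w, S_B=S_B, F_index=f)


def fisher_index(X: FeatureTable, partition: Partition, method: str = "trace") -> float:
    """Scalar within/between scatter ratio of a partition.

    ``trace`` (default) returns trace(S_w)/trace(S_B); ``det`` returns the
    determinant ratio. OUSTED observations are excluded.
    """
    stats = cluster_stats(X, partition)
    if method == "trace":
        return stats.F_index
    if method == "det":
        det_b = float(np.linalg.det(stats.S_B))
        if det_b == 0:
            raise ValueError("singular between-scatter: determinant ratio undefined")
        return float(np.linalg.det(stats.S_w)) / det_b
    raise ValueError(f"unknown method {method!r}")


def contingency_table(
    reference: list, predicted: list, drop_ousted: bool = True
) -> ContingencyTable:
    """Cross-tabulate reference classes (rows) against clusters (columns)."""
    if len(reference) != len(predicted):
        raise ValueError("label sequences differ in length")
    pairs = list(zip(reference, predicted))
    if drop_ousted:
        pairs = [(r, p) for r, p in pairs if p != OUSTED]
    if not pairs:
        raise ValueError("no classified observations to tabulate")
    ref, pred = zip(*pairs)
    ct = pd.crosstab(pd.Series(ref, name="reference"), pd.Series(pred, name="cluster"))
    return ContingencyTable(
        counts=ct.to_numpy(),
        row_labels=[str(r) for r in ct.index],
        col_labels=[str(c) for c in ct.columns],
    )


def classification_rate(table: ContingencyTable) -> float:
    """Agreement after the best one-to-one cluster-to-class assignment.

    Finds the injective assignment of columns to rows maximizing the matched
    count (Hungarian algorithm, exact) and returns matched / total, the
    total including every table entry.
    """
    counts = table.counts
    if counts.size == 0:
        raise ValueError("empty contingency table")
    total = int(counts.sum())
    if total == 0:
        raise ValueError("contingency table sums to zero")
    rows, cols = linear_sum_assignment(counts, maximize=True)
    matched = int(counts[rows, cols].sum())
    return matched / total
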