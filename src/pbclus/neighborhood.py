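"""From raw observations to the nested family of parsimonious binary matrices.

The pipeline head works in four steps:

1. a dissimilarity matrix ``D`` between the ``n`` observations,
2. an adjacency matrix ``A`` thresholding ``D`` at a proximity radius
   ``epsilon`` (by default the first quartile of the pairwise distances),
3. the common-neighbor (Gram) matrix ``B = A.T @ A`` whose entry ``b_ij``
   counts observations that are epsilon-neighbors of both ``i`` and ``j``,
4. a nested family of binary matrices ``B_lambda`` obtained by requiring at
   least ``lambda`` common neighbors; higher levels are sparser and contained
   in lower ones.

Observations whose column becomes entirely zero at a level are "ousted" at
that level — the mechanism by which noise and extreme points are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

__all__ = [
    "FeatureTable",
    "DissimilarityMatrix",
    "NeighborhoodConfig",
    "AdjacencyMatrix",
    "CommonNeighborMatrix",
    "ParsimonyFamily",
    "compute_dissimilarity",
    "build_adjacency",
    "common_neighbor_counts",
    "build_family",
]

_SYMMETRY_TOL = 1e-9


@dataclass
class FeatureTable:
    """n observations (rows) described by p real features (columns)."""

    values: np.ndarray
    row_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature table must be 2-dimensional")
        n, p = self.values.shape
        if n < 2:
            raise ValueError("need at least 2 observations")
        if p < 1:
            raise ValueError("need at least 1 feature")
        if not np.isfinite(self.values).all():
            raise ValueError("feature table contains missing/non-finite values")
        if not self.row_ids:
            self.row_ids = [str(i + 1) for i in range(n)]
        if len(self.row_ids) != n:
            raise ValueError("row_ids length does not match number of rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class DissimilarityMatrix:
    """Symmetric non-negative pairwise dissimilarities with zero diagonal."""

    d: np.ndarray
    metric_name: str = "euclidean"
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = self.d.shape[0]
        if self.d.ndim != 2 or self.d.shape[1] != n:
            raise ValueError("dissimilarity matrix must be square")
        if (np.abs(np.diag(self.d)) > _SYMMETRY_TOL).any():
            raise ValueError("dissimilarity diagonal must be zero")
        asym = np.abs(self.d - self.d.T)
        if asym.max(initial=0.0) > _SYMMETRY_TOL:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValueError(
                f"dissimilarity matrix is asymmetric at ({i + 1},{j + 1}): "
                f"{self.d[i, j]!r} vs {self.d[j, i]!r}"
            )
        if (self.d < -_SYMMETRY_TOL).any():
            raise ValueError("dissimilarities must be non-negative")
        if not self.ids:
            self.ids = [str(i + 1) for i in range(n)]

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass
class NeighborhoodConfig:
    """Neighborhood radius: explicit ``epsilon`` or a distance quantile.

    When ``epsilon`` is None it is taken as the ``quantile`` (default: first
    quartile) of the off-diagonal pairwise distance multiset, with linear
    interpolation on the sorted values.
    """

    epsilon: float | None = None
    quantile: float = 0.25

    def __post_init__(self) -> None:
        if self.epsilon is not None and self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if not 0 < self.quantile <= 1:
            raise ValueError("quantile must be in (0, 1]")


@dataclass
class AdjacencyMatrix:
    a: np.ndarray
    epsilon: float = float("nan")
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a)
        if not np.isin(self.a, (0, 1)).all():
            raise ValueError("adjacency matrix must be binary")
        self.a = self.a.astype(np.int64)
        if (self.a != self.a.T).any():
            raise ValueError("adjacency matrix must be symmetric")
        if not self.ids:
            self.ids = [str(i + 1) for i in range(self.a.shape[0])]


@dataclass
class CommonNeighborMatrix:
    """Gram matrix of the adjacency: b_ij = |N(i) ∩ N(j)| (self included)."""

    b: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=np.int64)
        if (self.b < 0).any():
            raise ValueError("common-neighbor counts must be non-negative")
        if not self.ids:
            self.ids = [str(i + 1) for i in range(self.b.shape[0])]

    @property
    def n(self) -> int:
        return self.b.shape[0]

    def max_offdiag(self) -> int:
        off = self.b[~np.eye(self.n, dtype=bool)]
        return int(off.max(initial=0))


@dataclass
class ParsimonyFamily:
    """Nested binary matrices B_λ1 ⊇ B_λ2 ⊇ … at increasing parsimony."""

    levels: list[int]
    matrices: dict[int, np.ndarray]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ids and self.levels:
            n = self.matrices[self.levels[0]].shape[0]
            self.ids = [str(i + 1) for i in range(n)]

    @property
    def M(self) -> int:
        return len(self.levels)

    def __getitem__(self, level: int) -> np.ndarray:
        return self.matrices[level]


def _correlation_dissimilarity(values: np.ndarray, rank: bool) -> np.ndarray:
    x = values
    if rank:
        x = np.apply_along_axis(rankdata, 1, x)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(
            f"row {bad + 1} is constant: correlation dissimilarity undefined"
        )
    c = np.corrcoef(x)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def compute_dissimilarity(
    X: FeatureTable, metric: str = "euclidean", p: float = 2.0
) -> DissimilarityMatrix:
    """Pairwise dissimilarities between the rows of a feature table.

    Parameters
    ----------
    X : FeatureTable
    metric : str
        One of ``euclidean``, ``pnorm`` (Minkowski, exponent ``p``),
        ``correlation`` (1 − Pearson r), ``spearman`` (1 − Spearman rho) or
        ``maximum`` (Chebyshev).
    p : float
        Exponent for the ``pnorm`` metric (ignored otherwise).
    """
    v = X.values
    if metric == "euclidean":
        d = squareform(pdist(v, metric="euclidean"))
    elif metric in ("pnorm", "minkowski"):
        d = squareform(pdist(v, metric="minkowski", p=p))
        metric = f"pnorm({p:g})"
    elif metric == "maximum":
        d = squareform(pdist(v, metric="chebyshev"))
    elif metric == "correlation":
        d = _correlation_dissimilarity(v, rank=False)
    elif metric == "spearman":
        d = _correlation_dissimilarity(v, rank=True)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    d = (d + d.T) / 2.0  # squash float asymmetry from pdist round-trips
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(d=d, metric_name=metric, ids=list(X.row_ids))


def offdiagonal_distances(D: DissimilarityMatrix) -> np.ndarray:
    """The strictly upper-triangular distance multiset {d_ij : i < j}."""
    iu = np.triu_indices(D.n, k=1)
    return D.d[iu]


def build_adjacency(
    D: DissimilarityMatrix, config: NeighborhoodConfig | None = None
) -> AdjacencyMatrix:
    """Threshold the dissimilarity matrix: a_ij = 1 iff d_ij <= epsilon.

    A boundary distance d_ij == epsilon counts as a neighbor, and the
    diagonal is always 1 (d_ii = 0 <= epsilon).
    """
    config = config or NeighborhoodConfig()
    if D.n < 2:
        raise ValueError("need at least 2 observations to form neighborhoods")
    eps = config.epsilon
    if eps is None:
        eps = float(np.quantile(offdiagonal_distances(D), config.quantile))
    a = (D.d <= eps).astype(np.int64)
    return AdjacencyMatrix(a=a, epsilon=float(eps), ids=list(D.ids))


def common_neighbor_counts(A: AdjacencyMatrix) -> CommonNeighborMatrix:
    """Gram matrix B = AᵀA; b_ij counts shared epsilon-neighbors of i and j."""
    b = A.a.T @ A.a
    return CommonNeighborMatrix(b=b, ids=list(A.ids))


def threshold_at_level(b: np.ndarray, level: int) -> np.ndarray:
    """Binarize a common-neighbor matrix at one parsimony level.

    Every entry (diagonal included) is thresholded at ``b_ij >= level``; the
    diagonal is then forced to 1 in any row that keeps at least one
    off-diagonal 1, so a retained observation is always its own neighbor. A
    row left entirely zero is "ousted" at this level.
    """
    m = (np.asarray(b) >= level).astype(np.int64)
    off = m.copy()
    np.fill_diagonal(off, 0)
    keep = off.any(axis=1) | off.any(axis=0)
    diag = np.diag(m).copy()
    diag[keep] = 1
    np.fill_diagonal(m, diag)
    return m


def build_family(
    B: CommonNeighborMatrix, levels="auto"
) -> ParsimonyFamily:
    """Build the nested family of parsimonious binary matrices.

    ``levels="auto"`` scans every integer level from 1 up to the largest
    off-diagonal common-neighbor count (beyond which everything is ousted).
    An explicit sequence must be strictly increasing positive integers.
    """
    if isinstance(levels, str):
        if levels != "auto":
            raise ValueError(f"unknown level policy {levels!r}")
        top = B.max_offdiag()
        lvls = list(range(1, max(top, 1) + 1))
    else:
        lvls = [int(l) for l in levels]
        if not lvls:
            raise ValueError("level sequence is empty")
        if any(l2 <= l1 for l1, l2 in zip(lvls, lvls[1:])):
            raise ValueError("levels must be strictly increasing")
        if lvls[0] < 1:
            raise ValueError("levels must be positive integers")
    mats = {lam: threshold_at_level(B.b, lam) for lam in lvls}
    return ParsimonyFamily(levels=lvls, matrices=mats, ids=list(B.ids))
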