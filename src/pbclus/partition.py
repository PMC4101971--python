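"""From a seriated ordering to flat cluster labels.

Along the seriated chain, the Tanimoto similarity of adjacent columns drops
to zero exactly where one diagonal block ends and the next begins ("points
of rupture"). Cutting the chain at positions where the consecutive
similarity falls at or below a threshold ``tau`` (default 0: exact
disconnection) yields contiguous segments that become the clusters, numbered
left to right. Columns ousted at the selected parsimony level get the
explicit OUSTED label instead of a cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seriation import OrderingResult

__all__ = ["OUSTED", "Partition", "find_breakpoints", "extract_partition"]

#: label assigned to observations excluded at the selected parsimony level
OUSTED = "OUSTED"


@dataclass
class Partition:
    """Flat clustering with an explicit unclassified state.

    ``labels`` maps each observation id to a cluster index 1..K or to the
    OUSTED sentinel; ``boundaries`` are the 0-based chain positions after
    which a new cluster starts.
    """

    labels: dict[str, int | str]
    K: int
    boundaries: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.labels)

    def members(self, k: int | str) -> list[str]:
        return [i for i, lab in self.labels.items() if lab == k]

    def ousted_ids(self) -> list[str]:
        return self.members(OUSTED)


def find_breakpoints(consecutive: np.ndarray, tau: float = 0.0) -> list[int]:
    """Positions i where consecutive[i] <= tau (cut between i and i+1)."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    c = np.asarray(consecutive, dtype=float)
    return np.flatnonzero(c <= tau).tolist()


def extract_partition(
    result: OrderingResult,
    breakpoints: list[int],
    ids: list[str] | None = None,
) -> Partition:
    """Cut the seriated order at the breakpoints into contiguous clusters.

    ``ids`` gives the observation identifiers in ORIGINAL matrix order; by
    default positions are used ("1", "2", ...). Breakpoint i separates chain
    positions i and i+1 (0-based).
    """
    order = result.permutation.order
    if not order:
        raise ValueError("empty ordering")
    n = len(order) + len(result.permutation.ousted)
    if ids is None:
        ids = [str(i + 1) for i in range(n)]
    bps = sorted(set(int(b) for b in breakpoints))
    if bps and (bps[0] < 0 or bps[-1] >= len(order) - 1):
        raise ValueError("breakpoint out of range")

    labels: dict[str, int | str] = {}
    k = 1
    for pos, col in enumerate(order):
        labels[ids[col]] = k
        if pos in bps:
            k += 1
    for col in result.permutation.ousted:
        labels[ids[col]] = OUSTED
    return Partition(labels=labels, K=k, boundaries=bps)
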