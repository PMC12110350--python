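"""Small-world substrate: construction, degree ranking, discharge-mode
allocation, and virtual resection.

The network is a Watts-Strogatz graph stored as a dense binary symmetric
adjacency matrix together with a per-node activity mask.  Resected nodes
stay in the arrays (indices remain stable across treatment plans) but have
their rows and columns zeroed and are excluded from every downstream
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "AdjacencyNetwork",
    "ModeAssignment",
    "generate_ws_network",
    "degree_rank",
    "assign_modes",
    "resect",
    "RESECTION_PLANS",
    "MODE_RATIOS",
    "read_adjacency",
    "write_adjacency",
    "read_edge_list",
    "write_edge_list",
    "read_modes",
    "write_modes",
]

#: resection plan -> set of discharge modes whose nodes are removed
RESECTION_PLANS: dict[int, frozenset[int]] = {
    1: frozenset({2}),
    2: frozenset({3}),
    3: frozenset({4}),
    4: frozenset({2, 3, 4}),
}

#: mode-allocation ratios, in degree-rank order (highest degree first).
#: Keys are scheme names; values are (mode, count-out-of-50) pairs.
MODE_RATIOS: dict[str, tuple[tuple[int, int], ...]] = {
    "stimulation": ((2, 19), (3, 11), (1, 20)),
    "surgery": ((2, 20), (3, 8), (4, 2), (1, 20)),
}


@dataclass
class AdjacencyNetwork:
    """Binary symmetric graph with a per-node activity mask.

    Attributes
    ----------
    adjacency : (N, N) int array with entries in {0, 1}, zero diagonal.
    active_mask : (N,) bool array; False marks a resected node.
    seed : RNG seed used at construction (None for hand-built graphs).
    """

    adjacency: np.ndarray
    active_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    seed: int | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.int8)
        if self.active_mask is None:
            self.active_mask = np.ones(self.adjacency.shape[0], dtype=bool)
        self.active_mask = np.asarray(self.active_mask, dtype=bool)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise InvalidParameterError("adjacency must be square")
        if self.active_mask.shape != (a.shape[0],):
            raise InvalidParameterError("active_mask length must match adjacency")
        if not np.array_equal(a, a.T):
            raise InvalidParameterError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise InvalidParameterError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise InvalidParameterError("adjacency entries must be 0/1")
        inactive = ~self.active_mask
        if inactive.any() and (a[inactive, :].any() or a[:, inactive].any()):
            raise InvalidParameterError("inactive nodes must have zero rows/columns")

    # -- views -----------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_active(self) -> int:
        return int(self.active_mask.sum())

    @property
    def active_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.active_mask)

    @property
    def degrees(self) -> np.ndarray:
        """Per-node degree (zero for inactive nodes)."""
        return self.adjacency.sum(axis=1).astype(int)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def copy(self) -> "AdjacencyNetwork":
        return AdjacencyNetwork(
            self.adjacency.copy(), self.active_mask.copy(), self.seed
        )


@dataclass(frozen=True)
class ModeAssignment:
    """Per-node discharge-mode labels (1-4; 0 for inactive nodes)."""

    mode_of_node: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "mode_of_node", np.asarray(self.mode_of_node, dtype=int)
        )

    def nodes_with_mode(self, mode: int) -> np.ndarray:
        return np.flatnonzero(self.mode_of_node == mode)

    def counts(self) -> dict[int, int]:
        labels = self.mode_of_node[self.mode_of_node > 0]
        return {int(m): int((labels == m).sum()) for m in np.unique(labels)}


def generate_ws_network(
    n: int, n0: int, p: float, seed: int | None = None
) -> AdjacencyNetwork:
    """Build a Watts-Strogatz small-world graph.

    ``n0`` is the ring degree of the initial lattice (each node connects to
    ``n0/2`` neighbours on either side before rewiring); ``n0 = 2`` gives a
    cycle.  Rewiring moves edges with probability ``p`` without ever
    deleting one, so the edge count ``n * n0 / 2`` is invariant in ``p``.
    """
    if n < 3:
        raise InvalidParameterError(f"need at least 3 nodes, got {n}")
    if n0 >= n:
        raise InvalidParameterError(f"ring degree n0={n0} must be < n={n}")
    if n0 < 2 or n0 % 2:
        raise InvalidParameterError(f"ring degree n0={n0} must be even and >= 2")
    if not 0.0 <= p <= 1.0:
        raise InvalidParameterError(f"rewiring probability p={p} outside [0, 1]")
    g = nx.watts_strogatz_graph(n, n0, p, seed=seed)
    adjacency = nx.to_numpy_array(g, nodelist=range(n), dtype=np.int8)
    return AdjacencyNetwork(adjacency, seed=seed)


def degree_rank(net: AdjacencyNetwork) -> np.ndarray:
    """Active nodes ordered by descending degree, ties by ascending index."""
    nodes = net.active_nodes
    deg = net.degrees[nodes]
    order = np.lexsort((nodes, -deg))
    return nodes[order]


def _largest_remainder(n: int, weights: np.ndarray) -> np.ndarray:
    """Apportion n items to groups proportionally (largest-remainder)."""
    quotas = n * weights / weights.sum()
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    # ties in fractional part resolved by group order
    for idx in np.argsort(-(quotas - counts), kind="stable")[:remainder]:
        counts[idx] += 1
    return counts


def assign_modes(net: AdjacencyNetwork, scheme: str) -> ModeAssignment:
    """Allocate discharge modes to active nodes in degree-rank order.

    The ``stimulation`` scheme splits a 50-node network 19/11/20 into modes
    2/3/1; the ``surgery`` scheme splits it 20/8/2/20 into modes 2/3/4/1.
    Other sizes are apportioned proportionally (largest remainder), keeping
    the allocation ratios fixed.
    """
    if scheme not in MODE_RATIOS:
        raise InvalidParameterError(
            f"unknown scheme {scheme!r}; expected one of {sorted(MODE_RATIOS)}"
        )
    ratios = MODE_RATIOS[scheme]
    ranked = degree_rank(net)
    counts = _largest_remainder(
        len(ranked), np.array([c for _, c in ratios], dtype=float)
    )
    mode_of_node = np.zeros(net.n_nodes, dtype=int)
    start = 0
    for (mode, _), count in zip(ratios, counts):
        mode_of_node[ranked[start : start + count]] = mode
        start += count
    return ModeAssignment(mode_of_node, scheme)


def resect(
    net: AdjacencyNetwork, modes: ModeAssignment, plan: int
) -> AdjacencyNetwork:
    """Apply a surgical resection plan, deactivating the targeted modes.

    Plans remove the nodes carrying discharge modes {2}, {3}, {4} or
    {2, 3, 4} respectively.  Targeted nodes become inactive and their
    adjacency rows/columns are zeroed; the remaining submatrix and all node
    indices are unchanged.
    """
    if plan not in RESECTION_PLANS:
        raise InvalidParameterError(f"resection plan must be 1-4, got {plan}")
    targets = np.isin(modes.mode_of_node, list(RESECTION_PLANS[plan]))
    targets &= net.active_mask
    adjacency = net.adjacency.copy()
    adjacency[targets, :] = 0
    adjacency[:, targets] = 0
    return AdjacencyNetwork(adjacency, net.active_mask & ~targets, net.seed)


# ---------------------------------------------------------------------------
# plain-text I/O


def write_adjacency(net: AdjacencyNetwork, path: str | Path) -> None:
    """Whitespace-delimited N x N 0/1 matrix."""
    np.savetxt(path, net.adjacency, fmt="%d")


def read_adjacency(path: str | Path) -> AdjacencyNetwork:
    return AdjacencyNetwork(np.loadtxt(path, dtype=np.int8, ndmin=2))


def write_edge_list(net: AdjacencyNetwork, path: str | Path) -> None:
    """One undirected edge per line, two 0-based node ids."""
    i, j = np.nonzero(np.triu(net.adjacency))
    np.savetxt(path, np.column_stack([i, j]), fmt="%d")


def read_edge_list(path: str | Path, n_nodes: int | None = None) -> AdjacencyNetwork:
    edges = np.loadtxt(path, dtype=int, ndmin=2)
    if edges.size == 0:
        edges = edges.reshape(0, 2)
    n = int(edges.max()) + 1 if edges.size else 0
    n = max(n, n_nodes or 0)
    adjacency = np.zeros((n, n), dtype=np.int8)
    adjacency[edges[:, 0], edges[:, 1]] = 1
    adjacency[edges[:, 1], edges[:, 0]] = 1
    return AdjacencyNetwork(adjacency)


def write_modes(modes: ModeAssignment, path: str | Path) -> None:
    """Two-column table: node_id, mode (0-based node ids)."""
    ids = np.arange(len(modes.mode_of_node))
    np.savetxt(
        path,
        np.column_stack([ids, modes.mode_of_node]),
        fmt="%d",
        header="node_id mode",
    )


def read_modes(path: str | Path, scheme: str = "stimulation") -> ModeAssignment:
    table = np.loadtxt(path, dtype=int, ndmin=2)
    mode_of_node = np.zeros(len(table), dtype=int)
    mode_of_node[table[:, 0]] = table[:, 1]
    return ModeAssignment(mode_of_node, scheme)
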