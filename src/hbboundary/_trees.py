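"""Log-domain steady states for occupancy-graph promoter models.

Randomized kinetic rates span many decades (1e-20 .. 1e20 / s), so
solving ``pi Q = 0`` in floating point is hopeless for the tails of the
rate distribution.  Instead we use the Markov chain tree theorem: the
stationary weight of state ``i`` is the sum, over all spanning
arborescences of the transition graph rooted at ``i`` (edges oriented
toward the root), of the product of the edge rates.  Each arborescence
weight is a monomial in the TF concentration ``u = exp(X)`` whose degree
is the number of binding edges it contains, so

    pi_i(X)  ~  sum_c  exp(L[i, c] + c * X)

with ``L[i, c]`` the log-sum of the X-independent parts of all
arborescences rooted at ``i`` that contain ``c`` binding edges.  The
tables mapping edge rates to ``L`` are enumerated once per architecture
(384 spanning trees for the 3-site hypercube) and cached.

All functions here operate on *log* rates and are safe for rates that
underflow or overflow in linear space.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
from scipy import sparse

__all__ = [
    "TreeTable",
    "neq_graph_table",
    "hybrid_table",
    "neq_edge_order",
    "N_NEQ_SITES",
]

#: Number of operator sites in the full occupancy-graph model.
N_NEQ_SITES = 3


def neq_edge_order(n_sites: int = N_NEQ_SITES) -> list[tuple[int, int]]:
    """Canonical ordering of the binding edges of the occupancy graph.

    Edge ``e = (state, site)`` is the binding transition from bitmask
    ``state`` (site free) to ``state | (1 << site)``.  The paired
    unbinding transition shares the same index in ``unbinding_rates``.
    """
    edges = []
    for s in range(1 << n_sites):
        for j in range(n_sites):
            if not (s >> j) & 1:
                edges.append((s, j))
    return edges


@dataclass(frozen=True)
class TreeTable:
    """Precomputed arborescence table for one graph architecture.

    Attributes
    ----------
    indicator : sparse.csr_matrix, shape (n_groups_rows, 2 * n_edges)
        Maps the concatenated vector ``[log binding_rates,
        log unbinding_rates]`` to per-arborescence log weights
        (X-independent part).
    row_root, row_bcount : ndarray
        Root state and binding-edge count of each arborescence row.
    group_root, group_bcount, group_start : ndarray
        Rows are sorted by (root, binding count); ``group_start`` are
        segment boundaries (length n_groups + 1) for log-sum-exp
        reduction into the ``L[root, c]`` table.
    n_nodes : int
    n_edges : int
    active_node : int
    """

    indicator: sparse.csr_matrix
    row_root: np.ndarray
    row_bcount: np.ndarray
    group_root: np.ndarray
    group_bcount: np.ndarray
    group_start: np.ndarray
    n_nodes: int
    n_edges: int
    active_node: int

    @property
    def n_groups(self) -> int:
        return len(self.group_root)

    def log_tree_weights(self, log_binding: np.ndarray, log_unbinding: np.ndarray) -> np.ndarray:
        """Per-arborescence log weights for a batch of rate sets.

        Parameters are arrays of shape ``(..., n_edges)``; the result has
        shape ``(..., n_rows)``.
        """
        logk = np.concatenate([log_binding, log_unbinding], axis=-1)
        # -inf entries (zero rates) must propagate: the sparse product
        # touches only the indicator's stored ones, so no 0 * inf = NaN
        # arises (unlike a dense product).
        squeeze = logk.ndim == 1
        out = np.asarray(self.indicator @ np.atleast_2d(logk).T).T
        return out[0] if squeeze else out

    def group_logsumexp(self, w: np.ndarray) -> np.ndarray:
        """Reduce per-row log weights ``(..., n_rows)`` to per-group
        log weights ``(..., n_groups)`` by log-sum-exp."""
        out = np.empty(w.shape[:-1] + (self.n_groups,))
        for g in range(self.n_groups):
            seg = w[..., self.group_start[g]: self.group_start[g + 1]]
            m = np.max(seg, axis=-1)
            safe = np.where(np.isfinite(m), m, 0.0)
            out[..., g] = safe + np.log(np.sum(np.exp(seg - safe[..., None]), axis=-1))
            out[..., g] = np.where(np.isfinite(m), out[..., g], -np.inf)
        return out


def _build_table(
    nodes: list,
    edges: list[tuple[object, object, int]],
    active_node: object,
) -> TreeTable:
    """Enumerate spanning arborescences of an undirected graph whose
    edges each carry a (binding, unbinding) rate pair.

    ``edges`` entries are ``(lo, hi, idx)``: the transition lo -> hi is
    binding with rate slot ``idx`` (scales with TF concentration), and
    hi -> lo is unbinding with rate slot ``n_edges + idx``.
    """
    n_edges = len(edges)
    node_id = {n: i for i, n in enumerate(nodes)}
    g = nx.Graph()
    g.add_nodes_from(range(len(nodes)))
    edge_info = {}
    for lo, hi, idx in edges:
        a, b = node_id[lo], node_id[hi]
        g.add_edge(a, b)
        edge_info[frozenset((a, b))] = (a, b, idx)  # a = low-occupancy end

    rows_slots, rows_root, rows_bcount = [], [], []
    for tree in nx.SpanningTreeIterator(g):
        adj = {n: list(tree.neighbors(n)) for n in tree.nodes}
        for root in range(len(nodes)):
            # orient toward root: BFS parents
            parent = {root: None}
            stack = [root]
            while stack:
                u = stack.pop()
                for v in adj[u]:
                    if v not in parent:
                        parent[v] = u
                        stack.append(v)
            slots, bcount = [], 0
            for child, par in parent.items():
                if par is None:
                    continue
                a, b, idx = edge_info[frozenset((child, par))]
                if par == b:  # child -> parent goes up in occupancy: binding
                    slots.append(idx)
                    bcount += 1
                else:  # unbinding
                    slots.append(n_edges + idx)
            rows_slots.append(slots)
            rows_root.append(root)
            rows_bcount.append(bcount)

    n_rows = len(rows_root)
    row_root = np.asarray(rows_root, dtype=np.int64)
    row_bcount = np.asarray(rows_bcount, dtype=np.int64)
    order = np.lexsort((row_bcount, row_root))
    row_root = row_root[order]
    row_bcount = row_bcount[order]
    rows_slots = [rows_slots[i] for i in order]

    data, indices, indptr = [], [], [0]
    for slots in rows_slots:
        indices.extend(slots)
        data.extend([1.0] * len(slots))
        indptr.append(len(indices))
    indicator = sparse.csr_matrix(
        (np.asarray(data), np.asarray(indices), np.asarray(indptr)),
        shape=(n_rows, 2 * n_edges),
    )

    keys = row_root * (row_bcount.max() + 2) + row_bcount
    boundaries = np.flatnonzero(np.diff(keys)) + 1
    group_start = np.concatenate([[0], boundaries, [n_rows]])
    group_root = row_root[group_start[:-1]]
    group_bcount = row_bcount[group_start[:-1]]

    return TreeTable(
        indicator=indicator,
        row_root=row_root,
        row_bcount=row_bcount,
        group_root=group_root,
        group_bcount=group_bcount,
        group_start=group_start,
        n_nodes=len(nodes),
        n_edges=n_edges,
        active_node=node_id[active_node],
    )


@lru_cache(maxsize=None)
def neq_graph_table(n_sites: int = N_NEQ_SITES) -> TreeTable:
    """Arborescence table for the full 2^n occupancy graph.

    Nodes are occupancy bitmasks; the active node is the fully bound
    state.  For ``n_sites = 3`` there are 8 nodes, 12 undirected edges
    (24 directed rates) and 384 spanning trees.
    """
    nodes = list(range(1 << n_sites))
    edges = [(s, s | (1 << j), e) for e, (s, j) in enumerate(neq_edge_order(n_sites))]
    return _build_table(nodes, edges, (1 << n_sites) - 1)


@lru_cache(maxsize=None)
def hybrid_table(n_eq: int = 3, n_neq: int = N_NEQ_SITES) -> TreeTable:
    """Arborescence table for the sequential hybrid promoter.

    The three non-equilibrium sites load first over their full
    occupancy graph; once they are all bound, the three equilibrium
    sites complete activation as an identical-site chain (their binding
    requires the graph full, and graph unbinding out of the full state
    requires the chain empty).  The reachable state space is the
    ``2^n_neq`` graph states plus the chain states ``1 .. n_eq`` at
    graph-full: 11 states for 3 + 3; state 0 is all-free and the last
    state is everything bound (active).

    Rate slot layout: binding ``[chain steps 1..n_eq, neq edges]``,
    unbinding likewise.
    """
    nodes: list = [("neq", s) for s in range(1 << n_neq)] + [("chain", i) for i in range(1, n_eq + 1)]
    edges = []
    full = (1 << n_neq) - 1
    for e, (s, j) in enumerate(neq_edge_order(n_neq)):
        edges.append((("neq", s), ("neq", s | (1 << j)), n_eq + e))
    for i in range(n_eq):
        lo = ("neq", full) if i == 0 else ("chain", i)
        edges.append((lo, ("chain", i + 1), i))
    return _build_table(nodes, edges, ("chain", n_eq))
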