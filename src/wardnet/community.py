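"""Newman modularity and Louvain community detection, implemented from scratch.

The modularity of a partition of an undirected graph into communities is

    Q = sum_c [ L_c / m  -  (D_c / 2m)^2 ]

where ``m`` is the total number of edges, ``L_c`` the number of edges inside
community ``c`` and ``D_c`` the summed degree of its nodes.  Values near 0
indicate no more internal structure than a random graph with the same degrees;
0.3-0.7 is typical of networks with recognisable communities.  The bipartite
ward-unit graphs are scored as ordinary undirected graphs (the convention used
by mainstream tooling), not with a bipartite-specific null model.

The Louvain algorithm greedily maximizes Q in two alternating phases: local
moving of single nodes to the neighbouring community with the best modularity
gain, then aggregation of communities into super-nodes.  Both phases repeat
until no move improves Q beyond a tolerance.  A brute-force optimal-partition
oracle (exhaustive over all set partitions, feasible to ~12 nodes) and a
bipartite random-graph null are provided for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from .build import SnapshotGraph
from .errors import GraphError, UndefinedModularityError

#: Minimum modularity gain for a local move to be accepted.
GAIN_TOL = 1e-9


@dataclass
class Partition:
    """Assignment of every node of a graph to exactly one community.

    ``membership`` maps node label to a community id; ids are contiguous
    integers starting at 0.  ``modularity`` is the Newman Q of the partition
    on the graph it was computed for.
    """

    membership: dict[str, int]
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def community_of(self, node: str) -> int:
        return self.membership[node]

    def communities(self) -> dict[int, set[str]]:
        """Community id -> set of member nodes."""
        out: dict[int, set[str]] = {}
        for n, c in self.membership.items():
            out.setdefault(c, set()).add(n)
        return out

    def relabelled(self) -> "Partition":
        """Canonical form: ids renumbered 0.. in order of first appearance
        over the lexicographically sorted node list."""
        remap: dict[int, int] = {}
        new = {}
        for n in sorted(self.membership):
            c = self.membership[n]
            if c not in remap:
                remap[c] = len(remap)
            new[n] = remap[c]
        return Partition(membership=new, modularity=self.modularity)


@dataclass
class ModularityTerms:
    """The per-community ingredients of Q: intra-community edge counts and
    degree sums, plus the total edge count ``m``."""

    m: int
    intra_edges: dict[int, int]   # L_c
    degree_sums: dict[int, int]   # D_c


def _check_membership(graph: SnapshotGraph, membership: Mapping[str, int]) -> None:
    nodes = graph.ward_nodes | graph.unit_nodes
    missing = nodes - set(membership)
    if missing:
        raise GraphError(f"membership missing {len(missing)} node(s), e.g. {sorted(missing)[:3]}")


def modularity_terms(graph: SnapshotGraph, membership: Mapping[str, int]) -> ModularityTerms:
    """Compute m, L_c and D_c for a membership on a graph."""
    _check_membership(graph, membership)
    m = graph.n_edges
    intra: dict[int, int] = {}
    dsum: dict[int, int] = {}
    for n, d in graph.degree().items():
        c = membership[n]
        dsum[c] = dsum.get(c, 0) + d
        intra.setdefault(c, 0)
    for w, u in graph.edges:
        if membership[w] == membership[u]:
            intra[membership[w]] += 1
    return ModularityTerms(m=m, intra_edges=intra, degree_sums=dsum)


def modularity(
    graph: SnapshotGraph,
    membership: Mapping[str, int],
    resolution: float = 1.0,
) -> float:
    """Newman modularity Q of a membership on an unweighted graph.

    Raises
    ------
    UndefinedModularityError
        If the graph has no edges (Q involves division by m).
    """
    if graph.n_edges == 0:
        raise UndefinedModularityError(
            f"modularity undefined on edgeless graph {graph.period_label!r}"
        )
    t = modularity_terms(graph, membership)
    m = t.m
    q = 0.0
    for c in t.degree_sums:
        q += t.intra_edges[c] / m - resolution * (t.degree_sums[c] / (2 * m)) ** 2
    return q


# ---------------------------------------------------------------------------
# Louvain
# ---------------------------------------------------------------------------


def _index_graph(graph: SnapshotGraph) -> tuple[list[str], list[dict[int, float]]]:
    """Integer-indexed adjacency (sorted label order) with unit weights."""
    nodes = graph.nodes
    index = {n: i for i, n in enumerate(nodes)}
    adj: list[dict[int, float]] = [dict() for _ in nodes]
    for w, u in graph.edges:
        i, j = index[w], index[u]
        adj[i][j] = adj[i].get(j, 0.0) + 1.0
        adj[j][i] = adj[j].get(i, 0.0) + 1.0
    return nodes, adj


def _one_level(
    adj: list[dict[int, float]],
    loops: list[float],
    m: float,
    rng: np.random.Generator,
    resolution: float,
) -> tuple[list[int], bool]:
    """One local-moving phase.  Returns (community labels, any_move_made).

    ``adj`` holds neighbour weights (no self entries); ``loops`` the
    self-loop weights of aggregated nodes; ``m`` the grand total edge weight.
    """
    n = len(adj)
    k = [sum(adj[i].values()) + 2.0 * loops[i] for i in range(n)]  # degrees
    comm = list(range(n))
    sum_tot = k.copy()  # degree sum per community

    improved_any = False
    while True:
        moved = False
        order = rng.permutation(n)
        for i in order:
            ci = comm[i]
            ki = k[i]
            # weight from i to each neighbouring community
            links: dict[int, float] = {}
            for j, w in adj[i].items():
                links[comm[j]] = links.get(comm[j], 0.0) + w
            # remove i from its community
            sum_tot[ci] -= ki
            base = links.get(ci, 0.0) - resolution * sum_tot[ci] * ki / (2.0 * m)
            best_c, best_gain = ci, base
            for c, w_ic in links.items():
                if c == ci:
                    continue
                gain = w_ic - resolution * sum_tot[c] * ki / (2.0 * m)
                # strict improvement beyond tolerance; ties keep current
                if gain > best_gain + GAIN_TOL:
                    best_c, best_gain = c, gain
            sum_tot[best_c] += ki
            if best_c != ci:
                comm[i] = best_c
                moved = True
                improved_any = True
        if not moved:
            break
    return comm, improved_any


def _aggregate(
    adj: list[dict[int, float]],
    loops: list[float],
    comm: list[int],
) -> tuple[list[dict[int, float]], list[float], dict[int, int]]:
    """Build the community super-node graph: intra-community weight becomes a
    self-loop; inter-community weights sum on the corresponding edge."""
    remap: dict[int, int] = {}
    for c in comm:
        if c not in remap:
            remap[c] = len(remap)
    nc = len(remap)
    new_adj: list[dict[int, float]] = [dict() for _ in range(nc)]
    new_loops = [0.0] * nc
    for i, nbrs in enumerate(adj):
        ci = remap[comm[i]]
        new_loops[ci] += loops[i]
        for j, w in nbrs.items():
            cj = remap[comm[j]]
            if ci == cj:
                if i < j:
                    new_loops[ci] += w
            else:
                new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
    return new_adj, new_loops, remap


def louvain(
    graph: SnapshotGraph,
    seed: int = 0,
    resolution: float = 1.0,
) -> Partition:
    """Louvain modularity maximization on a snapshot graph.

    Local moves visit nodes in a seeded random order each pass; ties keep the
    node's current community.  Deterministic given ``seed``.  The returned
    partition's Q is at least that of the all-singletons partition.

    Parameters
    ----------
    graph
        Graph with at least one edge.
    seed
        Seed of the shuffle stream.
    resolution
        Multiplies the null-model term; 1.0 is the conventional default.
    """
    if graph.n_edges == 0:
        raise UndefinedModularityError(
            f"cannot run community detection on edgeless graph {graph.period_label!r}"
        )
    nodes, adj = _index_graph(graph)
    loops = [0.0] * len(nodes)
    m = float(graph.n_edges)
    rng = np.random.default_rng(seed)

    # flat assignment of original nodes, refined level by level
    assignment = list(range(len(nodes)))
    while True:
        comm, improved = _one_level(adj, loops, m, rng, resolution)
        adj, loops, remap = _aggregate(adj, loops, comm)
        assignment = [remap[comm[a]] for a in assignment]
        if not improved or len(adj) == 1:
            break

    membership = {nodes[i]: assignment[i] for i in range(len(nodes))}
    part = Partition(membership=membership, modularity=0.0).relabelled()
    part.modularity = modularity(graph, part.membership, resolution=resolution)
    return part


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

MAX_BRUTE_NODES = 12


def _restricted_growth_strings(n: int) -> Iterator[tuple[int, ...]]:
    """All set partitions of n items as canonical label tuples.

    A restricted growth string assigns each item the id of its block, with
    each new block taking the smallest unused id; every set partition has
    exactly one such encoding, so enumeration is duplicate-free.
    """
    labels = [0] * n

    def rec(i: int, max_used: int):
        if i == n:
            yield tuple(labels)
            return
        for c in range(max_used + 2):
            labels[i] = c
            yield from rec(i + 1, max(max_used, c))

    if n == 0:
        yield ()
    else:
        yield from rec(1, 0)


def brute_force_best(graph: SnapshotGraph, resolution: float = 1.0) -> Partition:
    """Exhaustive maximum-modularity partition for graphs of <= 12 nodes.

    Scores every set partition (Bell-number enumeration, vectorised in
    chunks); ties are broken by fewest communities, then by the
    lexicographically smallest membership tuple in sorted node order.
    """
    if graph.n_edges == 0:
        raise UndefinedModularityError("brute_force_best requires at least one edge")
    nodes = graph.nodes
    n = len(nodes)
    if n > MAX_BRUTE_NODES:
        raise GraphError(
            f"brute_force_best limited to {MAX_BRUTE_NODES} nodes, got {n}"
        )
    index = {x: i for i, x in enumerate(nodes)}
    deg = graph.degree()
    d = np.array([deg[x] for x in nodes], dtype=float)
    m = float(graph.n_edges)
    edge_idx = [(index[w], index[u]) for w, u in graph.edges]
    pair_idx = [(i, j) for i in range(n) for j in range(i + 1, n)]
    sum_d2 = float(np.sum(d**2))

    best_q = -np.inf
    best: tuple[int, tuple[int, ...]] | None = None

    chunk: list[tuple[int, ...]] = []

    def score_chunk(rows: list[tuple[int, ...]]):
        nonlocal best_q, best
        p = np.array(rows, dtype=np.int8)
        intra = np.zeros(len(rows))
        for i, j in edge_idx:
            intra += p[:, i] == p[:, j]
        s = np.full(len(rows), sum_d2)
        for i, j in pair_idx:
            s += 2.0 * d[i] * d[j] * (p[:, i] == p[:, j])
        q = intra / m - resolution * s / (4.0 * m * m)
        for r, qv in zip(rows, q):
            if qv > best_q + 1e-12:
                best_q = qv
                best = (len(set(r)), r)
            elif abs(qv - best_q) <= 1e-12:
                cand = (len(set(r)), r)
                if cand < best:
                    best = cand

    for rgs in _restricted_growth_strings(n):
        chunk.append(rgs)
        if len(chunk) >= 50_000:
            score_chunk(chunk)
            chunk = []
    if chunk:
        score_chunk(chunk)

    assert best is not None
    membership = {nodes[i]: int(best[1][i]) for i in range(n)}
    return Partition(membership=membership, modularity=float(best_q))


# ---------------------------------------------------------------------------
# Random-graph null
# ---------------------------------------------------------------------------


@dataclass
class NullSummary:
    """Distribution of Louvain modularity over bipartite random graphs with a
    fixed number of uniformly placed ward-unit edges."""

    mean: float
    sd: float
    p99: float
    n_reps: int
    samples: np.ndarray = field(repr=False)

    def z_score(self, q_observed: float) -> float:
        """Empirical z-score of an observed modularity against the null."""
        if self.sd == 0:
            return float("inf") if q_observed > self.mean else 0.0
        return (q_observed - self.mean) / self.sd


def random_graph_null(
    n_ward: int,
    n_unit: int,
    m: int,
    n_reps: int = 500,
    seed: int = 0,
    resolution: float = 1.0,
) -> NullSummary:
    """Louvain modularity distribution on bipartite Erdos-Renyi-style graphs.

    Each replicate places ``m`` distinct ward-unit edges uniformly at random
    among the ``n_ward * n_unit`` possible pairs, mirroring the null in which
    nodes connect at random with no modular organisation.  Isolated nodes are
    dropped, as in graphs built from stays.
    """
    if m > n_ward * n_unit:
        raise GraphError(f"cannot place {m} edges among {n_ward}x{n_unit} pairs")
    if m < 1:
        raise GraphError("null model needs at least one edge")
    rng = np.random.default_rng(seed)
    qs = np.empty(n_reps)
    for rep in range(n_reps):
        flat = rng.choice(n_ward * n_unit, size=m, replace=False)
        edges = {(f"w{f // n_unit:03d}", f"u{f % n_unit:03d}"): 1 for f in flat}
        g = SnapshotGraph(
            ward_nodes={e[0] for e in edges},
            unit_nodes={e[1] for e in edges},
            edges=edges,
            period_label=f"null:{rep}",
        )
        qs[rep] = louvain(g, seed=int(rng.integers(2**31)), resolution=resolution).modularity
    return NullSummary(
        mean=float(np.mean(qs)),
        sd=float(np.std(qs, ddof=1)) if n_reps > 1 else 0.0,
        p99=float(np.percentile(qs, 99)),
        n_reps=n_reps,
        samples=qs,
    )
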