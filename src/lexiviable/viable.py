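"""Viable clusters (mutually connected components) of multiplex networks.

A *viable cluster* is a node set whose induced subgraph is connected on
every layer considered in isolation: any member can reach any other member
without leaving the cluster, using links of a single layer, for each layer
in turn.  On a single-layer network the largest viable cluster coincides
with the largest connected component; with several layers it is a strictly
stronger notion, and its sudden appearance under node addition is the
hallmark of explosive (hybrid) percolation in interdependent networks.

Clusters of one or two nodes always exist wherever a link overlaps on all
layers and are called *trivial*; analyses focus on non-trivial clusters
(more than two members).

Detection uses fixpoint refinement: starting from a candidate superset,
repeatedly replace the candidate by the connected component (within the
candidate, on one layer at a time) containing a seed node, until the set
stabilises.  The fixpoint is the unique maximal viable cluster containing
the seed, independent of the layer refinement order; maximal viable
clusters are pairwise disjoint because the union of two overlapping viable
sets is itself viable.  A subset-enumeration brute force is provided as an
independent correctness oracle for small instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable, Mapping
from itertools import combinations

from .multiplex import MultiplexNetwork

__all__ = [
    "ViableCluster",
    "maximal_viable_clusters",
    "largest_viable_cluster",
    "brute_force_viable_clusters",
    "NONTRIVIAL_MIN_SIZE",
]

#: A viable cluster is non-trivial iff it has more than two members.
NONTRIVIAL_MIN_SIZE = 3

_BRUTE_FORCE_MAX_NODES = 15


@dataclass(frozen=True)
class ViableCluster:
    """A maximal node set connected within every layer's induced subgraph."""

    members: frozenset
    per_layer_connected: Mapping[str, bool]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def nontrivial(self) -> bool:
        return len(self.members) >= NONTRIVIAL_MIN_SIZE

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


def _adjacencies(net: MultiplexNetwork) -> list[dict]:
    return [net.adjacency(layer) for layer in net.layers]


def _component_within(adj: dict, seed, candidate: set) -> set:
    """Connected component of ``seed`` in the induced subgraph on ``candidate``."""
    seen = {seed}
    stack = [seed]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v in candidate and v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def refine_to_viable(adjacencies: list[dict], seed, candidate: set) -> set:
    """Fixpoint refinement of ``candidate`` around ``seed``.

    Requires ``candidate`` to contain the maximal viable cluster of
    ``seed`` (any superset works, e.g. all nodes).  Iterates layer-wise
    component extraction until the set stabilises; the result is viable on
    every layer and maximal among viable sets containing the seed.
    """
    current = set(candidate)
    while True:
        size_before = len(current)
        for adj in adjacencies:
            if len(current) == 1:
                return current
            current = _component_within(adj, seed, current)
        if len(current) == size_before:
            # One clean pass with no shrinkage on any layer: fixpoint.
            return current


def maximal_viable_clusters(
    net: MultiplexNetwork, include_trivial: bool = False
) -> list[ViableCluster]:
    """All maximal viable clusters, largest first.

    Clusters are pairwise disjoint and partition-complete over the node
    set when ``include_trivial`` is set (every node belongs to exactly one
    maximal cluster, possibly a singleton).  By default clusters of one or
    two nodes are dropped.

    Ties in the size ordering break on the lexicographically smallest
    member set, so output order is deterministic.
    """
    adjacencies = _adjacencies(net)
    unassigned = set(net.nodes)
    clusters: list[set] = []
    for seed in net.nodes:  # lexicographic seed order
        if seed not in unassigned:
            continue
        # Starting from the unassigned pool is safe: maximal viable
        # clusters are disjoint, so the seed's cluster cannot intersect
        # previously extracted ones.
        cluster = refine_to_viable(adjacencies, seed, unassigned)
        clusters.append(cluster)
        unassigned -= cluster
    result = [
        ViableCluster(frozenset(c), {layer: True for layer in net.layers})
        for c in clusters
        if include_trivial or len(c) >= NONTRIVIAL_MIN_SIZE
    ]
    result.sort(key=lambda c: (-c.size, c.sorted_members()))
    return result


def largest_viable_cluster(net: MultiplexNetwork) -> ViableCluster:
    """The largest non-trivial viable cluster (LVC), or an empty cluster.

    On single-layer input this is exactly the largest connected component.
    Size ties break on the lexicographically smallest member set.
    """
    clusters = maximal_viable_clusters(net, include_trivial=False)
    if not clusters:
        return ViableCluster(frozenset(), {layer: True for layer in net.layers})
    return clusters[0]


def is_viable(net: MultiplexNetwork, members: Iterable[str]) -> bool:
    """Check viability of an explicit node set (induced connectivity on
    every layer).  Singleton sets count as (trivially) viable."""
    members = set(members)
    if not members:
        return False
    if len(members) == 1:
        return True
    adjacencies = _adjacencies(net)
    seed = next(iter(members))
    for adj in adjacencies:
        if _component_within(adj, seed, members) != members:
            return False
    return True


def brute_force_viable_clusters(
    net: MultiplexNetwork, include_trivial: bool = False
) -> list[ViableCluster]:
    """Subset-enumeration oracle: every viable set of size ≥ 2, reduced to
    the maximal ones under inclusion.  Guarded to ≤ 15 nodes.

    Singleton maximal clusters are emitted (under ``include_trivial``) for
    nodes covered by no viable pair, matching the fixpoint detector's
    partition-completeness.
    """
    nodes = list(net.nodes)
    if len(nodes) > _BRUTE_FORCE_MAX_NODES:
        raise ValueError(
            f"brute force limited to {_BRUTE_FORCE_MAX_NODES} nodes, got {len(nodes)}"
        )
    viable_sets: list[frozenset] = []
    for size in range(2, len(nodes) + 1):
        for subset in combinations(nodes, size):
            if is_viable(net, subset):
                viable_sets.append(frozenset(subset))
    maximal = [
        s for s in viable_sets if not any(s < t for t in viable_sets)
    ]
    if include_trivial:
        covered = set().union(*maximal) if maximal else set()
        maximal.extend(frozenset({n}) for n in nodes if n not in covered)
    layers_ok = {layer: True for layer in net.layers}
    result = [
        ViableCluster(s, layers_ok)
        for s in maximal
        if include_trivial or len(s) >= NONTRIVIAL_MIN_SIZE
    ]
    result.sort(key=lambda c: (-c.size, c.sorted_members()))
    return result
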