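"""Topology and attribute randomisation null models.

Four randomisations probe which correlations carry the largest viable
cluster (LVC):

* **configuration rewiring** — degree-preserving double-edge swaps within
  each layer; destroys specific link placement while keeping every word's
  within-layer degree.
* **full reshuffling** — an independent uniform relabelling of words on
  each layer; every layer stays isomorphic to itself, but word identity
  across layers (the inter-layer correlation viability relies on) is
  destroyed.  A *targeted* variant restricts the relabelling to a chosen
  word subset, e.g. the heavy tail of the polysemy distribution.
* **label perturbation** — a small fraction of labels permuted per layer,
  modelling annotation errors.
* **partial reshuffling** — topology fixed, named node attributes
  permuted across words; destroys attribute–topology correlations only.

All topology nulls preserve N, the layer count and per-layer edge counts;
configuration rewiring additionally preserves per-layer degree sequences
exactly (asserted on every call).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from collections.abc import Iterable, Sequence

import numpy as np

from .multiplex import MultiplexNetwork, WordAttributes, multidegree
from .viable import largest_viable_cluster

logger = logging.getLogger(__name__)

__all__ = [
    "configuration_rewire",
    "full_reshuffle",
    "targeted_full_reshuffle",
    "attribute_tail",
    "label_perturbation",
    "partial_reshuffle",
    "lvc_persistence",
    "PersistenceResult",
]

_SWAP_ATTEMPT_FACTOR = 100  # cap: attempts per requested swap


def _layer_degrees(edges: Iterable[tuple[str, str]]) -> dict[str, int]:
    deg: dict[str, int] = {}
    for u, v in edges:
        deg[u] = deg.get(u, 0) + 1
        deg[v] = deg.get(v, 0) + 1
    return deg


def _rewire_layer(
    edges: frozenset, fraction: float, rng: np.random.Generator
) -> frozenset:
    """Double-edge swaps until ``fraction`` of the layer's links have been
    displaced from their original position (no self-loops/multi-edges)."""
    edge_list = [tuple(e) for e in edges]
    m = len(edge_list)
    if m < 2:
        logger.warning("layer with %d edges left unchanged by rewiring", m)
        return edges
    original = set(edge_list)
    current = set(edge_list)
    if fraction >= 1.0:
        attempts_budget = 10 * m  # burn-in for full randomisation
        target_moved = m
    else:
        target_moved = math.ceil(fraction * m)
        requested_swaps = max(1, math.ceil(target_moved / 2))
        attempts_budget = _SWAP_ATTEMPT_FACTOR * requested_swaps
    moved = 0
    attempts = 0
    while attempts < attempts_budget:
        if fraction < 1.0 and moved >= target_moved:
            break
        attempts += 1
        i, j = rng.integers(m), rng.integers(m)
        if i == j:
            continue
        a, b = edge_list[i]
        c, d = edge_list[j]
        if rng.random() < 0.5:
            b, a = a, b
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        e1 = (a, d) if a < d else (d, a)
        e2 = (c, b) if c < b else (b, c)
        old1, old2 = edge_list[i], edge_list[j]
        if e1 in current or e2 in current or e1 == e2:
            continue
        current.discard(old1)
        current.discard(old2)
        current.add(e1)
        current.add(e2)
        moved += (old1 in original) + (old2 in original)
        moved -= (e1 in original) + (e2 in original)
        edge_list[i], edge_list[j] = e1, e2
    else:
        if fraction < 1.0 and moved < target_moved:
            logger.warning(
                "rewiring attempt cap reached: moved %d of %d requested links",
                moved, target_moved,
            )
    return frozenset(current)


def configuration_rewire(
    net: MultiplexNetwork, fraction: float, seed: int | np.random.Generator
) -> MultiplexNetwork:
    """Degree-preserving rewiring of a fraction of each layer's links.

    ``fraction=0`` returns an identical network; ``fraction=1`` fully
    randomises each layer (10×|E| attempted swaps).  Layers with fewer
    than two edges are left unchanged with a warning.  Per-layer degree
    sequences are asserted identical to the input on every call.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if fraction == 0.0:
        return net
    new_edges = {
        layer: _rewire_layer(net.edges[layer], fraction, rng)
        for layer in net.layers
    }
    for layer in net.layers:  # invariant: exact degree preservation
        assert _layer_degrees(new_edges[layer]) == _layer_degrees(net.edges[layer]), (
            f"degree sequence broken on layer {layer!r}"
        )
    return MultiplexNetwork(net.nodes, net.layers, new_edges,
                            allow_isolated=net.allow_isolated)


def full_reshuffle(
    net: MultiplexNetwork,
    seed: int | np.random.Generator,
    subset: Iterable[str] | None = None,
) -> MultiplexNetwork:
    """Independent per-layer relabelling of words (within ``subset``).

    Each layer is isomorphic to its original, but word identification
    across layers is destroyed inside the subset.  Single-layer networks
    are therefore unaffected in every label-invariant quantity.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = sorted(set(net.nodes) if subset is None else set(map(str, subset)))
    unknown = set(pool) - set(net.nodes)
    if unknown:
        raise KeyError(f"subset nodes not in network: {sorted(unknown)[:5]}")
    new_edges = {}
    for layer in net.layers:
        perm = rng.permutation(len(pool))
        mapping = {pool[i]: pool[perm[i]] for i in range(len(pool))}
        relabelled = set()
        for u, v in net.edges[layer]:
            a, b = mapping.get(u, u), mapping.get(v, v)
            relabelled.add((a, b) if a < b else (b, a))
        new_edges[layer] = frozenset(relabelled)
    return MultiplexNetwork(net.nodes, net.layers, new_edges, allow_isolated=True)


def targeted_full_reshuffle(
    net: MultiplexNetwork, words: Iterable[str], seed: int | np.random.Generator
) -> MultiplexNetwork:
    """Full reshuffling restricted to a word subset (e.g. the heavy tail
    of the polysemy distribution)."""
    words = set(words)
    if not words:
        raise ValueError("targeted reshuffle needs a non-empty word subset")
    return full_reshuffle(net, seed, subset=words)


def attribute_tail(attrs: WordAttributes, attribute: str, k: int) -> set:
    """The k words with the largest value of ``attribute`` (the heavy
    tail), ties broken lexicographically."""
    col = attrs.column(attribute).dropna()
    if k > col.size:
        raise ValueError(f"requested tail of {k} but only {col.size} rated words")
    ranked = col.sort_values(ascending=False, kind="mergesort")
    return set(ranked.index[:k])


def label_perturbation(
    net: MultiplexNetwork, per_layer_fraction: float, seed: int | np.random.Generator
) -> MultiplexNetwork:
    """Permute the labels of ⌈fraction·N⌉ uniformly chosen words on each
    layer independently, modelling annotation noise."""
    if not 0.0 <= per_layer_fraction <= 1.0:
        raise ValueError("per_layer_fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if per_layer_fraction == 0.0:
        return net
    k = math.ceil(per_layer_fraction * net.n_nodes)
    nodes = list(net.nodes)
    new_edges = {}
    for layer in net.layers:
        chosen = [nodes[i] for i in rng.choice(net.n_nodes, size=k, replace=False)]
        perm = rng.permutation(k)
        mapping = {chosen[i]: chosen[perm[i]] for i in range(k)}
        relabelled = set()
        for u, v in net.edges[layer]:
            a, b = mapping.get(u, u), mapping.get(v, v)
            relabelled.add((a, b) if a < b else (b, a))
        new_edges[layer] = frozenset(relabelled)
    return MultiplexNetwork(net.nodes, net.layers, new_edges, allow_isolated=True)


def partial_reshuffle(
    attrs: WordAttributes,
    attribute_names: Sequence[str],
    seed: int | np.random.Generator,
    joint: bool = False,
) -> WordAttributes:
    """Permute named attribute columns across words, topology untouched.

    Each named column is permuted independently by default; ``joint=True``
    applies one common permutation to all named columns (preserving their
    mutual dependence while breaking the link to the words)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    table = attrs.table.copy()
    for name in attribute_names:
        if name not in table.columns:
            raise KeyError(f"unknown attribute {name!r}")
    if joint and attribute_names:
        perm = rng.permutation(len(table))
        for name in attribute_names:
            table[name] = table[name].to_numpy()[perm]
    else:
        for name in attribute_names:
            table[name] = table[name].to_numpy()[rng.permutation(len(table))]
    return WordAttributes(table.reset_index())


@dataclass(frozen=True)
class PersistenceResult:
    """Percentage of original LVC members still in the LVC after rewiring."""

    mean: float
    sd: float
    values: np.ndarray
    rewire_fraction: float
    repetitions: int


def lvc_persistence(
    net: MultiplexNetwork,
    rewire_fraction: float,
    repetitions: int,
    seed: int | np.random.Generator,
) -> PersistenceResult:
    """LVC membership persistence under configuration rewiring.

    Per repetition: rewire ``rewire_fraction`` of each layer's links,
    re-detect the LVC, and record |LVC_orig ∩ LVC_new| / |LVC_orig| × 100.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    original = largest_viable_cluster(net).members
    if not original:
        raise ValueError("network has no non-trivial LVC")
    values = np.zeros(repetitions)
    for r in range(repetitions):
        rewired = configuration_rewire(net, rewire_fraction, rng)
        new = largest_viable_cluster(rewired).members
        values[r] = 100.0 * len(original & new) / len(original)
    return PersistenceResult(
        mean=float(values.mean()),
        sd=float(values.std(ddof=0)),
        values=values,
        rewire_fraction=rewire_fraction,
        repetitions=repetitions,
    )
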