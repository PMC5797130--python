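"""Progressive-anomia experiments: targeted word removal and closeness.

Anomia — progressive loss of word retrieval — is modelled as random word
failure: words are removed from every layer at once, and lexical
navigability is summarised by the median closeness centrality over the
remaining words.  Because a node-aligned multiplex imposes no cost on
switching layers, shortest paths reduce to paths on the aggregate (union)
graph, and closeness of word i is (N−1)/Σ_j d(i, j) in hops.

Removal strategies target words inside the largest viable cluster, a
random outside sample, or a multidegree-matched outside sample (isolating
the degree effect).  The contrast between the in-core and degree-matched
curves measures how much of the lexicon's navigability the viable core
carries beyond what its degrees explain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from collections.abc import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .multiplex import MultiplexNetwork
from .stats import degree_corrected_sample

logger = logging.getLogger(__name__)

__all__ = [
    "multiplex_closeness",
    "is_connected",
    "removal_experiment",
    "RemovalExperiment",
]


def _aggregate_csr(net: MultiplexNetwork, subset: Sequence[str] | None = None):
    nodes = list(net.nodes) if subset is None else sorted(subset)
    index = {w: i for i, w in enumerate(nodes)}
    rows, cols = [], []
    for layer in net.layers:
        for u, v in net.edges[layer]:
            if u in index and v in index:
                rows.append(index[u])
                cols.append(index[v])
    n = len(nodes)
    data = np.ones(2 * len(rows), dtype=np.int8)
    adj = csr_matrix(
        (data, (rows + cols, cols + rows)), shape=(n, n), dtype=np.int8
    )
    adj.data[:] = 1  # collapse parallel copies from different layers
    return adj, nodes


def is_connected(net: MultiplexNetwork, subset: Sequence[str] | None = None) -> bool:
    """Whether every pair of words is reachable when traversal may use
    links of any layer (connectivity of the aggregate graph)."""
    adj, nodes = _aggregate_csr(net, subset)
    if len(nodes) <= 1:
        return True
    n_comp, _ = connected_components(adj, directed=False)
    return n_comp == 1


def multiplex_closeness(
    net: MultiplexNetwork,
    subset: Sequence[str] | None = None,
    harmonic: bool = False,
):
    """Closeness centrality of every word on the aggregate graph.

    Returns ``(mapping word -> closeness, median closeness)``.  Distances
    are shortest-path hop counts allowing traversal along any layer's
    links.  The aggregate graph must be connected; ``harmonic=True``
    switches to harmonic closeness (mean of 1/d), which tolerates
    disconnected aggregates.
    """
    adj, nodes = _aggregate_csr(net, subset)
    n = len(nodes)
    if n < 2:
        raise ValueError("closeness needs at least two words")
    dist = shortest_path(adj, method="D", directed=False, unweighted=True)
    if not harmonic:
        if np.isinf(dist).any():
            raise ValueError(
                "aggregate graph is disconnected; use harmonic=True for a fallback"
            )
        closeness = (n - 1) / dist.sum(axis=1)
    else:
        with np.errstate(divide="ignore"):
            inv = 1.0 / dist
        np.fill_diagonal(inv, 0.0)
        inv[np.isinf(dist)] = 0.0
        closeness = inv.sum(axis=1) / (n - 1)
    mapping = dict(zip(nodes, closeness.tolist()))
    return mapping, float(np.median(closeness))


@dataclass(frozen=True)
class RemovalExperiment:
    """Median-closeness degradation under progressive word removal."""

    strategy: str
    removal_counts: np.ndarray      # words removed at each measurement
    median_closeness: np.ndarray    # mean over repetitions, per count
    sd: np.ndarray                  # sd over repetitions, per count
    mean_closeness: np.ndarray      # mean of the per-node mean, logged too
    repetitions: int
    seed: int | None
    truncated_repetitions: int = 0  # repetitions stopped by disconnection


def removal_experiment(
    net: MultiplexNetwork,
    pool: Iterable[str],
    max_removed: int,
    step: int = 25,
    repetitions: int = 50,
    seed: int | np.random.Generator = 0,
    degree_match_pool: Iterable[str] | None = None,
    strategy: str | None = None,
) -> RemovalExperiment:
    """Progressive random removal from ``pool`` with closeness tracking.

    Per repetition, a uniformly random removal sequence of length
    ``max_removed`` is drawn from the pool; median closeness of the
    remaining multiplex is recorded at every multiple of ``step`` (and at
    0 and ``max_removed``).  When ``degree_match_pool`` is given, the
    drawn words act as the reference sample and their multidegree-matched
    counterparts from that pool are removed instead.

    Aggregate connectivity is asserted after each batch: a repetition
    whose removals disconnect the aggregate stops early with a warning
    and NaNs for the remaining measurement points.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = sorted(set(pool))
    if not pool:
        raise ValueError("empty removal pool")
    if max_removed > len(pool):
        raise ValueError(f"max_removed={max_removed} exceeds pool size {len(pool)}")
    if step < 1:
        raise ValueError("step must be >= 1")
    counts = list(range(0, max_removed + 1, step))
    if counts[-1] != max_removed:
        counts.append(max_removed)
    counts = np.asarray(counts)

    results = np.full((repetitions, counts.size), np.nan)
    means = np.full((repetitions, counts.size), np.nan)
    truncated = 0
    all_nodes = set(net.nodes)
    for rep in range(repetitions):
        drawn = [pool[i] for i in rng.choice(len(pool), size=max_removed, replace=False)]
        if degree_match_pool is not None:
            drawn, _ = degree_corrected_sample(net, drawn, degree_match_pool, rng)
        broke = False
        for ci, count in enumerate(counts):
            if broke:
                continue
            remaining = all_nodes - set(drawn[:count])
            if not is_connected(net, remaining):
                warnings.warn(
                    f"aggregate disconnected after removing {count} words; "
                    f"repetition {rep} stopped early"
                )
                truncated += 1
                broke = True
                continue
            mapping, median = multiplex_closeness(net, remaining)
            results[rep, ci] = median
            means[rep, ci] = float(np.mean(list(mapping.values())))

    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return RemovalExperiment(
            strategy=strategy or ("degree_corrected" if degree_match_pool is not None else "pool"),
            removal_counts=counts,
            median_closeness=np.nanmean(results, axis=0),
            sd=np.nanstd(results, axis=0, ddof=0),
            mean_closeness=np.nanmean(means, axis=0),
            repetitions=repetitions,
            seed=seed_val,
            truncated_repetitions=truncated,
        )
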