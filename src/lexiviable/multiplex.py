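"""Node-aligned multiplex networks of word-word similarity relations.

The mental lexicon is modelled as a multiplex network: one shared set of
words replicated across layers, where each layer holds a single relation
type (free associations, synonyms, taxonomic links, phonological
similarities, ...).  Layers are undirected and unweighted, and a word must
carry at least one link on at least one layer to belong to the lexicon.

This module provides the :class:`MultiplexNetwork` container, the
:class:`WordAttributes` psycholinguistic attribute table, tabular I/O, and
the graph primitives (induced subnetworks, per-layer components,
multidegree, layer aggregation) that every analysis stage builds on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MultiplexNetwork",
    "WordAttributes",
    "ATTRIBUTE_COLUMNS",
    "load_multiplex",
    "write_multiplex",
    "read_edge_tables",
    "induced_subnetwork",
    "layer_components",
    "multidegree",
    "aggregate_graph",
]

#: Canonical attribute columns, in table order.
ATTRIBUTE_COLUMNS = (
    "aoa_mean",
    "aoa_sd",
    "frequency",
    "polysemy",
    "concreteness",
    "reaction_time",
    "length",
)


def _canonical_edge(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class MultiplexNetwork:
    """A node-aligned multiplex network with named undirected layers.

    Parameters
    ----------
    nodes
        Shared node (word) set, stored in lexicographic order.
    layers
        Ordered layer names.
    edges
        Mapping ``layer -> frozenset`` of canonical (sorted) node pairs.
    allow_isolated
        Induced subnetworks of growth prefixes legitimately contain words
        with no links yet; they set this flag.  Freshly loaded lexica do
        not: every word must be connected on at least one layer.
    """

    nodes: tuple[str, ...]
    layers: tuple[str, ...]
    edges: Mapping[str, frozenset]
    allow_isolated: bool = False
    _graph_cache: dict = field(default_factory=dict, compare=False, repr=False)

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Mapping[str, Iterable[tuple[str, str]]],
        nodes: Iterable[str] | None = None,
        allow_isolated: bool = False,
    ) -> "MultiplexNetwork":
        """Build a canonical multiplex from per-layer edge iterables.

        Self-loops are rejected, duplicate/reversed pairs collapse to one
        stored edge, and the node set defaults to all edge endpoints.
        """
        layer_names = tuple(edges.keys())
        if len(set(layer_names)) != len(layer_names):
            raise ValueError("layer names must be unique")
        canon: dict[str, frozenset] = {}
        endpoints: set[str] = set()
        for layer, pairs in edges.items():
            layer_edges = set()
            for u, v in pairs:
                if u == v:
                    raise ValueError(f"self-loop {u!r} on layer {layer!r}")
                layer_edges.add(_canonical_edge(str(u), str(v)))
            canon[layer] = frozenset(layer_edges)
            endpoints.update(u for e in layer_edges for u in e)
        if nodes is None:
            node_tuple = tuple(sorted(endpoints))
        else:
            node_tuple = tuple(sorted(set(map(str, nodes))))
            missing = endpoints - set(node_tuple)
            if missing:
                raise ValueError(f"edge endpoints not in node set: {sorted(missing)[:5]}")
        net = cls(node_tuple, layer_names, canon, allow_isolated=allow_isolated)
        if not allow_isolated:
            isolated = net.isolated_nodes()
            if isolated:
                raise ValueError(
                    f"{len(isolated)} nodes isolated on every layer "
                    f"(e.g. {sorted(isolated)[:5]}); drop them or pass allow_isolated=True"
                )
        return net

    # -- basic queries ------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def edge_count(self, layer: str | None = None) -> int:
        """Edges on one layer, or summed over all layers."""
        if layer is not None:
            self._check_layer(layer)
            return len(self.edges[layer])
        return sum(len(e) for e in self.edges.values())

    def has_node(self, word: str) -> bool:
        return word in set(self.nodes)

    def isolated_nodes(self) -> set[str]:
        """Nodes with no edge on any layer."""
        touched: set[str] = set()
        for layer_edges in self.edges.values():
            for u, v in layer_edges:
                touched.add(u)
                touched.add(v)
        return set(self.nodes) - touched

    def _check_layer(self, layer: str) -> None:
        if layer not in self.edges:
            raise KeyError(f"unknown layer {layer!r}; have {list(self.layers)}")

    # -- graph views --------------------------------------------------

    def layer_graph(self, layer: str) -> nx.Graph:
        """networkx view of one layer over the full shared node set."""
        self._check_layer(layer)
        if layer not in self._graph_cache:
            g = nx.Graph()
            g.add_nodes_from(self.nodes)
            g.add_edges_from(self.edges[layer])
            self._graph_cache[layer] = g
        return self._graph_cache[layer]

    def adjacency(self, layer: str) -> dict[str, set]:
        """Plain dict-of-sets adjacency for one layer (all nodes keyed)."""
        self._check_layer(layer)
        adj: dict[str, set] = {n: set() for n in self.nodes}
        for u, v in self.edges[layer]:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def degree(self, word: str, layer: str) -> int:
        self._check_layer(layer)
        if word not in set(self.nodes):
            raise KeyError(f"unknown word {word!r}")
        return sum(1 for u, v in self.edges[layer] if word in (u, v))


def load_multiplex(
    edge_tables: Mapping[str, Iterable[tuple[str, str]]],
) -> MultiplexNetwork:
    """Assemble a canonical multiplex from per-layer edge lists.

    Rows with two identical endpoints are rejected (reported via a
    warning); reversed and duplicated pairs collapse to a single stored
    undirected edge.  Nodes left isolated on every layer are dropped with
    a logged warning — the lexicon requires connectivity on at least one
    layer.  An empty layer (no surviving edges) is an error.
    """
    cleaned: dict[str, list[tuple[str, str]]] = {}
    layer_names = list(edge_tables.keys())
    if len(set(layer_names)) != len(layer_names):
        raise ValueError("layer names must be unique")
    if not layer_names:
        raise ValueError("at least one layer is required")
    for layer, rows in edge_tables.items():
        kept = []
        rejected = 0
        for row in rows:
            u, v = row[0], row[1]
            if u == v:
                rejected += 1
                continue
            kept.append((str(u), str(v)))
        if rejected:
            logger.warning("layer %r: rejected %d self-loop rows", layer, rejected)
        if not kept:
            raise ValueError(f"layer {layer!r} is empty after cleaning")
        cleaned[layer] = kept

    net = MultiplexNetwork.from_edges(cleaned, allow_isolated=True)
    isolated = net.isolated_nodes()
    if isolated:  # cannot happen when nodes come from endpoints, kept for safety
        logger.warning("dropping %d all-isolated nodes", len(isolated))
        return induced_subnetwork(net, set(net.nodes) - isolated)
    return MultiplexNetwork(net.nodes, net.layers, net.edges, allow_isolated=False)


def read_edge_tables(
    paths: Mapping[str, str | Path] | str | Path,
) -> dict[str, list[tuple[str, str]]]:
    """Read TSV edge lists: one two-column file per layer, or a single
    three-column (word1, word2, layer) file.  ``#`` comment lines are
    ignored; files are UTF-8."""
    tables: dict[str, list[tuple[str, str]]] = {}
    if isinstance(paths, (str, Path)):
        df = pd.read_csv(paths, sep="\t", comment="#", header=None, dtype=str)
        if df.shape[1] != 3:
            raise ValueError("single-file edge list must have 3 columns (word1, word2, layer)")
        for layer, sub in df.groupby(df.columns[2], sort=False):
            tables[str(layer)] = list(zip(sub.iloc[:, 0], sub.iloc[:, 1]))
        return tables
    for layer, path in paths.items():
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"edge list {path} needs two columns")
        tables[str(layer)] = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return tables


def write_multiplex(net: MultiplexNetwork, directory: str | Path) -> dict[str, Path]:
    """Write one canonical TSV edge list per layer; returns the paths.

    Edges are written as sorted pairs in lexicographic order so that
    ``load_multiplex(read_edge_tables(...))`` round-trips byte-identically.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for layer in net.layers:
        path = directory / f"{layer}.tsv"
        rows = sorted(net.edges[layer])
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in rows:
                fh.write(f"{u}\t{v}\n")
        paths[layer] = path
    return paths


def induced_subnetwork(net: MultiplexNetwork, subset: Iterable[str]) -> MultiplexNetwork:
    """Restrict the multiplex to a node subset, keeping all layers.

    Only edges with both endpoints inside ``subset`` survive.  Nodes that
    end up isolated on every layer are *retained*: growth prefixes contain
    words whose links have not been acquired yet.
    """
    subset = set(map(str, subset))
    unknown = subset - set(net.nodes)
    if unknown:
        raise KeyError(f"nodes not in network: {sorted(unknown)[:5]}")
    edges = {
        layer: frozenset(e for e in net.edges[layer] if e[0] in subset and e[1] in subset)
        for layer in net.layers
    }
    return MultiplexNetwork(
        tuple(sorted(subset)), net.layers, edges, allow_isolated=True
    )


def layer_components(net: MultiplexNetwork, layer: str) -> list[set]:
    """Connected components of one layer, covering every node.

    Singleton components are allowed (nodes isolated on this layer)."""
    net._check_layer(layer)
    return [set(c) for c in nx.connected_components(net.layer_graph(layer))]


def multidegree(net: MultiplexNetwork, word: str | None = None):
    """Sum of a word's within-layer degrees over all layers.

    With ``word=None`` returns a dict for every node."""
    counts = {n: 0 for n in net.nodes}
    for layer_edges in net.edges.values():
        for u, v in layer_edges:
            counts[u] += 1
            counts[v] += 1
    if word is None:
        return counts
    if word not in counts:
        raise KeyError(f"unknown word {word!r}")
    return counts[word]


def aggregate_graph(net: MultiplexNetwork) -> nx.Graph:
    """Union of all layers' edges on the shared node set.

    Traversal "along links on any layer" reduces to paths on this graph;
    parallel copies of an edge on several layers collapse to one."""
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for layer_edges in net.edges.values():
        g.add_edges_from(layer_edges)
    return g


class WordAttributes:
    """Per-word psycholinguistic records backed by a pandas DataFrame.

    Columns: ``aoa_mean`` / ``aoa_sd`` (years, rated age of acquisition and
    its between-rater spread), ``frequency`` (occurrence counts),
    ``polysemy`` (number of dictionary definitions, ≥ 1), ``concreteness``
    (rating on a 1–5 scale), ``reaction_time`` (ms, lexical decision), and
    ``length`` (letters).  Missing values are NaN and explicitly queryable
    through :meth:`missing`.
    """

    def __init__(self, table: pd.DataFrame, validate: bool = True):
        table = table.copy()
        if table.index.name != "word":
            if "word" in table.columns:
                table = table.set_index("word")
            else:
                table.index.name = "word"
        table.index = table.index.astype(str)
        for col in ATTRIBUTE_COLUMNS:
            if col not in table.columns:
                table[col] = np.nan
        self.table = table[list(ATTRIBUTE_COLUMNS)].astype(float).sort_index()
        if validate:
            self.validate()

    def validate(self) -> None:
        t = self.table
        checks = [
            ("aoa_sd", t["aoa_sd"] < 0),
            ("frequency", t["frequency"] < 0),
            ("polysemy", t["polysemy"] < 1),
            ("length", t["length"] < 1),
            ("concreteness", (t["concreteness"] < 1) | (t["concreteness"] > 5)),
        ]
        for name, bad in checks:
            bad = bad.fillna(False)
            if bad.any():
                raise ValueError(
                    f"invalid {name} for words {list(t.index[bad])[:5]}"
                )

    @property
    def words(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def __getitem__(self, word: str) -> pd.Series:
        return self.table.loc[word]

    def missing(self, column: str) -> list[str]:
        """Words whose value for ``column`` is missing."""
        return list(self.table.index[self.table[column].isna()])

    def column(self, name: str, words: Sequence[str] | None = None) -> pd.Series:
        if name == "log_frequency":
            freq = self.table["frequency"]
            vals = np.log10(freq.where(freq > 0))
            vals.name = "log_frequency"
        else:
            if name not in self.table.columns:
                raise KeyError(f"unknown attribute {name!r}")
            vals = self.table[name]
        if words is not None:
            vals = vals.loc[list(words)]
        return vals

    # -- I/O -----------------------------------------------------------

    @classmethod
    def read_table(cls, path: str | Path) -> "WordAttributes":
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep, comment="#", dtype={"word": str})
        if "word" not in df.columns:
            raise ValueError("attribute table needs a 'word' header column")
        return cls(df)

    def write_table(self, path: str | Path) -> None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        self.table.to_csv(path, sep=sep, index=True)
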