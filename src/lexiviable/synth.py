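"""Synthetic multiplex lexica with a planted viable core and correlated
psycholinguistic attributes.

The generator emulates the statistical skeleton of a multi-relational
mental lexicon: a few thousand words on four layers, heavy-tailed degrees,
a densely interlinked core that is viable (connected on every layer), and
node attributes whose rank correlations with age of acquisition mirror
those reported for English norms (Kendall τ ≈ −0.47 for frequency, −0.31
for multidegree, −0.26 for polysemy, +0.24 for word length).

Topology follows a stochastic block construction per layer — Bernoulli
edges at ``p_core`` within the core, ``p_boundary`` across, and
``p_periphery`` outside — plus heavy-tailed "stub" augmentation on
periphery nodes driven by a Pareto degree propensity.  Attributes come
from a latent Gaussian copula: a target Kendall τ maps to the latent
correlation through Greiner's relation ρ = sin(πτ/2), and marginals are
applied by inverse-CDF transform.  Core words are biased toward low age
of acquisition by a latent location shift, which propagates coherently to
every correlated attribute (core words end up frequent, polysemous, and
early-acquired, as in the empirical core).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sps

from .multiplex import MultiplexNetwork, WordAttributes

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "REFERENCE_CONFIG",
    "generate_multiplex",
    "copula_correlated_attributes",
    "reference_fixture",
]

#: Reference layer names, mirroring the four relation types of the
#: empirical lexicon.
LAYER_NAMES = ("associations", "synonyms", "taxonomic", "phonological")


@dataclass(frozen=True)
class SyntheticConfig:
    """Reference study conditions for the planted-core generator.

    The shipped defaults are the reference configuration every simulation
    in the test-bed runs under: N = 2000 words on 4 layers with a 200-word
    core whose layers are independent sparse Bernoulli graphs (so the
    core's viability appears through a discontinuous, hybrid transition
    when the core assembles), a block of high-polysemy *connector* words
    whose links are replicated identically on every layer (cross-layer
    edge overlap — the redundancy mechanism that lets a viable cluster
    grow continuously word by word), a sparse independent periphery, and
    Pareto degree propensities driving heavy-tailed stub augmentation.
    """

    n_words: int = 2000
    n_layers: int = 4
    n_core: int = 200
    p_core: float = 0.024
    p_boundary: float = 0.002
    p_periphery: float = 0.0006
    #: connector words carry a shared (all-layer-identical) backbone
    n_connector: int = 300
    p_connector_shared: float = 0.0134
    p_core_connector_shared: float = 0.012
    #: latent polysemy boost (latent SD units) for the words that carry
    #: the viable structure (core and connectors): the viable cluster is
    #: polysemy-rich, and cross-layer overlap is carried by
    #: high-polysemy words
    connector_polysemy_shift: float = 2.0
    tail_exponent: float = 2.5
    stub_scale: float = 0.8
    #: Kendall τ targets between age of acquisition and each attribute.
    tau_frequency: float = -0.47
    tau_degree: float = -0.31
    tau_polysemy: float = -0.26
    tau_length: float = 0.24
    #: Latent location shift (in latent SD units) applied to core words'
    #: age-of-acquisition latent; propagates to correlated attributes.
    core_aoa_shift: float = 2.5
    #: Marginal parameters (units in comments).
    aoa_mean_loc: float = 9.0   # years
    aoa_mean_scale: float = 2.5  # years
    aoa_sd_range: tuple[float, float] = (0.5, 2.5)  # years
    log10_frequency_loc: float = 2.5   # log10 counts
    log10_frequency_scale: float = 1.0
    polysemy_p: float = 0.18    # geometric success prob; mean ≈ 5.6 senses
    reaction_time_loc: float = 600.0  # ms
    reaction_time_scale: float = 60.0
    length_poisson_mean: float = 4.5  # letters beyond the first

    def validate(self) -> None:
        bad = []
        if not 2 < self.n_core < self.n_words:
            bad.append("n_core")
        if not 0 <= self.n_connector <= self.n_words - self.n_core:
            bad.append("n_connector")
        for name in ("p_core", "p_boundary", "p_periphery",
                     "p_connector_shared", "p_core_connector_shared"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                bad.append(name)
        if not self.p_core > self.p_boundary > self.p_periphery:
            bad.append("p_core>p_boundary>p_periphery")
        if self.n_layers < 1:
            bad.append("n_layers")
        if self.tail_exponent <= 1.0:
            bad.append("tail_exponent")
        for name in ("tau_frequency", "tau_degree", "tau_polysemy", "tau_length"):
            if abs(getattr(self, name)) >= 1.0:
                bad.append(name)
        if bad:
            raise ValueError(f"invalid SyntheticConfig fields: {bad}")

    def to_dict(self) -> dict:
        return asdict(self)


REFERENCE_CONFIG = SyntheticConfig()


def _word_labels(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"w{i:0{width}d}" for i in range(n)]


def _latent(rng: np.random.Generator, z_ref: np.ndarray, tau: float) -> np.ndarray:
    """Latent Gaussian correlated with ``z_ref`` at Kendall τ (Greiner)."""
    rho = math.sin(math.pi * tau / 2.0)
    eps = rng.standard_normal(z_ref.shape[0])
    return rho * z_ref + math.sqrt(1.0 - rho * rho) * eps


def copula_correlated_attributes(
    config: SyntheticConfig,
    coreness: np.ndarray,
    seed: int | np.random.Generator,
    with_propensity: bool = False,
    connector: np.ndarray | None = None,
):
    """Sample a psycholinguistic attribute table from the latent copula.

    ``coreness`` is one score per word in [0, 1]; core words' AoA latent
    is shifted down by ``core_aoa_shift`` latent SDs times their score,
    which carries through (scaled by ρ) to each correlated attribute.
    ``connector`` scores (optional, same shape) raise the polysemy latent
    by ``connector_polysemy_shift`` — connector words carry the
    cross-layer overlap and are the polysemy-rich part of the lexicon.

    With ``with_propensity=True`` also returns the Pareto-distributed
    degree propensity per word (the continuous driver of periphery stub
    degrees, correlated with AoA at ``tau_degree``).
    """
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coreness = np.asarray(coreness, dtype=float)
    n = coreness.shape[0]
    words = _word_labels(n)

    z_aoa = rng.standard_normal(n) - config.core_aoa_shift * coreness
    # Correlated latents (each vs. the shifted AoA latent).
    z_freq = _latent(rng, z_aoa, config.tau_frequency)
    z_deg = _latent(rng, z_aoa, config.tau_degree)
    z_poly = _latent(rng, z_aoa, config.tau_polysemy)
    if connector is not None:
        carrier = np.maximum(np.asarray(connector, dtype=float), coreness)
        z_poly = z_poly + config.connector_polysemy_shift * carrier
    z_len = _latent(rng, z_aoa, config.tau_length)

    def u(z):  # probability-integral transform of the latent
        return sps.norm.cdf(z)

    aoa_mean = np.maximum(
        1.0, config.aoa_mean_loc + config.aoa_mean_scale * z_aoa
    )
    aoa_sd = rng.uniform(*config.aoa_sd_range, size=n)
    frequency = np.power(
        10.0,
        config.log10_frequency_loc + config.log10_frequency_scale * z_freq,
    )
    polysemy = sps.geom.ppf(np.clip(u(z_poly), 1e-12, 1 - 1e-12), config.polysemy_p)
    concreteness = rng.uniform(1.0, 5.0, size=n)
    reaction_time = config.reaction_time_loc + config.reaction_time_scale * rng.standard_normal(n)
    length = 1.0 + sps.poisson.ppf(
        np.clip(u(z_len), 1e-12, 1 - 1e-12), config.length_poisson_mean
    )

    import pandas as pd

    table = pd.DataFrame(
        {
            "word": words,
            "aoa_mean": aoa_mean,
            "aoa_sd": aoa_sd,
            "frequency": frequency,
            "polysemy": polysemy,
            "concreteness": concreteness,
            "reaction_time": reaction_time,
            "length": length,
        }
    )
    attrs = WordAttributes(table)
    if with_propensity:
        propensity = np.power(1.0 - np.clip(u(z_deg), 1e-12, 1 - 1e-12),
                              -1.0 / config.tail_exponent)
        return attrs, propensity
    return attrs


def _sample_block_edges(rng, left: np.ndarray, right: np.ndarray | None, p: float):
    """Distinct Bernoulli(p) pairs within ``left`` (right=None) or across
    the two disjoint index blocks, via binomial count + index sampling."""
    if p <= 0.0:
        return []
    if right is None:
        n = left.shape[0]
        n_pairs = n * (n - 1) // 2
    else:
        n_pairs = left.shape[0] * right.shape[0]
    if n_pairs == 0:
        return []
    k = rng.binomial(n_pairs, p)
    if k == 0:
        return []
    idx = rng.choice(n_pairs, size=k, replace=False)
    edges = []
    if right is None:
        # decode upper-triangular index -> (i, j), i < j
        n = left.shape[0]
        i = (n - 2 - np.floor(
            np.sqrt(-8.0 * idx + 4 * n * (n - 1) - 7) / 2.0 - 0.5)).astype(int)
        j = (idx + i + 1 - n * (n - 1) // 2 + (n - i) * ((n - i) - 1) // 2).astype(int)
        edges = list(zip(left[i], left[j]))
    else:
        i, j = np.divmod(idx, right.shape[0])
        edges = list(zip(left[i], right[j]))
    return edges


def generate_multiplex(
    config: SyntheticConfig = REFERENCE_CONFIG, seed: int = 0
):
    """Generate a planted-core multiplex with matching attributes.

    Returns ``(network, attributes, core)`` where ``core`` is the set of
    planted core words.  Per layer, edges are independent Bernoulli draws
    at the block probabilities, plus heavy-tailed stub augmentation on
    periphery nodes; any word left isolated on every layer is repaired
    with one random edge on a random layer (logged).  Deterministic for a
    given seed.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n, n_core = config.n_words, config.n_core
    words = np.array(_word_labels(n))
    core_idx = np.arange(n_core)
    periph_idx = np.arange(n_core, n)  # includes the connector block
    conn_idx = np.arange(n_core, n_core + config.n_connector)
    coreness = np.zeros(n)
    coreness[core_idx] = 1.0
    connector = np.zeros(n)
    connector[conn_idx] = 1.0

    attrs, propensity = copula_correlated_attributes(
        config, coreness, rng, with_propensity=True, connector=connector
    )

    layer_names = [
        LAYER_NAMES[i] if i < len(LAYER_NAMES) else f"layer{i}"
        for i in range(config.n_layers)
    ]
    # Shared overlap backbone: connector-connector and core-connector
    # edges replicated identically on every layer.  A connected patch of
    # this backbone is viable by construction, so viable structure can
    # accrete continuously along it.
    shared = set()
    for u, v in (
        _sample_block_edges(rng, conn_idx, None, config.p_connector_shared)
        + _sample_block_edges(rng, core_idx, conn_idx, config.p_core_connector_shared)
    ):
        shared.add((u, v) if u < v else (v, u))

    edge_sets: dict[str, set] = {}
    for layer in layer_names:
        edges = set(shared)
        for u, v in (
            _sample_block_edges(rng, core_idx, None, config.p_core)
            + _sample_block_edges(rng, core_idx, periph_idx, config.p_boundary)
            + _sample_block_edges(rng, periph_idx, None, config.p_periphery)
        ):
            a, b = (u, v) if u < v else (v, u)
            edges.add((a, b))
        edge_sets[layer] = edges

    # Heavy-tailed stub augmentation on the periphery: each periphery
    # node receives Poisson(stub_scale * propensity) extra edges, each on
    # a uniformly chosen layer to a uniformly chosen partner.
    extra = rng.poisson(config.stub_scale * propensity[periph_idx])
    for node, k in zip(periph_idx, extra):
        for _ in range(int(k)):
            layer = layer_names[rng.integers(config.n_layers)]
            partner = int(rng.integers(n - 1))
            if partner >= node:
                partner += 1
            a, b = (node, partner) if node < partner else (partner, node)
            edge_sets[layer].add((a, b))

    # Repair: every word needs at least one link on some layer, and at
    # least two aggregate links so that single word failures cannot
    # strand pendant words (the empirical lexicon stays connected even
    # under the deletion of its whole core).
    agg_degree = np.zeros(n, dtype=int)
    for edges in edge_sets.values():
        for a, b in edges:
            agg_degree[a] += 1
            agg_degree[b] += 1
    weak = np.nonzero(agg_degree < 2)[0]
    if weak.size:
        logger.info("repairing %d words with aggregate degree < 2", weak.size)
    for node in weak:
        while agg_degree[node] < 2:
            layer = layer_names[rng.integers(config.n_layers)]
            partner = int(rng.integers(n - 1))
            if partner >= node:
                partner += 1
            a, b = (node, partner) if node < partner else (partner, node)
            if (a, b) in edge_sets[layer]:
                continue
            edge_sets[layer].add((a, b))
            agg_degree[a] += 1
            agg_degree[b] += 1

    named_edges = {
        layer: [(words[a], words[b]) for a, b in sorted(edges)]
        for layer, edges in edge_sets.items()
    }
    net = MultiplexNetwork.from_edges(named_edges, nodes=words)
    core = set(words[core_idx])
    return net, attrs, core


#: Fixture geometry: 60 words on 2 layers with a 12-word planted core.
FIXTURE_CONFIG = SyntheticConfig(
    n_words=60,
    n_layers=2,
    n_core=12,
    p_core=0.15,
    p_boundary=0.03,
    p_periphery=0.01,
    n_connector=0,
)


def reference_fixture(seed: int = 0):
    """Small deterministic instance (N=60, 2 layers) with a hand-checkable
    largest viable cluster.

    The 12-word core is dense and connected on both layers; every
    periphery word carries edges only on the first layer (a path into the
    core, making the aggregate connected) and is isolated on the second.
    A word with no second-layer link can never belong to a viable cluster
    of size ≥ 2, so the planted core is provably the unique non-trivial
    viable cluster.  Returns ``(network, attributes, core)``.
    """
    config = FIXTURE_CONFIG
    rng = np.random.default_rng(seed)
    n, n_core = config.n_words, config.n_core
    words = _word_labels(n)
    core = words[:n_core]
    periphery = words[n_core:]

    def dense_connected_core(layer_rng) -> set:
        # a random spanning cycle guarantees per-layer connectivity of the
        # full core; a different cycle per layer keeps partial-core
        # viability sparse, so growth completes with a visible jump
        order = list(layer_rng.permutation(n_core))
        edges = {
            tuple(sorted((core[order[i]], core[order[(i + 1) % n_core]])))
            for i in range(n_core)
        }
        for i in range(n_core):
            for j in range(i + 1, n_core):
                if layer_rng.random() < config.p_core:
                    edges.add((core[i], core[j]))
        return edges

    layer1 = dense_connected_core(rng)
    # periphery path threaded into the core on layer 1 only
    layer1.add(tuple(sorted((core[0], periphery[0]))))
    for a, b in zip(periphery, periphery[1:]):
        layer1.add(tuple(sorted((a, b))))
    for p in periphery:  # sparse extra texture toward the core
        if rng.random() < 0.15:
            layer1.add(tuple(sorted((p, core[int(rng.integers(n_core))]))))

    layer2 = dense_connected_core(rng)  # periphery isolated here

    net = MultiplexNetwork.from_edges(
        {"semantic": sorted(layer1), "phonological": sorted(layer2)},
        nodes=words,
    )
    coreness = np.zeros(n)
    coreness[:n_core] = 1.0
    attrs = copula_correlated_attributes(config, coreness, rng)
    return net, attrs, set(core)
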