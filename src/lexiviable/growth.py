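"""Lexicon growth simulation and explosive-transition analysis.

Vocabulary growth is modelled by adding words one at a time in an
*acquisition ordering* and tracking the size L(n) of the largest
non-trivial viable cluster (LVC) of the induced prefix subnetwork.
Orderings come from smeared age-of-acquisition ratings (each word's age
resampled from a normal with its rated mean and SD), from attribute ranks
(frequency, polysemy, multidegree, length, ...; ties reshuffled), or at
random.  The number of acquired words maps to a developmental age t(n)
through the non-smeared mean-AoA ranking.

L(n) is monotone non-decreasing because viability is preserved under node
addition (the induced subgraph of an existing cluster never changes).
This monotonicity powers an incremental detector: when word v arrives,
every existing maximal viable cluster persists, and the only cluster that
can change is the one containing v — computed by fixpoint refinement
seeded at v, started from the intersection of v's per-layer connected
components (tracked by per-layer incremental union-find).  The result is
provably equal to from-scratch detection at every prefix, which the test
suite asserts.

An *explosive transition* is a single-step jump of more than a threshold
number of words (default 10) entering the LVC; the word whose arrival
triggers it is the *critical word*.  Ensembles over orderings summarise
explosiveness by the fraction χ of explosive iterations and the jump
magnitude ΔL.  Distributions of emergence ages are compared with the
overlapping coefficient: histogram overlap normalised by the maximum
overlap attainable when sliding one sample's location.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Callable, Sequence

import numpy as np

from .multiplex import MultiplexNetwork, WordAttributes, multidegree
from .viable import NONTRIVIAL_MIN_SIZE, refine_to_viable

__all__ = [
    "AcquisitionOrdering",
    "GrowthTrajectory",
    "TransitionSummary",
    "TransitionEnsembleSummary",
    "smear_aoa",
    "attribute_ordering",
    "developmental_ages",
    "growth_trajectory",
    "detect_transition",
    "ensemble_transitions",
    "critical_word",
    "overlapping_coefficient",
    "lvc_attribute_timeseries",
    "DEFAULT_JUMP_THRESHOLD",
]

#: A discontinuity of more than this many words in one step is explosive.
DEFAULT_JUMP_THRESHOLD = 10

_DESCENDING_KEYS = {"frequency", "polysemy", "multidegree", "concreteness"}
_ASCENDING_KEYS = {"length", "aoa_mean"}


@dataclass(frozen=True)
class AcquisitionOrdering:
    """A permutation of all words, with the scheme and seed that built it."""

    sequence: tuple[str, ...]
    scheme: str
    seed: int | None = None

    def __post_init__(self):
        if len(set(self.sequence)) != len(self.sequence):
            raise ValueError("ordering sequence must be a permutation (duplicates found)")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GrowthTrajectory:
    """L(n) and t(n) for one acquisition ordering (n = 1..N words)."""

    ordering: AcquisitionOrdering
    lvc_size: np.ndarray
    age: np.ndarray | None = None
    #: mean node-value over current LVC members per n (NaN before emergence)
    lvc_value: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.lvc_size)


@dataclass(frozen=True)
class TransitionSummary:
    """First super-threshold discontinuity of a growth trajectory."""

    explosive: bool
    emergence_index: int | None   # n* in words (1-based)
    emergence_age: float | None   # years, when an age mapping is given
    jump: int                     # L(n*) − L(n*−1)
    lvc_size_at_emergence: int    # L(n*)
    critical_word: str | None
    threshold: int
    #: every super-threshold jump as (n, ΔL) pairs, for later transitions
    jumps: tuple[tuple[int, int], ...] = field(default=())


@dataclass(frozen=True)
class TransitionEnsembleSummary:
    """Ensemble statistics over repeated orderings of one scheme."""

    chi: float                     # fraction of explosive iterations
    delta_l_mean: float            # mean jump over explosive iterations
    delta_l_sd: float
    emergence_ages: np.ndarray     # one age (or NaN) per iteration
    emergence_indices: np.ndarray  # n* per iteration (-1 when undefined)
    jumps: np.ndarray              # ΔL per iteration (0 when not explosive)
    iterations: int
    scheme: str


# ---------------------------------------------------------------------
# Orderings
# ---------------------------------------------------------------------

def smear_aoa(
    attrs: WordAttributes,
    seed: int | np.random.Generator,
    words: Sequence[str] | None = None,
) -> AcquisitionOrdering:
    """Normative acquisition ordering from smeared age-of-acquisition.

    Each word's acquisition age is drawn from Normal(a_i, σ_a(i)) and
    words are sorted by sampled age (ascending).  Sampled ages are used
    for ordering only and are deliberately not clamped at zero.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    words = list(words) if words is not None else attrs.words
    means = attrs.column("aoa_mean", words).to_numpy()
    sds = attrs.column("aoa_sd", words).to_numpy()
    missing = [w for w, m, s in zip(words, means, sds) if np.isnan(m) or np.isnan(s)]
    if missing:
        raise ValueError(f"words missing aoa_mean/aoa_sd: {missing[:10]}")
    sampled = rng.normal(means, sds)
    order = np.lexsort((np.asarray(words, dtype=object), sampled))
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)
    return AcquisitionOrdering(tuple(np.asarray(words, dtype=object)[order]),
                               scheme="aoa_smeared", seed=seed_val)


def attribute_ordering(
    source: WordAttributes | MultiplexNetwork,
    key: str,
    seed: int | np.random.Generator = 0,
    direction: str | None = None,
    words: Sequence[str] | None = None,
) -> AcquisitionOrdering:
    """Ordering by an attribute or multidegree, ties reshuffled uniformly.

    Default directions follow the acquisition hypotheses: frequency,
    polysemy, multidegree and concreteness descending (richer words are
    learned earlier), length ascending (shorter earlier); ``key='random'``
    is a uniform shuffle.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)

    if key == "multidegree":
        if not isinstance(source, MultiplexNetwork):
            raise TypeError("multidegree ordering needs a MultiplexNetwork source")
        counts = multidegree(source)
        words = list(words) if words is not None else list(source.nodes)
        values = np.array([counts[w] for w in words], dtype=float)
    elif key == "random":
        if isinstance(source, MultiplexNetwork):
            words = list(words) if words is not None else list(source.nodes)
        else:
            words = list(words) if words is not None else source.words
        perm = rng.permutation(len(words))
        return AcquisitionOrdering(
            tuple(np.asarray(words, dtype=object)[perm]), scheme="random", seed=seed_val
        )
    else:
        if not isinstance(source, WordAttributes):
            raise TypeError(f"{key!r} ordering needs a WordAttributes source")
        words = list(words) if words is not None else source.words
        values = source.column(key, words).to_numpy()
        if np.isnan(values).any():
            bad = [w for w, v in zip(words, values) if np.isnan(v)]
            raise ValueError(f"words missing {key!r}: {bad[:10]}")

    if direction is None:
        direction = "desc" if key in _DESCENDING_KEYS else "asc"
    if direction not in ("asc", "desc"):
        raise ValueError("direction must be 'asc' or 'desc'")
    sort_key = -values if direction == "desc" else values
    tiebreak = rng.random(len(words))  # uniform within tie groups
    order = np.lexsort((tiebreak, sort_key))
    return AcquisitionOrdering(
        tuple(np.asarray(words, dtype=object)[order]), scheme=key, seed=seed_val
    )


def developmental_ages(attrs: WordAttributes, n_words: int | None = None) -> np.ndarray:
    """t(n): the n-th smallest non-smeared mean AoA, in years.

    Relates a vocabulary size to a developmental stage — acquiring n words
    corresponds to the age by which the n earliest-rated words are known.
    """
    ages = np.sort(attrs.column("aoa_mean").dropna().to_numpy())
    if n_words is not None:
        if n_words > ages.size:
            raise ValueError("not enough rated words for the requested length")
        ages = ages[:n_words]
    return ages


# ---------------------------------------------------------------------
# Incremental growth engine
# ---------------------------------------------------------------------

class _ComponentTracker:
    """Per-layer union-find plus cross-layer component signatures.

    For every present node the tracker maintains the tuple of its
    connected-component roots, one per layer, and groups nodes by that
    signature.  Nodes sharing a signature are exactly those in the same
    component as each other on *every* layer — the natural starting
    superset for viable-cluster refinement.  Small-into-large merging
    bounds total re-keying work at O(N log N) per layer.
    """

    __slots__ = ("n_layers", "parent", "members", "sig", "groups")

    def __init__(self, n_layers: int):
        self.n_layers = n_layers
        self.parent = [dict() for _ in range(n_layers)]
        self.members = [dict() for _ in range(n_layers)]
        self.sig: dict = {}
        self.groups: dict = {}

    def add(self, x) -> None:
        for layer in range(self.n_layers):
            self.parent[layer][x] = x
            self.members[layer][x] = [x]
        sig = (x,) * self.n_layers
        self.sig[x] = sig
        self.groups.setdefault(sig, set()).add(x)

    def find(self, layer: int, x):
        parent = self.parent[layer]
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    def union(self, layer: int, a, b) -> None:
        ra, rb = self.find(layer, a), self.find(layer, b)
        if ra == rb:
            return
        members = self.members[layer]
        if len(members[ra]) < len(members[rb]):
            ra, rb = rb, ra
        self.parent[layer][rb] = ra
        absorbed = members[rb]
        members[ra].extend(absorbed)
        del members[rb]
        groups, sig = self.groups, self.sig
        for u in absorbed:  # re-key the smaller side's signatures
            old = sig[u]
            group = groups[old]
            group.discard(u)
            if not group:
                del groups[old]
            new = old[:layer] + (ra,) + old[layer + 1:]
            sig[u] = new
            groups.setdefault(new, set()).add(u)

    def cohort(self, x) -> set:
        """Nodes in the same component as ``x`` on every layer."""
        return self.groups[self.sig[x]]


def _grow(
    net: MultiplexNetwork,
    sequence: Sequence[str],
    node_values: dict | None = None,
):
    """Core incremental loop: returns (L array, mean-value array or None).

    Maintains, per layer, the present-subgraph adjacency and a union-find
    over its connected components.  For each arriving word v, the only
    maximal viable cluster that can change is the one containing v; it is
    found by fixpoint refinement started from the set of present words
    sharing v's component on *every* layer (a superset of the true
    cluster, usually small).
    """
    seq = list(sequence)
    if set(seq) != set(net.nodes) or len(seq) != net.n_nodes:
        raise ValueError("ordering must be a permutation of the network's nodes")
    layers = list(net.layers)
    full_adj = [net.adjacency(layer) for layer in layers]
    present_adj = [dict() for _ in layers]
    tracker = _ComponentTracker(len(layers))

    cluster_of: dict = {}       # node -> cluster id (clusters of size >= 2)
    cluster_members: dict = {}  # id -> set
    cluster_value_sum: dict = {}
    next_id = 0
    largest_id = None
    lmax = 0

    sizes = np.zeros(len(seq), dtype=int)
    values = np.full(len(seq), np.nan) if node_values is not None else None

    for n, v in enumerate(seq):
        tracker.add(v)
        degrees = []
        for layer, (adj, fadj) in enumerate(zip(present_adj, full_adj)):
            adj[v] = set()
            for u in fadj[v]:
                if u in adj:
                    adj[v].add(u)
                    adj[u].add(v)
                    tracker.union(layer, u, v)
            degrees.append(len(adj[v]))

        if all(d > 0 for d in degrees):
            # candidate superset: present words in v's component on every layer
            candidate = tracker.cohort(v)
            # Fast path: the candidate is one existing cluster plus v, and v
            # has a within-cluster neighbour on every layer -> the cluster
            # simply absorbs v (the fixpoint equals the whole candidate).
            cids = {cluster_of.get(u) for u in candidate if u != v}
            if (
                len(candidate) >= 3
                and len(cids) == 1
                and (cid := next(iter(cids))) is not None
                and len(cluster_members[cid]) == len(candidate) - 1
                and all(
                    any(u in cluster_members[cid] for u in adj[v])
                    for adj in present_adj
                )
            ):
                cluster_members[cid].add(v)
                cluster_of[v] = cid
                if node_values is not None:
                    cluster_value_sum[cid] += node_values[v]
                size = len(cluster_members[cid])
                if size >= NONTRIVIAL_MIN_SIZE and size >= lmax:
                    lmax = size
                    largest_id = cid
                sizes[n] = lmax
                if values is not None and largest_id is not None and lmax >= NONTRIVIAL_MIN_SIZE:
                    values[n] = (cluster_value_sum[largest_id]
                                 / len(cluster_members[largest_id]))
                continue
            cluster = refine_to_viable(present_adj, v, candidate)
            if len(cluster) >= 2:
                merged = {cluster_of[u] for u in cluster if u in cluster_of}
                value_sum = 0.0
                if node_values is not None:
                    value_sum = sum(node_values[u] for u in cluster)
                for cid in merged:
                    del cluster_members[cid]
                    cluster_value_sum.pop(cid, None)
                cid = next_id
                next_id += 1
                cluster_members[cid] = cluster
                cluster_value_sum[cid] = value_sum
                for u in cluster:
                    cluster_of[u] = cid
                if len(cluster) >= NONTRIVIAL_MIN_SIZE and len(cluster) >= lmax:
                    lmax = len(cluster)
                    largest_id = cid
                elif largest_id in merged:
                    largest_id = cid

        sizes[n] = lmax
        if values is not None and largest_id is not None and lmax >= NONTRIVIAL_MIN_SIZE:
            values[n] = cluster_value_sum[largest_id] / len(cluster_members[largest_id])
    return sizes, values


def growth_trajectory(
    net: MultiplexNetwork,
    ordering: AcquisitionOrdering,
    ages: np.ndarray | None = None,
    node_values: dict | None = None,
) -> GrowthTrajectory:
    """L(n) for n = 1..N under one ordering (incremental detection).

    ``ages`` is the t(n) mapping from :func:`developmental_ages`;
    ``node_values`` optionally tracks the mean of a per-word value over
    current LVC members.
    """
    sizes, values = _grow(net, ordering.sequence, node_values=node_values)
    if ages is not None:
        ages = np.asarray(ages, dtype=float)
        if ages.shape[0] != sizes.shape[0]:
            raise ValueError("ages must have one entry per acquired word")
    return GrowthTrajectory(ordering, sizes, age=ages, lvc_value=values)


# ---------------------------------------------------------------------
# Transition detection
# ---------------------------------------------------------------------

def detect_transition(
    trajectory: GrowthTrajectory,
    threshold: int = DEFAULT_JUMP_THRESHOLD,
) -> TransitionSummary:
    """First single-step jump of more than ``threshold`` words.

    The jump must strictly exceed the threshold.  When no jump qualifies,
    the summary is non-explosive and the emergence index falls back to
    the first n with L(n) > 2 (first appearance of a non-trivial LVC).
    All qualifying jumps are reported in ``jumps`` — orderings such as
    the frequency ranking can show a second explosive transition later
    in development.
    """
    sizes = np.asarray(trajectory.lvc_size)
    if sizes.size == 0:
        raise ValueError("empty trajectory")
    diffs = np.diff(np.concatenate(([0], sizes)))
    hits = np.nonzero(diffs > threshold)[0]
    all_jumps = tuple((int(i + 1), int(diffs[i])) for i in hits)
    if hits.size:
        idx = int(hits[0])
        explosive = True
        jump = int(diffs[idx])
    else:
        explosive = False
        nontrivial = np.nonzero(sizes > 2)[0]
        idx = int(nontrivial[0]) if nontrivial.size else None
        jump = int(diffs[idx]) if idx is not None else 0
    n_star = idx + 1 if idx is not None else None
    age = None
    if n_star is not None and trajectory.age is not None:
        age = float(trajectory.age[idx])
    word = trajectory.ordering.sequence[idx] if (explosive and idx is not None) else None
    return TransitionSummary(
        explosive=explosive,
        emergence_index=n_star,
        emergence_age=age,
        jump=jump,
        lvc_size_at_emergence=int(sizes[idx]) if idx is not None else 0,
        critical_word=word,
        threshold=threshold,
        jumps=all_jumps,
    )


def critical_word(
    net: MultiplexNetwork,
    ordering: AcquisitionOrdering,
    threshold: int = DEFAULT_JUMP_THRESHOLD,
) -> str | None:
    """The single word whose arrival triggers the explosive emergence of
    the LVC, or None for a non-explosive trajectory."""
    summary = detect_transition(growth_trajectory(net, ordering), threshold)
    return summary.critical_word


def ensemble_transitions(
    net: MultiplexNetwork,
    ordering_factory: Callable[[int], AcquisitionOrdering],
    iterations: int = 200,
    threshold: int = DEFAULT_JUMP_THRESHOLD,
    seed: int = 0,
    ages: np.ndarray | None = None,
) -> TransitionEnsembleSummary:
    """Transition statistics over an ensemble of orderings.

    ``ordering_factory(seed_i)`` builds iteration i's ordering; the
    per-iteration seeds derive deterministically from the master seed, so
    results are bit-exact reproducible.  χ is the fraction of explosive
    iterations; ΔL statistics are taken over explosive iterations only.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=iterations)
    scheme = None
    jumps = np.zeros(iterations)
    ages_out = np.full(iterations, np.nan)
    indices = np.full(iterations, -1, dtype=int)
    explosive = np.zeros(iterations, dtype=bool)
    for i, s in enumerate(sub_seeds):
        ordering = ordering_factory(int(s))
        scheme = ordering.scheme
        summary = detect_transition(
            growth_trajectory(net, ordering, ages=ages), threshold
        )
        explosive[i] = summary.explosive
        jumps[i] = summary.jump if summary.explosive else 0
        if summary.emergence_index is not None:
            indices[i] = summary.emergence_index
            if summary.emergence_age is not None:
                ages_out[i] = summary.emergence_age
    expl_jumps = jumps[explosive]
    return TransitionEnsembleSummary(
        chi=float(explosive.mean()),
        delta_l_mean=float(expl_jumps.mean()) if expl_jumps.size else float("nan"),
        delta_l_sd=float(expl_jumps.std(ddof=0)) if expl_jumps.size else float("nan"),
        emergence_ages=ages_out,
        emergence_indices=indices,
        jumps=jumps,
        iterations=iterations,
        scheme=scheme or "unknown",
    )


# ---------------------------------------------------------------------
# Distribution overlap and attribute time series
# ---------------------------------------------------------------------

def overlapping_coefficient(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    bins: int | None = None,
    n_shifts: int = 201,
) -> float:
    """Histogram overlap of two samples, in percent of the maximum
    overlap attainable when sliding sample_b's location.

    Both histograms are probability masses on a shared binning
    (Freedman–Diaconis width on the pooled sample unless ``bins`` fixes
    the count); the raw overlap is Σ_i min(p_i, q_i).  The normaliser is
    the maximum raw overlap over a uniform grid of ``n_shifts`` location
    shifts spanning ± the pooled range.  100% means one distribution is
    fully contained in the other; 0% means no overlap at all.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    lo, hi = pooled.min(), pooled.max()
    span = hi - lo
    if span == 0.0:
        return 100.0  # both samples are the same constant
    if bins is None:
        iqr = np.subtract(*np.percentile(pooled, [75, 25]))
        width = 2.0 * iqr * pooled.size ** (-1.0 / 3.0)
        if width <= 0.0:
            raise ValueError("degenerate binning: pooled IQR is zero")
        # heavy outliers can make the FD width minuscule relative to the
        # span; cap the grid at 4096 bins over the base range
        width = max(width, span / 4096.0)
    else:
        if bins < 1:
            raise ValueError("degenerate binning: bins must be >= 1")
        width = span / bins
    # Edges wide enough to hold every shifted copy of sample_b.
    edges = np.arange(lo - span - width, hi + span + 2 * width, width)
    p, _ = np.histogram(a, bins=edges)
    p = p / a.size
    shifts = np.linspace(-span, span, n_shifts)
    if n_shifts % 2 == 1:
        shifts[n_shifts // 2] = 0.0  # make the unshifted grid point exact
    best = 0.0
    raw = None
    for s in shifts:
        q, _ = np.histogram(b + s, bins=edges)
        overlap = np.minimum(p, q / b.size).sum()
        best = max(best, overlap)
        if s == 0.0:
            raw = overlap
    if raw is None:  # guard: n_shifts even
        q, _ = np.histogram(b, bins=edges)
        raw = np.minimum(p, q / b.size).sum()
    if best == 0.0:
        raise ValueError("degenerate binning: no overlap under any shift")
    return float(100.0 * raw / best)


def lvc_attribute_timeseries(
    net: MultiplexNetwork,
    ordering_factory: Callable[[int], AcquisitionOrdering],
    attrs: WordAttributes,
    attribute: str,
    iterations: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Mean attribute of current LVC members vs. n, averaged over an
    ensemble of orderings and rescaled to [0, 1] by its maximum.

    Entries before the LVC exists in every iteration are NaN.
    """
    values = attrs.column(attribute)
    if values.isna().any():
        raise ValueError(f"attribute {attribute!r} has missing values")
    node_values = values.to_dict()
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=iterations)
    acc = np.zeros(net.n_nodes)
    counts = np.zeros(net.n_nodes)
    for s in sub_seeds:
        ordering = ordering_factory(int(s))
        traj = growth_trajectory(net, ordering, node_values=node_values)
        mask = ~np.isnan(traj.lvc_value)
        acc[mask] += traj.lvc_value[mask]
        counts[mask] += 1
    with np.errstate(invalid="ignore"):
        series = acc / counts
    top = np.nanmax(series) if np.isfinite(series).any() else np.nan
    if not np.isfinite(top) or top == 0:
        return series
    return series / top
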