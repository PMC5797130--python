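"""Psycholinguistic group statistics and core-periphery link densities.

Machinery for comparing words inside and outside the largest viable
cluster: Monte-Carlo sample-size-corrected medians/means (heavy-tailed
attributes — frequency, polysemy — use the mean, all others the median),
degree-corrected control samples, exact sign tests, tie-corrected Kendall
τ-b rank correlations, empirical cumulative attribute curves, and
In/In–In/Out–Out/Out link densities whose ordering diagnoses a
core-periphery partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .multiplex import MultiplexNetwork, WordAttributes, multidegree

__all__ = [
    "sample_size_corrected_stat",
    "degree_corrected_sample",
    "compare_groups",
    "GroupComparison",
    "sign_test",
    "kendall_tau",
    "cumulative_curve",
    "core_periphery_densities",
    "CorePeripheryDensities",
    "MEAN_ATTRIBUTES",
    "DEFAULT_COMPARISON_ATTRIBUTES",
]

#: Heavy-tailed attributes summarised by the arithmetic mean; all other
#: attributes use the median.
MEAN_ATTRIBUTES = frozenset({"frequency", "log_frequency", "polysemy"})

DEFAULT_COMPARISON_ATTRIBUTES = (
    "aoa_mean",
    "concreteness",
    "reaction_time",
    "log_frequency",
    "polysemy",
    "length",
)


def sample_size_corrected_stat(
    values: Sequence[float],
    target_n: int,
    kind: str = "median",
    repetitions: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Monte-Carlo sample-size correction of a median or mean.

    Repeatedly subsamples ``target_n`` values uniformly without
    replacement; returns (mean over repetitions, sd over repetitions).
    With ``target_n`` equal to the sample size the plain statistic is
    returned with zero error.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if target_n > values.size:
        raise ValueError(f"target_n={target_n} exceeds sample size {values.size}")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    stat = {"median": np.median, "mean": np.mean}.get(kind)
    if stat is None:
        raise ValueError("kind must be 'median' or 'mean'")
    if target_n == values.size:
        return float(stat(values)), 0.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = np.empty(repetitions)
    for r in range(repetitions):
        draws[r] = stat(rng.choice(values, size=target_n, replace=False))
    return float(draws.mean()), float(draws.std(ddof=0))


def degree_corrected_sample(
    net: MultiplexNetwork,
    in_set: Sequence[str],
    out_pool: Iterable[str],
    seed: int | np.random.Generator = 0,
) -> tuple[list[str], int]:
    """Multidegree-matched control sample from ``out_pool``.

    For each in-word (in order), draws without replacement an out-word of
    equal multidegree; when no exact match remains, the nearest available
    multidegree is used and counted as a mismatch.  Returns the matched
    words and the mismatch count.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    in_set = list(in_set)
    pool = sorted(set(out_pool))
    if not pool:
        raise ValueError("empty out-of-group pool")
    if set(in_set) & set(pool):
        raise ValueError("out_pool must be disjoint from in_set")
    degrees = multidegree(net)
    by_degree: dict[int, list[str]] = {}
    for w in pool:
        by_degree.setdefault(degrees[w], []).append(w)
    for words in by_degree.values():
        rng.shuffle(words)
    matched: list[str] = []
    mismatches = 0
    for w in in_set:
        want = degrees[w]
        if want in by_degree and by_degree[want]:
            matched.append(by_degree[want].pop())
        else:
            available = [d for d, lst in by_degree.items() if lst]
            if not available:
                raise ValueError("out-of-group pool exhausted")
            nearest = min(available, key=lambda d: (abs(d - want), d))
            matched.append(by_degree[nearest].pop())
            mismatches += 1
    return matched, mismatches


@dataclass(frozen=True)
class GroupComparison:
    """Per-attribute in-group vs out-group statistics (Table layout)."""

    table: pd.DataFrame  # index: attribute; columns: kind, in/out stat ± err, n
    degree_corrected: bool
    mismatches: int = 0


def compare_groups(
    attrs: WordAttributes,
    in_set: Iterable[str],
    out_set: Iterable[str],
    repetitions: int = 1000,
    seed: int | np.random.Generator = 0,
    degree_corrected: bool = False,
    net: MultiplexNetwork | None = None,
    attributes: Sequence[str] = DEFAULT_COMPARISON_ATTRIBUTES,
) -> GroupComparison:
    """Attribute statistics for two word groups with Monte-Carlo
    sample-size correction to the smaller group.

    Frequency enters as its base-10 logarithm (``log_frequency``); heavy
    tailed attributes use the mean, all others the median.  With
    ``degree_corrected=True`` (requires ``net``) the out-group is replaced
    by a multidegree-matched sample of the in-group.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    in_words = sorted(set(in_set))
    out_words = sorted(set(out_set))
    if not in_words or not out_words:
        raise ValueError("both groups must be non-empty")
    mismatches = 0
    if degree_corrected:
        if net is None:
            raise ValueError("degree-corrected comparison needs the network")
        out_words, mismatches = degree_corrected_sample(net, in_words, out_words, rng)
    rows = []
    for attribute in attributes:
        kind = "mean" if attribute in MEAN_ATTRIBUTES else "median"
        in_vals = attrs.column(attribute, in_words).dropna().to_numpy()
        out_vals = attrs.column(attribute, out_words).dropna().to_numpy()
        if in_vals.size == 0 or out_vals.size == 0:
            raise ValueError(f"no coverage for attribute {attribute!r} in a group")
        target = min(in_vals.size, out_vals.size)
        in_stat, in_err = sample_size_corrected_stat(in_vals, target, kind, repetitions, rng)
        out_stat, out_err = sample_size_corrected_stat(out_vals, target, kind, repetitions, rng)
        rows.append(
            {
                "attribute": attribute,
                "kind": kind,
                "in_stat": in_stat,
                "in_err": in_err,
                "out_stat": out_stat,
                "out_err": out_err,
                "n_in": in_vals.size,
                "n_out": out_vals.size,
                "target_n": target,
            }
        )
    table = pd.DataFrame(rows).set_index("attribute")
    return GroupComparison(table=table, degree_corrected=degree_corrected,
                           mismatches=mismatches)


def sign_test(
    differences: Sequence[float], alternative: str = "two-sided"
) -> float:
    """Exact binomial sign test on paired differences.

    Zero differences are dropped; the p-value is the exact binomial
    probability of the observed split under P(+) = 1/2.  Two-sided by
    default; ``alternative='greater'``/'less' give one-sided variants.
    """
    diffs = np.asarray(differences, dtype=float)
    diffs = diffs[~np.isnan(diffs)]
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        raise ValueError("all differences are zero (or missing)")
    positives = int((diffs > 0).sum())
    return float(
        sps.binomtest(positives, diffs.size, 0.5, alternative=alternative).pvalue
    )


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-corrected Kendall τ-b between two equal-length sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("inputs must be equal-length sequences of length >= 2")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("Kendall tau undefined for a constant input")
    return float(sps.kendalltau(x, y, variant="b").statistic)


def cumulative_curve(
    attrs: WordAttributes,
    attribute: str,
    group: Iterable[str],
    thresholds: Sequence[float],
) -> np.ndarray:
    """Empirical P(value ≤ T) per threshold for one word group.

    Concreteness is min-max renormalised to [0, 1] (over the group's
    values) before evaluation, matching the presentation convention for
    its bounded 1–5 scale.
    """
    group = sorted(set(group))
    if not group:
        raise ValueError("empty group")
    values = attrs.column(attribute, group).dropna().to_numpy()
    if values.size == 0:
        raise ValueError(f"no {attribute!r} coverage in the group")
    if attribute == "concreteness":
        span = values.max() - values.min()
        values = (values - values.min()) / span if span > 0 else np.zeros_like(values)
    thresholds = np.asarray(thresholds, dtype=float)
    return np.searchsorted(np.sort(values), thresholds, side="right") / values.size


@dataclass(frozen=True)
class CorePeripheryDensities:
    """Link counts and pair-normalised densities for {In, Out} partitions.

    ``counts`` sums to each layer's total link count; ``densities`` divide
    by the number of available pairs per class; ``normalised`` divides the
    density matrix by its global maximum.
    """

    counts: pd.DataFrame      # layers × (in_in, in_out, out_out), links
    densities: pd.DataFrame   # same shape, in [0, 1]
    normalised: pd.DataFrame  # densities / global max

    def ordered(self) -> bool:
        """True iff p_In/In > p_In/Out > p_Out/Out on every layer."""
        d = self.densities
        return bool(((d["in_in"] > d["in_out"]) & (d["in_out"] > d["out_out"])).all())


def core_periphery_densities(
    net: MultiplexNetwork, core: Iterable[str]
) -> CorePeripheryDensities:
    """Classify each layer's links as In/In, In/Out or Out/Out relative
    to ``core`` and derive pair-normalised densities."""
    core = set(core)
    unknown = core - set(net.nodes)
    if unknown:
        raise KeyError(f"core words not in network: {sorted(unknown)[:5]}")
    if not core or core == set(net.nodes):
        raise ValueError("core must be a non-empty proper subset of the nodes")
    n_in = len(core)
    n_out = net.n_nodes - n_in
    pairs = {
        "in_in": n_in * (n_in - 1) / 2,
        "in_out": n_in * n_out,
        "out_out": n_out * (n_out - 1) / 2,
    }
    counts = {}
    for layer in net.layers:
        c = {"in_in": 0, "in_out": 0, "out_out": 0}
        for u, v in net.edges[layer]:
            inside = (u in core) + (v in core)
            c[("out_out", "in_out", "in_in")[inside]] += 1
        assert sum(c.values()) == len(net.edges[layer])
        counts[layer] = c
    counts_df = pd.DataFrame(counts).T[["in_in", "in_out", "out_out"]]
    densities = counts_df / pd.Series(pairs)
    top = densities.to_numpy().max()
    normalised = densities / top if top > 0 else densities
    return CorePeripheryDensities(counts_df, densities, normalised)
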