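"""Growth simulation, transition detection and distribution overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lexiviable import (
    AcquisitionOrdering,
    MultiplexNetwork,
    WordAttributes,
    attribute_ordering,
    critical_word,
    detect_transition,
    developmental_ages,
    ensemble_transitions,
    growth_trajectory,
    induced_subnetwork,
    lvc_attribute_timeseries,
    maximal_viable_clusters,
    largest_viable_cluster,
    overlapping_coefficient,
    smear_aoa,
)
from lexiviable.growth import GrowthTrajectory
from tests.conftest import random_multiplex


def _attrs(words, aoa_mean, aoa_sd, **extra):
    frame = pd.DataFrame({"word": words, "aoa_mean": aoa_mean, "aoa_sd": aoa_sd})
    for key, values in extra.items():
        frame[key] = values
    return WordAttributes(frame)


class TestSmearing:
    def test_zero_sd_recovers_mean_ranking(self):
        attrs = _attrs(["a", "b", "c"], [7.0, 3.0, 5.0], [0.0, 0.0, 0.0])
        ordering = smear_aoa(attrs, seed=1)
        assert ordering.sequence == ("b", "c", "a")

    def test_singleton(self):
        attrs = _attrs(["only"], [4.0], [1.0])
        assert smear_aoa(attrs, seed=0).sequence == ("only",)

    def test_missing_aoa_listed(self):
        attrs = _attrs(["a", "b"], [4.0, np.nan], [1.0, 1.0])
        with pytest.raises(ValueError, match="b"):
            smear_aoa(attrs, seed=0)

    def test_inversion_probability_matches_gaussian_difference(self):
        # a ~ N(5,1), b ~ N(6,1): P(b precedes a) = Phi(-1/sqrt(2))
        attrs = _attrs(["a", "b"], [5.0, 6.0], [1.0, 1.0])
        rng = np.random.default_rng(12345)
        draws = 20000
        inversions = sum(
            smear_aoa(attrs, rng).sequence[0] == "b" for _ in range(draws)
        )
        expected = sps.norm.cdf(-1 / np.sqrt(2))
        assert inversions / draws == pytest.approx(expected, abs=0.01)

    def test_sigma_to_zero_converges_to_mean_ranking(self):
        words = [f"w{i}" for i in range(30)]
        means = np.linspace(2, 12, 30)
        base = tuple(words)
        mismatches = []
        for sd in (1.0, 0.1, 0.001, 0.0):
            attrs = _attrs(words, means, np.full(30, sd))
            ordering = smear_aoa(attrs, seed=3)
            mismatches.append(sum(a != b for a, b in zip(ordering.sequence, base)))
        assert mismatches[-1] == 0
        assert mismatches == sorted(mismatches, reverse=True)


class TestAttributeOrdering:
    def test_distinct_frequencies_descending(self):
        attrs = _attrs(["x", "y", "z"], [5, 5, 5], [1, 1, 1],
                       frequency=[1.0, 3.0, 2.0])
        ordering = attribute_ordering(attrs, "frequency", seed=0)
        assert ordering.sequence == ("y", "z", "x")

    def test_length_ascending(self):
        attrs = _attrs(["ab", "a", "abc"], [5, 5, 5], [1, 1, 1],
                       length=[2.0, 1.0, 3.0])
        ordering = attribute_ordering(attrs, "length", seed=0)
        assert ordering.sequence == ("a", "ab", "abc")

    def test_all_ties_is_seed_reproducible_shuffle(self):
        attrs = _attrs(list("abcdef"), [5] * 6, [1] * 6, frequency=[2.0] * 6)
        first = attribute_ordering(attrs, "frequency", seed=9)
        second = attribute_ordering(attrs, "frequency", seed=9)
        assert first.sequence == second.sequence
        other = attribute_ordering(attrs, "frequency", seed=10)
        assert set(other.sequence) == set(first.sequence)

    def test_tie_groups_permuted_uniformly(self):
        # three tied words: the 6 permutations should be equally likely
        attrs = _attrs(["a", "b", "c"], [5] * 3, [1] * 3, frequency=[1.0] * 3)
        counts: dict = {}
        n = 3000
        for seed in range(n):
            seq = attribute_ordering(attrs, "frequency", seed=seed).sequence
            counts[seq] = counts.get(seq, 0) + 1
        assert len(counts) == 6
        chi2 = sum((c - n / 6) ** 2 / (n / 6) for c in counts.values())
        assert chi2 < sps.chi2.ppf(0.999, df=5)

    def test_unknown_key_errors(self):
        attrs = _attrs(["a"], [5], [1])
        with pytest.raises((KeyError, ValueError)):
            attribute_ordering(attrs, "sparkliness", seed=0)

    def test_multidegree_needs_network(self):
        attrs = _attrs(["a"], [5], [1])
        with pytest.raises(TypeError):
            attribute_ordering(attrs, "multidegree", seed=0)


class TestGrowthTrajectory:
    def test_monotone_and_reaches_full_lvc(self, fixture_instance):
        net, attrs, _ = fixture_instance
        traj = growth_trajectory(net, smear_aoa(attrs, seed=4))
        assert np.all(np.diff(traj.lvc_size) >= 0)
        assert np.all(traj.lvc_size <= np.arange(1, net.n_nodes + 1))
        assert traj.lvc_size[-1] == largest_viable_cluster(net).size

    def test_lvc_members_last_stays_zero(self, fixture_instance):
        net, _, core = fixture_instance
        rest = [w for w in net.nodes if w not in core]
        sequence = tuple(rest) + tuple(sorted(core))
        traj = growth_trajectory(net, AcquisitionOrdering(sequence, "manual"))
        assert traj.lvc_size[len(rest) - 1] == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_incremental_equals_from_scratch(self, seed):
        rng = np.random.default_rng(300 + seed)
        net = random_multiplex(rng, n_nodes=16, n_layers=2, p=0.22)
        sequence = tuple(rng.permutation(list(net.nodes)))
        traj = growth_trajectory(net, AcquisitionOrdering(sequence, "random"))
        for n in range(1, net.n_nodes + 1):
            clusters = maximal_viable_clusters(
                induced_subnetwork(net, sequence[:n])
            )
            expected = clusters[0].size if clusters else 0
            assert traj.lvc_size[n - 1] == expected

    def test_ordering_mismatch_errors(self, fixture_instance):
        net, _, _ = fixture_instance
        with pytest.raises(ValueError, match="permutation"):
            growth_trajectory(
                net, AcquisitionOrdering(tuple(net.nodes[:-1]), "manual")
            )

    def test_developmental_ages_monotone(self, fixture_instance):
        _, attrs, _ = fixture_instance
        ages = developmental_ages(attrs)
        assert np.all(np.diff(ages) >= 0)


class TestDetectTransition:
    def _traj(self, sizes):
        n = len(sizes)
        ordering = AcquisitionOrdering(tuple(f"w{i}" for i in range(n)), "manual")
        return GrowthTrajectory(ordering, np.asarray(sizes))

    def test_explosive_jump(self):
        summary = detect_transition(self._traj([0, 0, 260, 261]))
        assert summary.explosive and summary.jump == 260
        assert summary.emergence_index == 3
        assert summary.critical_word == "w2"

    def test_gradual_growth_not_explosive(self):
        summary = detect_transition(self._traj(list(range(1, 30))))
        assert not summary.explosive
        assert summary.critical_word is None
        assert summary.emergence_index == 3  # first n with L(n) > 2

    def test_threshold_is_strict(self):
        summary = detect_transition(self._traj([0, 10, 10]))
        assert not summary.explosive
        over = detect_transition(self._traj([0, 11, 11]))
        assert over.explosive and over.jump == 11

    def test_flat_tail_invariance(self):
        base = detect_transition(self._traj([0, 15, 20]))
        padded = detect_transition(self._traj([0, 15, 20, 20, 20, 20]))
        assert (base.emergence_index, base.jump) == (
            padded.emergence_index, padded.jump)

    def test_second_transition_reported(self):
        summary = detect_transition(self._traj([0, 30, 31, 32, 80]))
        assert summary.jumps == ((2, 30), (5, 48))


class TestEnsemble:
    def test_deterministic_ordering_degenerate_stats(self, fixture_instance):
        net, attrs, _ = fixture_instance
        zero_sd = attrs.table.copy()
        zero_sd["aoa_sd"] = 0.0
        frozen = WordAttributes(zero_sd.reset_index())

        summary = ensemble_transitions(
            net, lambda s: smear_aoa(frozen, s), iterations=5, seed=0
        )
        assert summary.chi in (0.0, 1.0)
        if summary.chi == 1.0:
            assert summary.delta_l_sd == 0.0

    def test_chi_equals_manual_count(self, fixture_instance):
        net, attrs, _ = fixture_instance
        factory = lambda s: smear_aoa(attrs, s)  # noqa: E731
        summary = ensemble_transitions(net, factory, iterations=20, seed=7)
        rng = np.random.default_rng(7)
        seeds = rng.integers(0, 2**31 - 1, size=20)
        manual = np.mean([
            detect_transition(growth_trajectory(net, factory(int(s)))).explosive
            for s in seeds
        ])
        assert summary.chi == manual

    def test_bit_exact_reproducibility(self, fixture_instance):
        net, attrs, _ = fixture_instance
        factory = lambda s: smear_aoa(attrs, s)  # noqa: E731
        a = ensemble_transitions(net, factory, iterations=10, seed=42)
        b = ensemble_transitions(net, factory, iterations=10, seed=42)
        assert a.chi == b.chi
        np.testing.assert_array_equal(a.jumps, b.jumps)
        np.testing.assert_array_equal(a.emergence_indices, b.emergence_indices)


class TestCriticalWord:
    def test_none_when_not_explosive(self):
        tri = [("a", "b"), ("b", "c"), ("a", "c")]
        net = MultiplexNetwork.from_edges({"L1": tri, "L2": tri})
        ordering = AcquisitionOrdering(("a", "b", "c"), "manual")
        assert critical_word(net, ordering, threshold=10) is None

    def test_planted_completing_word(self):
        # hub word m completes the cluster: without it nothing is viable
        star = [("a", "m"), ("b", "m"), ("c", "m")]
        net = MultiplexNetwork.from_edges({"L1": star, "L2": star})
        word = critical_word(net, AcquisitionOrdering(("a", "b", "c", "m"),
                                                      "manual"), threshold=3)
        assert word == "m"

    def test_removing_critical_word_removes_the_jump(self, fixture_instance):
        net, attrs, _ = fixture_instance
        ordering = smear_aoa(attrs, seed=11)
        summary = detect_transition(growth_trajectory(net, ordering), threshold=4)
        assert summary.explosive  # known explosive at this fixture/seed
        word = summary.critical_word
        prefix = ordering.sequence[: summary.emergence_index]
        assert prefix[-1] == word
        # from-scratch cross-check: the prefix LVC matches the trajectory,
        # and dropping the critical word removes the whole jump
        with_word = maximal_viable_clusters(induced_subnetwork(net, prefix))
        without = maximal_viable_clusters(
            induced_subnetwork(net, set(prefix) - {word})
        )
        size_with = with_word[0].size if with_word else 0
        size_without = without[0].size if without else 0
        assert size_with == summary.lvc_size_at_emergence
        assert size_with - size_without == summary.jump
        assert size_with - size_without > summary.threshold


class TestOverlappingCoefficient:
    def test_identical_samples_are_100(self):
        sample = np.random.default_rng(0).normal(size=500)
        assert overlapping_coefficient(sample, sample) == pytest.approx(100.0)

    def test_disjoint_supports_are_0(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, 1000)
        b = rng.uniform(100, 101, 1000)
        assert overlapping_coefficient(a, b) == pytest.approx(0.0)

    def test_shifted_gaussians_match_closed_form(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 200000)
        b = rng.normal(1, 1, 200000)
        expected = 100 * 2 * sps.norm.cdf(-0.5)  # raw overlap; max shift ~ 1
        assert overlapping_coefficient(a, b) == pytest.approx(expected, abs=2.0)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            overlapping_coefficient([], [1.0])

    def test_degenerate_binning_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            overlapping_coefficient([0.0] * 50 + [1.0], [0.0] * 50 + [1.0],
                                    bins=0)


class TestAttributeTimeseries:
    def test_constant_attribute_flat_at_one(self, fixture_instance):
        net, attrs, _ = fixture_instance
        table = attrs.table.copy()
        table["concreteness"] = 3.0
        flat = WordAttributes(table.reset_index())
        series = lvc_attribute_timeseries(
            net, lambda s: smear_aoa(flat, s), flat, "concreteness",
            iterations=3, seed=0)
        defined = series[~np.isnan(series)]
        assert np.allclose(defined, 1.0)

    def test_maximum_is_exactly_one(self, fixture_instance):
        net, attrs, _ = fixture_instance
        series = lvc_attribute_timeseries(
            net, lambda s: smear_aoa(attrs, s), attrs, "polysemy",
            iterations=3, seed=1)
        assert np.nanmax(series) == pytest.approx(1.0)

    def test_unknown_attribute_errors(self, fixture_instance):
        net, attrs, _ = fixture_instance
        with pytest.raises(KeyError):
            lvc_attribute_timeseries(
                net, lambda s: smear_aoa(attrs, s), attrs, "zap",
                iterations=1, seed=0)

    def test_polysemy_peaks_after_emergence(self, reference_instance):
        # the newly emerged LVC is the polysemy-rich core; later joiners
        # dilute it, so the curve peaks early and declines
        net, attrs, _ = reference_instance
        series = lvc_attribute_timeseries(
            net, lambda s: smear_aoa(attrs, s), attrs, "polysemy",
            iterations=2, seed=0)
        defined = np.nonzero(~np.isnan(series))[0]
        early = np.nanmean(series[defined[0]: defined[0] + 50])
        late = np.nanmean(series[-50:])
        assert early > late
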