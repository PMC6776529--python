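"""Structural perturbation, topology distance, enrichment, and the full
robustness experiment."""

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from signalflow import (
    SignedDirectedNetwork,
    degree_preserving_swap,
    enrichment_score,
    erdos_renyi_signed,
    flip_signs,
    hypergeom_tail,
    n_dl,
    perturb_network,
    r_t,
    robustness_experiment,
    to_adjacency,
)


def degrees(net):
    adj = to_adjacency(net)
    return list(adj.in_degrees()), list(adj.out_degrees())


class TestSwap:
    def test_two_disjoint_links_swap(self):
        net = SignedDirectedNetwork.from_links([("A", "B", 1), ("C", "D", -1)])
        out = degree_preserving_swap(net, 50, np.random.default_rng(0))
        pairs = {(l.source, l.target) for l in out.links}
        assert pairs in ({("A", "D"), ("C", "B")}, {("A", "B"), ("C", "D")})
        assert degrees(out) == degrees(net)

    def test_degenerate_network_returned_unchanged(self):
        # any swap of these two links creates a self-loop
        net = SignedDirectedNetwork.from_links([("A", "B", 1), ("B", "A", 1)])
        out = degree_preserving_swap(net, 20, np.random.default_rng(0))
        assert set(out.links) == set(net.links)

    def test_seed_reproducibility(self):
        net = erdos_renyi_signed(20, 0.12, seed=3)
        a = degree_preserving_swap(net, 200, np.random.default_rng(42))
        b = degree_preserving_swap(net, 200, np.random.default_rng(42))
        assert a.links == b.links

    def test_signs_travel_with_source_link(self):
        net = SignedDirectedNetwork.from_links([("A", "B", 1), ("C", "D", -1)])
        out = degree_preserving_swap(net, 1, np.random.default_rng(1))
        signs = {l.source: l.sign for l in out.links}
        assert signs == {"A": 1, "C": -1}

    def test_no_duplicates_or_self_loops_ever(self):
        net = erdos_renyi_signed(15, 0.2, seed=5)
        out = degree_preserving_swap(net, 500, np.random.default_rng(7))
        pairs = [(l.source, l.target) for l in out.links]
        assert len(set(pairs)) == len(pairs)
        assert all(s != t for s, t in pairs)

    def test_too_few_links_rejected(self):
        net = SignedDirectedNetwork.from_links([("A", "B", 1)])
        with pytest.raises(ValueError):
            degree_preserving_swap(net, 1, np.random.default_rng(0))


class TestFlip:
    def test_single_flip_changes_ndl_by_two(self):
        net = SignedDirectedNetwork.from_links([("A", "B", 1), ("C", "D", 1)])
        out = flip_signs(net, 1, np.random.default_rng(0))
        assert n_dl(to_adjacency(net), to_adjacency(out)) == 2

    def test_double_flip_of_same_link_restores(self):
        net = SignedDirectedNetwork.from_links([("A", "B", 1)])
        out = flip_signs(net, 2, np.random.default_rng(0))
        assert n_dl(to_adjacency(net), to_adjacency(out)) == 0

    def test_topology_unchanged(self):
        net = erdos_renyi_signed(12, 0.2, seed=1)
        out = flip_signs(net, 30, np.random.default_rng(2))
        assert {(l.source, l.target) for l in out.links} == {
            (l.source, l.target) for l in net.links
        }

    def test_critical_mode_restricted_to_incident_links(self):
        net = SignedDirectedNetwork.from_links(
            [("A", "out", 1), ("B", "C", 1), ("C", "B", 1)]
        )
        out = flip_signs(net, 25, np.random.default_rng(3), critical_nodes={"out"})
        key = lambda l: (l.source, l.target)
        changed = {
            (l.source, l.target)
            for l, m in zip(sorted(net.links, key=key), sorted(out.links, key=key))
            if l.sign != m.sign
        }
        assert changed <= {("A", "out")}


class TestNdl:
    def test_identical_networks(self):
        net = erdos_renyi_signed(10, 0.2, seed=0)
        A = to_adjacency(net)
        assert n_dl(A, A) == 0

    def test_moved_link_contributes_two(self):
        a = SignedDirectedNetwork(("A", "B", "C"), (("A", "B", 1),))
        b = SignedDirectedNetwork(("A", "B", "C"), (("A", "C", 1),))
        assert n_dl(to_adjacency(a), to_adjacency(b)) == 2

    def test_symmetry_and_positivity(self):
        x = to_adjacency(erdos_renyi_signed(10, 0.2, seed=1))
        y = to_adjacency(
            flip_signs(erdos_renyi_signed(10, 0.2, seed=1), 4, np.random.default_rng(0))
        )
        assert n_dl(x, y) == n_dl(y, x) >= 0

    def test_dimension_mismatch(self):
        a = to_adjacency(SignedDirectedNetwork(("A", "B"), (("A", "B", 1),)))
        b = to_adjacency(SignedDirectedNetwork(("A", "C"), (("A", "C", 1),)))
        with pytest.raises(ValueError):
            n_dl(a, b)


class TestRt:
    def test_superset_recovers_all(self):
        assert r_t({"a", "b", "c"}, {"a", "b"}) == 1.0

    def test_disjoint_recovers_none(self):
        assert r_t({"x"}, {"a", "b"}) == 0.0

    def test_six_of_eight(self):
        found = {f"t{i}" for i in range(6)} | {"other"}
        original = {f"t{i}" for i in range(8)}
        assert r_t(found, original) == 0.75

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            r_t({"a"}, set())


def _hypergeom_enumeration(M, n, N, k):
    """Exact rational tail by enumerating all N-subsets of M items."""
    total = 0
    hits = 0
    items = list(range(M))
    successes = set(range(n))
    for subset in itertools.combinations(items, N):
        total += 1
        if len(successes.intersection(subset)) >= k:
            hits += 1
    return Fraction(hits, total)


class TestHypergeom:
    def test_printed_worked_example(self):
        p = hypergeom_tail(200, 8, 56, 6)
        assert p == pytest.approx(6.699e-03, rel=5e-4)
        assert enrichment_score(p) == pytest.approx(2.174, abs=5e-4)

    def test_k_zero_is_certain(self):
        assert hypergeom_tail(50, 5, 10, 0) == 1.0

    def test_small_enumeration_case(self):
        # 2 successes in 5, draw 2: 7 of the 10 subsets contain >= 1 success
        assert hypergeom_tail(5, 2, 2, 1) == pytest.approx(0.7)
        assert _hypergeom_enumeration(5, 2, 2, 1) == Fraction(7, 10)

    def test_agrees_with_exact_enumeration_grid(self):
        for M in (2, 5, 8):
            for n in range(M + 1):
                for N in range(M + 1):
                    for k in range(min(n, N) + 1):
                        exact = float(_hypergeom_enumeration(M, n, N, k))
                        assert hypergeom_tail(M, n, N, k) == pytest.approx(
                            exact, abs=1e-12
                        )

    def test_non_increasing_in_k(self):
        values = [hypergeom_tail(30, 6, 10, k) for k in range(7)]
        assert all(a >= b - 1e-15 for a, b in zip(values, values[1:]))

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tail(10, 12, 3, 1)
        with pytest.raises(ValueError):
            hypergeom_tail(10, 3, 3, 4)

    def test_enrichment_score_values(self):
        assert enrichment_score(1.0) == 0.0
        assert enrichment_score(1e-3) == pytest.approx(3.0)
        with pytest.raises(ValueError):
            enrichment_score(0.0)


@pytest.fixture(scope="module")
def planted():
    """A random network with planted reference targets: the targets are a
    subset of the unperturbed candidate discovery, so unperturbed R_T = 1 by
    construction."""
    net = erdos_renyi_signed(40, 0.08, sign_probability=0.2, seed=11)
    outputs = [net.nodes[0]]
    from signalflow.robustness import _AnalysisSettings, _discover_candidates
    from signalflow import Hyperparams

    settings = _AnalysisSettings(tuple(outputs), {}, 0.10, None, Hyperparams())
    candidates, _ = _discover_candidates(net, settings)
    targets = set(sorted(candidates)[:5])
    assert len(targets) == 5
    return net, outputs, targets


class TestExperiment:

    def test_level_zero_reproduces_unperturbed_analysis(self, planted):
        net, outputs, targets = planted
        table = robustness_experiment(
            net, outputs, targets, levels=[0], replicates=5, seed=1
        )
        assert (table["n_dl"] == 0).all()
        assert (table["r_t"] == 1.0).all()

    def test_degree_sequences_preserved_across_replicates(self, planted):
        net, *_ = planted
        d0 = degrees(net)
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            perturbed = perturb_network(net, 20, rng)
            assert degrees(perturbed) == d0

    def test_seeded_determinism_of_table(self, planted):
        net, outputs, targets = planted
        kwargs = dict(levels=[0, 3], replicates=4, seed=99)
        t1 = robustness_experiment(net, outputs, targets, **kwargs)
        t2 = robustness_experiment(net, outputs, targets, **kwargs)
        pd.testing.assert_frame_equal(t1, t2)

    def test_replicates_differ_but_share_degrees(self, planted):
        net, outputs, targets = planted
        table = robustness_experiment(
            net, outputs, targets, levels=[8], replicates=6, seed=5
        )
        assert table["n_dl"].nunique() > 1  # distinct perturbed topologies

    def test_critical_modes_accepted(self, planted):
        net, outputs, targets = planted
        for mode in ("targets", "outputs"):
            table = robustness_experiment(
                net, outputs, targets, levels=[2], replicates=2, seed=0,
                critical_mode=mode,
            )
            assert len(table) == 2
        with pytest.raises(ValueError):
            robustness_experiment(
                net, outputs, targets, levels=[1], replicates=1, seed=0,
                critical_mode="everything",
            )

    def test_small_perturbations_keep_recovery_high(self, planted):
        """Median R_T under mild structural perturbation stays within one
        target of the unperturbed recovery."""
        net, outputs, targets = planted
        table = robustness_experiment(
            net, outputs, targets, levels=[2], replicates=50, seed=7
        )
        median_rt = table["r_t"].median()
        assert median_rt >= 1.0 - 1.0 / len(targets)
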