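"""Scope expansion, minimal-pathway backtracking and pathway geometry."""

import itertools

import numpy as np
import pytest

from toolboxnet import (
    MetabolicUniverse,
    Reaction,
    backtrack_pathway,
    expand_scope,
    expansion_profile,
    pathway_geometry,
    shortest_distance_to_core,
)
from toolboxnet.errors import UnreachableTargetError
from toolboxnet.scope import is_feasible

from conftest import random_toy_universe


def brute_force_expansion(universe, core):
    """Independent set-based fixed point: avail_{n+1} = avail_n plus products
    of every directed instance whose substrates are all in avail_n."""
    avail = set(core)
    first = dict.fromkeys(core, 0)
    n = 0
    while True:
        new = set()
        for inst in universe.instances:
            if all(s in avail for s in inst.substrates):
                new.update(p for p in inst.products if p not in avail)
        if not new:
            return first
        n += 1
        for m in new:
            first[m] = n
        avail |= new


def chain_universe(length):
    mets = [chr(ord("A") + i) for i in range(length + 1)]
    return MetabolicUniverse(
        [
            Reaction(f"c{i}", frozenset(mets[i]), frozenset(mets[i + 1]))
            for i in range(length)
        ]
    ), mets


class TestExpandScope:
    def test_chain_layers(self):
        u, mets = chain_universe(2)
        exp = expand_scope(u, {"A"})
        assert exp.first_layer == {"A": 0, "B": 1, "C": 2}
        assert exp.S.tolist() == [1, 2, 3]

    def test_and_gate_layers(self, and_gate_universe):
        exp = expand_scope(and_gate_universe, {"A"})
        rids = [sorted(and_gate_universe.instances[i].rid for i in lay) for lay in exp.layers]
        assert rids == [["r1", "r2"], ["r3"], ["r4"]]
        assert exp.first_layer["F"] == 3

    def test_target_in_core_gives_zero_layers(self, and_gate_universe):
        exp = expand_scope(and_gate_universe, {"A"}, target="A")
        assert exp.n_layers == 0

    def test_target_mode_stops_at_first_producing_layer(self, and_gate_universe):
        exp = expand_scope(and_gate_universe, {"A"}, target="E")
        assert exp.n_layers == 2

    def test_unreachable_target_raises(self, and_gate_universe):
        with pytest.raises(UnreachableTargetError):
            expand_scope(and_gate_universe, {"B"}, target="F")  # needs D too

    def test_matches_brute_force_on_random_toys(self):
        rng = np.random.default_rng(202)
        for _ in range(100):
            universe, core = random_toy_universe(rng)
            exp = expand_scope(universe, core)
            assert exp.first_layer == brute_force_expansion(universe, core)

    def test_scope_monotone_in_core(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            universe, core = random_toy_universe(rng)
            extra = set(core) | {sorted(universe.metabolites)[0]} if universe.metabolites else core
            small = expand_scope(universe, core).reached
            large = expand_scope(universe, extra).reached
            assert small <= large | core


class TestExpansionProfile:
    def test_chain_ratios(self):
        u, _ = chain_universe(5)
        ratios = expansion_profile(expand_scope(u, {"A"}))
        assert ratios == pytest.approx((np.arange(2, 7)) / np.arange(1, 6))

    def test_single_layer_single_ratio(self):
        u, _ = chain_universe(1)
        assert expansion_profile(expand_scope(u, {"A"})).size == 1

    def test_degenerate_expansion_rejected(self, and_gate_universe):
        with pytest.raises(ValueError):
            expansion_profile(expand_scope(and_gate_universe, {"F"}))


class TestBacktrack:
    def test_unique_chain_recovers_all_reactions(self, rng):
        u, _ = chain_universe(3)
        exp = expand_scope(u, {"A"}, target="D")
        pw = backtrack_pathway(exp, "D", rng)
        assert sorted(pw.reaction_ids) == ["c0", "c1", "c2"]
        assert pw.length == 3

    def test_and_gate_minimal_pathway(self, and_gate_universe, rng):
        exp = expand_scope(and_gate_universe, {"A"}, target="F")
        pw = backtrack_pathway(exp, "F", rng)
        assert sorted(pw.reaction_ids) == ["r1", "r2", "r3", "r4"]
        assert pw.length == 3

    def test_producer_tie_break_is_uniform(self):
        u = MetabolicUniverse(
            [
                Reaction("p1", frozenset("A"), frozenset("T")),
                Reaction("p2", frozenset("A"), frozenset("T")),
            ]
        )
        exp = expand_scope(u, {"A"}, target="T")
        picks = []
        for seed in range(2000):
            pw = backtrack_pathway(exp, "T", np.random.default_rng(seed))
            picks.append(pw.reaction_ids[0])
        freq = picks.count("p1") / len(picks)
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / len(picks))

    def test_backtracked_pathways_feasible_and_subset_minimal(self):
        """Exhaustive check on random toys: the pathway reaches the target
        from the core and no proper subset of its reactions does."""
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(100):
            universe, core = random_toy_universe(rng)
            exp = expand_scope(universe, core)
            targets = sorted(exp.reached - core)
            if not targets:
                continue
            target = targets[int(rng.integers(len(targets)))]
            exp_t = expand_scope(universe, core, target=target)
            pw = backtrack_pathway(exp_t, target, rng)
            ids = pw.instance_ids
            assert is_feasible(universe, ids, core, target)
            if len(ids) <= 12:
                for k in range(len(ids)):
                    for subset in itertools.combinations(ids, k):
                        assert not is_feasible(universe, subset, core, target)
                checked += 1
        assert checked >= 50

    def test_replay_in_layer_order_is_executable(self):
        """Firing the pathway's reactions in layer order from the core
        produces every substrate before it is consumed."""
        rng = np.random.default_rng(13)
        for _ in range(50):
            universe, core = random_toy_universe(rng)
            exp = expand_scope(universe, core)
            targets = sorted(exp.reached - core)
            if not targets:
                continue
            target = targets[int(rng.integers(len(targets)))]
            pw = backtrack_pathway(
                expand_scope(universe, core, target=target), target, rng
            )
            avail = set(core)
            for i in sorted(pw.instance_ids, key=lambda i: pw.layer[i]):
                inst = universe.instances[i]
                assert set(inst.substrates) <= avail
                avail |= set(inst.products)
            assert target in avail

    def test_no_pathway_uses_both_directions_of_one_reaction(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            universe, core = random_toy_universe(rng)
            exp = expand_scope(universe, core)
            targets = sorted(exp.reached - core)
            if not targets:
                continue
            target = targets[int(rng.integers(len(targets)))]
            pw = backtrack_pathway(
                expand_scope(universe, core, target=target), target, rng
            )
            assert len(set(pw.reaction_ids)) == len(pw.reaction_ids)


class TestPathwayGeometry:
    def test_single_border_reaction(self, rng):
        u = MetabolicUniverse([Reaction("r", frozenset("A"), frozenset("T"))])
        pw = backtrack_pathway(expand_scope(u, {"A"}, target="T"), "T", rng)
        g = pathway_geometry(pw, {"A"})
        assert (g.n_border_rxn, g.n_base, g.n_feedback, g.n_byproduct) == (1, 1, 0, 0)
        assert g.length == 1
        assert g.n_metabolites == 1  # the target

    def test_unconsumed_co_product_is_a_byproduct(self, rng):
        u = MetabolicUniverse([Reaction("r", frozenset("A"), frozenset(["T", "X"]))])
        pw = backtrack_pathway(expand_scope(u, {"A"}, target="T"), "T", rng)
        g = pathway_geometry(pw, {"A"})
        assert g.n_byproduct == 1

    def test_currency_excluded_from_byproducts(self, rng):
        u = MetabolicUniverse([Reaction("r", frozenset("A"), frozenset(["T", "X"]))])
        pw = backtrack_pathway(expand_scope(u, {"A"}, target="T"), "T", rng)
        g = pathway_geometry(pw, {"A"}, currency={"X"})
        assert g.n_byproduct == 0

    def test_core_product_counts_as_feedback_not_byproduct(self, rng):
        u = MetabolicUniverse(
            [Reaction("r", frozenset("A"), frozenset(["T", "W"]))]
        )
        pw = backtrack_pathway(expand_scope(u, {"A", "W"}, target="T"), "T", rng)
        g = pathway_geometry(pw, {"A", "W"})
        assert g.n_feedback == 1
        assert g.n_byproduct == 0

    def test_and_gate_geometry(self, and_gate_universe, rng):
        pw = backtrack_pathway(
            expand_scope(and_gate_universe, {"A"}, target="F"), "F", rng
        )
        g = pathway_geometry(pw, {"A"})
        assert g.n_reactions == 4
        assert g.n_metabolites == 4  # B, D, E, F
        assert g.n_base == 1
        assert g.n_border_rxn == 2  # r1 and r2 touch the core


class TestShortestDistance:
    def test_adjacent_target(self, and_gate_universe):
        assert shortest_distance_to_core(and_gate_universe, {"E"}, "F") == 1

    def test_chain_distance(self):
        u, _ = chain_universe(4)
        assert shortest_distance_to_core(u, {"A"}, "E") == 4

    def test_shortcut_makes_distance_shorter_than_pathway_length(self, rng):
        """A simple-graph shortcut (ignoring AND constraints) undercuts the
        true pathway length: distance 2 < length 3."""
        u = MetabolicUniverse(
            [
                Reaction("r1", frozenset("A"), frozenset("B")),
                Reaction("r2", frozenset("A"), frozenset("D")),
                Reaction("r3", frozenset(["B", "D"]), frozenset("E")),
                Reaction("r4", frozenset("E"), frozenset("F")),
                Reaction("shortcut", frozenset(["A", "Z"]), frozenset("E")),
            ]
        )
        assert shortest_distance_to_core(u, {"A"}, "F") == 2
        exp = expand_scope(u, {"A"}, target="F")
        pw = backtrack_pathway(exp, "F", rng)
        assert pw.length == 3
        assert pw.length >= shortest_distance_to_core(u, {"A"}, "F")

    def test_pathway_length_bounded_below_by_distance(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            universe, core = random_toy_universe(rng)
            exp = expand_scope(universe, core)
            for target in sorted(exp.reached - core):
                assert exp.first_layer[target] >= shortest_distance_to_core(
                    universe, core, target
                )

    def test_unreachable_raises(self):
        u, _ = chain_universe(2)
        with pytest.raises(UnreachableTargetError):
            shortest_distance_to_core(u, {"B"}, "A")
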