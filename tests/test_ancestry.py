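"""Dollo reconstruction, ambiguity flags, rootings, and LECA bounds."""

import numpy as np
import pytest

from conftest import random_matrix_and_taxonomy
from oracles import dollo_min_cost, unrestricted_min_changes
from lecatrace.ancestry import (
    RootingSpec,
    collapse_to_supergroups,
    dollo_reconstruct,
    gain_loss_summary,
    leca_complement,
    mark_ambiguous,
    rooting_topology,
    star_tree_bounds,
    universal_components,
)
from lecatrace.matrix import presence_by_supergroup, supergroup_counts
from lecatrace.simulate import simulate_tree
from lecatrace.trees import ROOT_EDGE, Clade, from_newick


def _random_states(tree, rng, p=0.5):
    return {leaf: int(rng.random() < p) for leaf in tree.leaf_names}


class TestTopologies:
    def test_preset_root_bipartitions(self):
        ub = rooting_topology("unikont_bikont")
        assert {frozenset(c.leaf_names) for c in ub.children} == {
            frozenset({"Opisthokonts", "Amoebozoa"}),
            frozenset({"Plantae", "Chromalveolates", "Excavates"}),
        }
        eb = rooting_topology("excavate_basal")
        assert {frozenset(c.leaf_names) for c in eb.children} == {
            frozenset({"Excavates"}),
            frozenset({"Opisthokonts", "Amoebozoa", "Plantae", "Chromalveolates"}),
        }
        star = rooting_topology("star")
        assert len(star.children) == 5 and all(c.is_leaf for c in star.children)

    def test_custom_rooting_must_cover_supergroups(self):
        with pytest.raises(ValueError, match="lacks supergroups"):
            rooting_topology(RootingSpec(preset="custom", newick="(Excavates,Plantae);"))

    def test_newick_round_trip(self):
        t = from_newick("((A,B),(C,(D,E)));")
        assert from_newick(t.to_newick()).signature == t.signature


class TestCollapse:
    def test_collapse_shape_on_fixture(self, nup_matrix, nup_taxonomy):
        c = collapse_to_supergroups(nup_matrix, nup_taxonomy)
        assert c.shape == (31, 5)
        assert c.genomes == nup_taxonomy.supergroups

    def test_single_genome_supergroup_copies_state(self):
        rng = np.random.default_rng(0)
        matrix, taxonomy = random_matrix_and_taxonomy(rng, n_genomes=4, n_supergroups=4)
        collapsed = collapse_to_supergroups(matrix, taxonomy)
        # one genome per supergroup: collapse must be a column permutation
        for j, sg in enumerate(taxonomy.supergroups):
            src = taxonomy.genomes_in(sg)[0]
            k = matrix.genomes.index(src)
            assert np.array_equal(collapsed.states[:, j], matrix.states[:, k])

    @pytest.mark.parametrize("seed", range(5))
    def test_collapse_equals_naive_any(self, seed):
        rng = np.random.default_rng(seed)
        matrix, taxonomy = random_matrix_and_taxonomy(rng)
        collapsed = collapse_to_supergroups(matrix, taxonomy)
        for i in range(len(matrix.components)):
            for j, sg in enumerate(taxonomy.supergroups):
                members = [matrix.genomes.index(g) for g in taxonomy.genomes_in(sg)]
                assert collapsed.states[i, j] == int(
                    any(matrix.states[i, k] == 1 for k in members)
                )


class TestDollo:
    def test_all_present_gains_at_root(self):
        t = from_newick("((A,B),(C,D));")
        res = dollo_reconstruct(t, {"c": {"A": 1, "B": 1, "C": 1, "D": 1}})
        ev = res["c"]
        assert ev.gain_edge == ROOT_EDGE and ev.root_state and ev.loss_edges == ()
        assert ev.cost == 1

    def test_single_carrier_gains_on_its_edge(self):
        t = from_newick("((A,B),C);")
        ev = dollo_reconstruct(t, {"c": {"A": 1, "B": 0, "C": 0}})["c"]
        assert ev.gain_edge == "A" and not ev.root_state

    def test_absent_everywhere_is_a_no_event_result(self):
        t = from_newick("(A,B);")
        ev = dollo_reconstruct(t, {"c": {"A": 0, "B": 0}})["c"]
        assert ev.gain_edge is None and ev.cost == 0 and not ev.root_state

    def test_missing_leaf_state_raises(self):
        t = from_newick("(A,B);")
        with pytest.raises(KeyError, match="missing states"):
            dollo_reconstruct(t, {"c": {"A": 1}})

    def test_loss_edges_are_maximal_absent_subtrees(self):
        t = from_newick("((A,B),(C,D));")
        ev = dollo_reconstruct(t, {"c": {"A": 1, "B": 1, "C": 0, "D": 0}})["c"]
        assert ev.gain_edge == "A+B" and ev.loss_edges == () and not ev.root_state
        ev2 = dollo_reconstruct(t, {"c": {"A": 1, "B": 0, "C": 1, "D": 0}})["c"]
        assert ev2.gain_edge == ROOT_EDGE and set(ev2.loss_edges) == {"B", "D"}
        assert ev2.cost == 3

    def test_invariant_under_child_reordering(self):
        rng = np.random.default_rng(7)
        for seed in range(5):
            t = simulate_tree(6, seed)
            states = {"c": _random_states(t, rng)}

            def mirror(node):
                if node.is_leaf:
                    return node
                return Clade(children=tuple(mirror(ch) for ch in reversed(node.children)))

            r1 = dollo_reconstruct(t, states)["c"]
            r2 = dollo_reconstruct(mirror(t), states)["c"]
            assert (r1.gain_edge, r1.root_state, r1.cost) == (r2.gain_edge, r2.root_state, r2.cost)
            assert sorted(r1.loss_edges) == sorted(r2.loss_edges)

    @pytest.mark.parametrize("n_leaves", [2, 3, 4, 5, 6, 7, 8])
    def test_cost_matches_single_gain_enumeration_oracle(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        for seed in range(6):
            tree = simulate_tree(n_leaves, seed)
            for _ in range(4):
                states = _random_states(tree, rng)
                if not any(states.values()):
                    continue
                ev = dollo_reconstruct(tree, {"c": states})["c"]
                assert ev.cost == dollo_min_cost(tree, states)

    @pytest.mark.parametrize("n_leaves", [3, 4, 5, 6, 7, 8])
    def test_ambiguity_flag_matches_enumeration_oracle(self, n_leaves):
        rng = np.random.default_rng(100 + n_leaves)
        for seed in range(5):
            tree = simulate_tree(n_leaves, seed)
            for _ in range(4):
                states = _random_states(tree, rng)
                if not any(states.values()):
                    continue
                dollo = dollo_reconstruct(tree, {"c": states})
                ev = mark_ambiguous(tree, {"c": states}, dollo)["c"]
                opposite = 0 if ev.root_state else 1
                alt = unrestricted_min_changes(tree, states, opposite)
                assert ev.ambiguous == (alt <= ev.cost)

    def test_symmetric_case_is_root_ambiguous(self):
        t = from_newick("((A,B),(C,D));")
        states = {"c": {"A": 1, "B": 1, "C": 0, "D": 0}}
        res = mark_ambiguous(t, states, dollo_reconstruct(t, states))
        assert res["c"].ambiguous is True

    def test_all_present_is_unambiguous(self):
        t = from_newick("((A,B),(C,D));")
        states = {"c": {l: 1 for l in "ABCD"}}
        res = mark_ambiguous(t, states, dollo_reconstruct(t, states))
        assert res["c"].ambiguous is False


class TestLeca:
    def test_fixture_complement_sizes_under_both_rootings(self, nup_matrix, nup_taxonomy):
        assert len(leca_complement(nup_matrix, nup_taxonomy, "unikont_bikont")) == 26
        assert len(leca_complement(nup_matrix, nup_taxonomy, "excavate_basal")) == 23

    def test_complement_equals_present_on_both_root_sides(self, nup_matrix, nup_taxonomy):
        profile = presence_by_supergroup(nup_matrix, nup_taxonomy)
        expected = {
            c
            for c in nup_matrix.components
            if profile[c] & {"Opisthokonts", "Amoebozoa"}
            and profile[c] & {"Plantae", "Chromalveolates", "Excavates"}
        }
        assert leca_complement(nup_matrix, nup_taxonomy, "unikont_bikont") == expected

    def test_single_supergroup_component_never_ancestral(self, nup_matrix, nup_taxonomy):
        profile = presence_by_supergroup(nup_matrix, nup_taxonomy)
        singles = {c for c in nup_matrix.components if len(profile[c]) == 1}
        assert singles  # the fixture has lineage-restricted components
        for preset in ("unikont_bikont", "excavate_basal"):
            assert not (singles & leca_complement(nup_matrix, nup_taxonomy, preset))

    @pytest.mark.parametrize("seed", range(4))
    def test_complement_bracketed_by_universal_and_multi_supergroup(self, seed):
        rng = np.random.default_rng(seed)
        matrix, taxonomy = random_matrix_and_taxonomy(rng, n_supergroups=5)
        taxonomy = taxonomy  # five groups so the presets apply
        # relabel supergroups to the default names
        from lecatrace.matrix import DEFAULT_SUPERGROUPS, TaxonEntry, TaxonomyMap

        mapping = dict(zip(taxonomy.supergroups, DEFAULT_SUPERGROUPS))
        taxonomy = TaxonomyMap(
            entries={
                g: TaxonEntry("", "", mapping[e.supergroup])
                for g, e in taxonomy.entries.items()
            },
            supergroups=DEFAULT_SUPERGROUPS,
        )
        profile = presence_by_supergroup(matrix, taxonomy)
        universal = set(universal_components(matrix, taxonomy))
        multi = {c for c in matrix.components if len(profile[c]) >= 2}
        for preset in ("unikont_bikont", "excavate_basal"):
            leca = leca_complement(matrix, taxonomy, preset)
            assert universal <= leca <= multi

    def test_star_bounds_on_fixture(self, nup_matrix, nup_taxonomy):
        bounds = star_tree_bounds(nup_matrix, nup_taxonomy)
        assert bounds.upper == 22
        assert bounds.witness_supergroup == "Amoebozoa"
        assert bounds.lower == len(universal_components(nup_matrix, nup_taxonomy))
        assert bounds.lower <= bounds.upper

    def test_star_bounds_coincide_when_all_universal(self):
        rng = np.random.default_rng(0)
        matrix, taxonomy = random_matrix_and_taxonomy(rng, n_components=4)
        matrix = matrix.with_states(np.ones_like(matrix.states))
        bounds = star_tree_bounds(matrix, taxonomy)
        assert bounds.as_tuple() == (4, 4)

    @pytest.mark.parametrize("seed", range(4))
    def test_star_bounds_match_definitions(self, seed):
        rng = np.random.default_rng(seed)
        matrix, taxonomy = random_matrix_and_taxonomy(rng)
        bounds = star_tree_bounds(matrix, taxonomy)
        counts = supergroup_counts(matrix, taxonomy)
        assert bounds.lower == len(universal_components(matrix, taxonomy))
        assert bounds.upper == min(counts.values())

    def test_leca_star_returns_bounds(self, nup_matrix, nup_taxonomy):
        result = leca_complement(nup_matrix, nup_taxonomy, "star")
        assert result.as_tuple() == star_tree_bounds(nup_matrix, nup_taxonomy).as_tuple()


class TestEventSummary:
    def test_opisthokont_restricted_components_are_opisthokont_gains(
        self, nup_matrix, nup_taxonomy
    ):
        topology = rooting_topology("unikont_bikont")
        collapsed = collapse_to_supergroups(nup_matrix, nup_taxonomy)
        tip_states = {
            comp: dict(zip(collapsed.genomes, map(int, collapsed.states[i])))
            for i, comp in enumerate(collapsed.components)
        }
        dollo = mark_ambiguous(topology, tip_states, dollo_reconstruct(topology, tip_states))
        summary = gain_loss_summary(dollo, topology)
        assert set(summary.gained.get("Opisthokonts", ())) == {
            "Nup358",
            "Pom121",
            "Pom152",
            "Pom34",
            "Nup37",
        }
        assert len(summary.leca) == 26

    def test_complement_plus_later_gains_covers_all_present(self, nup_matrix, nup_taxonomy):
        topology = rooting_topology("unikont_bikont")
        collapsed = collapse_to_supergroups(nup_matrix, nup_taxonomy)
        tip_states = {
            comp: dict(zip(collapsed.genomes, map(int, collapsed.states[i])))
            for i, comp in enumerate(collapsed.components)
        }
        dollo = dollo_reconstruct(topology, tip_states)
        summary = gain_loss_summary(dollo, topology)
        gained_later = sum(len(v) for v in summary.gained.values())
        present_somewhere = sum(
            1 for comp in collapsed.components if collapsed.row(comp).any()
        )
        assert len(summary.leca) + gained_later == present_somewhere

    def test_all_present_component_only_in_complement(self):
        topology = rooting_topology("unikont_bikont")
        states = {"c": {sg: 1 for sg in topology.leaf_names}}
        summary = gain_loss_summary(dollo_reconstruct(topology, states), topology)
        assert summary.leca == {"c"}
        assert not summary.gained and not summary.lost
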