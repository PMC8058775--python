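"""Basic GAMES: MEQ partition, inequality graph, cycles, isolation."""

import random
import re

import pytest

from rxnlint import (
    build_meq_graph,
    build_meq_partition,
    build_stoichiometry_matrix,
    detect_inconsistency_lp,
    find_inconsistency_cycle,
    isolate_from_cycle,
    render_bgames_narrative,
)
from rxnlint.fixtures import (
    generate_consistent_network,
    inject_cycle_error,
    inject_dc_error,
)

from conftest import net_from_text


def bfs_components(net):
    """Independent oracle: connected components of the undirected uni-uni
    graph, found by plain BFS over an adjacency it builds itself."""
    from rxnlint.network import ReactionCategory, classify_reaction

    adj = {sid: set() for sid in net.species_ids}
    for rxn in net.reactions:
        if classify_reaction(rxn) == ReactionCategory.UNI_UNI:
            a, b = rxn.reactants[0][0], rxn.products[0][0]
            adj[a].add(b)
            adj[b].add(a)
    seen, comps = set(), []
    for start in net.species_ids:
        if start in seen:
            continue
        comp, queue = set(), [start]
        while queue:
            node = queue.pop()
            if node in comp:
                continue
            comp.add(node)
            queue.extend(adj[node] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


class TestPartition:
    def test_transitive_merge(self):
        net = net_from_text("v537: c160 -> c86\nv601: c154 -> c86")
        part = build_meq_partition(net)
        labels = {m.label for m in part.meqs}
        assert "{c154=c160=c86}" in labels

    def test_no_uni_uni_gives_singletons(self):
        net = net_from_text("r: a + b -> c")
        part = build_meq_partition(net)
        assert sorted(m.label for m in part.meqs) == ["{a}", "{b}", "{c}"]

    def test_untouched_species_are_singletons(self, cycle_pattern_net):
        part = build_meq_partition(cycle_pattern_net)
        labels = {m.label for m in part.meqs}
        assert {"{c10}", "{c11}", "{c16}"} <= labels

    def test_spanning_reactions_form_spanning_tree(self, cycle_pattern_net):
        part = build_meq_partition(cycle_pattern_net)
        merged = next(m for m in part.meqs if len(m.members) == 3)
        assert sorted(merged.spanning_reactions) == ["v537", "v601"]
        assert len(merged.spanning_reactions) >= len(merged.members) - 1

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bfs_component_oracle(self, seed):
        net, _ = generate_consistent_network(3 + seed % 9, 8, seed)
        part = build_meq_partition(net)
        got = {frozenset(m.members) for m in part.meqs}
        assert got == bfs_components(net)

    def test_redundant_uni_uni_recorded_separately(self):
        net = net_from_text("u1: a -> b\nu2: b -> a")
        part = build_meq_partition(net)
        meq = part.meqs[0]
        assert len(meq.spanning_reactions) == 1
        assert len(meq.redundant_reactions) == 1


class TestGraph:
    def test_generic_multi_uni_arcs(self):
        net = net_from_text("r: a + b -> c")
        part = build_meq_partition(net)
        g = build_meq_graph(net, part)
        arcs = {(a.src_species, a.dst_species) for a in g.arcs}
        assert arcs == {("a", "c"), ("b", "c")}

    def test_same_meq_arc_is_contradiction_self_arc(self):
        # with c154 and c160 merged, v13 forces mass(c154) < mass(c160)
        # inside one MEQ
        net = net_from_text(
            "v537: c160 -> c154\nv13: c10 + c154 -> c160"
        )
        part = build_meq_partition(net)
        g = build_meq_graph(net, part)
        assert any(a.source == a.target for a in g.arcs)

    def test_multi_multi_contributes_nothing(self):
        net = net_from_text("r: a + b -> c + d\nq: c + d -> e + f")
        g = build_meq_graph(net, build_meq_partition(net))
        assert g.arcs == []

    def test_uni_multi_arc_points_to_heavier_side(self):
        # A -> 2 B conserving means mass(B) = mass(A)/2 < mass(A)
        net = net_from_text("r: A -> 2 B")
        g = build_meq_graph(net, build_meq_partition(net))
        assert [(a.src_species, a.dst_species) for a in g.arcs] == [("B", "A")]

    def test_understoichiometric_side_species_gets_no_arc(self):
        # b: 1 vs single-side 2: mass(b) < mass(c) is NOT implied
        net = net_from_text("r: 2 a + b -> 2 c")
        g = build_meq_graph(net, build_meq_partition(net))
        assert {(a.src_species, a.dst_species) for a in g.arcs} == {("a", "c")}


class TestCycleFinding:
    def test_acyclic_graph_returns_none(self):
        net = net_from_text("r1: a + b -> c\nr2: c + d -> e")
        g = build_meq_graph(net, build_meq_partition(net))
        assert find_inconsistency_cycle(g) is None

    def test_self_arc_is_length_one_cycle(self):
        net = net_from_text("v537: c160 -> c154\nv13: c10 + c154 -> c160")
        g = build_meq_graph(net, build_meq_partition(net))
        cycle = find_inconsistency_cycle(g)
        assert len(cycle) == 1 and cycle[0].source == cycle[0].target

    def test_two_arc_cycle_found(self, cycle_pattern_net):
        g = build_meq_graph(
            cycle_pattern_net, build_meq_partition(cycle_pattern_net)
        )
        cycle = find_inconsistency_cycle(g)
        assert sorted(a.reaction_id for a in cycle) == ["v13", "v208"]

    def test_deterministic(self, cycle_pattern_net):
        part = build_meq_partition(cycle_pattern_net)
        g = build_meq_graph(cycle_pattern_net, part)
        c1 = find_inconsistency_cycle(g)
        c2 = find_inconsistency_cycle(g)
        assert c1 == c2


class TestIsolation:
    def test_cycle_pattern_report(self, cycle_pattern_net):
        part = build_meq_partition(cycle_pattern_net)
        g = build_meq_graph(cycle_pattern_net, part)
        cycle = find_inconsistency_cycle(g)
        rep = isolate_from_cycle(cycle, part, cycle_pattern_net)
        # both multi-uni arc reactions plus the uni-uni chain
        assert set(rep.ris) == {"v13", "v208", "v537", "v601"}
        # only species touched by RIS reactions within traversed MEQs
        assert rep.sis == ["c10", "c154", "c160", "c86"]
        assert rep.method == "bgames"

    def test_narrative_three_parts(self, cycle_pattern_net):
        part = build_meq_partition(cycle_pattern_net)
        g = build_meq_graph(cycle_pattern_net, part)
        rep = isolate_from_cycle(
            find_inconsistency_cycle(g), part, cycle_pattern_net
        )
        eq = [s for s in rep.narrative if " = " in s]
        lt = [s for s in rep.narrative if " < " in s and "contradiction" not in s]
        contra = [s for s in rep.narrative if s.startswith("contradiction")]
        assert eq and lt and len(contra) == 1
        assert re.search(r"mass\((\w+)\) < .*mass\(\1\)", contra[0])

    def test_self_arc_contradiction_uses_uni_uni_path(self):
        net = net_from_text(
            "u1: a -> d\nu2: d -> c\nr: a + b -> c"
        )
        part = build_meq_partition(net)
        g = build_meq_graph(net, part)
        cycle = find_inconsistency_cycle(g)
        rep = isolate_from_cycle(cycle, part, net)
        assert set(rep.ris) == {"r", "u1", "u2"}

    def test_two_cycle_between_singletons_has_no_uni_unis(self):
        net = net_from_text("r1: a + b -> c\nr2: c + d -> a")
        part = build_meq_partition(net)
        cycle = find_inconsistency_cycle(build_meq_graph(net, part))
        rep = isolate_from_cycle(cycle, part, net)
        assert set(rep.ris) == {"r1", "r2"}

    def test_removing_any_arc_reaction_breaks_the_cycle(self, cycle_pattern_net):
        """Each arc of the reported cycle is necessary."""
        from rxnlint import ReactionNetwork

        part = build_meq_partition(cycle_pattern_net)
        cycle = find_inconsistency_cycle(
            build_meq_graph(cycle_pattern_net, part)
        )
        for arc in cycle:
            pruned = ReactionNetwork.from_reactions(
                [r for r in cycle_pattern_net.reactions if r.id != arc.reaction_id]
            )
            p2 = build_meq_partition(pruned)
            assert find_inconsistency_cycle(build_meq_graph(pruned, p2)) is None

    @pytest.mark.parametrize("seed", range(30))
    def test_narrative_references_only_ris_and_sis(self, seed):
        net, truth = generate_consistent_network(8, 8, seed)
        broken, _ = inject_cycle_error(net, truth, seed)
        part = build_meq_partition(broken)
        cycle = find_inconsistency_cycle(build_meq_graph(broken, part))
        rep = isolate_from_cycle(cycle, part, broken)
        for step in rep.narrative:
            for sid in re.findall(r"mass\((\w+)\)", step):
                assert sid in rep.sis
            m = re.search(r"by (\w+)$", step)
            if m:
                assert m.group(1) in rep.ris


class TestRenderNarrative:
    def test_contains_each_ris_reaction(self, cycle_pattern_net):
        part = build_meq_partition(cycle_pattern_net)
        rep = isolate_from_cycle(
            find_inconsistency_cycle(build_meq_graph(cycle_pattern_net, part)),
            part,
            cycle_pattern_net,
        )
        text = render_bgames_narrative(rep)
        for rid in rep.ris:
            assert text.count(f"by {rid}") == 1

    def test_length_one_cycle_gives_short_narrative(self):
        net = net_from_text("u: c -> a\nr: a + b -> c")
        part = build_meq_partition(net)
        rep = isolate_from_cycle(
            find_inconsistency_cycle(build_meq_graph(net, part)), part, net
        )
        assert len(rep.narrative) <= 3


class TestCoverageGap:
    @pytest.mark.parametrize("seed", range(20))
    def test_dc_only_errors_are_cycle_free_yet_inconsistent(self, seed):
        """The paired near-duplicate error class defeats graphical analysis:
        no MEQGraph cycle exists although LP correctly reports the error."""
        net, truth = generate_consistent_network(8, 8, seed)
        broken, _ = inject_dc_error(net, truth, seed)
        part = build_meq_partition(broken)
        assert find_inconsistency_cycle(build_meq_graph(broken, part)) is None
        lp = detect_inconsistency_lp(build_stoichiometry_matrix(broken))
        assert not lp.is_consistent


class TestSoundness:
    @pytest.mark.parametrize("chunk", range(5))
    def test_cycles_only_on_lp_inconsistent_networks(self, chunk):
        """No random consistent network ever shows a cycle (no false
        positives); injected cycles always coincide with LP infeasibility."""
        rng = random.Random(chunk)
        for _ in range(60):
            seed = rng.randrange(1 << 30)
            net, truth = generate_consistent_network(
                3 + seed % 10, 4 + seed % 6, seed
            )
            part = build_meq_partition(net)
            assert find_inconsistency_cycle(build_meq_graph(net, part)) is None
            broken, _ = inject_cycle_error(net, truth, seed)
            p2 = build_meq_partition(broken)
            cycle = find_inconsistency_cycle(build_meq_graph(broken, p2))
            if cycle is not None:
                lp = detect_inconsistency_lp(
                    build_stoichiometry_matrix(broken)
                )
                assert not lp.is_consistent
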