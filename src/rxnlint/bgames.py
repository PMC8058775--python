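"""Basic GAMES: graphical isolation of stoichiometric inconsistencies.

The inference engine works from two kinds of mass relations implied by
reaction structure:

* a uni-uni reaction (one reactant, one product, equal stoichiometries)
  forces mass equality; the transitive closure of these equalities
  partitions the species into Mass Equivalence Sets (MEQs);
* a multi-uni reaction (>=2 species on one side, one on the other)
  forces each multi-side species to be strictly lighter than the
  single-side species, yielding arcs of a digraph over MEQs.

A directed cycle in that MEQGraph is a proof that some mass is smaller
than itself, i.e. a stoichiometric inconsistency.  The cycle's arcs and
the uni-uni chains inside the traversed MEQs form the reaction isolation
set (RIS); the species they touch form the species isolation set (SIS);
and a three-part narrative (equalities, inequalities, contradiction)
explains the error to a human.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .network import (
    Reaction,
    ReactionCategory,
    ReactionNetwork,
    classify_reaction,
)

__all__ = [
    "MEQ",
    "MEQPartition",
    "MEQArc",
    "MEQGraph",
    "IsolationReport",
    "build_meq_partition",
    "build_meq_graph",
    "find_inconsistency_cycle",
    "isolate_from_cycle",
    "render_bgames_narrative",
]


@dataclass
class MEQ:
    """One mass equivalence set.

    ``spanning_reactions`` are the uni-uni reactions whose unions actually
    merged the members (a spanning tree); redundant uni-unis inside the
    set are kept separately.
    """

    members: list[str]
    spanning_reactions: list[str] = field(default_factory=list)
    redundant_reactions: list[str] = field(default_factory=list)

    @property
    def label(self) -> str:
        return "{" + "=".join(sorted(self.members)) + "}"

    def __contains__(self, sid: str) -> bool:
        return sid in self.members


@dataclass
class MEQPartition:
    """Partition of the species set into MEQs.

    ``uni_uni_edges`` holds every uni-uni relation (reactant, product,
    reaction id), spanning or redundant, for path reconstruction inside
    an MEQ.
    """

    meqs: list[MEQ]
    species_to_meq: dict[str, int]
    uni_uni_edges: list[tuple[str, str, str]] = field(default_factory=list)

    def meq_of(self, sid: str) -> MEQ:
        return self.meqs[self.species_to_meq[sid]]

    def label_of(self, sid: str) -> str:
        return self.meq_of(sid).label


@dataclass(frozen=True)
class MEQArc:
    """Arc (source -> target): mass(source MEQ) < mass(target MEQ),
    witnessed by ``reaction_id`` touching ``src_species``/``dst_species``."""

    source: int
    target: int
    reaction_id: str
    src_species: str
    dst_species: str


@dataclass
class MEQGraph:
    nodes: list[int]
    arcs: list[MEQArc]

    def successors(self, node: int) -> list[MEQArc]:
        return [a for a in self.arcs if a.source == node]

    @property
    def self_arcs(self) -> list[MEQArc]:
        return [a for a in self.arcs if a.source == a.target]


@dataclass
class IsolationReport:
    """An isolated inconsistency: RIS, SIS, and an ordered narrative."""

    ris: list[str]
    sis: list[str]
    narrative: list[str]
    method: str

    def __post_init__(self) -> None:
        if not self.ris or not self.sis:
            raise ValueError("RIS and SIS must be nonempty")

    def to_dict(self) -> dict:
        return {
            "ris": list(self.ris),
            "sis": list(self.sis),
            "narrative": list(self.narrative),
            "method": self.method,
        }


# ---------------------------------------------------------------------------
# MEQ construction (union-find over uni-uni reactions)
# ---------------------------------------------------------------------------


def build_meq_partition(net: ReactionNetwork) -> MEQPartition:
    """Union-find over species, one union per uni-uni reaction.

    Species untouched by uni-uni reactions form singleton MEQs.  MEQ
    order is deterministic: by first mention of any member in the
    network's species order.
    """
    parent: dict[str, str] = {sid: sid for sid in net.species_ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    spanning: dict[str, list[str]] = {}
    redundant: dict[str, list[str]] = {}
    edges: list[tuple[str, str, str]] = []
    for rxn in net.reactions:
        if classify_reaction(rxn) != ReactionCategory.UNI_UNI:
            continue
        a, b = rxn.reactants[0][0], rxn.products[0][0]
        edges.append((a, b, rxn.id))
        ra, rb = find(a), find(b)
        if ra == rb:
            redundant.setdefault(ra, []).append(rxn.id)
        else:
            # merge smaller label into larger is unnecessary at this size;
            # attach rb under ra and pool the bookkeeping
            parent[rb] = ra
            pooled = spanning.pop(rb, [])
            spanning.setdefault(ra, []).extend(pooled + [rxn.id])
            pooled_red = redundant.pop(rb, [])
            if pooled_red:
                redundant.setdefault(ra, []).extend(pooled_red)

    groups: dict[str, list[str]] = {}
    for sid in net.species_ids:
        groups.setdefault(find(sid), []).append(sid)

    meqs: list[MEQ] = []
    species_to_meq: dict[str, int] = {}
    for root in groups:  # insertion order == first-mention order
        idx = len(meqs)
        meqs.append(
            MEQ(
                members=groups[root],
                spanning_reactions=spanning.get(root, []),
                redundant_reactions=redundant.get(root, []),
            )
        )
        for sid in groups[root]:
            species_to_meq[sid] = idx
    return MEQPartition(
        meqs=meqs, species_to_meq=species_to_meq, uni_uni_edges=edges
    )


# ---------------------------------------------------------------------------
# MEQGraph construction
# ---------------------------------------------------------------------------


def _inequality_arcs(rxn: Reaction) -> list[tuple[str, str]]:
    """Strict mass inequalities (lighter, heavier) implied by one reaction.

    multi-uni with single-side species s (stoichiometry s_c) and
    multi-side terms k_x * x: mass(x) < mass(s) is strictly implied
    whenever k_x >= s_c (the remaining multi-side terms have positive
    mass).  uni-multi k A -> m B: k < m implies mass(B) < mass(A), and
    conversely.  Other categories contribute nothing.
    """
    category = classify_reaction(rxn)
    pairs: list[tuple[str, str]] = []
    if category == ReactionCategory.MULTI_UNI:
        if len(rxn.reactants) == 1:
            single, multi = rxn.reactants[0], rxn.products
        else:
            single, multi = rxn.products[0], rxn.reactants
        s_id, s_c = single
        for x_id, k_x in multi:
            if k_x >= s_c:
                pairs.append((x_id, s_id))
    elif category == ReactionCategory.UNI_MULTI:
        (a_id, k), (b_id, m) = rxn.reactants[0], rxn.products[0]
        if k < m:
            pairs.append((b_id, a_id))
        else:
            pairs.append((a_id, b_id))
    return pairs


def build_meq_graph(net: ReactionNetwork, part: MEQPartition) -> MEQGraph:
    """Arcs (MEQ(x) -> MEQ(s)) for each strict inequality mass(x) < mass(s).

    An arc inside a single MEQ (source == target) is an immediate
    contradiction — the reaction forces a mass to be smaller than itself
    — and is kept as a self-arc for the cycle finder to short-circuit on.
    Parallel arcs from different reactions are retained.
    """
    arcs: list[MEQArc] = []
    for rxn in net.reactions:
        for lighter, heavier in _inequality_arcs(rxn):
            arcs.append(
                MEQArc(
                    source=part.species_to_meq[lighter],
                    target=part.species_to_meq[heavier],
                    reaction_id=rxn.id,
                    src_species=lighter,
                    dst_species=heavier,
                )
            )
    return MEQGraph(nodes=list(range(len(part.meqs))), arcs=arcs)


# ---------------------------------------------------------------------------
# Cycle detection (shortest directed cycle, deterministic)
# ---------------------------------------------------------------------------


def find_inconsistency_cycle(graph: MEQGraph) -> list[MEQArc] | None:
    """Shortest directed cycle of the MEQGraph, or None if acyclic.

    Self-arcs are length-1 cycles and win immediately (lowest node, then
    arc order).  Otherwise BFS from each node in ascending index order;
    ties broken by the earlier start node, then arc insertion order.
    """
    for arc in graph.arcs:
        if arc.source == arc.target:
            return [arc]

    adjacency: dict[int, list[MEQArc]] = {n: [] for n in graph.nodes}
    for arc in graph.arcs:
        adjacency[arc.source].append(arc)

    best: list[MEQArc] | None = None
    for start in graph.nodes:
        # BFS over arcs, tracking the arc used to reach each node
        dist = {start: 0}
        via: dict[int, MEQArc] = {}
        queue: deque[int] = deque([start])
        found: list[MEQArc] | None = None
        while queue and found is None:
            node = queue.popleft()
            for arc in adjacency[node]:
                if arc.target == start:
                    # close the cycle
                    path = [arc]
                    cur = node
                    while cur != start:
                        path.append(via[cur])
                        cur = via[cur].source
                    found = list(reversed(path))
                    break
                if arc.target not in dist:
                    dist[arc.target] = dist[node] + 1
                    via[arc.target] = arc
                    queue.append(arc.target)
        if found is not None and (best is None or len(found) < len(best)):
            best = found
    return best


# ---------------------------------------------------------------------------
# Isolation
# ---------------------------------------------------------------------------


def _uni_uni_path(
    part: MEQPartition, meq: MEQ, start: str, goal: str
) -> list[tuple[str, str, str]]:
    """Shortest path (BFS, deterministic edge order) between two species
    inside one MEQ, through its uni-uni relation graph.  Returns edges
    as (from_species, to_species, reaction_id)."""
    if start == goal:
        return []
    adjacency: dict[str, list[tuple[str, str]]] = {m: [] for m in meq.members}
    for a, b, rid in part.uni_uni_edges:
        if a in adjacency and b in adjacency:
            adjacency[a].append((b, rid))
            adjacency[b].append((a, rid))
    prev: dict[str, tuple[str, str]] = {}
    queue: deque[str] = deque([start])
    seen = {start}
    while queue:
        node = queue.popleft()
        if node == goal:
            break
        for nxt, rid in adjacency[node]:
            if nxt not in seen:
                seen.add(nxt)
                prev[nxt] = (node, rid)
                queue.append(nxt)
    if goal not in prev:
        raise ValueError(
            f"species {start!r} and {goal!r} not connected inside MEQ "
            f"{meq.label}"
        )
    path: list[tuple[str, str, str]] = []
    cur = goal
    while cur != start:
        came, rid = prev[cur]
        path.append((came, cur, rid))
        cur = came
    return list(reversed(path))


def isolate_from_cycle(
    cycle: list[MEQArc], part: MEQPartition, net: ReactionNetwork
) -> IsolationReport:
    """Build RIS/SIS and a three-part narrative from a MEQGraph cycle.

    RIS: the cycle's arc reactions plus, per traversed MEQ, the uni-uni
    reactions on a shortest path between the species where the cycle
    enters and leaves that MEQ.  SIS: members of traversed MEQs that
    occur in RIS reactions.
    """
    if not cycle:
        raise ValueError("cycle must be nonempty")

    equality_lines: list[str] = []
    inequality_lines: list[str] = []
    ris: list[str] = []
    path_species: set[str] = set()

    def add_ris(rid: str) -> None:
        if rid not in ris:
            ris.append(rid)

    n = len(cycle)
    for i, arc in enumerate(cycle):
        add_ris(arc.reaction_id)
        inequality_lines.append(
            f"mass({arc.src_species}) < mass({arc.dst_species}) "
            f"by {arc.reaction_id}"
        )
        # inside the MEQ the cycle enters at this arc's head and leaves at
        # the next arc's tail (for a self-arc: from head back to tail)
        next_arc = cycle[(i + 1) % n]
        meq = part.meqs[arc.target]
        entry, exit_ = arc.dst_species, next_arc.src_species
        for a, b, rid in _uni_uni_path(part, meq, entry, exit_):
            add_ris(rid)
            equality_lines.append(f"mass({a}) = mass({b}) by {rid}")
            path_species.update((a, b))
        path_species.update((arc.src_species, arc.dst_species))

    # contradiction line: chain of strict inequalities closing on itself
    chain = [cycle[0].src_species] + [arc.dst_species for arc in cycle]
    chain[-1] = cycle[0].src_species
    contradiction = (
        "contradiction: " + " < ".join(f"mass({s})" for s in chain)
    )

    traversed = {arc.source for arc in cycle} | {arc.target for arc in cycle}
    ris_reactions = [net.reaction(rid) for rid in ris]
    ris_species = {
        sid for rxn in ris_reactions for sid in rxn.species_ids
    }
    sis = sorted(
        sid
        for idx in traversed
        for sid in part.meqs[idx].members
        if sid in ris_species
    )
    narrative = equality_lines + inequality_lines + [contradiction]
    return IsolationReport(ris=ris, sis=sis, narrative=narrative, method="bgames")


def render_bgames_narrative(report: IsolationReport) -> str:
    if report.method != "bgames":
        raise ValueError("narrative renderer expects a bgames report")
    if not report.narrative:
        raise ValueError("empty narrative")
    header = (
        f"RIS: {', '.join(report.ris)}\n"
        f"SIS: {', '.join(report.sis)}\n"
    )
    return header + "\n".join(report.narrative) + "\n"
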