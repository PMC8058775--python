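"""Seeded synthetic reaction networks with known ground truth.

The generator assigns every species a hidden positive integer vector
over k moieties and builds only reactions that conserve those vectors
exactly.  Any positive linear functional of the vectors (e.g. the total
moiety count) is then a strictly positive mass witness, so generated
networks are stoichiometrically consistent *and* moiety balanced by
construction — one generator exercises both analysis subsystems.

Error injectors then break a network in a controlled way:

* ``inject_cycle_error`` adds a uni-uni back-edge across a multi-uni
  reaction, forcing an MEQGraph cycle (the basic-GAMES error class);
* ``inject_dc_error`` duplicates a multi-uni reaction with one reactant
  stoichiometry incremented; the difference of the two columns is pure
  mass destruction, detectable by the echelon criteria but invisible to
  the cycle finder;
* ``inject_moiety_drop`` deletes one product occurrence, producing a
  moiety imbalance that need not be a stoichiometric inconsistency.

Ground truth records what was injected so recovery can be scored.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from fractions import Fraction

from .network import (
    Reaction,
    ReactionCategory,
    ReactionNetwork,
    Species,
    classify_reaction,
)

__all__ = [
    "GroundTruth",
    "GenerationError",
    "generate_consistent_network",
    "inject_cycle_error",
    "inject_dc_error",
    "inject_moiety_drop",
]

RETRY_BUDGET = 100
MAX_STOICH = 3
K_RANGE = (2, 5)


class GenerationError(RuntimeError):
    """The retry budget was exhausted while constructing a reaction."""


@dataclass
class GroundTruth:
    """What a fixture contains, for scoring recovery.

    ``kind``: none | cycle_error | dc_error | moiety_drop | stoich_perturb.
    ``hidden_vectors``: species id -> per-moiety count vector (the
    conserved quantity every generated reaction respects).
    """

    kind: str = "none"
    injected_reactions: set[str] = field(default_factory=set)
    hidden_vectors: dict[str, tuple[int, ...]] = field(default_factory=dict)
    moiety_names: tuple[str, ...] = ()
    partner_reactions: set[str] = field(default_factory=set)
    dropped_species: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "none" and self.injected_reactions:
            raise ValueError("kind=none implies no injected reactions")


def _vec_add(a: tuple[int, ...], b: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(x + y for x, y in zip(a, b))


def generate_consistent_network(
    n_species: int, n_reactions: int, seed: int
) -> tuple[ReactionNetwork, GroundTruth]:
    """Generate a conserving (hence consistent) network, reproducibly.

    Species vectors are built so that uni-uni pairs (equal vectors) and
    multi-uni triples (vector sums) exist whenever ``n_species`` allows:
    species 2 duplicates species 1's vector, and species 3 (when
    present) is the exact sum of species 1 and 2, with the reaction
    ``s1 + s2 -> s3`` always emitted first.  Remaining reactions are a
    seeded mix of uni-uni, multi-uni and greedily solved conserving
    reactions (retry budget per reaction, integer stoichiometries <= 3).
    """
    if n_species < 2 or n_reactions < 1:
        raise ValueError("need n_species >= 2 and n_reactions >= 1")
    rng = random.Random(seed)
    k = rng.randint(*K_RANGE)
    moiety_names = tuple(f"m{i}" for i in range(k))
    sids = [f"s{i}" for i in range(1, n_species + 1)]
    vectors: dict[str, tuple[int, ...]] = {}
    vectors[sids[0]] = tuple(rng.randint(1, 3) for _ in range(k))
    vectors[sids[1]] = vectors[sids[0]]  # uni-uni partner
    for i, sid in enumerate(sids[2:], start=2):
        mode = rng.random()
        if i == 2 or mode < 0.35:
            a, b = rng.sample(sids[:i], 2) if i > 1 else (sids[0], sids[0])
            vectors[sid] = _vec_add(vectors[a], vectors[b])
        elif mode < 0.55:
            vectors[sid] = vectors[rng.choice(sids[:i])]
        else:
            vectors[sid] = tuple(rng.randint(1, 3) for _ in range(k))

    equal_pairs = [
        (a, b)
        for i, a in enumerate(sids)
        for b in sids[i + 1 :]
        if vectors[a] == vectors[b]
    ]
    sum_triples = [
        (a, b, c)
        for c in sids
        for i, a in enumerate(sids)
        for b in sids[i:]
        if a != c and b != c and _vec_add(vectors[a], vectors[b]) == vectors[c]
    ]

    reactions: list[Reaction] = []

    def add(reactants, products) -> None:
        rid = f"r{len(reactions) + 1}"
        reactions.append(
            Reaction(
                id=rid,
                reactants=tuple((s, Fraction(c)) for s, c in reactants),
                products=tuple((s, Fraction(c)) for s, c in products),
            )
        )

    def greedy_conserving() -> tuple[list, list] | None:
        for _ in range(RETRY_BUDGET):
            n_r = rng.randint(1, 2)
            chosen = rng.sample(sids, n_r)
            coeffs = [rng.randint(1, MAX_STOICH) for _ in chosen]
            target = (0,) * k
            for s, c in zip(chosen, coeffs):
                for _ in range(c):
                    target = _vec_add(target, vectors[s])
            remaining = list(target)
            products: dict[str, int] = {}
            for _ in range(3 * max(remaining)):
                options = [
                    s
                    for s in sids
                    if all(v <= r for v, r in zip(vectors[s], remaining))
                ]
                if not options:
                    break
                s = rng.choice(options)
                products[s] = products.get(s, 0) + 1
                remaining = [r - v for r, v in zip(remaining, vectors[s])]
                if not any(remaining):
                    break
            if not any(remaining) and products:
                return list(zip(chosen, coeffs)), sorted(products.items())
        return None

    if n_species >= 3:
        # s3's vector is s1 + s2 by construction: a guaranteed true
        # multi-uni so the error injectors always have a target
        add([(sids[0], 1), (sids[1], 1)], [(sids[2], 1)])
    while len(reactions) < n_reactions:
        mode = rng.random()
        if mode < 0.3 and equal_pairs:
            a, b = rng.choice(equal_pairs)
            if rng.random() < 0.5:
                a, b = b, a
            add([(a, 1)], [(b, 1)])
        elif mode < 0.6 and sum_triples:
            a, b, c = rng.choice(sum_triples)
            lhs = [(a, 1), (b, 1)] if a != b else [(a, 2)]
            if rng.random() < 0.5:
                add(lhs, [(c, 1)])
            else:
                add([(c, 1)], lhs)
        else:
            built = greedy_conserving()
            if built is not None:
                add(*built)
            elif equal_pairs:
                a, b = rng.choice(equal_pairs)
                add([(a, 1)], [(b, 1)])
            elif sum_triples:
                a, b, c = rng.choice(sum_triples)
                add([(a, 1), (b, 1)] if a != b else [(a, 2)], [(c, 1)])
            else:
                raise GenerationError(
                    "could not construct a conserving reaction within the "
                    "retry budget"
                )

    net = ReactionNetwork.from_reactions(reactions, name=f"synthetic_{seed}")
    for sid in sids:  # declare even species no reaction mentions
        if sid not in net.species:
            net.species[sid] = Species(id=sid)
    truth = GroundTruth(
        kind="none", hidden_vectors=dict(vectors), moiety_names=moiety_names
    )
    return net, truth


def _injection_targets(
    net: ReactionNetwork,
) -> list[tuple[Reaction, bool, int]]:
    """Injection targets: (multi-uni reaction, multi-side-is-reactants,
    index of a multi-side term whose coefficient >= the single-side
    coefficient).

    That coefficient condition is what makes the injected errors
    well-posed: with k_x >= s_c the reaction strictly implies
    mass(x) < mass(single), so a uni-uni back-edge is a guaranteed
    contradiction, and bumping k_x adds no mass relation that a correct
    network could not also exhibit (hence no spurious cycle).
    """
    out: list[tuple[Reaction, bool, int]] = []
    for rxn in net.reactions:
        if classify_reaction(rxn) != ReactionCategory.MULTI_UNI:
            continue
        on_reactants = len(rxn.reactants) >= 2
        multi = rxn.reactants if on_reactants else rxn.products
        single_coeff = (rxn.products if on_reactants else rxn.reactants)[0][1]
        if len(multi) < 2:
            continue
        for idx, (_, coeff) in enumerate(multi):
            if coeff >= single_coeff:
                out.append((rxn, on_reactants, idx))
    return out


def inject_cycle_error(
    net: ReactionNetwork, truth: GroundTruth, seed: int
) -> tuple[ReactionNetwork, GroundTruth]:
    """Add a uni-uni back-edge across a multi-uni reaction.

    For a multi-uni x + ... -> y the added reaction y -> x asserts
    mass(y) = mass(x) while the original asserts mass(y) > mass(x): the
    MEQGraph acquires a guaranteed cycle and the network becomes
    provably LP-inconsistent.
    """
    rng = random.Random(seed)
    candidates = _injection_targets(net)
    if not candidates:
        raise GenerationError("no multi-uni reaction available for injection")
    rxn, on_reactants, idx = rng.choice(candidates)
    multi = rxn.reactants if on_reactants else rxn.products
    x = multi[idx][0]
    y = (rxn.products if on_reactants else rxn.reactants)[0][0]
    rid = "err_cycle"
    new = Reaction(
        id=rid, reactants=((y, Fraction(1)),), products=((x, Fraction(1)),)
    )
    out = ReactionNetwork(
        species=dict(net.species),
        reactions=list(net.reactions) + [new],
        name=net.name + "+cycle",
    )
    new_truth = replace(
        truth,
        kind="cycle_error",
        injected_reactions={rid},
        partner_reactions={rxn.id},
    )
    return out, new_truth


def inject_dc_error(
    net: ReactionNetwork, truth: GroundTruth, seed: int
) -> tuple[ReactionNetwork, GroundTruth]:
    """Add a near-duplicate of a multi-uni reaction.

    The duplicate has one multi-side stoichiometry incremented, so the
    difference of the two columns is a pure destruction column: the
    detection criteria hold, yet no new uni-uni merge or inequality
    cycle appears, so the cycle finder stays blind to it.
    """
    rng = random.Random(seed)
    candidates = _injection_targets(net)
    if not candidates:
        raise GenerationError("no multi-uni reaction available for injection")
    rxn, on_reactants, bump = rng.choice(candidates)
    side = list(rxn.reactants if on_reactants else rxn.products)
    side[bump] = (side[bump][0], side[bump][1] + 1)
    rid = "err_dup"
    new = Reaction(
        id=rid,
        reactants=tuple(side) if on_reactants else rxn.reactants,
        products=rxn.products if on_reactants else tuple(side),
    )
    out = ReactionNetwork(
        species=dict(net.species),
        reactions=list(net.reactions) + [new],
        name=net.name + "+dc",
    )
    new_truth = replace(
        truth,
        kind="dc_error",
        injected_reactions={rid},
        partner_reactions={rxn.id},
    )
    return out, new_truth


def inject_moiety_drop(
    net: ReactionNetwork, truth: GroundTruth, seed: int
) -> tuple[ReactionNetwork, GroundTruth]:
    """Delete one product occurrence from a reaction with >=1 product.

    The mutilated reaction acquires a negative moiety delta equal to the
    dropped species' hidden vector; the network may or may not remain
    LP-consistent (a moiety imbalance is not necessarily a
    stoichiometric inconsistency).
    """
    rng = random.Random(seed)
    candidates = [r for r in net.reactions if len(r.products) >= 1]
    if not candidates:
        raise GenerationError("no reaction with products")
    rxn = rng.choice(candidates)
    drop_idx = rng.randrange(len(rxn.products))
    sid, coeff = rxn.products[drop_idx]
    products = list(rxn.products)
    if coeff > 1:
        products[drop_idx] = (sid, coeff - 1)
    else:
        del products[drop_idx]
    mutated = replace(rxn, products=tuple(products))
    reactions = [mutated if r.id == rxn.id else r for r in net.reactions]
    out = ReactionNetwork(
        species=dict(net.species), reactions=reactions, name=net.name + "+drop"
    )
    new_truth = replace(
        truth,
        kind="moiety_drop",
        injected_reactions={rxn.id},
        dropped_species=sid,
    )
    return out, new_truth
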