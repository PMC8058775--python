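"""Core representation of reaction networks.

A reaction network is a set of chemical species plus an ordered list of
reactions, each reaction listing reactants and products with positive
rational stoichiometries.  All downstream analyses (moiety balance, LP
consistency, GAMES isolation) consume the objects defined here.

Stoichiometries are kept as exact :class:`fractions.Fraction` values
throughout: the analyses are algebraic statements about mass balance, and
floating point would introduce spurious near-singular behaviour.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Sequence

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "StoichiometryMatrix",
    "AnalysisConfig",
    "ReactionCategory",
    "classify_reaction",
    "apply_config",
    "build_stoichiometry_matrix",
    "NetworkError",
]


class NetworkError(ValueError):
    """Structural problem with a network definition."""


@dataclass(frozen=True)
class Species:
    """A chemical species.

    Parameters
    ----------
    id : str
        Unique identifier within the network (SBML ``id`` attribute).
    name : str or None
        Optional display name.
    compartment : str or None
        Optional compartment identifier; carried through but not analysed.
    is_boundary : bool
        SBML ``boundaryCondition`` flag.
    """

    id: str
    name: str | None = None
    compartment: str | None = None
    is_boundary: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("species id must be nonempty")


def _merge_terms(
    terms: Iterable[tuple[str, Fraction]]
) -> tuple[tuple[str, Fraction], ...]:
    """Merge duplicate species mentions on one reaction side by summing."""
    merged: dict[str, Fraction] = {}
    order: list[str] = []
    for sid, coeff in terms:
        coeff = Fraction(coeff)
        if coeff <= 0:
            raise NetworkError(f"stoichiometry for {sid!r} must be positive")
        if not sid:
            raise NetworkError("empty species id in reaction term")
        if sid not in merged:
            merged[sid] = coeff
            order.append(sid)
        else:
            merged[sid] += coeff
    return tuple((sid, merged[sid]) for sid in order)


@dataclass(frozen=True)
class Reaction:
    """One reaction: reactants -> products with positive rational stoichiometries.

    Duplicate mentions of a species on one side are merged by summing their
    coefficients.  ``reversible`` is carried through from SBML but all
    balance analyses are direction-independent.
    """

    id: str
    reactants: tuple[tuple[str, Fraction], ...]
    products: tuple[tuple[str, Fraction], ...]
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("reaction id must be nonempty")
        object.__setattr__(self, "reactants", _merge_terms(self.reactants))
        object.__setattr__(self, "products", _merge_terms(self.products))

    @property
    def species_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for sid, _ in (*self.reactants, *self.products):
            if sid not in seen:
                seen.append(sid)
        return tuple(seen)

    def net_stoichiometry(self) -> dict[str, Fraction]:
        """Products minus reactants per species (exact)."""
        net: dict[str, Fraction] = {}
        for sid, coeff in self.products:
            net[sid] = net.get(sid, Fraction(0)) + coeff
        for sid, coeff in self.reactants:
            net[sid] = net.get(sid, Fraction(0)) - coeff
        return net


@dataclass
class ReactionNetwork:
    """Species map plus ordered reaction list.

    Invariants: species ids unique, reaction ids unique, every species
    referenced by a reaction present in the species map.
    """

    species: dict[str, Species] = field(default_factory=dict)
    reactions: list[Reaction] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rxn in self.reactions:
            if rxn.id in seen:
                raise NetworkError(f"duplicate reaction id {rxn.id!r}")
            seen.add(rxn.id)
            for sid in rxn.species_ids:
                if sid not in self.species:
                    raise NetworkError(
                        f"reaction {rxn.id!r} references unknown species {sid!r}"
                    )

    @classmethod
    def from_reactions(
        cls, reactions: Sequence[Reaction], name: str = ""
    ) -> "ReactionNetwork":
        """Build a network auto-declaring species in first-mention order."""
        species: dict[str, Species] = {}
        for rxn in reactions:
            for sid in rxn.species_ids:
                if sid not in species:
                    species[sid] = Species(id=sid)
        return cls(species=species, reactions=list(reactions), name=name)

    @property
    def species_ids(self) -> list[str]:
        return list(self.species)

    def reaction(self, rid: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rid:
                return rxn
        raise KeyError(rid)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        return (
            list(self.species) == list(other.species)
            and self.species == other.species
            and self.reactions == other.reactions
        )


class ReactionCategory:
    """Reaction categories by side arity; drive MEQ/MEQGraph construction."""

    UNI_UNI = "uni-uni"
    MULTI_UNI = "multi-uni"
    UNI_MULTI = "uni-multi"
    MULTI_MULTI = "multi-multi"
    BOUNDARY = "boundary"


def classify_reaction(rxn: Reaction) -> str:
    """Classify a reaction by its side arities.

    * ``boundary``: either side empty (exchange with the environment).
    * ``uni-uni``: one reactant, one product, equal stoichiometries —
      implies mass equality between the two species.
    * ``multi-uni``: >=2 species on one side and exactly one on the other —
      implies a strict mass inequality for each multi-side species.
    * ``uni-multi``: one reactant, one product, *unequal* stoichiometries
      (k A -> m B); implies a strict inequality oriented by k vs m.
    * ``multi-multi``: everything else; carries no direct mass relation.
    """
    n_r, n_p = len(rxn.reactants), len(rxn.products)
    if n_r == 0 or n_p == 0:
        return ReactionCategory.BOUNDARY
    if n_r == 1 and n_p == 1:
        if rxn.reactants[0][1] == rxn.products[0][1]:
            return ReactionCategory.UNI_UNI
        return ReactionCategory.UNI_MULTI
    if (n_r >= 2 and n_p == 1) or (n_r == 1 and n_p >= 2):
        return ReactionCategory.MULTI_UNI
    return ReactionCategory.MULTI_MULTI


@dataclass
class AnalysisConfig:
    """User-tunable analysis configuration.

    ``ignored_species`` are glob patterns of species excluded from moiety
    resolution (e.g. compartment tags).  ``implicit_species`` are removed
    from every reaction before any analysis (e.g. water, EmptySet).
    ``ignored_moieties`` suppress balance checking for named moieties.
    Boundary reactions (one side empty) violate the premise that every
    reaction has a reactant and a product and are dropped by default.
    """

    ignored_species: list[str] = field(default_factory=list)
    ignored_moieties: list[str] = field(default_factory=list)
    implicit_species: list[str] = field(default_factory=list)
    drop_boundary_reactions: bool = True
    max_permutation_reruns: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_permutation_reruns < 0:
            raise ValueError("max_permutation_reruns must be >= 0")

    def is_species_ignored(self, sid: str) -> bool:
        return any(fnmatch.fnmatchcase(sid, pat) for pat in self.ignored_species)


def apply_config(
    net: ReactionNetwork, config: AnalysisConfig
) -> tuple[ReactionNetwork, list[str]]:
    """Return a filtered copy of ``net`` plus a list of diagnostic messages.

    Implicit species are removed from every reaction side; reactions left
    with an empty side are dropped (and logged), as are boundary reactions
    when ``drop_boundary_reactions`` is set.  The input is not modified and
    the operation is idempotent.
    """
    diagnostics: list[str] = []
    implicit = set(config.implicit_species)
    matched = {
        s for s in implicit if s in net.species
    }
    for miss in sorted(implicit - matched):
        diagnostics.append(f"implicit species {miss!r} matches nothing")

    new_reactions: list[Reaction] = []
    for rxn in net.reactions:
        reactants = tuple(t for t in rxn.reactants if t[0] not in implicit)
        products = tuple(t for t in rxn.products if t[0] not in implicit)
        changed = reactants != rxn.reactants or products != rxn.products
        if not reactants or not products:
            if changed:
                diagnostics.append(
                    f"reaction {rxn.id!r} dropped: one side empty after "
                    "implicit-species removal"
                )
                continue
            if config.drop_boundary_reactions:
                diagnostics.append(f"boundary reaction {rxn.id!r} dropped")
                continue
        if changed:
            rxn = replace(rxn, reactants=reactants, products=products)
        new_reactions.append(rxn)

    kept_species = {
        sid: sp
        for sid, sp in net.species.items()
        if sid not in implicit
    }
    filtered = ReactionNetwork(
        species=kept_species, reactions=new_reactions, name=net.name
    )
    return filtered, diagnostics


@dataclass
class StoichiometryMatrix:
    """Exact stoichiometry matrix N.

    ``entries[i][j]`` is the net moles of row label *i* produced by column
    reaction *j* (negative when consumed).  Rows may be species ids or MEQ
    labels.  ``degenerate_columns`` flags all-zero columns (e.g. A -> A).
    """

    row_labels: list[str]
    column_labels: list[str]
    entries: list[list[Fraction]]
    degenerate_columns: list[str] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_labels), len(self.column_labels))

    def column(self, j: int) -> list[Fraction]:
        return [row[j] for row in self.entries]

    def to_float_array(self):
        import numpy as np

        return np.array(
            [[float(x) for x in row] for row in self.entries], dtype=float
        )

    def column_dict(self, label: str) -> dict[str, Fraction]:
        j = self.column_labels.index(label)
        return {
            self.row_labels[i]: self.entries[i][j]
            for i in range(len(self.row_labels))
            if self.entries[i][j] != 0
        }


def build_stoichiometry_matrix(
    net: ReactionNetwork, config: AnalysisConfig | None = None
) -> StoichiometryMatrix:
    """Species-level stoichiometry matrix of a (config-filtered) network.

    A species consumed and produced by the same reaction is net-cancelled
    in the matrix (its written form is preserved on the Reaction for
    moiety counting).  All-zero columns are retained but flagged.
    """
    if config is not None:
        net, _ = apply_config(net, config)
    row_labels = net.species_ids
    row_index = {sid: i for i, sid in enumerate(row_labels)}
    column_labels = [rxn.id for rxn in net.reactions]
    entries = [
        [Fraction(0)] * len(column_labels) for _ in row_labels
    ]
    degenerate: list[str] = []
    for j, rxn in enumerate(net.reactions):
        net_st = rxn.net_stoichiometry()
        nonzero = False
        for sid, coeff in net_st.items():
            if coeff != 0:
                entries[row_index[sid]][j] = coeff
                nonzero = True
        if not nonzero:
            degenerate.append(rxn.id)
    return StoichiometryMatrix(
        row_labels=row_labels,
        column_labels=column_labels,
        entries=entries,
        degenerate_columns=degenerate,
    )
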