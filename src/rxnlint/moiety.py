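"""Moiety analysis: decompose species names into moieties and check balance.

A moiety is a characteristic chemical substructure (inorganic phosphate,
adenosine, a phospho group ...) whose instances may have slightly
different atomic formulas.  Many biochemical reactions — notably those
catalysed by transferases — preserve the multiset of moieties between
reactants and products, so an imbalance is a strong signal of a model
error, reported in units a modeler thinks in rather than as thousands of
unbalanced atoms.

Two naming conventions expose moiety structure through species ids:

* NC-2: underscore-separated, e.g. ``A_Pi_Pi_Pi`` for ATP;
* NC-1: gap-free concatenation against a user-supplied moiety list,
  e.g. ``MEKpp`` = MEK + p + p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

from .network import AnalysisConfig, Reaction, ReactionNetwork

__all__ = [
    "MoietySet",
    "MoietyStructure",
    "MoietyImbalance",
    "MoietyError",
    "parse_species_moieties_nc2",
    "decompose_nc1",
    "make_moiety_structure",
    "reaction_moiety_delta",
    "check_moiety_balance",
    "render_moiety_report",
    "read_moiety_structure_csv",
    "write_moiety_structure_csv",
]


class MoietyError(ValueError):
    """Malformed species name or unresolved species during analysis."""


@dataclass(frozen=True)
class MoietySet:
    """A multiset of moieties: moiety name -> positive count."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "MoietySet":
        for name, count in d.items():
            if count < 1:
                raise MoietyError(f"moiety count for {name!r} must be >= 1")
        return cls(counts=tuple(sorted(d.items())))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def size(self) -> int:
        return sum(c for _, c in self.counts)

    def __str__(self) -> str:
        return ";".join(f"{name}:{count}" for name, count in self.counts)


@dataclass
class MoietyStructure:
    """Mapping species id -> moiety multiset for one analyzed network."""

    per_species: dict[str, MoietySet] = field(default_factory=dict)
    moiety_universe: set[str] = field(default_factory=set)
    unresolved: list[str] = field(default_factory=list)
    ambiguous: dict[str, int] = field(default_factory=dict)

    def get(self, sid: str) -> MoietySet | None:
        return self.per_species.get(sid)


@dataclass
class MoietyImbalance:
    """One imbalanced reaction: moiety -> (products − reactants) count."""

    reaction_id: str
    deltas: dict[str, Fraction]

    def __post_init__(self) -> None:
        self.deltas = {m: d for m, d in self.deltas.items() if d != 0}
        if not self.deltas:
            raise MoietyError("an imbalance record must have a nonzero delta")


def parse_species_moieties_nc2(species_id: str) -> MoietySet:
    """Split an underscore-separated species id into its moiety multiset.

    ``A_Pi_Pi_Pi`` -> {A: 1, Pi: 3}.  Empty tokens (double or dangling
    underscores) are malformed.
    """
    if not species_id:
        raise MoietyError("empty species id")
    counts: dict[str, int] = {}
    for token in species_id.split("_"):
        if not token:
            raise MoietyError(
                f"malformed species name {species_id!r}: empty moiety token"
            )
        counts[token] = counts.get(token, 0) + 1
    return MoietySet.from_dict(counts)


def decompose_nc1(species_id: str, moiety_names: set[str]) -> list[MoietySet]:
    """All distinct multiset decompositions of a gap-free concatenated name.

    Dynamic programming over string positions: ``reachable[i]`` holds the
    set of moiety multisets that exactly cover ``species_id[:i]``.
    Matching is case-sensitive and exact.  Results are sorted
    fewest-moieties-first, then lexicographically; an empty list means no
    decomposition exists.
    """
    if not moiety_names or any(not m for m in moiety_names):
        raise MoietyError("moiety_names must be nonempty strings")
    n = len(species_id)
    names = sorted(moiety_names)
    reachable: list[set[tuple[tuple[str, int], ...]]] = [set() for _ in range(n + 1)]
    reachable[0].add(())
    for i in range(n):
        if not reachable[i]:
            continue
        for name in names:
            j = i + len(name)
            if j <= n and species_id[i:j] == name:
                for multiset in reachable[i]:
                    d = dict(multiset)
                    d[name] = d.get(name, 0) + 1
                    reachable[j].add(tuple(sorted(d.items())))
    results = [MoietySet(counts=ms) for ms in reachable[n]]
    results.sort(key=lambda ms: (ms.size, ms.counts))
    return results


def make_moiety_structure(
    net: ReactionNetwork,
    moiety_names: set[str],
    config: AnalysisConfig | None = None,
) -> MoietyStructure:
    """Resolve every non-ignored species of a network to a moiety multiset.

    Per species: try the NC-2 underscore split first; any token not
    itself a known moiety is further decomposed with NC-1; the first
    decomposition under the deterministic ordering is selected.  Species
    with no decomposition land in ``unresolved``; species with more than
    one NC-1 decomposition are noted in ``ambiguous``.
    """
    config = config or AnalysisConfig()
    structure = MoietyStructure(moiety_universe=set(moiety_names))
    for sid in net.species_ids:
        if config.is_species_ignored(sid):
            continue
        counts: dict[str, int] = {}
        resolved = True
        for token, times in parse_species_moieties_nc2(sid).counts:
            if token in moiety_names:
                counts[token] = counts.get(token, 0) + times
                continue
            options = decompose_nc1(token, moiety_names)
            if not options:
                resolved = False
                break
            if len(options) > 1:
                structure.ambiguous[sid] = len(options)
            for name, count in options[0].counts:
                counts[name] = counts.get(name, 0) + count * times
        if resolved:
            structure.per_species[sid] = MoietySet.from_dict(counts)
        else:
            structure.unresolved.append(sid)
    return structure


def reaction_moiety_delta(
    rxn: Reaction, structure: MoietyStructure
) -> dict[str, Fraction]:
    """Stoichiometry-weighted moiety difference, products minus reactants.

    Exact arithmetic: integer stoichiometries give integer-valued deltas,
    rational stoichiometries give rational deltas.  All species of the
    reaction must be resolved in the structure.
    """
    deltas: dict[str, Fraction] = {}
    for terms, sign in ((rxn.products, 1), (rxn.reactants, -1)):
        for sid, stoich in terms:
            mset = structure.get(sid)
            if mset is None:
                raise MoietyError(
                    f"species {sid!r} in reaction {rxn.id!r} has no moiety "
                    "decomposition"
                )
            for name, count in mset.counts:
                deltas[name] = deltas.get(name, Fraction(0)) + sign * stoich * count
    return deltas


def check_moiety_balance(
    net: ReactionNetwork,
    structure: MoietyStructure,
    config: AnalysisConfig | None = None,
) -> tuple[list[MoietyImbalance], list[str]]:
    """Per-reaction moiety balance check.

    Returns imbalances (network reaction order; fully balanced reactions
    absent) plus per-reaction diagnostics for unresolved species.
    Moieties listed in ``config.ignored_moieties`` are removed from the
    deltas before judging balance.
    """
    config = config or AnalysisConfig()
    ignored = set(config.ignored_moieties)
    imbalances: list[MoietyImbalance] = []
    diagnostics: list[str] = []
    for rxn in net.reactions:
        try:
            deltas = reaction_moiety_delta(rxn, structure)
        except MoietyError as exc:
            diagnostics.append(f"reaction {rxn.id!r} skipped: {exc}")
            continue
        deltas = {m: d for m, d in deltas.items() if d != 0 and m not in ignored}
        if deltas:
            imbalances.append(MoietyImbalance(reaction_id=rxn.id, deltas=deltas))
    return imbalances, diagnostics


def _fmt(x: Fraction) -> str:
    return str(x.numerator) if x.denominator == 1 else f"{x.numerator}/{x.denominator}"


def _side_count(
    terms: tuple[tuple[str, Fraction], ...],
    moiety: str,
    structure: MoietyStructure | None,
) -> Fraction | None:
    if structure is None:
        return None
    total = Fraction(0)
    for sid, stoich in terms:
        mset = structure.get(sid)
        if mset is None:
            return None
        total += stoich * dict(mset.counts).get(moiety, 0)
    return total


def render_moiety_report(
    imbalances: list[MoietyImbalance],
    net: ReactionNetwork,
    structure: MoietyStructure | None = None,
) -> str:
    """Human-readable moiety report: summary line, then one section per
    imbalanced reaction listing each moiety's reactant and product counts
    (counts shown when the moiety structure is supplied)."""
    from .io import format_side

    lines = [f"{len(imbalances)} reactions with moiety imbalance", ""]
    by_id = {rxn.id: rxn for rxn in net.reactions}
    for imb in imbalances:
        rxn = by_id[imb.reaction_id]
        arrow = "<->" if rxn.reversible else "->"
        lines.append(
            f"reaction {imb.reaction_id}: {format_side(rxn.reactants)} "
            f"{arrow} {format_side(rxn.products)}"
        )
        for moiety in sorted(imb.deltas):
            delta = imb.deltas[moiety]
            reac = _side_count(rxn.reactants, moiety, structure)
            prod = _side_count(rxn.products, moiety, structure)
            if reac is not None and prod is not None:
                lines.append(
                    f"  moiety {moiety}: reactants {_fmt(reac)}, "
                    f"products {_fmt(prod)} (delta {_fmt(delta)})"
                )
            else:
                lines.append(
                    f"  moiety {moiety}: products - reactants = {_fmt(delta)}"
                )
        lines.append("")
    return "\n".join(lines).rstrip() + "\n"


# ---------------------------------------------------------------------------
# Explicit structure files: two-column CSV `species_id, moiety:count;...`
# ---------------------------------------------------------------------------


def write_moiety_structure_csv(structure: MoietyStructure, path: str | Path) -> None:
    lines = ["species_id,moieties"]
    for sid, mset in structure.per_species.items():
        lines.append(f"{sid},{mset}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_moiety_structure_csv(path: str | Path) -> MoietyStructure:
    structure = MoietyStructure()
    text = Path(path).read_text().splitlines()
    for lineno, line in enumerate(text, start=1):
        line = line.strip()
        if not line or line.startswith("species_id"):
            continue
        sid, _, spec = line.partition(",")
        sid = sid.strip()
        counts: dict[str, int] = {}
        for item in spec.split(";"):
            item = item.strip()
            if not item:
                continue
            name, _, count = item.partition(":")
            try:
                counts[name.strip()] = int(count) if count else 1
            except ValueError as exc:
                raise MoietyError(
                    f"line {lineno}: bad moiety count in {item!r}"
                ) from exc
        structure.per_species[sid] = MoietySet.from_dict(counts)
        structure.moiety_universe.update(counts)
    return structure
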