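"""Reading and writing reaction networks.

Two formats are supported:

* a plain-text reaction dialect, one reaction per line::

      # comment
      v537: c160 -> c86
      r2: 2 Pstat_nuc -> PstatDimer_nuc
      h: A_Pi_Pi_Pi -> A_Pi_Pi + Pi

  Coefficients may be positive integers, decimals, or fractions ``p/q``;
  ``<->`` marks a reversible reaction; the Unicode arrow ``→`` is accepted
  on input.  An empty side is only legal when ``allow_boundary`` is set.

* a minimal SBML Level 2/3 subset: ``listOfSpecies`` and
  ``listOfReactions`` with stoichiometries.  Kinetic laws, rules and
  events are ignored.  Decimal stoichiometries are converted exactly to
  rationals.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from decimal import Decimal, InvalidOperation
from fractions import Fraction
from pathlib import Path
from typing import Iterable, TextIO

from .network import (
    AnalysisConfig,
    NetworkError,
    Reaction,
    ReactionNetwork,
    Species,
)

__all__ = [
    "ReactionParseError",
    "SBMLFormatError",
    "parse_reaction_line",
    "read_reaction_file",
    "write_reaction_file",
    "read_sbml",
    "write_sbml",
    "read_config_file",
]


class ReactionParseError(ValueError):
    """Malformed reaction line; message names the line and column."""


class SBMLFormatError(ValueError):
    """Unreadable or structurally invalid SBML input."""


_ARROWS = [("<->", True), ("->", False), ("→", False), ("⇄", True)]
_ID_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_']*")
_COEFF_RE = re.compile(r"\d+/\d+|\d+\.\d+|\.\d+|\d+")


def _parse_coefficient(tok: str, line: str, col: int) -> Fraction:
    try:
        if "/" in tok:
            num, den = tok.split("/")
            value = Fraction(int(num), int(den))
        elif "." in tok:
            value = Fraction(Decimal(tok))
        else:
            value = Fraction(int(tok))
    except (ValueError, ZeroDivisionError, InvalidOperation) as exc:
        raise ReactionParseError(
            f"bad coefficient {tok!r} at column {col} in {line!r}"
        ) from exc
    if value <= 0:
        raise ReactionParseError(
            f"nonpositive coefficient {tok!r} at column {col} in {line!r}"
        )
    return value


def _parse_side(
    text: str, line: str, offset: int, allow_empty: bool
) -> list[tuple[str, Fraction]]:
    terms: list[tuple[str, Fraction]] = []
    if not text.strip():
        if allow_empty:
            return terms
        raise ReactionParseError(
            f"empty reaction side at column {offset} in {line!r}"
        )
    pos = 0
    for chunk in text.split("+"):
        col = offset + pos
        pos += len(chunk) + 1
        body = chunk.strip()
        if not body:
            raise ReactionParseError(f"empty term at column {col} in {line!r}")
        coeff = Fraction(1)
        m = _COEFF_RE.match(body)
        if m and (len(m.group()) == len(body) or body[m.end()] in " \t"):
            if len(m.group()) == len(body):
                raise ReactionParseError(
                    f"term with coefficient but no species id at column "
                    f"{col} in {line!r}"
                )
            coeff = _parse_coefficient(m.group(), line, col)
            body = body[m.end() :].strip()
        idm = _ID_RE.fullmatch(body)
        if not idm:
            raise ReactionParseError(
                f"bad species id {body!r} at column {col} in {line!r}"
            )
        terms.append((body, coeff))
    return terms


def parse_reaction_line(line: str, allow_boundary: bool = False) -> Reaction:
    """Parse one ``id: reactants -> products`` line into a Reaction."""
    if ":" not in line:
        raise ReactionParseError(f"missing ':' separator in {line!r}")
    rid, _, rest = line.partition(":")
    rid = rid.strip()
    if not _ID_RE.fullmatch(rid or ""):
        raise ReactionParseError(f"bad reaction id {rid!r} in {line!r}")
    arrow = None
    reversible = False
    for symbol, rev in _ARROWS:
        if symbol in rest:
            arrow, reversible = symbol, rev
            break
    if arrow is None:
        raise ReactionParseError(f"missing or malformed arrow in {line!r}")
    lhs, _, rhs = rest.partition(arrow)
    offset = len(rid) + 1
    reactants = _parse_side(lhs, line, offset, allow_boundary)
    products = _parse_side(
        rhs, line, offset + len(lhs) + len(arrow), allow_boundary
    )
    return Reaction(
        id=rid,
        reactants=tuple(reactants),
        products=tuple(products),
        reversible=reversible,
    )


def read_reaction_file(
    path: str | Path | TextIO, allow_boundary: bool = False
) -> ReactionNetwork:
    """Read a plain-text reaction file into a network.

    Species are auto-declared in first-mention order; '#' comments and
    blank lines are ignored; an empty file yields an empty network.
    """
    if hasattr(path, "read"):
        text = path.read()
        name = getattr(path, "name", "")
    else:
        text = Path(path).read_text()
        name = Path(path).stem
    reactions: list[Reaction] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            rxn = parse_reaction_line(line, allow_boundary=allow_boundary)
        except ReactionParseError as exc:
            raise ReactionParseError(f"line {lineno}: {exc}") from exc
        if rxn.id in seen:
            raise NetworkError(f"line {lineno}: duplicate reaction id {rxn.id!r}")
        seen.add(rxn.id)
        reactions.append(rxn)
    return ReactionNetwork.from_reactions(reactions, name=str(name))


def _format_coeff(c: Fraction) -> str:
    if c == 1:
        return ""
    if c.denominator == 1:
        return f"{c.numerator} "
    return f"{c.numerator}/{c.denominator} "


def format_side(terms: Iterable[tuple[str, Fraction]]) -> str:
    return " + ".join(f"{_format_coeff(c)}{sid}" for sid, c in terms)


def format_reaction(rxn: Reaction) -> str:
    arrow = "<->" if rxn.reversible else "->"
    return (
        f"{rxn.id}: {format_side(rxn.reactants)} {arrow} "
        f"{format_side(rxn.products)}".rstrip()
    )


def write_reaction_file(net: ReactionNetwork, path: str | Path) -> None:
    lines = [format_reaction(rxn) for rxn in net.reactions]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# SBML subset
# ---------------------------------------------------------------------------

_SBML_L3_NS = "http://www.sbml.org/sbml/level3/version2/core"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _find_children(elem: ET.Element, name: str) -> list[ET.Element]:
    return [child for child in elem.iter() if _local(child.tag) == name]


def _stoich_to_fraction(value: str | None) -> Fraction:
    if value is None or value == "":
        return Fraction(1)
    try:
        return Fraction(Decimal(value))
    except InvalidOperation as exc:
        raise SBMLFormatError(f"bad stoichiometry {value!r}") from exc


def read_sbml(path: str | Path | TextIO) -> ReactionNetwork:
    """Read the species/reaction structure of an SBML file.

    Handles SBML Level 2 and Level 3 namespaces; decimal stoichiometry
    values are converted exactly to rationals; ``boundaryCondition``
    maps to :attr:`Species.is_boundary`.
    """
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise SBMLFormatError(f"unreadable SBML: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise SBMLFormatError(f"not an SBML document (root {root.tag!r})")
    models = _find_children(root, "model")
    if not models:
        raise SBMLFormatError("SBML document has no model element")
    model = models[0]

    species: dict[str, Species] = {}
    for elem in _find_children(model, "species"):
        sid = elem.get("id")
        if not sid:
            raise SBMLFormatError("species without id attribute")
        species[sid] = Species(
            id=sid,
            name=elem.get("name"),
            compartment=elem.get("compartment"),
            is_boundary=elem.get("boundaryCondition", "false") == "true",
        )

    reactions: list[Reaction] = []
    for elem in _find_children(model, "reaction"):
        rid = elem.get("id")
        if not rid:
            raise SBMLFormatError("reaction without id attribute")
        sides: dict[str, list[tuple[str, Fraction]]] = {
            "listOfReactants": [],
            "listOfProducts": [],
        }
        for side_name, terms in sides.items():
            for lst in elem:
                if _local(lst.tag) != side_name:
                    continue
                for ref in lst:
                    if _local(ref.tag) != "speciesReference":
                        continue
                    sid = ref.get("species")
                    if not sid:
                        raise SBMLFormatError(
                            f"reaction {rid!r}: speciesReference missing "
                            "species id"
                        )
                    if sid not in species:
                        raise SBMLFormatError(
                            f"reaction {rid!r} references unknown species "
                            f"{sid!r}"
                        )
                    terms.append((sid, _stoich_to_fraction(ref.get("stoichiometry"))))
        reactions.append(
            Reaction(
                id=rid,
                reactants=tuple(sides["listOfReactants"]),
                products=tuple(sides["listOfProducts"]),
                reversible=elem.get("reversible", "false") == "true",
            )
        )

    name = model.get("id") or model.get("name") or ""
    mentioned: dict[str, Species] = dict(species)
    return ReactionNetwork(species=mentioned, reactions=reactions, name=name)


def write_sbml(net: ReactionNetwork, path: str | Path) -> None:
    """Write a minimal SBML Level 3 document (species + reactions only)."""
    ET.register_namespace("", _SBML_L3_NS)
    root = ET.Element(
        f"{{{_SBML_L3_NS}}}sbml", {"level": "3", "version": "2"}
    )
    model = ET.SubElement(root, f"{{{_SBML_L3_NS}}}model")
    if net.name:
        model.set("id", net.name)
    compartments = {sp.compartment for sp in net.species.values() if sp.compartment}
    compartments.add("default")
    loc = ET.SubElement(model, f"{{{_SBML_L3_NS}}}listOfCompartments")
    for comp in sorted(compartments):
        ET.SubElement(
            loc, f"{{{_SBML_L3_NS}}}compartment", {"id": comp, "constant": "true"}
        )
    los = ET.SubElement(model, f"{{{_SBML_L3_NS}}}listOfSpecies")
    for sp in net.species.values():
        attrs = {
            "id": sp.id,
            "compartment": sp.compartment or "default",
            "hasOnlySubstanceUnits": "false",
            "boundaryCondition": "true" if sp.is_boundary else "false",
            "constant": "false",
        }
        if sp.name:
            attrs["name"] = sp.name
        ET.SubElement(los, f"{{{_SBML_L3_NS}}}species", attrs)
    lor = ET.SubElement(model, f"{{{_SBML_L3_NS}}}listOfReactions")
    for rxn in net.reactions:
        rel = ET.SubElement(
            lor,
            f"{{{_SBML_L3_NS}}}reaction",
            {"id": rxn.id, "reversible": "true" if rxn.reversible else "false"},
        )
        for side_name, terms in (
            ("listOfReactants", rxn.reactants),
            ("listOfProducts", rxn.products),
        ):
            if not terms:
                continue
            lst = ET.SubElement(rel, f"{{{_SBML_L3_NS}}}{side_name}")
            for sid, coeff in terms:
                ET.SubElement(
                    lst,
                    f"{{{_SBML_L3_NS}}}speciesReference",
                    {
                        "species": sid,
                        "stoichiometry": repr(float(coeff)),
                        "constant": "true",
                    },
                )
    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


# ---------------------------------------------------------------------------
# Configuration files
# ---------------------------------------------------------------------------

_LIST_KEYS = {"ignored_species", "ignored_moieties", "implicit_species"}
_BOOL_KEYS = {"drop_boundary_reactions"}
_INT_KEYS = {"max_permutation_reruns", "rng_seed"}


def read_config_file(path: str | Path) -> AnalysisConfig:
    """Read a key/value configuration file.

    Recognized keys: ``ignored_species``, ``ignored_moieties``,
    ``implicit_species`` (comma-separated lists),
    ``drop_boundary_reactions`` (true/false), ``max_permutation_reruns``
    and ``rng_seed`` (integers).  Unknown keys raise an error.
    """
    config = AnalysisConfig()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line:
            key, _, value = line.partition("=")
        elif ":" in line:
            key, _, value = line.partition(":")
        else:
            raise ValueError(f"config line {lineno}: expected key=value")
        key, value = key.strip(), value.strip()
        if key in _LIST_KEYS:
            items = [v.strip() for v in value.split(",") if v.strip()]
            setattr(config, key, items)
        elif key in _BOOL_KEYS:
            setattr(config, key, value.lower() in {"1", "true", "yes", "on"})
        elif key in _INT_KEYS:
            setattr(config, key, int(value))
        else:
            raise ValueError(f"config line {lineno}: unknown key {key!r}")
    return config
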