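"""Moiety analysis against brute-force counting and segmentation oracles."""

import random
from fractions import Fraction

import pytest

from rxnlint import (
    AnalysisConfig,
    Reaction,
    check_moiety_balance,
    decompose_nc1,
    make_moiety_structure,
    parse_species_moieties_nc2,
    reaction_moiety_delta,
    render_moiety_report,
)
from rxnlint.fixtures import generate_consistent_network
from rxnlint.moiety import (
    MoietyError,
    MoietySet,
    MoietyStructure,
    read_moiety_structure_csv,
    write_moiety_structure_csv,
)

from conftest import net_from_text

F = Fraction


def structure_from_hidden_vectors(truth) -> MoietyStructure:
    """Moiety structure induced by a fixture's hidden conservation vectors."""
    per = {
        sid: MoietySet.from_dict(
            {m: c for m, c in zip(truth.moiety_names, vec) if c > 0}
        )
        for sid, vec in truth.hidden_vectors.items()
    }
    return MoietyStructure(
        per_species=per, moiety_universe=set(truth.moiety_names)
    )


# --- independent oracles ---------------------------------------------------


def enumerate_segmentations(name: str, names: set[str]) -> set[tuple]:
    """Exhaustive recursion over all exact covers of `name` by `names`."""
    out: set[tuple] = set()

    def recurse(rest: str, acc: dict):
        if not rest:
            out.add(tuple(sorted(acc.items())))
            return
        for n in names:
            if rest.startswith(n):
                acc2 = dict(acc)
                acc2[n] = acc2.get(n, 0) + 1
                recurse(rest[len(n):], acc2)

    recurse(name, {})
    return out


def brute_force_delta(rxn: Reaction, structure: MoietyStructure) -> dict:
    """Expand every species instance into repeated moiety tokens and count."""
    def tokens(side):
        bag: dict[str, Fraction] = {}
        for sid, stoich in side:
            for name, count in structure.get(sid).counts:
                for _ in range(count):
                    bag[name] = bag.get(name, F(0)) + stoich
        return bag

    reac, prod = tokens(rxn.reactants), tokens(rxn.products)
    return {
        m: prod.get(m, F(0)) - reac.get(m, F(0))
        for m in set(reac) | set(prod)
        if prod.get(m, F(0)) != reac.get(m, F(0))
    }


# --- NC-2 ------------------------------------------------------------------


class TestNC2:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("A_Pi_Pi_Pi", {"A": 1, "Pi": 3}),
            ("X", {"X": 1}),
            ("Pstat_nuc", {"Pstat": 1, "nuc": 1}),
        ],
    )
    def test_split(self, name, expected):
        assert parse_species_moieties_nc2(name).as_dict() == expected

    @pytest.mark.parametrize("name", ["A__B", "_A", "A_", ""])
    def test_empty_tokens_rejected(self, name):
        with pytest.raises(MoietyError):
            parse_species_moieties_nc2(name)


# --- NC-1 ------------------------------------------------------------------


class TestNC1:
    @pytest.mark.parametrize(
        "name, names, expected",
        [
            ("MEKpp", {"MEK", "p"}, [{"MEK": 1, "p": 2}]),
            ("PstatDimer", {"P", "stat", "Dimer"}, [{"P": 1, "stat": 1, "Dimer": 1}]),
            ("AB", {"A", "B", "AB"}, [{"AB": 1}, {"A": 1, "B": 1}]),
            ("Q7", {"P", "stat"}, []),
        ],
    )
    def test_examples(self, name, names, expected):
        got = [d.as_dict() for d in decompose_nc1(name, names)]
        assert got == expected

    def test_ordering_fewest_moieties_first(self):
        got = decompose_nc1("AAAA", {"A", "AA"})
        sizes = [d.size for d in got]
        assert sizes == sorted(sizes)

    @pytest.mark.parametrize("seed", range(30))
    def test_agrees_with_exhaustive_enumeration(self, seed):
        """DP decomposition equals brute-force segmentation on ids <= 20 chars."""
        rng = random.Random(seed)
        alphabet = ["a", "b", "ab", "ba", "aab", "P", "p", "stat"]
        names = set(rng.sample(alphabet, rng.randint(2, 5)))
        # half the time compose the id from the names so covers exist
        if rng.random() < 0.5:
            name = "".join(
                rng.choice(sorted(names)) for _ in range(rng.randint(1, 5))
            )[:20]
        else:
            name = "".join(
                rng.choice("abPp") for _ in range(rng.randint(1, 12))
            )
        got = {d.counts for d in decompose_nc1(name, names)}
        assert got == enumerate_segmentations(name, names)

    def test_case_sensitive(self):
        assert decompose_nc1("mek", {"MEK"}) == []


# --- make_moiety_structure -------------------------------------------------


class TestMakeStructure:
    def test_dimer_model_with_ignored_compartment_tags(self, dimer_net):
        cfg = AnalysisConfig(ignored_species=["species_test"])
        st = make_moiety_structure(
            dimer_net, {"P", "stat", "Dimer", "sol", "nuc"}, cfg
        )
        assert st.get("Pstat_nuc").as_dict() == {"P": 1, "stat": 1, "nuc": 1}
        assert st.get("PstatDimer_sol").as_dict() == {
            "P": 1,
            "stat": 1,
            "Dimer": 1,
            "sol": 1,
        }
        assert st.get("species_test") is None  # ignored

    def test_single_moiety_species(self):
        net = net_from_text("r: Pi -> Pi")
        st = make_moiety_structure(net, {"Pi"})
        assert st.get("Pi").as_dict() == {"Pi": 1}

    def test_undecomposable_species_reported_unresolved(self):
        net = net_from_text("r: Q7 -> Q7")
        st = make_moiety_structure(net, {"P", "stat"})
        assert st.unresolved == ["Q7"]


# --- deltas and balance ----------------------------------------------------


class TestDelta:
    def test_atp_hydrolysis_balanced(self, atp_net):
        st = make_moiety_structure(atp_net, {"A", "Pi"})
        delta = reaction_moiety_delta(atp_net.reaction("hydrolysis"), st)
        assert all(v == 0 for v in delta.values())

    def test_dropped_phosphate_detected(self, atp_net):
        st = make_moiety_structure(atp_net, {"A", "Pi"})
        delta = reaction_moiety_delta(atp_net.reaction("sloppy"), st)
        assert delta["Pi"] == -1 and delta["A"] == 0

    def test_missing_product_kinase(self):
        net = net_from_text("Reaction19a: MAPK + MEKpp -> MEKpp")
        st = make_moiety_structure(net, {"MAPK", "MEK", "p"})
        delta = reaction_moiety_delta(net.reaction("Reaction19a"), st)
        assert {m: v for m, v in delta.items() if v != 0} == {"MAPK": F(-1)}

    def test_identity_reaction_all_zero(self):
        net = net_from_text("r: A -> A")
        st = make_moiety_structure(net, {"A"})
        assert all(
            v == 0
            for v in reaction_moiety_delta(net.reaction("r"), st).values()
        )

    def test_unresolved_species_raises_naming_both(self):
        net = net_from_text("r: Q7 -> Q7")
        st = MoietyStructure()
        with pytest.raises(MoietyError, match="Q7.*'r'"):
            reaction_moiety_delta(net.reaction("r"), st)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force_expansion(self, seed):
        """Weighted counting equals literal token expansion on random reactions."""
        rng = random.Random(1000 + seed)
        moieties = [f"m{i}" for i in range(rng.randint(2, 4))]
        species = {}
        for i in range(rng.randint(2, 5)):
            species[f"x{i}"] = MoietySet.from_dict(
                {
                    m: rng.randint(1, 3)
                    for m in rng.sample(moieties, rng.randint(1, len(moieties)))
                }
            )
        st = MoietyStructure(per_species=species, moiety_universe=set(moieties))
        sids = list(species)
        rxn = Reaction(
            id="r",
            reactants=tuple(
                (s, F(rng.randint(1, 3)))
                for s in rng.sample(sids, rng.randint(1, len(sids)))
            ),
            products=tuple(
                (s, F(rng.randint(1, 3)))
                for s in rng.sample(sids, rng.randint(1, len(sids)))
            ),
        )
        got = {m: v for m, v in reaction_moiety_delta(rxn, st).items() if v != 0}
        assert got == brute_force_delta(rxn, st)


class TestBalance:
    def test_balanced_network_empty(self, atp_net):
        st = make_moiety_structure(atp_net, {"A", "Pi"})
        net = net_from_text("hydrolysis: A_Pi_Pi_Pi -> A_Pi_Pi + Pi")
        imb, diags = check_moiety_balance(net, st)
        assert imb == [] and diags == []

    def test_sloppy_hydrolysis_flagged(self, atp_net):
        st = make_moiety_structure(atp_net, {"A", "Pi"})
        imb, _ = check_moiety_balance(atp_net, st)
        assert [i.reaction_id for i in imb] == ["sloppy"]
        assert imb[0].deltas == {"Pi": F(-1)}

    def test_ignored_moiety_suppresses_finding(self, atp_net):
        st = make_moiety_structure(atp_net, {"A", "Pi"})
        cfg = AnalysisConfig(ignored_moieties=["Pi"])
        imb, _ = check_moiety_balance(atp_net, st, cfg)
        assert imb == []

    @pytest.mark.parametrize("seed", range(25))
    def test_ignoring_never_creates_imbalance(self, seed):
        """Findings under an ignore list are a subset of findings without."""
        net, truth = generate_consistent_network(7, 7, seed)
        from rxnlint.fixtures import inject_moiety_drop

        broken, _ = inject_moiety_drop(net, truth, seed)
        st = structure_from_hidden_vectors(truth)
        base, _ = check_moiety_balance(broken, st)
        cfg = AnalysisConfig(ignored_moieties=[truth.moiety_names[0]])
        fewer, _ = check_moiety_balance(broken, st, cfg)
        assert {i.reaction_id for i in fewer} <= {i.reaction_id for i in base}

    @pytest.mark.parametrize("seed", range(25))
    def test_conserving_fixtures_balanced(self, seed):
        net, truth = generate_consistent_network(8, 8, seed)
        st = structure_from_hidden_vectors(truth)
        imb, diags = check_moiety_balance(net, st)
        assert imb == [] and diags == []

    def test_unresolved_species_becomes_diagnostic_not_abort(self):
        net = net_from_text("good: Pi -> Pi\nbad: Q7 -> Pi")
        st = make_moiety_structure(net, {"Pi"})
        imb, diags = check_moiety_balance(net, st)
        assert [i.reaction_id for i in imb] == []
        assert len(diags) == 1 and "bad" in diags[0]


class TestReportAndCsv:
    def test_empty_report(self):
        net = net_from_text("")
        assert render_moiety_report([], net).startswith(
            "0 reactions with moiety imbalance"
        )

    def test_report_names_reaction_moiety_and_counts(self):
        net = net_from_text("Reaction19a: MAPK + MEKpp -> MEKpp")
        st = make_moiety_structure(net, {"MAPK", "MEK", "p"})
        imb, _ = check_moiety_balance(net, st)
        text = render_moiety_report(imb, net, st)
        assert "Reaction19a" in text and "MAPK" in text
        assert "reactants 1, products 0" in text

    def test_structure_csv_round_trip(self, tmp_path, atp_net):
        st = make_moiety_structure(atp_net, {"A", "Pi"})
        path = tmp_path / "structure.csv"
        write_moiety_structure_csv(st, path)
        again = read_moiety_structure_csv(path)
        assert again.per_species == st.per_species
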