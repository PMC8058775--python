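"""Shared fixtures: small hand-checkable networks used across the suite."""

from __future__ import annotations

import io
from fractions import Fraction

import pytest

from rxnlint import ReactionNetwork, read_reaction_file


def net_from_text(text: str) -> ReactionNetwork:
    return read_reaction_file(io.StringIO(text))


# An inconsistency of the cycle kind: a uni-uni chain merges c86, c154
# and c160 into one mass-equivalence set, while two opposing multi-uni
# reactions force {c10} to be both lighter and heavier than that set.
CYCLE_PATTERN_TEXT = """
v537: c160 -> c86
v601: c154 -> c86
v13: c10 + c11 -> c160
v208: c154 + c16 -> c10
"""

# A dimerizing signalling model whose MEQ-level matrix is the 4x3
# worked example: uni-uni shuttling (R2, R5, R6) merges the monomer and
# dimer pools across compartments, leaving three pseudo reactions.
DIMER_MODEL_TEXT = """
R3: Pstat_nuc -> species_test + Pstat_sol
R1: 2 Pstat_sol -> PstatDimer_sol
R4: 2 Pstat_nuc -> PstatDimer_nuc
R2: Pstat_nuc -> stat_nuc
R5: stat_nuc -> stat_sol
R6: PstatDimer_sol -> PstatDimer_nuc
"""

# The MEQ-level stoichiometry matrix of the dimer model as a labelled
# dict, rows in the conventional order, and its reduced column echelon
# form (both hand-checkable).
F = Fraction
TABLE_ROWS = [
    "{species_test}",
    "{Pstat_sol}",
    "{PstatDimer_nuc=PstatDimer_sol}",
    "{Pstat_nuc=stat_nuc=stat_sol}",
]
TABLE_COLS = ["R3", "R1", "R4"]
TABLE_N = [
    [F(1), F(0), F(0)],
    [F(1), F(-2), F(0)],
    [F(0), F(1), F(1)],
    [F(-1), F(0), F(-2)],
]
TABLE_R = [
    [F(1), F(0), F(0)],
    [F(0), F(1), F(0)],
    [F(0), F(0), F(1)],
    [F(0), F(-1), F(-2)],
]
TABLE_C_FIRST = [F(1), F(1, 2), F(-1, 2)]  # first column: R3 + 1/2 R1 - 1/2 R4

ATP_TEXT = """
hydrolysis: A_Pi_Pi_Pi -> A_Pi_Pi + Pi
sloppy: A_Pi_Pi_Pi -> A_Pi_Pi
"""


@pytest.fixture
def cycle_pattern_net() -> ReactionNetwork:
    return net_from_text(CYCLE_PATTERN_TEXT)


@pytest.fixture
def dimer_net() -> ReactionNetwork:
    return net_from_text(DIMER_MODEL_TEXT)


@pytest.fixture
def atp_net() -> ReactionNetwork:
    return net_from_text(ATP_TEXT)
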