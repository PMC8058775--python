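"""Stoichiometric-inconsistency detection by linear programming.

A network is stoichiometrically consistent when a strictly positive mass
can be assigned to every species such that every reaction is balanced:
there exists v > 0 with N^T v = 0, where N is the stoichiometry matrix.
Strict positivity is not expressible in an LP, so the scale-invariant
reformulation v_i >= 1 is solved as a pure feasibility problem (constant
objective).  This stage *detects* only; isolation is the job of GAMES.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.optimize import linprog

from .network import StoichiometryMatrix

__all__ = [
    "LPResult",
    "LPStatus",
    "detect_inconsistency_lp",
    "exact_consistency",
]

DEFAULT_TOLERANCE = 1e-9


class LPStatus:
    CONSISTENT = "consistent"
    INCONSISTENT = "inconsistent"
    SOLVER_ERROR = "solver-error"


@dataclass
class LPResult:
    """Outcome of the LP feasibility check.

    ``mass_vector`` is a positive witness v (scaled so its minimum
    component is 1), present exactly when the network is consistent and
    verified against N^T v = 0 before being returned.
    """

    status: str
    mass_vector: dict[str, float] | None = None
    residual: float = 0.0
    message: str = ""

    @property
    def is_consistent(self) -> bool:
        return self.status == LPStatus.CONSISTENT


def detect_inconsistency_lp(
    matrix: StoichiometryMatrix, tolerance: float = DEFAULT_TOLERANCE
) -> LPResult:
    """Solve the feasibility problem {N^T v = 0, v >= 1}.

    Consistent iff feasible.  An empty matrix (no retained reactions or
    species) is vacuously consistent.  Solver failures are reported as a
    distinct status, never silently as "consistent".
    """
    n_species, n_reactions = matrix.shape
    if n_species == 0 or n_reactions == 0:
        witness = {sid: 1.0 for sid in matrix.row_labels}
        return LPResult(
            status=LPStatus.CONSISTENT,
            mass_vector=witness,
            message="empty matrix: vacuously consistent",
        )

    N = matrix.to_float_array()  # species x reactions
    A_eq = N.T  # reactions x species
    b_eq = np.zeros(n_reactions)
    c = np.zeros(n_species)
    try:
        res = linprog(
            c,
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=[(1.0, None)] * n_species,
            method="highs",
        )
    except ValueError as exc:  # malformed problem
        return LPResult(status=LPStatus.SOLVER_ERROR, message=str(exc))

    if res.status == 2:  # infeasible
        return LPResult(status=LPStatus.INCONSISTENT)
    if not res.success:
        return LPResult(
            status=LPStatus.SOLVER_ERROR,
            message=f"linprog status {res.status}: {res.message}",
        )

    v = np.asarray(res.x, dtype=float)
    v = v / v.min()  # scale witness so min component is 1
    residual = float(np.abs(A_eq @ v).max())
    scale = max(1.0, float(np.abs(A_eq).max()) * float(v.max()))
    if residual > tolerance * scale:
        return LPResult(
            status=LPStatus.SOLVER_ERROR,
            residual=residual,
            message="witness failed balance verification",
        )
    witness = {sid: float(val) for sid, val in zip(matrix.row_labels, v)}
    return LPResult(
        status=LPStatus.CONSISTENT, mass_vector=witness, residual=residual
    )


def exact_consistency(matrix: StoichiometryMatrix) -> bool:
    """Exact-rational consistency decision for small matrices.

    Decides feasibility of {N^T v = 0, v >= 1} by eliminating the
    equality constraints with exact Gaussian elimination and then
    applying Fourier-Motzkin elimination to the remaining inequalities
    over the free variables.  Everything is fractions.Fraction, so the
    answer is exact; cost grows quickly with the null-space dimension,
    which keeps this a small-matrix cross-check rather than the
    production detector (the HiGHS path above).
    """
    n_species, n_reactions = matrix.shape
    if n_species == 0 or n_reactions == 0:
        return True

    # Row-reduce the equality system N^T v = 0 (rows: reactions).
    rows = [
        [matrix.entries[i][j] for i in range(n_species)]
        for j in range(n_reactions)
    ]
    pivots: dict[int, list[Fraction]] = {}  # pivot column -> reduced row
    for row in rows:
        row = list(row)
        for col, prow in pivots.items():
            if row[col] != 0:
                factor = row[col]
                row = [a - factor * b for a, b in zip(row, prow)]
        lead = next((c for c, x in enumerate(row) if x != 0), None)
        if lead is None:
            continue
        row = [x / row[lead] for x in row]
        for col, prow in pivots.items():
            if prow[lead] != 0:
                factor = prow[lead]
                pivots[col] = [a - factor * b for a, b in zip(prow, row)]
        pivots[lead] = row

    free = [c for c in range(n_species) if c not in pivots]
    f_index = {c: k for k, c in enumerate(free)}

    # Each inequality: sum(coeffs * x_free) + const >= 0.
    inequalities: list[tuple[list[Fraction], Fraction]] = []
    for c in range(n_species):
        if c in pivots:
            # v_c = -sum over free columns of row[f] * x_f  (homogeneous)
            row = pivots[c]
            coeffs = [-row[f] for f in free]
        else:
            coeffs = [Fraction(0)] * len(free)
            coeffs[f_index[c]] = Fraction(1)
        inequalities.append((coeffs, Fraction(-1)))  # v_c - 1 >= 0

    # Fourier-Motzkin elimination over the free variables.
    for k in range(len(free)):
        pos = [iq for iq in inequalities if iq[0][k] > 0]
        neg = [iq for iq in inequalities if iq[0][k] < 0]
        rest = [iq for iq in inequalities if iq[0][k] == 0]
        combined = []
        for cp, dp in pos:
            for cn, dn in neg:
                scale_p, scale_n = -cn[k], cp[k]
                coeffs = [
                    scale_p * a + scale_n * b for a, b in zip(cp, cn)
                ]
                combined.append((coeffs, scale_p * dp + scale_n * dn))
        inequalities = rest + combined

    return all(const >= 0 for _, const in inequalities)
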