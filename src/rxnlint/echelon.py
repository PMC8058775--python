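"""Exact reduced column echelon form with combination tracking.

Given a rational matrix N (rows: MEQs, columns: reactions), we need the
reduced column echelon form R *together with* the invertible combination
matrix C such that N . C = R: every column of R is then an explicit
pseudo reaction — a linear combination of original reactions — and a
same-sign column of R is a constructive proof of mass creation or
destruction.

The computation row-reduces A = N^T.  Forward elimination with partial
pivoting yields the factorization A = P . L . U (recorded for
inspection); continuing to reduced row echelon form while accumulating
every row operation in a transform M gives M . A = rref(A), whence
C = M^T and R = rref(A)^T.  All arithmetic is fractions.Fraction —
floats never enter, so near-singular inputs cannot cause false results.

Pivoting is deterministic (largest absolute value, ties to the lowest
original row index); a seeded random tie-shuffle provides the alternate
permutations used for isolation re-runs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction

__all__ = ["EchelonDecomposition", "reduced_column_echelon", "mat_mul"]

Matrix = list[list[Fraction]]


def _zeros(rows: int, cols: int) -> Matrix:
    return [[Fraction(0)] * cols for _ in range(rows)]


def _identity(n: int) -> Matrix:
    out = _zeros(n, n)
    for i in range(n):
        out[i][i] = Fraction(1)
    return out


def mat_mul(a: Matrix, b: Matrix) -> Matrix:
    rows, inner, cols = len(a), len(b), len(b[0]) if b else 0
    out = _zeros(rows, cols)
    for i in range(rows):
        ai = a[i]
        for k in range(inner):
            aik = ai[k]
            if aik == 0:
                continue
            bk = b[k]
            oi = out[i]
            for j in range(cols):
                if bk[j] != 0:
                    oi[j] += aik * bk[j]
    return out


def _transpose(a: Matrix) -> Matrix:
    if not a:
        return []
    return [list(col) for col in zip(*a)]


@dataclass
class EchelonDecomposition:
    """R = N . C with R in reduced column echelon form.

    ``P``, ``L``, ``U`` factor the transpose: N^T = P . L . U.
    ``pivot_order`` lists, in elimination order, the N^T row chosen as
    pivot for each pivot column.  ``rank`` is the number of nonzero
    columns of R (zero columns are rightmost).
    """

    N: Matrix
    R: Matrix
    C: Matrix
    P: Matrix
    L: Matrix
    U: Matrix
    pivot_order: list[int] = field(default_factory=list)
    rank: int = 0

    def verify(self) -> bool:
        """Exact check of the algebraic contract N . C = R."""
        return mat_mul(self.N, self.C) == self.R


def _choose_pivot(
    column_values: list[tuple[int, Fraction]], rng: random.Random | None
) -> int:
    """Index (into A's rows) of the pivot: largest |value|, ties to the
    lowest row index, or a seeded shuffle of the maximal tie group."""
    best = max(abs(v) for _, v in column_values)
    ties = [i for i, v in column_values if abs(v) == best]
    if rng is not None and len(ties) > 1:
        return rng.choice(ties)
    return ties[0]


def reduced_column_echelon(
    N: Matrix, permutation_rng: random.Random | None = None
) -> EchelonDecomposition:
    """Reduced column echelon form of N with combination matrix.

    ``permutation_rng`` (optional) randomizes pivot choice within tie
    groups, producing the alternative permutation matrices used by
    isolation re-runs; with None the pivot choice is the deterministic
    default.  Zero and rank-deficient matrices are valid inputs.
    """
    n_rows = len(N)
    n_cols = len(N[0]) if n_rows else 0
    A = _transpose(N)  # n_cols x n_rows, rows are reactions
    m = n_cols  # rows of A

    # --- forward elimination with partial pivoting: P A = L U ----------
    # M accumulates every row operation applied to the *original* A, so
    # M . A = work holds throughout (and finally M . A = rref).
    perm = list(range(m))  # perm[i] = original A-row now at position i
    work = [list(row) for row in A]
    M = _identity(m)
    lower = _identity(m)
    pivot_cols: list[int] = []
    pivot_order: list[int] = []
    r = 0
    for col in range(n_rows):
        candidates = [(i, work[i][col]) for i in range(r, m) if work[i][col] != 0]
        if not candidates:
            continue
        pivot = _choose_pivot(candidates, permutation_rng)
        if pivot != r:
            work[r], work[pivot] = work[pivot], work[r]
            M[r], M[pivot] = M[pivot], M[r]
            perm[r], perm[pivot] = perm[pivot], perm[r]
            # swap the computed part of L below the diagonal
            for j in range(r):
                lower[r][j], lower[pivot][j] = lower[pivot][j], lower[r][j]
        pivot_order.append(perm[r])
        pivot_cols.append(col)
        for i in range(r + 1, m):
            if work[i][col] == 0:
                continue
            factor = work[i][col] / work[r][col]
            lower[i][r] = factor
            for j in range(col, n_rows):
                work[i][j] -= factor * work[r][j]
            M[i] = [a - factor * b for a, b in zip(M[i], M[r])]
        r += 1
        if r == m:
            break

    rank = len(pivot_cols)
    U = [list(row) for row in work]
    P_inv = _zeros(m, m)  # P_inv rows reorder A into work: work = P_inv . A
    for i, orig in enumerate(perm):
        P_inv[i][orig] = Fraction(1)
    P = _transpose(P_inv)  # permutation matrices: inverse == transpose

    # --- back substitution to reduced row echelon form ------------------
    rref = [list(row) for row in work]
    for k in reversed(range(rank)):
        col = pivot_cols[k]
        # normalize pivot row
        pv = rref[k][col]
        if pv != 1:
            rref[k] = [x / pv for x in rref[k]]
            M[k] = [x / pv for x in M[k]]
        # eliminate above
        for i in range(k):
            factor = rref[i][col]
            if factor == 0:
                continue
            rref[i] = [a - factor * b for a, b in zip(rref[i], rref[k])]
            M[i] = [a - factor * b for a, b in zip(M[i], M[k])]

    R = _transpose(rref) if rref else [[] for _ in range(n_rows)]
    if n_rows and not rref:
        R = [[] for _ in range(n_rows)]
    C = _transpose(M)
    dec = EchelonDecomposition(
        N=[list(row) for row in N],
        R=R,
        C=C,
        P=P,
        L=lower,
        U=U,
        pivot_order=pivot_order,
        rank=rank,
    )
    if not dec.verify():  # pragma: no cover - algebraic contract
        raise AssertionError("echelon decomposition violated N . C = R")
    if mat_mul(mat_mul(P, lower), U) != A:  # pragma: no cover
        raise AssertionError("PLU factorization violated N^T = P . L . U")
    return dec
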