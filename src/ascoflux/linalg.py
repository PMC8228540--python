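"""Exact rational linear algebra helpers.

Small dense routines over :class:`fractions.Fraction`, used where the
EFM machinery needs exactness (nullspace bases, rank tests, solving the
square systems that certify LP vertices).  Matrices are lists of lists of
Fractions; these networks are small enough that plain Gaussian elimination
is the right tool.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

Matrix = list[list[Fraction]]


def _as_fraction_matrix(rows: Sequence[Sequence]) -> Matrix:
    return [[Fraction(x) for x in row] for row in rows]


def rref(rows: Sequence[Sequence]) -> tuple[Matrix, list[int]]:
    """Reduced row echelon form; returns (matrix, pivot column indices)."""
    m = _as_fraction_matrix(rows)
    if not m:
        return m, []
    nrow, ncol = len(m), len(m[0])
    pivots: list[int] = []
    r = 0
    for c in range(ncol):
        if r >= nrow:
            break
        pivot = next((i for i in range(r, nrow) if m[i][c] != 0), None)
        if pivot is None:
            continue
        m[r], m[pivot] = m[pivot], m[r]
        inv = 1 / m[r][c]
        m[r] = [x * inv for x in m[r]]
        for i in range(nrow):
            if i != r and m[i][c] != 0:
                f = m[i][c]
                m[i] = [a - f * b for a, b in zip(m[i], m[r])]
        pivots.append(c)
        r += 1
    return m, pivots


def rank(rows: Sequence[Sequence]) -> int:
    if not rows or not rows[0]:
        return 0
    return len(rref(rows)[1])


def nullspace(rows: Sequence[Sequence], ncols: int | None = None) -> Matrix:
    """Basis of the right nullspace, one basis vector per returned row."""
    if not rows:
        if not ncols:
            return []
        return [[Fraction(int(i == j)) for j in range(ncols)] for i in range(ncols)]
    ncol = ncols if ncols is not None else len(rows[0])
    red, pivots = rref(rows)
    free = [c for c in range(ncol) if c not in pivots]
    basis: Matrix = []
    for fc in free:
        v = [Fraction(0)] * ncol
        v[fc] = Fraction(1)
        for r, pc in enumerate(pivots):
            v[pc] = -red[r][fc]
        basis.append(v)
    return basis


def solve_exact(a: Sequence[Sequence], b: Sequence) -> list[Fraction] | None:
    """Solve ``a @ x = b`` exactly; None if inconsistent.

    ``a`` may be rectangular; a particular solution is returned with free
    variables set to zero.
    """
    if not a:
        return [] if all(Fraction(x) == 0 for x in b) else None
    aug = [[Fraction(x) for x in row] + [Fraction(bv)] for row, bv in zip(a, b)]
    red, pivots = rref(aug)
    ncol = len(a[0])
    if ncol in pivots:  # pivot in the RHS column: inconsistent
        return None
    x = [Fraction(0)] * ncol
    for r, pc in enumerate(pivots):
        x[pc] = red[r][ncol]
    return x


def matvec(rows: Sequence[Sequence], v: Sequence) -> list[Fraction]:
    return [sum((Fraction(a) * Fraction(x) for a, x in zip(row, v)), Fraction(0)) for row in rows]
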