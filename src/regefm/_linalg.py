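"""Exact rational linear algebra on small dense matrices.

All elementary flux mode computations in this package are carried out over
the rationals so that toy-example assertions are bit-exact and the double
description iteration never suffers from floating point sign errors.
Matrices are plain ``list[list[Fraction]]``; the sizes involved (tens of
rows/columns) make dedicated array types unnecessary.

The pivoting rule is fixed (first nonzero entry scanning top-down, columns
left to right) so that every kernel basis and reduced form is deterministic
for a given input.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Sequence

Matrix = list[list[Fraction]]


def parse_rational(text: str) -> Fraction:
    """Parse ``3``, ``-0.5`` or ``p/q`` into an exact :class:`Fraction`."""
    return Fraction(text.strip())


def format_rational(x: Fraction) -> str:
    """Render a rational compactly: integers bare, otherwise ``p/q``."""
    if x.denominator == 1:
        return str(x.numerator)
    return f"{x.numerator}/{x.denominator}"


def copy_matrix(m: Sequence[Sequence[Fraction]]) -> Matrix:
    return [list(row) for row in m]


def rref(m: Sequence[Sequence[Fraction]]) -> tuple[Matrix, list[int]]:
    """Reduced row echelon form with the fixed first-nonzero pivot rule.

    Returns the reduced matrix and the list of pivot column indices.
    """
    a = copy_matrix(m)
    n_rows = len(a)
    n_cols = len(a[0]) if n_rows else 0
    pivots: list[int] = []
    r = 0
    for c in range(n_cols):
        if r == n_rows:
            break
        pivot_row = next((i for i in range(r, n_rows) if a[i][c] != 0), None)
        if pivot_row is None:
            continue
        a[r], a[pivot_row] = a[pivot_row], a[r]
        inv = a[r][c]
        a[r] = [x / inv for x in a[r]]
        for i in range(n_rows):
            if i != r and a[i][c] != 0:
                f = a[i][c]
                a[i] = [x - f * y for x, y in zip(a[i], a[r])]
        pivots.append(c)
        r += 1
    return a, pivots


def rank(m: Sequence[Sequence[Fraction]]) -> int:
    if not m or not m[0]:
        return 0
    return len(rref(m)[1])


def nullspace(m: Sequence[Sequence[Fraction]], n_cols: int | None = None) -> list[list[Fraction]]:
    """Basis of the right null space ``{x : m x = 0}``.

    One basis vector per free column, free columns in ascending order, each
    vector carrying a 1 in its free coordinate.  ``n_cols`` must be given for
    an empty matrix (no constraints).
    """
    if not m:
        if n_cols is None:
            raise ValueError("n_cols required for an empty constraint matrix")
        return [[Fraction(i == j) for j in range(n_cols)] for i in range(n_cols)]
    width = len(m[0])
    reduced, pivots = rref(m)
    free = [c for c in range(width) if c not in pivots]
    basis = []
    for fc in free:
        v = [Fraction(0)] * width
        v[fc] = Fraction(1)
        for i, pc in enumerate(pivots):
            v[pc] = -reduced[i][fc]
        basis.append(v)
    return basis


def mat_vec(m: Sequence[Sequence[Fraction]], v: Sequence[Fraction]) -> list[Fraction]:
    return [sum((a * b for a, b in zip(row, v)), Fraction(0)) for row in m]


def transpose(m: Sequence[Sequence[Fraction]]) -> Matrix:
    return [list(col) for col in zip(*m)]


def integerize(v: Iterable[Fraction]) -> list[int]:
    """Scale a rational vector to coprime integers (empty-safe)."""
    from math import gcd

    vec = list(v)
    den = 1
    for x in vec:
        den = den * x.denominator // gcd(den, x.denominator)
    ints = [int(x * den) for x in vec]
    g = 0
    for x in ints:
        g = gcd(g, abs(x))
    return [x // g for x in ints] if g else ints
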