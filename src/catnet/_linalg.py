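"""Exact rational linear algebra used by the analytical solvers.

Rates may arrive as :class:`fractions.Fraction` (parsed from ``"p/q"``
strings) or as floats.  Whenever every coefficient is rational the
null-space / solve routines below stay in exact arithmetic, so printed
fractions such as 2/11 come out bit-exact; otherwise they fall back to
numpy in double precision.
"""

from __future__ import annotations

from fractions import Fraction
from numbers import Rational

import numpy as np

__all__ = [
    "parse_rate",
    "format_rate",
    "all_rational",
    "rref",
    "nullspace",
    "solve_linear",
]


def parse_rate(value):
    """Parse a rate given as a number or a ``"p/q"`` string.

    Integers, Fractions and strings become exact Fractions; floats stay
    floats (no attempt is made to rationalise them).
    """
    if isinstance(value, str):
        return Fraction(value)
    if isinstance(value, bool):
        raise TypeError("rate must be a number, not a bool")
    if isinstance(value, Rational):
        return Fraction(value)
    if isinstance(value, float):
        return value
    raise TypeError(f"cannot interpret rate {value!r}")


def format_rate(value):
    """Render a rate for JSON output: ``"p/q"`` if exact, else a float."""
    if isinstance(value, Fraction):
        if value.denominator == 1:
            return int(value)
        return f"{value.numerator}/{value.denominator}"
    return float(value)


def all_rational(values) -> bool:
    return all(isinstance(v, Rational) for v in values)


def _as_fraction_matrix(rows):
    return [[Fraction(x) for x in row] for row in rows]


def rref(rows):
    """Reduced row echelon form over Fractions.

    Returns ``(matrix, pivot_columns)``.  Deterministic pivoting: first
    nonzero entry scanning rows top-down in each column left-to-right.
    """
    m = _as_fraction_matrix(rows)
    if not m:
        return m, []
    nrow, ncol = len(m), len(m[0])
    pivots = []
    r = 0
    for c in range(ncol):
        piv = next((i for i in range(r, nrow) if m[i][c] != 0), None)
        if piv is None:
            continue
        m[r], m[piv] = m[piv], m[r]
        inv = m[r][c]
        m[r] = [x / inv for x in m[r]]
        for i in range(nrow):
            if i != r and m[i][c] != 0:
                f = m[i][c]
                m[i] = [a - f * b for a, b in zip(m[i], m[r])]
        pivots.append(c)
        r += 1
        if r == nrow:
            break
    return m, pivots


def nullspace(rows, ncols=None):
    """Null-space basis of a matrix.

    Exact (list of Fraction vectors) when every entry is rational,
    numpy SVD otherwise.  Basis vectors follow the free-column order of
    the RREF, one per free column, with a 1 in the free coordinate.
    """
    rows = list(rows)
    if not rows:
        if ncols is None:
            raise ValueError("ncols required for an empty matrix")
        return [
            [Fraction(int(i == j)) for j in range(ncols)] for i in range(ncols)
        ]
    flat = [x for row in rows for x in row]
    if all_rational(flat):
        red, pivots = rref(rows)
        ncol = len(rows[0])
        free = [c for c in range(ncol) if c not in pivots]
        basis = []
        for fc in free:
            v = [Fraction(0)] * ncol
            v[fc] = Fraction(1)
            for r, pc in enumerate(pivots):
                v[pc] = -red[r][fc]
            basis.append(v)
        return basis
    a = np.asarray(rows, dtype=float)
    _, s, vt = np.linalg.svd(a)
    tol = (s[0] if s.size else 0.0) * 1e-10
    rank = int((s > tol).sum())
    return [list(vt[i]) for i in range(rank, vt.shape[0])]


def solve_linear(rows, rhs):
    """Solve a square (or consistent rectangular) system A x = b.

    Exact when all inputs are rational; raises ValueError if the system
    is singular or inconsistent.
    """
    flat = [x for row in rows for x in row] + list(rhs)
    n = len(rows[0])
    if all_rational(flat):
        aug = [list(row) + [b] for row, b in zip(rows, rhs)]
        red, pivots = rref(aug)
        if n in pivots:
            raise ValueError("inconsistent linear system")
        if len(pivots) < n:
            raise ValueError("singular linear system")
        x = [Fraction(0)] * n
        for r, pc in enumerate(pivots):
            x[pc] = red[r][n]
        return x
    sol, residuals, rank, _ = np.linalg.lstsq(
        np.asarray(rows, dtype=float), np.asarray(rhs, dtype=float), rcond=None
    )
    if rank < n:
        raise ValueError("singular linear system")
    return list(sol)
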