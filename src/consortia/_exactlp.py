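"""Exact-arithmetic LP machinery backing the test oracle.

Two independent routes, both in ``fractions.Fraction`` arithmetic so no
floating tolerance enters the oracle itself:

* :func:`simplex_max` — primal simplex with Bland's anti-cycling rule on the
  all-inequality form ``max c'x  s.t.  A x <= b, x >= 0`` with ``b >= 0``
  (equalities are passed as opposing inequality pairs, which makes the
  all-slack starting basis feasible).
* :func:`enumerate_vertices_max` — brute-force enumeration of basic
  solutions over active constraint subsets, tractable only for very small
  systems; used to cross-check the simplex route.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from typing import Optional, Sequence

__all__ = ["simplex_max", "enumerate_vertices_max", "Unbounded"]

Zero = Fraction(0)
One = Fraction(1)


class Unbounded(Exception):
    """The LP has an unbounded maximize direction."""


def to_fraction(x) -> Fraction:
    """Exact rational for a coefficient.

    Floats are read as their shortest round-tripping decimal (repr), so a
    model built from round decimal constants like 0.1 enters the exact layer
    as 1/10, not as the neighbouring binary float.
    """
    if isinstance(x, (Fraction, int)):
        return Fraction(x)
    return Fraction(repr(float(x)))  # also normalizes numpy scalars


def _as_fraction_matrix(A: Sequence[Sequence]) -> list[list[Fraction]]:
    return [[to_fraction(x) for x in row] for row in A]


def simplex_max(
    c: Sequence,
    A_ub: Sequence[Sequence],
    b_ub: Sequence,
) -> tuple[Fraction, list[Fraction]]:
    """Maximize c'x subject to A x <= b, x >= 0 (requires b >= 0).

    Returns (optimum, x) exactly.  Bland's rule guarantees termination on
    the heavily degenerate systems that mass-balance equality pairs create.
    """
    A = _as_fraction_matrix(A_ub)
    b = [to_fraction(x) for x in b_ub]
    cvec = [to_fraction(x) for x in c]
    m, n = len(A), len(cvec)
    if any(bi < 0 for bi in b):
        raise ValueError("simplex_max requires b >= 0 for the slack basis")

    # tableau: m rows of [A | I | b]; objective row holds reduced costs.
    T = [A[i] + [One if j == i else Zero for j in range(m)] + [b[i]]
         for i in range(m)]
    obj = cvec + [Zero] * m + [Zero]
    basis = list(range(n, n + m))

    while True:
        enter = next((j for j in range(n + m) if obj[j] > 0), None)
        if enter is None:
            break
        leave_row: Optional[int] = None
        best_ratio: Optional[Fraction] = None
        for i in range(m):
            a = T[i][enter]
            if a > 0:
                ratio = T[i][-1] / a
                if (best_ratio is None or ratio < best_ratio
                        or (ratio == best_ratio and basis[i] < basis[leave_row])):
                    best_ratio, leave_row = ratio, i
        if leave_row is None:
            raise Unbounded(f"unbounded along variable {enter}")
        piv = T[leave_row][enter]
        T[leave_row] = [x / piv for x in T[leave_row]]
        for i in range(m):
            if i != leave_row and T[i][enter] != 0:
                f = T[i][enter]
                T[i] = [x - f * y for x, y in zip(T[i], T[leave_row])]
        f = obj[enter]
        if f != 0:
            obj = [x - f * y for x, y in zip(obj, T[leave_row])]
        basis[leave_row] = enter

    x = [Zero] * n
    for i, bi in enumerate(basis):
        if bi < n:
            x[bi] = T[i][-1]
    opt = sum(ci * xi for ci, xi in zip(cvec, x))
    return opt, x


def _solve_square(A: list[list[Fraction]], b: list[Fraction]) -> Optional[list[Fraction]]:
    """Gaussian elimination over Fractions; None if singular."""
    n = len(A)
    M = [row[:] + [b[i]] for i, row in enumerate(A)]
    for col in range(n):
        piv = next((r for r in range(col, n) if M[r][col] != 0), None)
        if piv is None:
            return None
        M[col], M[piv] = M[piv], M[col]
        pv = M[col][col]
        M[col] = [x / pv for x in M[col]]
        for r in range(n):
            if r != col and M[r][col] != 0:
                f = M[r][col]
                M[r] = [x - f * y for x, y in zip(M[r], M[col])]
    return [M[i][-1] for i in range(n)]


def enumerate_vertices_max(
    c: Sequence,
    A_eq: Sequence[Sequence],
    A_ub: Sequence[Sequence],
    b_ub: Sequence,
    ub: Sequence,
    max_dimension: int = 12,
) -> tuple[Fraction, list[list[Fraction]]]:
    """Brute-force the optimum over basic feasible solutions.

    Constraint pool: equalities (always active), inequality rows, finite
    upper bounds, and nonnegativity.  Every square active subset is solved
    exactly; feasible solutions are ranked by c'x.  Returns the optimum and
    all optimal vertices found.  Refuses systems with more than
    ``max_dimension`` variables — this is a test oracle, not a solver.
    """
    cvec = [to_fraction(x) for x in c]
    n = len(cvec)
    if n > max_dimension:
        raise ValueError(
            f"vertex enumeration limited to {max_dimension} variables, got {n}"
        )
    eq_rows = [([to_fraction(x) for x in row], Zero) for row in A_eq]
    cand_rows: list[tuple[list[Fraction], Fraction]] = []
    for row, bi in zip(A_ub, b_ub):
        cand_rows.append(([to_fraction(x) for x in row], to_fraction(bi)))
    for j, u in enumerate(ub):
        if u is not None and u != float("inf"):
            cand_rows.append(
                ([One if k == j else Zero for k in range(n)], to_fraction(u))
            )
    for j in range(n):  # nonnegativity x_j >= 0 as active constraint x_j = 0
        cand_rows.append(([-One if k == j else Zero for k in range(n)], Zero))

    need = n - len(eq_rows)
    if need < 0:
        need = 0
    best: Optional[Fraction] = None
    vertices: list[list[Fraction]] = []
    for combo in combinations(range(len(cand_rows)), need):
        A = [row for row, _ in eq_rows] + [cand_rows[i][0] for i in combo]
        b = [bi for _, bi in eq_rows] + [cand_rows[i][1] for i in combo]
        if len(A) != n:
            continue
        x = _solve_square(A, b)
        if x is None:
            continue
        if any(xi < 0 for xi in x):
            continue
        feasible = all(
            sum(a * xi for a, xi in zip(row, x)) <= bi for row, bi in cand_rows
        ) and all(
            sum(a * xi for a, xi in zip(row, x)) == bi for row, bi in eq_rows
        )
        if not feasible:
            continue
        val = sum(ci * xi for ci, xi in zip(cvec, x))
        if best is None or val > best:
            best, vertices = val, [x]
        elif val == best and x not in vertices:
            vertices.append(x)
    if best is None:
        raise ValueError("no feasible vertex found")
    return best, vertices
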