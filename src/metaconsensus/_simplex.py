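"""Exact linear programming over rationals.

A small two-phase primal simplex on :class:`fractions.Fraction` tableaus with
Bland's anti-cycling rule.  Intended for the small feasibility and
maximization problems arising in stoichiometric-consistency validation, where
exact rational certificates (mass vectors, leakage-mode combinations) are
wanted; it is not a general-purpose LP solver.

Problems are given in standard computational form::

    minimize    c^T x
    subject to  A x = b,  x >= 0
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


def _pivot(T: list[list[Fraction]], basis: list[int], row: int, col: int) -> None:
    piv = T[row][col]
    T[row] = [v / piv for v in T[row]]
    for i, r in enumerate(T):
        if i != row and r[col] != 0:
            factor = r[col]
            T[i] = [a - factor * b for a, b in zip(r, T[row])]
    basis[row] = col


def _simplex_iterate(
    T: list[list[Fraction]], basis: list[int], costs: list[Fraction]
) -> str:
    """Run simplex to optimality on a feasible canonical tableau (in place)."""
    m = len(T)
    ncols = len(T[0]) - 1
    while True:
        cb = [costs[b] for b in basis]
        entering = -1
        for j in range(ncols):
            rj = costs[j] - sum(cb[i] * T[i][j] for i in range(m))
            if rj < 0:
                entering = j  # Bland: first improving index
                break
        if entering == -1:
            return OPTIMAL
        leaving, best = -1, None
        for i in range(m):
            if T[i][entering] > 0:
                ratio = T[i][-1] / T[i][entering]
                if best is None or ratio < best or (
                    ratio == best and basis[i] < basis[leaving]
                ):
                    best, leaving = ratio, i
        if leaving == -1:
            return UNBOUNDED
        _pivot(T, basis, leaving, entering)


def solve_lp(
    A: Sequence[Sequence[Fraction]],
    b: Sequence[Fraction],
    c: Sequence[Fraction],
    maximize: bool = False,
) -> tuple[str, list[Fraction] | None, Fraction | None]:
    """Solve min (or max) c^T x s.t. A x = b, x >= 0 exactly.

    Returns ``(status, x, objective)``; ``x`` and ``objective`` are ``None``
    unless the status is ``optimal``.
    """
    m, n = len(A), len(c)
    A = [[Fraction(v) for v in row] for row in A]
    b = [Fraction(v) for v in b]
    obj = [-Fraction(v) for v in c] if maximize else [Fraction(v) for v in c]
    for i in range(m):
        if b[i] < 0:
            A[i] = [-v for v in A[i]]
            b[i] = -b[i]

    # phase 1: artificial variable per row
    T = [A[i] + [Fraction(int(i == j)) for j in range(m)] + [b[i]] for i in range(m)]
    basis = [n + i for i in range(m)]
    phase1_costs = [Fraction(0)] * n + [Fraction(1)] * m
    status = _simplex_iterate(T, basis, phase1_costs)
    assert status == OPTIMAL  # phase 1 is bounded below by 0
    infeas = sum(T[i][-1] for i in range(m) if basis[i] >= n)
    if infeas > 0:
        return INFEASIBLE, None, None

    # drive remaining zero-level artificials out of the basis
    drop_rows: list[int] = []
    for i in range(m):
        if basis[i] >= n:
            piv_col = next((j for j in range(n) if T[i][j] != 0), None)
            if piv_col is None:
                drop_rows.append(i)  # redundant constraint
            else:
                _pivot(T, basis, i, piv_col)
    if drop_rows:
        T = [r for i, r in enumerate(T) if i not in drop_rows]
        basis = [bv for i, bv in enumerate(basis) if i not in drop_rows]
    if not T:
        # every constraint was redundant: minimize over the bare orthant
        if any(v < 0 for v in obj):
            return UNBOUNDED, None, None
        return OPTIMAL, [Fraction(0)] * n, Fraction(0)

    # phase 2: strip artificial columns
    T = [row[:n] + [row[-1]] for row in T]
    status = _simplex_iterate(T, basis, obj)
    if status != OPTIMAL:
        return UNBOUNDED, None, None
    x = [Fraction(0)] * n
    for i, bv in enumerate(basis):
        if bv < n:
            x[bv] = T[i][-1]
    val = sum(Fraction(ci) * xi for ci, xi in zip(c, x))
    return OPTIMAL, x, val


def feasible(
    A: Sequence[Sequence[Fraction]],
    b: Sequence[Fraction],
    nvars: int,
) -> list[Fraction] | None:
    """Return some x >= 0 with A x = b, or None if none exists."""
    status, x, _ = solve_lp(A, b, [Fraction(0)] * nvars)
    return x if status == OPTIMAL else None
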