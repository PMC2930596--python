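"""Stoichiometric-consistency validation.

A reaction network is stoichiometrically consistent when every metabolite can
be assigned a strictly positive molecular mass that every reaction conserves.
Inconsistency — typically caused by generic compound classes, wrong
coefficients or variable-length polymers — shows up in the left null-space of
the stoichiometry matrix N:

* a network is consistent iff some vector v ≥ 1 satisfies vᵀN = 0;
* a metabolite is *non-conserved* when every non-negative conservation vector
  assigns it zero mass;
* an *elementary leakage mode* is a support-minimal combination y of reaction
  columns with N·y ≥ 0 and N·y ≠ 0 — it creates mass from nothing, and its
  net stoichiometry has an empty substrate side (the mirrored mass-destroying
  combination is obtained by negation);
* the *minimal inconsistent net stoichiometries* of a non-conserved
  metabolite are those one-sided nets that produce it.

Small instances are solved with an exact rational simplex so that mass
vectors and modes are exact certificates; larger instances fall back to
floating-point linear programming.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

from ._simplex import OPTIMAL, solve_lp
from .model_io import Reconstruction

log = logging.getLogger(__name__)

RATIONAL_METABOLITE_LIMIT = 20
FLOAT_TOL = 1e-9
DEFAULT_MODE_REACTION_CAP = 16

# names that identify molecular hydrogen, which inherits an unavoidable
# imbalance from the proton-neglect policy and is therefore flagged
H2_NAMES = frozenset({"h2", "hydrogen", "molecular hydrogen", "dihydrogen"})


@dataclass
class StoichMatrix:
    """Metabolite×reaction coefficient matrix with exact rational entries.

    Coefficients are net: products minus substrates, so substrates are
    negative.  Proton rows are excluded upstream by the integration engine's
    proton policy.
    """

    metabolites: list[str]
    reactions: list[str]
    coefficients: list[list[Fraction]]  # rows = metabolites

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.metabolites), len(self.reactions)

    def column(self, j: int) -> list[Fraction]:
        return [row[j] for row in self.coefficients]


@dataclass
class ConsistencyReport:
    consistent: bool
    mass_vector: dict[str, Fraction | float] | None
    non_conserved: set[str]
    inconsistent_net_stoichiometries: dict[str, list[dict]] = field(default_factory=dict)
    leakage_modes: list[dict[str, int]] = field(default_factory=list)
    flagged: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "consistent": self.consistent,
            "mass_vector": (
                None
                if self.mass_vector is None
                else {k: str(v) for k, v in sorted(self.mass_vector.items())}
            ),
            "non_conserved": sorted(self.non_conserved),
            "inconsistent_net_stoichiometries": {
                met: [
                    {
                        "combination": combo["combination"],
                        "net": {k: str(v) for k, v in combo["net"].items()},
                    }
                    for combo in combos
                ]
                for met, combos in self.inconsistent_net_stoichiometries.items()
            },
            "leakage_modes": self.leakage_modes,
            "flagged": self.flagged,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_text(self) -> str:
        lines = [f"stoichiometric consistency: {'PASS' if self.consistent else 'FAIL'}"]
        if self.non_conserved:
            lines.append("non-conserved metabolites: " + ", ".join(sorted(self.non_conserved)))
        for mode in self.leakage_modes:
            terms = " ".join(f"{'+' if v > 0 else ''}{v}*{r}" for r, v in mode.items())
            lines.append(f"leakage mode: {terms}")
        for met, combos in self.inconsistent_net_stoichiometries.items():
            for combo in combos:
                net = " + ".join(f"{v} {k}" for k, v in combo["net"].items())
                lines.append(f"minimal inconsistent net stoichiometry ({met}): Ø ↔ {net}")
        for name, why in self.flagged.items():
            lines.append(f"flagged: {name} ({why})")
        return "\n".join(lines) + "\n"


def build_matrix(
    recon: Reconstruction, exclude: frozenset[str] | set[str] = frozenset()
) -> StoichMatrix:
    """Net coefficient matrix of a reconstruction.

    Metabolites participating in no reaction are omitted; metabolites listed
    in ``exclude`` are left out of the matrix entirely.  A metabolite
    appearing with equal coefficients on both sides keeps its zero net entry
    (catalytic appearance, warned about); reactions whose net column is
    all-zero are dropped with a warning since they constrain nothing.
    """
    recon.validate()
    nets: dict[str, dict[str, Fraction]] = {}
    for rid in sorted(recon.reactions):
        rxn = recon.reactions[rid]
        net: dict[str, Fraction] = {}
        for cid, coeff in rxn.substrates:
            net[cid] = net.get(cid, Fraction(0)) - coeff
        for cid, coeff in rxn.products:
            net[cid] = net.get(cid, Fraction(0)) + coeff
        for cid, v in net.items():
            if v == 0:
                log.warning("reaction %s: %s appears catalytically (zero net)", rid, cid)
        net = {cid: v for cid, v in net.items() if cid not in exclude}
        if all(v == 0 for v in net.values()) or not net:
            log.warning("reaction %s has an all-zero net column; dropped", rid)
            continue
        nets[rid] = net
    reactions = sorted(nets)
    metabolites = sorted({cid for net in nets.values() for cid in net})
    coefficients = [
        [nets[rid].get(cid, Fraction(0)) for rid in reactions] for cid in metabolites
    ]
    return StoichMatrix(metabolites=metabolites, reactions=reactions, coefficients=coefficients)


def _np_matrix(m: StoichMatrix):
    import numpy as np

    return np.array([[float(v) for v in row] for row in m.coefficients])


def check_consistency(
    m: StoichMatrix,
    rational_limit: int = RATIONAL_METABOLITE_LIMIT,
    force_exact: bool | None = None,
) -> tuple[bool, dict[str, Fraction | float] | None]:
    """Decide consistency and return a witness mass vector if one exists.

    The witness satisfies vᵀN = 0 with every component ≥ 1.  Instances with
    at most ``rational_limit`` metabolites are solved exactly over the
    rationals; larger ones with floating-point LP (feasibility tolerance
    ~1e-9).  ``force_exact`` overrides the automatic path choice.
    """
    nm, nr = m.shape
    if nm == 0:
        return True, {}
    exact = nm <= rational_limit if force_exact is None else force_exact
    if exact:
        # v = 1 + u, u >= 0:  N^T u = -N^T 1
        A = [[m.coefficients[i][j] for i in range(nm)] for j in range(nr)]
        b = [-sum(m.coefficients[i][j] for i in range(nm)) for j in range(nr)]
        status, u, _ = solve_lp(A, b, [Fraction(0)] * nm)
        if status != OPTIMAL:
            return False, None
        return True, {
            met: 1 + u[i] for i, met in enumerate(m.metabolites)
        }
    from scipy.optimize import linprog

    N = _np_matrix(m)
    res = linprog(
        c=[0.0] * nm,
        A_eq=N.T,
        b_eq=[0.0] * nr,
        bounds=[(1.0, None)] * nm,
        method="highs",
    )
    if not res.success:
        return False, None
    return True, {met: float(res.x[i]) for i, met in enumerate(m.metabolites)}


def non_conserved_metabolites(
    m: StoichMatrix,
    rational_limit: int = RATIONAL_METABOLITE_LIMIT,
    force_exact: bool | None = None,
) -> set[str]:
    """Metabolites assigned zero by every non-negative conservation vector.

    For each metabolite i the maximum of vᵢ over {v : 0 ≤ v ≤ 1, vᵀN = 0}
    is computed; an optimum of zero certifies non-conservation.
    """
    nm, nr = m.shape
    exact = nm <= rational_limit if force_exact is None else force_exact
    out: set[str] = set()
    if exact:
        # variables: v (nm) then slack s (nm); rows: N^T v = 0 and v + s = 1
        A: list[list[Fraction]] = []
        b: list[Fraction] = []
        for j in range(nr):
            A.append(
                [m.coefficients[i][j] for i in range(nm)] + [Fraction(0)] * nm
            )
            b.append(Fraction(0))
        for i in range(nm):
            row = [Fraction(0)] * (2 * nm)
            row[i] = Fraction(1)
            row[nm + i] = Fraction(1)
            A.append(row)
            b.append(Fraction(1))
        for i, met in enumerate(m.metabolites):
            c = [Fraction(0)] * (2 * nm)
            c[i] = Fraction(1)
            status, _, val = solve_lp(A, b, c, maximize=True)
            assert status == OPTIMAL  # the feasible region contains 0 and is bounded
            if val == 0:
                out.add(met)
        return out
    from scipy.optimize import linprog

    N = _np_matrix(m)
    for i, met in enumerate(m.metabolites):
        c = [0.0] * nm
        c[i] = -1.0
        res = linprog(
            c=c, A_eq=N.T, b_eq=[0.0] * nr, bounds=[(0.0, 1.0)] * nm, method="highs"
        )
        if res.success and -res.fun <= FLOAT_TOL:
            out.add(met)
    return out


def _canonical_integer(y: Sequence[Fraction]) -> list[int]:
    """Scale a rational vector by a positive factor to coprime integers."""
    denom_lcm = 1
    for v in y:
        denom_lcm = denom_lcm * v.denominator // math.gcd(denom_lcm, v.denominator)
    ints = [int(v * denom_lcm) for v in y]
    g = 0
    for v in ints:
        g = math.gcd(g, abs(v))
    return [v // g for v in ints] if g else ints


def _support_minimal_combinations(
    m: StoichMatrix,
    normalize_row: int | None,
    max_reactions: int,
) -> list[tuple[dict[str, int], dict[str, Fraction]]]:
    """Enumerate support-minimal y with N·y ≥ 0 and a positivity normalization.

    ``normalize_row`` selects (N·y)ᵢ = 1 for that metabolite row; ``None``
    normalizes the total Σᵢ(N·y)ᵢ = 1 (any one-sided net).  Supports are
    enumerated in increasing size; supersets of found supports are skipped.
    """
    nm, nr = m.shape
    if nr > max_reactions:
        raise ValueError(
            f"{nr} reactions exceeds the enumeration cap ({max_reactions}); "
            "use the per-metabolite minimal-net-stoichiometry analysis instead"
        )
    found_supports: list[frozenset[int]] = []
    results: list[tuple[dict[str, int], dict[str, Fraction]]] = []
    for size in range(1, nr + 1):
        for subset in combinations(range(nr), size):
            sset = frozenset(subset)
            if any(fs <= sset for fs in found_supports):
                continue
            # variables: p_j, q_j for j in subset (y_j = p_j - q_j), slack s_i
            k = len(subset)
            nvars = 2 * k + nm
            A: list[list[Fraction]] = []
            b: list[Fraction] = []
            for i in range(nm):
                row = [Fraction(0)] * nvars
                for jj, j in enumerate(subset):
                    row[jj] = m.coefficients[i][j]
                    row[k + jj] = -m.coefficients[i][j]
                row[2 * k + i] = Fraction(-1)
                A.append(row)
                b.append(Fraction(0))
            norm = [Fraction(0)] * nvars
            rows = range(nm) if normalize_row is None else (normalize_row,)
            for i in rows:
                for jj, j in enumerate(subset):
                    norm[jj] += m.coefficients[i][j]
                    norm[k + jj] -= m.coefficients[i][j]
            A.append(norm)
            b.append(Fraction(1))
            status, x, _ = solve_lp(A, b, [Fraction(0)] * nvars)
            if status != OPTIMAL:
                continue
            y = [x[jj] - x[k + jj] for jj in range(k)]
            support = frozenset(j for jj, j in enumerate(subset) if y[jj] != 0)
            if support != sset:
                continue  # a smaller support is feasible and was found earlier
            ints = _canonical_integer(y)
            combo = {m.reactions[j]: ints[jj] for jj, j in enumerate(subset)}
            net_full = [
                sum(m.coefficients[i][j] * y[jj] for jj, j in enumerate(subset))
                for i in range(nm)
            ]
            scale = Fraction(ints[0], y[0].numerator) * y[0].denominator if y[0] else 1
            net = {
                m.metabolites[i]: net_full[i] * scale
                for i in range(nm)
                if net_full[i] != 0
            }
            found_supports.append(sset)
            results.append((combo, net))
    return results


def elementary_leakage_modes(
    m: StoichMatrix, max_reactions: int = DEFAULT_MODE_REACTION_CAP
) -> list[dict[str, int]]:
    """All support-minimal mass-creating reaction combinations.

    Returned as coprime-integer coefficient maps (reaction id → integer),
    canonical up to the positive scaling the cone admits; empty iff the
    network is consistent.
    """
    return [combo for combo, _ in _support_minimal_combinations(m, None, max_reactions)]


def inconsistent_net_stoichiometries(
    m: StoichMatrix,
    metabolite: str,
    max_reactions: int = DEFAULT_MODE_REACTION_CAP,
) -> list[dict]:
    """Minimal inconsistent net stoichiometries producing one metabolite.

    Each entry is ``{"combination": {reaction: int}, "net": {metabolite:
    Fraction}}`` with an empty substrate side (net production); the mirrored
    net-consumption case is the negation.  The metabolite must be
    non-conserved.
    """
    if metabolite not in non_conserved_metabolites(m):
        raise ValueError(f"{metabolite!r} is not a non-conserved metabolite")
    i = m.metabolites.index(metabolite)
    return [
        {"combination": combo, "net": net}
        for combo, net in _support_minimal_combinations(m, i, max_reactions)
    ]


def validate(
    recon: Reconstruction,
    exclude: frozenset[str] | set[str] = frozenset(),
    mode_cap: int = DEFAULT_MODE_REACTION_CAP,
) -> ConsistencyReport:
    """Full consistency report for a reconstruction.

    Molecular hydrogen is never excluded by default but is flagged in the
    report when present, since the proton-neglect policy makes its balance
    unattainable; pass its local id in ``exclude`` to drop it.
    """
    matrix = build_matrix(recon, exclude=frozenset(exclude))
    consistent, mass = check_consistency(matrix)
    non_conserved = set() if consistent else non_conserved_metabolites(matrix)
    modes: list[dict[str, int]] = []
    nets: dict[str, list[dict]] = {}
    if not consistent and len(matrix.reactions) <= mode_cap:
        modes = elementary_leakage_modes(matrix, mode_cap)
        for met in sorted(non_conserved):
            nets[met] = inconsistent_net_stoichiometries(matrix, met, mode_cap)
    flagged: dict[str, str] = {}
    for lid, comp in recon.compounds.items():
        names = {n.lower() for n in (comp.name_in_A, comp.name_in_B) if n}
        if names & H2_NAMES:
            flagged[lid] = (
                "molecular hydrogen: imbalance expected under the proton-neglect policy"
            )
    return ConsistencyReport(
        consistent=consistent,
        mass_vector=mass,
        non_conserved=non_conserved,
        inconsistent_net_stoichiometries=nets,
        leakage_modes=modes,
        flagged=flagged,
    )
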