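"""Shared builders and independent oracles used across the test modules.

The oracles here are deliberately written from first principles (BFS path
counting, brute-force subset enumeration, direct LP formulations through
scipy) so that they share no code path with the package implementations they
check.
"""

from __future__ import annotations

import itertools
from collections import deque
from fractions import Fraction

from metaconsensus.model_io import (
    MatchedCompound,
    MatchedReaction,
    Reconstruction,
)
from metaconsensus.stoich_check import StoichMatrix

FLOAT_TOL = 1e-7


def make_recon(reactions: dict, tier: str = "core") -> Reconstruction:
    """Build a Reconstruction from {rid: (substrate_list, product_list)}.

    Sides are lists of (compound_id, coefficient) with int/Fraction
    coefficients.
    """
    compound_ids = {
        cid
        for subs, prods in reactions.values()
        for cid, _ in list(subs) + list(prods)
    }
    compounds = {
        cid: MatchedCompound(local_id=cid, id_in_A=cid, name_in_A=cid)
        for cid in sorted(compound_ids)
    }
    rxns = {
        rid: MatchedReaction(
            local_id=rid,
            id_in_A=rid,
            substrates=tuple((cid, Fraction(k)) for cid, k in subs),
            products=tuple((cid, Fraction(k)) for cid, k in prods),
        )
        for rid, (subs, prods) in reactions.items()
    }
    return Reconstruction(tier=tier, compounds=compounds, reactions=rxns)


def toy_two_reaction_recon() -> Reconstruction:
    """R1: A ↔ B and R2: A ↔ B + C (the classic inconsistent pair)."""
    return make_recon(
        {
            "R1": ([("A", 1)], [("B", 1)]),
            "R2": ([("A", 1)], [("B", 1), ("C", 1)]),
        }
    )


def matrix_from_rows(rows: list[list[int]]) -> StoichMatrix:
    """StoichMatrix from integer rows (metabolites × reactions)."""
    nm = len(rows)
    nr = len(rows[0]) if rows else 0
    return StoichMatrix(
        metabolites=[f"M{i}" for i in range(nm)],
        reactions=[f"R{j}" for j in range(nr)],
        coefficients=[[Fraction(v) for v in row] for row in rows],
    )


# ---------------------------------------------------------------------------
# stoichiometry oracles (scipy-based, independent of the exact simplex)
# ---------------------------------------------------------------------------


def oracle_consistent(rows: list[list[int]]) -> bool:
    """∃ v ≥ 1 with vᵀN = 0, decided by scipy linprog."""
    from scipy.optimize import linprog

    nm = len(rows)
    nr = len(rows[0]) if rows else 0
    if nm == 0 or nr == 0:
        return True
    res = linprog(
        c=[0.0] * nm,
        A_eq=[[rows[i][j] for i in range(nm)] for j in range(nr)],
        b_eq=[0.0] * nr,
        bounds=[(1.0, None)] * nm,
        method="highs",
    )
    return bool(res.success)


def oracle_non_conserved(rows: list[list[int]]) -> set[str]:
    """Metabolites with max vᵢ = 0 over {0 ≤ v ≤ 1, vᵀN = 0}."""
    from scipy.optimize import linprog

    nm = len(rows)
    nr = len(rows[0]) if rows else 0
    out: set[str] = set()
    A_eq = [[rows[i][j] for i in range(nm)] for j in range(nr)]
    for i in range(nm):
        c = [0.0] * nm
        c[i] = -1.0
        res = linprog(
            c=c,
            A_eq=A_eq if nr else None,
            b_eq=[0.0] * nr if nr else None,
            bounds=[(0.0, 1.0)] * nm,
            method="highs",
        )
        assert res.success
        if -res.fun <= FLOAT_TOL:
            out.add(f"M{i}")
    return out


def _subset_feasible(rows, subset, signs_free=True):
    """Some y supported exactly on `subset` with N·y ≥ 0, N·y ≠ 0 (scipy).

    y is split into y = p − q with p, q ≥ 0; support entries get
    |y|-normalization |p_j + q_j| ≥ 1 handled by maximizing Σ(N·y) under a
    box, then checking positivity.
    """
    from scipy.optimize import linprog

    nm = len(rows)
    nr = len(rows[0])
    subset = list(subset)
    k = len(subset)
    # variables: p_0..p_{k-1}, q_0..q_{k-1}; maximize sum over metabolites of
    # (N y)_i subject to (N y)_i >= 0, |y_j| <= 1.  Positive optimum ⇒ a
    # mass-creating combination exists on (a subset of) this support.
    c = [0.0] * (2 * k)
    for idx, j in enumerate(subset):
        col = sum(rows[i][j] for i in range(nm))
        c[idx] -= col  # maximize ⇒ minimize negative
        c[k + idx] += col
    A_ub = []
    b_ub = []
    for i in range(nm):  # -(N y)_i <= 0
        row = [0.0] * (2 * k)
        for idx, j in enumerate(subset):
            row[idx] -= rows[i][j]
            row[k + idx] += rows[i][j]
        A_ub.append(row)
        b_ub.append(0.0)
    res = linprog(
        c=c,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=[(0.0, 1.0)] * (2 * k),
        method="highs",
    )
    assert res.success
    return -res.fun > FLOAT_TOL


def oracle_leakage_supports(rows: list[list[int]], cap: int = 8) -> set[frozenset[int]]:
    """Support-minimal reaction subsets admitting a mass-creating combination."""
    nr = len(rows[0]) if rows else 0
    found: set[frozenset[int]] = set()
    for size in range(1, min(nr, cap) + 1):
        for subset in itertools.combinations(range(nr), size):
            s = frozenset(subset)
            if any(f <= s for f in found):
                continue
            if _subset_feasible(rows, subset):
                found.add(s)
    return found


# ---------------------------------------------------------------------------
# graph oracles (pure-python BFS, independent of networkx)
# ---------------------------------------------------------------------------


def bfs_paths(adj: dict, source):
    """Distances and shortest-path counts from source."""
    dist = {source: 0}
    sigma = {source: 1}
    preds: dict = {source: []}
    q = deque([source])
    order = []
    while q:
        u = q.popleft()
        order.append(u)
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                preds[v] = []
                q.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
                preds[v].append(u)
    return dist, sigma, preds, order


def oracle_betweenness(adj: dict) -> dict:
    """Pair-normalized betweenness per connected component (accumulation-free:
    explicit per-pair dependency via path counting through each node)."""
    nodes = sorted(adj)
    comp_of = {}
    for n in nodes:
        if n in comp_of:
            continue
        dist, _, _, order = bfs_paths(adj, n)
        for m in dist:
            comp_of[m] = n
    bet = {n: 0.0 for n in nodes}
    # sigma maps per source
    all_dist = {}
    all_sigma = {}
    for s in nodes:
        d, sg, _, _ = bfs_paths(adj, s)
        all_dist[s] = d
        all_sigma[s] = sg
    for s, t in itertools.combinations(nodes, 2):
        if comp_of[s] != comp_of[t] or t not in all_dist[s]:
            continue
        dst = all_dist[s][t]
        sigma_st = all_sigma[s][t]
        for v in nodes:
            if v in (s, t) or comp_of[v] != comp_of[s]:
                continue
            if v in all_dist[s] and t in all_dist[v]:
                if all_dist[s][v] + all_dist[v][t] == dst:
                    bet[v] += all_sigma[s][v] * all_sigma[v][t] / sigma_st
    comp_sizes = {}
    for n in nodes:
        comp_sizes[comp_of[n]] = comp_sizes.get(comp_of[n], 0) + 1
    out = {}
    for n in nodes:
        size = comp_sizes[comp_of[n]]
        out[n] = 2.0 * bet[n] / ((size - 1) * (size - 2)) if size > 2 else 0.0
    return out


def oracle_closeness(adj: dict) -> dict:
    out = {}
    for n in sorted(adj):
        dist, _, _, _ = bfs_paths(adj, n)
        total = sum(dist.values())
        out[n] = (len(dist) - 1) / total if total else 0.0
    return out


def oracle_clustering(adj: dict) -> dict:
    out = {}
    for n in sorted(adj):
        neigh = [v for v in adj[n] if v != n]
        k = len(neigh)
        if k < 2:
            out[n] = 0.0
            continue
        links = sum(
            1
            for a, b in itertools.combinations(neigh, 2)
            if b in adj[a]
        )
        out[n] = 2.0 * links / (k * (k - 1))
    return out


def random_adjacency(seed: int):
    """A random simple undirected graph on ≤12 string-labelled nodes."""
    import random

    rng = random.Random(seed)
    n = rng.randint(3, 12)
    nodes = [f"n{i:02d}" for i in range(n)]
    adj = {u: set() for u in nodes}
    for a, b in itertools.combinations(nodes, 2):
        if rng.random() < 0.3:
            adj[a].add(b)
            adj[b].add(a)
    return adj
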