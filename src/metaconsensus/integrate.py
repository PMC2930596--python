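"""Iterative cross-database matching and tier assignment.

The engine starts from unambiguous seed matches (cross-references and exact
shared synonyms), then repeatedly scans reaction pairs in which all compounds
are identified or exactly one is missing.  Fully identified reaction pairs
with compatible enzymes become matched reactions; the unknown compounds of
one-missing pairs become candidates, accepted when the catalysing enzyme,
the name-similarity score and the structure (or hydrogen-blind formula) all
agree.  Candidates passing some but not all criteria are queued for manual
review, and externally resolved review decisions can be injected between
iterations.  The loop stops at a fixpoint.

Matched content forms the core network; one-database reactions with a full
substrate or product side anchored in core compounds form the intermediate
network; everything else lands in the complete network.  Free protons are
removed from reaction sides before any comparison and from all outputs,
because databases do not agree on protonation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Callable, Mapping, Sequence

from . import name_match, struct_match
from .model_io import (
    CompoundRecord,
    MatchedCompound,
    MatchedReaction,
    ReactionRecord,
    Reconstruction,
    make_local_id,
)

log = logging.getLogger(__name__)

DEFAULT_PROTON_NAMES = frozenset({"h+", "proton", "hydron", "h(+)"})


@dataclass
class IntegrationConfig:
    """Tunable parameters of the integration pipeline."""

    name_threshold: float = name_match.DEFAULT_THRESHOLD
    tanimoto_threshold: float = struct_match.DEFAULT_SIM_THRESHOLD
    negatives_per_positive: int = 1
    seed: int = 0
    proton_names: frozenset[str] = DEFAULT_PROTON_NAMES
    proton_ids: frozenset[str] = frozenset()
    max_iterations: int = 100

    @classmethod
    def from_file(cls, path: str | Path) -> "IntegrationConfig":
        """Parse a key=value config file (unknown keys rejected)."""
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in ("name_threshold", "tanimoto_threshold"):
                kwargs[key] = float(value)
            elif key in ("negatives_per_positive", "seed", "max_iterations"):
                kwargs[key] = int(value)
            elif key == "proton_allowlist":
                kwargs["proton_names"] = frozenset(
                    v.strip().lower() for v in value.split(",") if v.strip()
                )
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(**kwargs)


def is_proton(compound: CompoundRecord, config: IntegrationConfig) -> bool:
    """Free-proton species, recognized by name/id allowlist."""
    if compound.source_id in config.proton_ids:
        return True
    return any(n.strip().lower() in config.proton_names for n in compound.names)


def ec_is_full(ec: str) -> bool:
    parts = ec.split(".")
    return len(parts) == 4 and all(p.isdigit() for p in parts)


def ec_compatible(ea: str, eb: str) -> bool:
    """Wildcard-aware EC comparison ('2.7.1.-' is compatible with 2.7.1.40)."""
    pa = (ea.split(".") + ["-"] * 4)[:4]
    pb = (eb.split(".") + ["-"] * 4)[:4]
    return all(a == b for a, b in zip(pa, pb) if a != "-" and b != "-")


@dataclass(frozen=True)
class CompoundMatch:
    id_A: str
    id_B: str
    evidence: str
    name_probability: float | None = None
    structure_tier: str | None = None


@dataclass
class ReviewItem:
    """A candidate pair needing human attention, with its evidence summary."""

    kind: str  # ambiguous_seed | partial_candidate | ambiguous_candidate
    id_A: str
    id_B: str
    evidence: str


@dataclass
class MatchState:
    """Monotonically growing matching between the two databases."""

    compound_matches: list[CompoundMatch] = field(default_factory=list)
    reaction_matches: list[tuple[str, str]] = field(default_factory=list)
    review_queue: list[ReviewItem] = field(default_factory=list)
    iteration: int = 0
    history: list[dict] = field(default_factory=list)
    a2b: dict[str, str] = field(default_factory=dict)
    b2a: dict[str, str] = field(default_factory=dict)
    matched_rA: set[str] = field(default_factory=set)
    matched_rB: set[str] = field(default_factory=set)

    def add_compound_match(self, match: CompoundMatch) -> None:
        if match.id_A in self.a2b or match.id_B in self.b2a:
            raise ValueError(
                f"injectivity violated: {match.id_A}/{match.id_B} already matched"
            )
        self.compound_matches.append(match)
        self.a2b[match.id_A] = match.id_B
        self.b2a[match.id_B] = match.id_A

    def add_reaction_match(self, id_A: str, id_B: str) -> None:
        self.reaction_matches.append((id_A, id_B))
        self.matched_rA.add(id_A)
        self.matched_rB.add(id_B)


def _index(records: Sequence) -> dict[str, object]:
    return {r.source_id: r for r in records}


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------


def seed_matches(
    dbA: tuple[Sequence[CompoundRecord], Sequence[ReactionRecord]],
    dbB: tuple[Sequence[CompoundRecord], Sequence[ReactionRecord]],
    config: IntegrationConfig | None = None,
) -> MatchState:
    """Initial matching from cross-references and exact shared synonyms.

    A pair is seeded only when it is unambiguous in both directions; any
    compound claiming several partners is routed to the review queue instead.
    """
    config = config or IntegrationConfig()
    compounds_a, compounds_b = dbA[0], dbB[0]
    idx_a, idx_b = _index(compounds_a), _index(compounds_b)
    state = MatchState()

    def candidate_map_to_matches(
        cands: dict[str, set[str]], evidence: str
    ) -> None:
        reverse: dict[str, set[str]] = {}
        for a, bs in cands.items():
            for b in bs:
                reverse.setdefault(b, set()).add(a)
        for a in sorted(cands):
            bs = cands[a]
            if a in state.a2b:
                continue
            unique = {b for b in bs if b not in state.b2a}
            if len(unique) == 1:
                b = next(iter(unique))
                if len(reverse[b] - set(state.a2b)) == 1:
                    state.add_compound_match(CompoundMatch(a, b, evidence))
                    continue
            for b in sorted(bs):
                state.review_queue.append(
                    ReviewItem("ambiguous_seed", a, b, evidence)
                )

    # cross-reference seeds
    xref_cands: dict[str, set[str]] = {}
    shared: dict[tuple[str, str], tuple[set[str], set[str]]] = {}
    for a in compounds_a:
        for ns, val in a.xrefs.items():
            if val in idx_b:
                xref_cands.setdefault(a.source_id, set()).add(val)
            shared.setdefault((ns, val), (set(), set()))[0].add(a.source_id)
    for b in compounds_b:
        for ns, val in b.xrefs.items():
            if val in idx_a:
                xref_cands.setdefault(val, set()).add(b.source_id)
            shared.setdefault((ns, val), (set(), set()))[1].add(b.source_id)
    for (ns, val), (aset, bset) in shared.items():
        for a in aset:
            for b in bset:
                xref_cands.setdefault(a, set()).add(b)
    candidate_map_to_matches(xref_cands, "seed_xref")

    # exact-synonym seeds among the still-unmatched
    syn_a: dict[str, set[str]] = {}
    syn_b: dict[str, set[str]] = {}
    for a in compounds_a:
        if a.source_id in state.a2b or a.is_generic_class or is_proton(a, config):
            continue
        for n in a.names:
            nn = name_match.normalize_name(n)
            if nn:
                syn_a.setdefault(nn, set()).add(a.source_id)
    for b in compounds_b:
        if b.source_id in state.b2a or b.is_generic_class or is_proton(b, config):
            continue
        for n in b.names:
            nn = name_match.normalize_name(n)
            if nn:
                syn_b.setdefault(nn, set()).add(b.source_id)
    syn_cands: dict[str, set[str]] = {}
    for nn, aset in syn_a.items():
        for a in aset:
            for b in syn_b.get(nn, ()):
                syn_cands.setdefault(a, set()).add(b)
    candidate_map_to_matches(syn_cands, "exact_synonym")

    state.history.append(
        {"iteration": 0, "compounds_added": len(state.compound_matches), "reactions_added": 0}
    )
    return state


# ---------------------------------------------------------------------------
# reaction comparison
# ---------------------------------------------------------------------------


def _dropped_sides(
    rxn: ReactionRecord,
    idx: Mapping[str, CompoundRecord],
    config: IntegrationConfig,
) -> tuple[dict[str, Fraction], dict[str, Fraction]]:
    """Reaction sides as id→coefficient maps with free protons removed."""

    def side(entries) -> dict[str, Fraction]:
        return {
            cid: coeff
            for cid, coeff in entries
            if not is_proton(idx[cid], config)
        }

    return side(rxn.substrates), side(rxn.products)


FULL_MATCH = "full_match"
ONE_UNKNOWN = "one_unknown"
INCOMPATIBLE = "incompatible"


def _match_side(
    sa: Mapping[str, Fraction],
    sb: Mapping[str, Fraction],
    a2b: Mapping[str, str],
) -> tuple[str, tuple[str, str] | None] | None:
    """Match one pair of sides through the current compound matching.

    Returns ("full", None), ("one", (idA, idB)) or None on failure.
    """
    translated: dict[str, Fraction] = {}
    unknown_a: list[tuple[str, Fraction]] = []
    for cid, coeff in sa.items():
        partner = a2b.get(cid)
        if partner is None:
            unknown_a.append((cid, coeff))
        else:
            translated[partner] = coeff
    for bid, coeff in translated.items():
        if sb.get(bid) != coeff:
            return None
    remaining = {bid: c for bid, c in sb.items() if bid not in translated}
    if not unknown_a and not remaining:
        return ("full", None)
    if len(unknown_a) == 1 and len(remaining) == 1:
        (aid, ac), (bid, bc) = unknown_a[0], next(iter(remaining.items()))
        if ac == bc:
            return ("one", (aid, bid))
    return None


def _ec_sets_compatible(rA: ReactionRecord, rB: ReactionRecord) -> bool:
    # exact intersection, with either-side-empty treated as compatible
    if not rA.ec_numbers or not rB.ec_numbers:
        return True
    return bool(rA.ec_numbers & rB.ec_numbers)


def compare_reactions(
    rA: ReactionRecord,
    rB: ReactionRecord,
    state: MatchState,
    idx_a: Mapping[str, CompoundRecord],
    idx_b: Mapping[str, CompoundRecord],
    config: IntegrationConfig | None = None,
) -> tuple[str, tuple[str, str] | None]:
    """Compare two reactions through the current matching.

    Free protons are dropped from both sides first.  Returns
    ``(FULL_MATCH, None)`` when the sides map one-to-one with equal
    coefficients and the EC sets are compatible; ``(ONE_UNKNOWN, (idA,
    idB))`` when exactly one participant pair is unmatched; otherwise
    ``(INCOMPATIBLE, None)``.  Directionality is ignored: both orientations
    are tried and the best one wins.
    """
    config = config or IntegrationConfig()
    sa, pa = _dropped_sides(rA, idx_a, config)
    sb, pb = _dropped_sides(rB, idx_b, config)
    if not (sa and pa and sb and pb):
        return (INCOMPATIBLE, None)
    best: tuple[str, tuple[str, str] | None] = (INCOMPATIBLE, None)
    for left, right in ((sb, pb), (pb, sb)):
        m1 = _match_side(sa, left, state.a2b)
        m2 = _match_side(pa, right, state.a2b)
        if m1 is None or m2 is None:
            continue
        unknowns = [m for m in (m1, m2) if m[0] == "one"]
        if not unknowns:
            if _ec_sets_compatible(rA, rB):
                return (FULL_MATCH, None)
        elif len(unknowns) == 1 and best[0] != FULL_MATCH:
            best = (ONE_UNKNOWN, unknowns[0][1])
    return best


# ---------------------------------------------------------------------------
# candidate acceptance
# ---------------------------------------------------------------------------

_PASS, _PARTIAL, _FAIL = 2, 1, 0

ACCEPT = "accept"
REVIEW = "review"
REJECT = "reject"


def _ec_criterion(rA: ReactionRecord, rB: ReactionRecord) -> int:
    full = {e for e in rA.ec_numbers if ec_is_full(e)} & {
        e for e in rB.ec_numbers if ec_is_full(e)
    }
    if full:
        return _PASS
    if any(ec_compatible(ea, eb) for ea in rA.ec_numbers for eb in rB.ec_numbers):
        return _PARTIAL
    return _FAIL


def _name_criterion(
    ca: CompoundRecord,
    cb: CompoundRecord,
    name_model: name_match.NameModel,
    threshold: float,
) -> tuple[int, float]:
    best = 0.0
    for na in ca.names:
        for nb in cb.names:
            try:
                best = max(best, name_model.score(na, nb))
            except ValueError:
                continue
    if best >= threshold:
        return _PASS, best
    if best >= name_match.REVIEW_FLOOR:
        return _PARTIAL, best
    return _FAIL, best


def _structure_criterion(
    ca: CompoundRecord,
    cb: CompoundRecord,
    tanimoto_threshold: float,
    forms_cache: dict[str, struct_match.StructureForms],
) -> tuple[int, str]:
    if ca.is_generic_class or cb.is_generic_class:
        return _FAIL, "none"
    if ca.smiles and cb.smiles:
        for smi in (ca.smiles, cb.smiles):
            if smi not in forms_cache:
                forms_cache[smi] = struct_match.make_forms(smi)
        result = struct_match.match_structures(
            forms_cache[ca.smiles], forms_cache[cb.smiles], tanimoto_threshold
        )
        if result.tier == "exact":
            return _PASS, result.tier
        if result.tier in ("stereo", "tautomer", "charge", "similar"):
            return _PARTIAL, result.tier
        return _FAIL, result.tier
    if ca.formula and cb.formula:
        if struct_match.formula_equal_ignoring_h(ca.formula, cb.formula):
            return _PASS, "formula_only"
        return _FAIL, "none"
    return _PARTIAL, "none"  # no structural information at all: needs a human


def accept_candidate(
    pair: tuple[str, str],
    rA: ReactionRecord,
    rB: ReactionRecord,
    idx_a: Mapping[str, CompoundRecord],
    idx_b: Mapping[str, CompoundRecord],
    name_model: name_match.NameModel,
    config: IntegrationConfig | None = None,
    forms_cache: dict[str, struct_match.StructureForms] | None = None,
) -> tuple[str, CompoundMatch | None, str]:
    """Apply the acceptance rule to an unknown-compound candidate pair.

    Accept requires all three criteria: a shared full-precision EC, a name
    score at or above the threshold, and an exact structure match (or, when
    no structure is available, formulas equal ignoring hydrogen).  Pairs
    passing some but not all criteria go to review; pairs with no positive
    signal are rejected.
    """
    config = config or IntegrationConfig()
    forms_cache = {} if forms_cache is None else forms_cache
    ca, cb = idx_a[pair[0]], idx_b[pair[1]]
    ec = _ec_criterion(rA, rB)
    name, prob = _name_criterion(ca, cb, name_model, config.name_threshold)
    struct, tier = _structure_criterion(
        ca, cb, config.tanimoto_threshold, forms_cache
    )
    summary = f"ec={ec} name={name}({prob:.3f}) structure={struct}({tier})"
    if ec == _PASS and name == _PASS and struct == _PASS:
        match = CompoundMatch(
            pair[0],
            pair[1],
            evidence="classifier_plus_structure",
            name_probability=prob,
            structure_tier=tier,
        )
        return ACCEPT, match, summary
    if ec == _FAIL and name == _FAIL and struct == _FAIL:
        return REJECT, None, summary
    return REVIEW, None, summary


# ---------------------------------------------------------------------------
# fixpoint iteration
# ---------------------------------------------------------------------------


def iterate_to_fixpoint(
    dbA: tuple[Sequence[CompoundRecord], Sequence[ReactionRecord]],
    dbB: tuple[Sequence[CompoundRecord], Sequence[ReactionRecord]],
    name_model: name_match.NameModel,
    config: IntegrationConfig | None = None,
    state: MatchState | None = None,
    review_resolver: Callable[[list[ReviewItem]], list[tuple[str, str]]] | None = None,
) -> MatchState:
    """Run the matching loop until an iteration adds nothing.

    ``review_resolver`` may inject externally resolved review decisions
    (pairs to accept as manual matches) between iterations, mirroring the
    semi-automatic workflow; injected decisions conflicting with injectivity
    raise an error.
    """
    config = config or IntegrationConfig()
    idx_a, idx_b = _index(dbA[0]), _index(dbB[0])
    state = state if state is not None else seed_matches(dbA, dbB, config)
    forms_cache: dict[str, struct_match.StructureForms] = {}

    rxns_a = sorted(dbA[1], key=lambda r: r.source_id)
    rxns_b = sorted(dbB[1], key=lambda r: r.source_id)

    while state.iteration < config.max_iterations:
        state.iteration += 1
        compounds_before = len(state.compound_matches)
        reactions_before = len(state.reaction_matches)
        accept_votes: dict[tuple[str, str], tuple[CompoundMatch, str]] = {}
        new_reviews: list[ReviewItem] = []
        claimed_b: set[str] = set()
        for rA in rxns_a:
            if rA.source_id in state.matched_rA:
                continue
            for rB in rxns_b:
                if rB.source_id in state.matched_rB or rB.source_id in claimed_b:
                    continue
                verdict, payload = compare_reactions(rA, rB, state, idx_a, idx_b, config)
                if verdict == FULL_MATCH:
                    state.add_reaction_match(rA.source_id, rB.source_id)
                    claimed_b.add(rB.source_id)
                    break
                if verdict == ONE_UNKNOWN:
                    decision, match, summary = accept_candidate(
                        payload, rA, rB, idx_a, idx_b, name_model, config, forms_cache
                    )
                    if decision == ACCEPT:
                        accept_votes.setdefault(payload, (match, summary))
                    elif decision == REVIEW:
                        new_reviews.append(
                            ReviewItem("partial_candidate", payload[0], payload[1], summary)
                        )
        # apply accepted candidates, routing ambiguous ones to review
        by_a: dict[str, set[str]] = {}
        by_b: dict[str, set[str]] = {}
        for a, b in accept_votes:
            by_a.setdefault(a, set()).add(b)
            by_b.setdefault(b, set()).add(a)
        for (a, b), (match, summary) in sorted(accept_votes.items()):
            if a in state.a2b or b in state.b2a:
                continue
            if len(by_a[a]) > 1 or len(by_b[b]) > 1:
                new_reviews.append(ReviewItem("ambiguous_candidate", a, b, summary))
                continue
            state.add_compound_match(match)
        state.review_queue.extend(new_reviews)
        if review_resolver is not None:
            for a, b in review_resolver(state.review_queue):
                state.add_compound_match(CompoundMatch(a, b, evidence="manual"))
        added_c = len(state.compound_matches) - compounds_before
        added_r = len(state.reaction_matches) - reactions_before
        state.history.append(
            {"iteration": state.iteration, "compounds_added": added_c, "reactions_added": added_r}
        )
        log.info(
            "iteration %d: +%d compounds, +%d reactions", state.iteration, added_c, added_r
        )
        if added_c == 0 and added_r == 0:
            break
    return state


# ---------------------------------------------------------------------------
# tier assignment
# ---------------------------------------------------------------------------


@dataclass
class TierAssignment:
    core: Reconstruction
    intermediate: Reconstruction
    complete: Reconstruction

    def tier_of_reaction(self, source_db: str, source_id: str) -> str | None:
        """Innermost tier containing the given source reaction."""
        for tier_name in ("core", "intermediate", "complete"):
            recon = getattr(self, tier_name)
            for rxn in recon.reactions.values():
                sid = rxn.id_in_A if source_db == "A" else rxn.id_in_B
                if sid == source_id:
                    return tier_name
        return None


def assign_tiers(
    dbA: tuple[Sequence[CompoundRecord], Sequence[ReactionRecord]],
    dbB: tuple[Sequence[CompoundRecord], Sequence[ReactionRecord]],
    state: MatchState,
    config: IntegrationConfig | None = None,
) -> TierAssignment:
    """Build the three nested reconstructions from a fixpoint state.

    Local identifiers are assigned deterministically: matched compounds in
    match order, then compounds introduced by intermediate reactions, then
    the rest.  Unmatched content appearing in both databases deliberately
    yields double entries outside the core.
    """
    config = config or IntegrationConfig()
    idx_a, idx_b = _index(dbA[0]), _index(dbB[0])

    local_c: dict[tuple[str, str], str] = {}  # (db, source_id) -> local id
    compounds: dict[str, MatchedCompound] = {}
    counter_c = 0

    def new_compound(entry: MatchedCompound) -> None:
        compounds[entry.local_id] = entry

    for match in state.compound_matches:
        counter_c += 1
        lid = make_local_id("Ath_C", counter_c)
        local_c[("A", match.id_A)] = lid
        local_c[("B", match.id_B)] = lid
        new_compound(
            MatchedCompound(
                local_id=lid,
                id_in_A=match.id_A,
                id_in_B=match.id_B,
                name_in_A=idx_a[match.id_A].name,
                name_in_B=idx_b[match.id_B].name,
                evidence=match.evidence,
                name_probability=match.name_probability,
                structure_tier=match.structure_tier,
            )
        )
    core_compound_ids = set(compounds)

    counter_r = 0
    core_reactions: dict[str, MatchedReaction] = {}
    for id_A, id_B in state.reaction_matches:
        rA, rB = None, None
        for r in dbA[1]:
            if r.source_id == id_A:
                rA = r
        for r in dbB[1]:
            if r.source_id == id_B:
                rB = r
        assert rA is not None and rB is not None
        sa, pa = _dropped_sides(rA, idx_a, config)
        counter_r += 1
        lid = make_local_id("Ath_R", counter_r)
        core_reactions[lid] = MatchedReaction(
            local_id=lid,
            substrates=tuple((local_c[("A", cid)], c) for cid, c in sorted(sa.items())),
            products=tuple((local_c[("A", cid)], c) for cid, c in sorted(pa.items())),
            id_in_A=id_A,
            id_in_B=id_B,
            ec_numbers=rA.ec_numbers | rB.ec_numbers,
            reversible=rA.reversible or rB.reversible,
        )

    core = Reconstruction(
        tier="core", compounds=dict(compounds), reactions=dict(core_reactions)
    )

    # classify the unmatched reactions of both databases
    unmatched: list[tuple[str, ReactionRecord, Mapping[str, CompoundRecord]]] = []
    for r in sorted(dbA[1], key=lambda r: r.source_id):
        if r.source_id not in state.matched_rA:
            unmatched.append(("A", r, idx_a))
    for r in sorted(dbB[1], key=lambda r: r.source_id):
        if r.source_id not in state.matched_rB:
            unmatched.append(("B", r, idx_b))

    matched_ids = {"A": set(state.a2b), "B": set(state.b2a)}

    def side_in_core(db: str, side: Mapping[str, Fraction]) -> bool:
        return bool(side) and all(cid in matched_ids[db] for cid in side)

    inter_list: list[tuple[str, ReactionRecord, Mapping[str, CompoundRecord]]] = []
    complete_list: list[tuple[str, ReactionRecord, Mapping[str, CompoundRecord]]] = []
    for db, rxn, idx in unmatched:
        sa, pa = _dropped_sides(rxn, idx, config)
        if not (sa and pa):
            complete_list.append((db, rxn, idx))
            continue
        if side_in_core(db, sa) or side_in_core(db, pa):
            inter_list.append((db, rxn, idx))
        else:
            complete_list.append((db, rxn, idx))

    def materialize(
        batch: Sequence[tuple[str, ReactionRecord, Mapping[str, CompoundRecord]]],
        reactions_out: dict[str, MatchedReaction],
    ) -> None:
        nonlocal counter_c, counter_r
        for db, rxn, idx in batch:
            sa, pa = _dropped_sides(rxn, idx, config)
            if not (sa and pa):
                continue  # proton-only side: nothing left to model
            for cid in sorted(sa) + sorted(pa):
                if (db, cid) not in local_c:
                    counter_c += 1
                    lid = make_local_id("Ath_C", counter_c)
                    local_c[(db, cid)] = lid
                    rec = idx[cid]
                    new_compound(
                        MatchedCompound(
                            local_id=lid,
                            id_in_A=cid if db == "A" else None,
                            id_in_B=cid if db == "B" else None,
                            name_in_A=rec.name if db == "A" else None,
                            name_in_B=rec.name if db == "B" else None,
                        )
                    )
            counter_r += 1
            lid = make_local_id("Ath_R", counter_r)
            reactions_out[lid] = MatchedReaction(
                local_id=lid,
                substrates=tuple(
                    (local_c[(db, cid)], c) for cid, c in sorted(sa.items())
                ),
                products=tuple(
                    (local_c[(db, cid)], c) for cid, c in sorted(pa.items())
                ),
                id_in_A=rxn.source_id if db == "A" else None,
                id_in_B=rxn.source_id if db == "B" else None,
                ec_numbers=rxn.ec_numbers,
                reversible=rxn.reversible,
            )

    inter_reactions: dict[str, MatchedReaction] = {}
    materialize(inter_list, inter_reactions)
    intermediate = Reconstruction(
        tier="intermediate",
        compounds=dict(compounds),
        reactions={**core_reactions, **inter_reactions},
    )

    complete_reactions: dict[str, MatchedReaction] = {}
    materialize(complete_list, complete_reactions)
    # remaining compounds of either database (not in any reaction) also belong
    # to the complete network, except free protons
    for db, recs, matched in (("A", dbA[0], state.a2b), ("B", dbB[0], state.b2a)):
        for rec in sorted(recs, key=lambda r: r.source_id):
            if (db, rec.source_id) in local_c or is_proton(rec, config):
                continue
            counter_c += 1
            lid = make_local_id("Ath_C", counter_c)
            local_c[(db, rec.source_id)] = lid
            new_compound(
                MatchedCompound(
                    local_id=lid,
                    id_in_A=rec.source_id if db == "A" else None,
                    id_in_B=rec.source_id if db == "B" else None,
                    name_in_A=rec.name if db == "A" else None,
                    name_in_B=rec.name if db == "B" else None,
                )
            )
    complete = Reconstruction(
        tier="complete",
        compounds=dict(compounds),
        reactions={**core_reactions, **inter_reactions, **complete_reactions},
    )
    # intermediate shares the compound dict additions made for complete; trim
    inter_compound_ids = core_compound_ids | {
        cid
        for rxn in inter_reactions.values()
        for cid, _ in (*rxn.substrates, *rxn.products)
    }
    intermediate.compounds = {
        lid: compounds[lid] for lid in compounds if lid in inter_compound_ids
    }
    core.compounds = {lid: compounds[lid] for lid in core_compound_ids}
    return TierAssignment(core=core, intermediate=intermediate, complete=complete)


# ---------------------------------------------------------------------------
# pathway coverage
# ---------------------------------------------------------------------------


def pathway_coverage(
    tiers: TierAssignment, pathway_map: Mapping[str, set[str]]
):
    """Per-pathway enzyme coverage of the three tiers.

    ``pathway_map`` maps a pathway name to its EC numbers.  For each pathway
    present in the data, reports the count and percentage of its ECs found on
    reactions of each tier; the complete-tier count equals the total ECs of
    the pathway present in either database.  Returns a pandas DataFrame.
    """
    import pandas as pd

    def tier_ecs(recon: Reconstruction) -> set[str]:
        return {ec for rxn in recon.reactions.values() for ec in rxn.ec_numbers}

    ecs = {
        "core": tier_ecs(tiers.core),
        "intermediate": tier_ecs(tiers.intermediate),
        "complete": tier_ecs(tiers.complete),
    }
    rows = []
    for pathway in sorted(pathway_map):
        present = pathway_map[pathway] & ecs["complete"]
        total = len(present)
        if total == 0:
            continue
        row: dict = {"pathway": pathway, "total_ecs": total}
        for tier_name in ("core", "intermediate", "complete"):
            n = len(present & ecs[tier_name])
            row[f"{tier_name}_count"] = n
            row[f"{tier_name}_pct"] = 100.0 * n / total
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "pathway",
            "total_ecs",
            "core_count",
            "core_pct",
            "intermediate_count",
            "intermediate_pct",
            "complete_count",
            "complete_pct",
        ],
    )


def read_pathway_map(path: str | Path) -> dict[str, set[str]]:
    """Read a pathway→EC TSV (pathway, semicolon-separated EC list)."""
    out: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("pathway\t"):
            continue
        pathway, _, ecs = line.partition("\t")
        out[pathway] = set(filter(None, ecs.split(";")))
    return out


def write_review_queue(queue: Sequence[ReviewItem], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("kind\tid_A\tid_B\tevidence\tdecision\n")
        for item in queue:
            fh.write(f"{item.kind}\t{item.id_A}\t{item.id_B}\t{item.evidence}\t\n")


def read_review_decisions(path: str | Path) -> list[tuple[str, str]]:
    """Read accepted pairs (decision column == 'accept') from a queue TSV."""
    out = []
    for line in Path(path).read_text().splitlines()[1:]:
        fields = line.split("\t")
        if len(fields) >= 5 and fields[4].strip().lower() == "accept":
            out.append((fields[1], fields[2]))
    return out
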