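"""Seeding, reaction-driven propagation, acceptance rule, tier assignment."""

from __future__ import annotations

import random
from fractions import Fraction

import pytest

from metaconsensus import integrate, name_match
from metaconsensus.integrate import (
    ACCEPT,
    FULL_MATCH,
    INCOMPATIBLE,
    ONE_UNKNOWN,
    REJECT,
    REVIEW,
    IntegrationConfig,
    MatchState,
    accept_candidate,
    compare_reactions,
    ec_compatible,
    ec_is_full,
    is_proton,
    iterate_to_fixpoint,
    pathway_coverage,
    read_pathway_map,
    read_review_decisions,
    seed_matches,
    write_review_queue,
)
from metaconsensus.model_io import CompoundRecord, ReactionRecord


def comp(db, cid, names, formula=None, smiles=None, xrefs=None, generic=False):
    return CompoundRecord(
        source_db=db,
        source_id=cid,
        names=tuple(names),
        formula=formula or {},
        smiles=smiles,
        xrefs=xrefs or {},
        is_generic_class=generic,
    )


def rxn(db, rid, subs, prods, ecs=()):
    return ReactionRecord(
        db,
        rid,
        tuple((c, Fraction(k)) for c, k in subs),
        tuple((c, Fraction(k)) for c, k in prods),
        ec_numbers=frozenset(ecs),
    )


class TestEcHelpers:
    def test_full_precision(self):
        assert ec_is_full("2.7.1.40")
        assert not ec_is_full("2.7.1.-")
        assert not ec_is_full("2.7.1")

    def test_wildcard_compatibility(self):
        assert ec_compatible("2.7.1.-", "2.7.1.40")
        assert ec_compatible("2.7.1.40", "2.7.1.40")
        assert not ec_compatible("2.7.1.40", "2.7.1.41")
        assert not ec_compatible("1.1.1.1", "2.1.1.1")


class TestProtonPolicy:
    def test_by_name(self):
        cfg = IntegrationConfig()
        assert is_proton(comp("A", "c1", ["H+"]), cfg)
        assert is_proton(comp("A", "c1", ["proton"]), cfg)
        assert not is_proton(comp("A", "c1", ["H2O"]), cfg)

    def test_by_configured_id(self):
        cfg = IntegrationConfig(proton_ids=frozenset({"CPD-PROTON"}))
        assert is_proton(comp("B", "CPD-PROTON", ["odd name"]), cfg)


class TestConfigFile:
    def test_parse(self, tmp_path):
        p = tmp_path / "cfg"
        p.write_text(
            "# comment\nname_threshold = 0.8\nseed=7\nproton_allowlist=h+, hydron\n"
        )
        cfg = IntegrationConfig.from_file(p)
        assert cfg.name_threshold == 0.8
        assert cfg.seed == 7
        assert cfg.proton_names == frozenset({"h+", "hydron"})

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "cfg"
        p.write_text("typo_key = 1\n")
        with pytest.raises(ValueError, match="unknown config key"):
            IntegrationConfig.from_file(p)


class TestSeeding:
    def test_xref_seed(self):
        dba = ([comp("A", "a1", ["x"])], [])
        dbb = ([comp("B", "b1", ["y"], xrefs={"KEGG": "a1"})], [])
        state = seed_matches(dba, dbb)
        assert state.a2b == {"a1": "b1"}
        assert state.compound_matches[0].evidence == "seed_xref"

    def test_ambiguous_xref_goes_to_review(self):
        dba = ([comp("A", "a1", ["x"])], [])
        dbb = (
            [
                comp("B", "b1", ["y"], xrefs={"KEGG": "a1"}),
                comp("B", "b2", ["z"], xrefs={"KEGG": "a1"}),
            ],
            [],
        )
        state = seed_matches(dba, dbb)
        assert state.a2b == {}
        assert {(i.id_A, i.id_B) for i in state.review_queue} == {
            ("a1", "b1"),
            ("a1", "b2"),
        }
        assert all(i.kind == "ambiguous_seed" for i in state.review_queue)

    def test_exact_synonym_seed_via_normalization(self):
        dba = ([comp("A", "a1", ["alpha-Ketoglutarate"])], [])
        dbb = ([comp("B", "b1", ["α-ketoglutarate"])], [])
        state = seed_matches(dba, dbb)
        assert state.a2b == {"a1": "b1"}
        assert state.compound_matches[0].evidence == "exact_synonym"

    def test_ambiguous_synonym_not_seeded(self):
        dba = (
            [comp("A", "a1", ["malate"]), comp("A", "a2", ["malate", "other"])],
            [],
        )
        dbb = ([comp("B", "b1", ["malate"])], [])
        state = seed_matches(dba, dbb)
        assert state.a2b == {}

    def test_generic_and_proton_excluded_from_synonym_seeding(self):
        dba = (
            [
                comp("A", "a1", ["an alcohol"], generic=True),
                comp("A", "a2", ["H+"]),
            ],
            [],
        )
        dbb = (
            [
                comp("B", "b1", ["an alcohol"], generic=True),
                comp("B", "b2", ["H+"]),
            ],
            [],
        )
        state = seed_matches(dba, dbb)
        assert state.a2b == {}


class TestCompareReactions:
    def setup_method(self):
        self.idx_a = {
            c.source_id: c
            for c in [
                comp("A", "a1", ["one"]),
                comp("A", "a2", ["two"]),
                comp("A", "a3", ["three"]),
                comp("A", "aH", ["H+"]),
            ]
        }
        self.idx_b = {
            c.source_id: c
            for c in [
                comp("B", "b1", ["one"]),
                comp("B", "b2", ["two"]),
                comp("B", "b3", ["three"]),
            ]
        }
        self.state = MatchState()
        from metaconsensus.integrate import CompoundMatch

        self.state.add_compound_match(CompoundMatch("a1", "b1", "seed_xref"))
        self.state.add_compound_match(CompoundMatch("a2", "b2", "seed_xref"))

    def test_full_match(self):
        rA = rxn("A", "r1", [("a1", 1)], [("a2", 1)])
        rB = rxn("B", "s1", [("b1", 1)], [("b2", 1)])
        assert compare_reactions(rA, rB, self.state, self.idx_a, self.idx_b) == (
            FULL_MATCH,
            None,
        )

    def test_reversed_orientation_matches(self):
        rA = rxn("A", "r1", [("a1", 1)], [("a2", 1)])
        rB = rxn("B", "s1", [("b2", 1)], [("b1", 1)])
        assert compare_reactions(rA, rB, self.state, self.idx_a, self.idx_b)[0] == (
            FULL_MATCH
        )

    def test_one_unknown(self):
        rA = rxn("A", "r1", [("a1", 1)], [("a3", 1)])
        rB = rxn("B", "s1", [("b1", 1)], [("b3", 1)])
        verdict, pair = compare_reactions(rA, rB, self.state, self.idx_a, self.idx_b)
        assert verdict == ONE_UNKNOWN
        assert pair == ("a3", "b3")

    def test_coefficient_mismatch_incompatible(self):
        rA = rxn("A", "r1", [("a1", 2)], [("a2", 1)])
        rB = rxn("B", "s1", [("b1", 1)], [("b2", 1)])
        assert compare_reactions(rA, rB, self.state, self.idx_a, self.idx_b)[0] == (
            INCOMPATIBLE
        )

    def test_free_protons_dropped_before_comparison(self):
        rA = rxn("A", "r1", [("a1", 1)], [("a2", 1), ("aH", 1)])
        rB = rxn("B", "s1", [("b1", 1)], [("b2", 1)])
        assert compare_reactions(rA, rB, self.state, self.idx_a, self.idx_b)[0] == (
            FULL_MATCH
        )

    def test_disjoint_full_ec_sets_block_full_match(self):
        rA = rxn("A", "r1", [("a1", 1)], [("a2", 1)], ecs=["1.1.1.1"])
        rB = rxn("B", "s1", [("b1", 1)], [("b2", 1)], ecs=["2.2.2.2"])
        assert compare_reactions(rA, rB, self.state, self.idx_a, self.idx_b)[0] == (
            INCOMPATIBLE
        )

    def test_two_unknown_pairs_incompatible(self):
        state = MatchState()
        rA = rxn("A", "r1", [("a1", 1)], [("a3", 1)])
        rB = rxn("B", "s1", [("b1", 1)], [("b3", 1)])
        assert compare_reactions(rA, rB, state, self.idx_a, self.idx_b)[0] == (
            INCOMPATIBLE
        )


class TestAcceptanceRule:
    def pair_dbs(self, name_b="glucose-6-phosphate", smiles_b="OCC1OC(O)C(O)C(O)C1O",
                 ecs_a=("2.7.1.2",), ecs_b=("2.7.1.2",)):
        idx_a = {
            "a1": comp("A", "a1", ["glucose 6-phosphate"],
                       smiles="OCC1OC(O)C(O)C(O)C1O"),
        }
        idx_b = {"b1": comp("B", "b1", [name_b], smiles=smiles_b)}
        rA = rxn("A", "r1", [("a1", 1)], [("a1", 1)], ecs=ecs_a)
        rB = rxn("B", "s1", [("b1", 1)], [("b1", 1)], ecs=ecs_b)
        return idx_a, idx_b, rA, rB

    def test_accept_needs_all_three(self):
        idx_a, idx_b, rA, rB = self.pair_dbs()
        decision, match, summary = accept_candidate(
            ("a1", "b1"), rA, rB, idx_a, idx_b, name_match.heuristic_model()
        )
        assert decision == ACCEPT
        assert match.evidence == "classifier_plus_structure"
        assert match.structure_tier == "exact"
        assert match.name_probability >= 0.9

    def test_partial_ec_routes_to_review(self):
        idx_a, idx_b, rA, rB = self.pair_dbs(ecs_b=("2.7.1.-",))
        decision, match, _ = accept_candidate(
            ("a1", "b1"), rA, rB, idx_a, idx_b, name_match.heuristic_model()
        )
        assert decision == REVIEW and match is None

    def test_nonexact_structure_routes_to_review(self):
        # same constitution, different stereo tag: ladder tier 'stereo'
        idx_a, idx_b, rA, rB = self.pair_dbs(
            smiles_b="OC[C@H]1OC(O)C(O)C(O)C1O"
        )
        decision, _, summary = accept_candidate(
            ("a1", "b1"), rA, rB, idx_a, idx_b, name_match.heuristic_model()
        )
        assert decision == REVIEW
        assert "stereo" in summary

    def test_formula_fallback_accepts_proton_difference(self):
        idx_a = {
            "a1": comp("A", "a1", ["citrate"], formula={"C": 6, "H": 8, "O": 7})
        }
        idx_b = {
            "b1": comp("B", "b1", ["citrate"], formula={"C": 6, "H": 7, "O": 7})
        }
        rA = rxn("A", "r1", [("a1", 1)], [("a1", 1)], ecs=["1.1.1.1"])
        rB = rxn("B", "s1", [("b1", 1)], [("b1", 1)], ecs=["1.1.1.1"])
        decision, match, _ = accept_candidate(
            ("a1", "b1"), rA, rB, idx_a, idx_b, name_match.heuristic_model()
        )
        assert decision == ACCEPT
        assert match.structure_tier == "formula_only"

    def test_no_signal_rejected(self):
        idx_a = {"a1": comp("A", "a1", ["xxxx"], formula={"C": 1})}
        idx_b = {"b1": comp("B", "b1", ["zzzzzzz"], formula={"N": 9})}
        rA = rxn("A", "r1", [("a1", 1)], [("a1", 1)], ecs=["1.1.1.1"])
        rB = rxn("B", "s1", [("b1", 1)], [("b1", 1)], ecs=["2.2.2.2"])
        decision, _, _ = accept_candidate(
            ("a1", "b1"), rA, rB, idx_a, idx_b, name_match.heuristic_model()
        )
        assert decision == REJECT

    def test_generic_class_never_matches_structurally(self):
        idx_a = {"a1": comp("A", "a1", ["an alcohol"], generic=True)}
        idx_b = {"b1": comp("B", "b1", ["an alcohol"])}
        rA = rxn("A", "r1", [("a1", 1)], [("a1", 1)])
        rB = rxn("B", "s1", [("b1", 1)], [("b1", 1)])
        decision, _, _ = accept_candidate(
            ("a1", "b1"), rA, rB, idx_a, idx_b, name_match.heuristic_model()
        )
        assert decision == REVIEW  # name passes, EC/structure cannot


def orphan_dbs():
    """Four seeded pairs plus one compound pair only reachable via a reaction."""
    compounds_a = [
        comp("A", "a1", ["metha"], xrefs={}),
        comp("A", "a2", ["ethya"]),
        comp("A", "a3", ["propa"]),
        comp("A", "a4", ["butya"]),
        comp("A", "a5", ["glucose 6-phosphate"], smiles="OCC1OC(O)C(O)C(O)C1O"),
    ]
    compounds_b = [
        comp("B", "b1", ["metha"]),
        comp("B", "b2", ["ethya"]),
        comp("B", "b3", ["propa"]),
        comp("B", "b4", ["butya"]),
        comp("B", "b5", ["glucose-6-phosphate"], smiles="OCC1OC(O)C(O)C(O)C1O"),
    ]
    reactions_a = [
        rxn("A", "r1", [("a1", 1), ("a2", 1)], [("a3", 1), ("a5", 1)],
            ecs=["2.7.1.2"]),
        rxn("A", "r2", [("a5", 1)], [("a4", 1)]),
    ]
    reactions_b = [
        rxn("B", "s1", [("b1", 1), ("b2", 1)], [("b3", 1), ("b5", 1)],
            ecs=["2.7.1.2"]),
        rxn("B", "s2", [("b5", 1)], [("b4", 1)]),
    ]
    return (compounds_a, reactions_a), (compounds_b, reactions_b)


class TestFixpoint:
    def test_orphan_recovered_through_reaction(self):
        dba, dbb = orphan_dbs()
        state = iterate_to_fixpoint(dba, dbb, name_match.heuristic_model())
        assert state.a2b["a5"] == "b5"
        assert set(state.reaction_matches) == {("r1", "s1"), ("r2", "s2")}

    def test_history_records_the_cascade(self):
        dba, dbb = orphan_dbs()
        state = iterate_to_fixpoint(dba, dbb, name_match.heuristic_model())
        # iteration 0 = seeding; the candidate is accepted in iteration 1,
        # both reactions then fully match, and the last iteration adds nothing
        assert state.history[0]["compounds_added"] == 4
        assert state.history[1]["compounds_added"] == 1
        assert sum(h["reactions_added"] for h in state.history) == 2
        last = state.history[-1]
        assert last["compounds_added"] == 0 and last["reactions_added"] == 0

    def test_disjoint_databases_match_nothing(self):
        dba = ([comp("A", "a1", ["aaa"])], [rxn("A", "r1", [("a1", 1)], [("a1", 1)])])
        dbb = ([comp("B", "b1", ["zzz"])], [rxn("B", "s1", [("b1", 1)], [("b1", 1)])])
        state = iterate_to_fixpoint(dba, dbb, name_match.heuristic_model())
        assert state.a2b == {} and state.reaction_matches == []

    def test_record_order_does_not_change_result(self):
        dba, dbb = orphan_dbs()
        ref = iterate_to_fixpoint(dba, dbb, name_match.heuristic_model()).a2b
        rng = random.Random(5)
        for _ in range(3):
            ca, ra = list(dba[0]), list(dba[1])
            cb, rb = list(dbb[0]), list(dbb[1])
            for lst in (ca, ra, cb, rb):
                rng.shuffle(lst)
            state = iterate_to_fixpoint((ca, ra), (cb, rb), name_match.heuristic_model())
            assert state.a2b == ref

    def test_review_resolver_injection(self):
        dba = (
            [comp("A", "a1", ["aaa"], xrefs={}), comp("A", "a2", ["bbb"])],
            [],
        )
        dbb = (
            [comp("B", "b1", ["qqq"]), comp("B", "b2", ["rrr"])],
            [],
        )

        queue_done = [False]

        def resolver(queue):  # inject once
            if queue_done[0]:
                return []
            queue_done[0] = True
            return [("a1", "b1")]

        state = iterate_to_fixpoint(dba, dbb, name_match.heuristic_model(),
                                    review_resolver=resolver)
        assert state.a2b == {"a1": "b1"}
        match = [m for m in state.compound_matches if m.id_A == "a1"][0]
        assert match.evidence == "manual"

    def test_injected_conflict_raises(self):
        dba = ([comp("A", "a1", ["same"])], [])
        dbb = ([comp("B", "b1", ["same"]), comp("B", "b2", ["other"])], [])

        def resolver(queue):
            return [("a1", "b2")]  # a1 is already seeded to b1

        with pytest.raises(ValueError, match="injectivity"):
            iterate_to_fixpoint(dba, dbb, name_match.heuristic_model(),
                                review_resolver=resolver)


class TestTierAssignment:
    def test_nesting_on_synthetic_run(self, synth_run):
        t = synth_run.tiers
        assert set(t.core.reactions) <= set(t.intermediate.reactions)
        assert set(t.intermediate.reactions) <= set(t.complete.reactions)
        assert set(t.core.compounds) <= set(t.intermediate.compounds)
        assert set(t.intermediate.compounds) <= set(t.complete.compounds)
        from metaconsensus.model_io import check_tier_nesting

        check_tier_nesting(t.core, t.intermediate, t.complete)

    def test_core_compounds_carry_both_ids(self, synth_run):
        for c in synth_run.tiers.core.compounds.values():
            assert c.id_in_A and c.id_in_B

    def test_unmatched_duplicates_get_double_entries(self):
        # same compound unmatched in both databases (names differ too much):
        # the complete tier deliberately holds one entry per database
        dba = ([comp("A", "a1", ["aaaa"])],
               [rxn("A", "r1", [("a1", 1)], [("a1", 2)])])
        dbb = ([comp("B", "b1", ["zzzz"])],
               [rxn("B", "s1", [("b1", 1)], [("b1", 2)])])
        state = iterate_to_fixpoint(dba, dbb, name_match.heuristic_model())
        tiers = integrate.assign_tiers(dba, dbb, state)
        assert len(tiers.core.reactions) == 0
        assert len(tiers.complete.compounds) == 2
        assert len(tiers.complete.reactions) == 2

    def test_anchored_one_source_reaction_is_intermediate(self, showcase_run):
        t = showcase_run.truth.expected_tier
        for (db, rid), expected in t.items():
            assert showcase_run.tiers.tier_of_reaction(db, rid) == expected

    def test_free_protons_absent_from_all_tiers(self, synth_run):
        for recon in (
            synth_run.tiers.core,
            synth_run.tiers.intermediate,
            synth_run.tiers.complete,
        ):
            for c in recon.compounds.values():
                for name in (c.name_in_A, c.name_in_B):
                    assert name is None or name.strip().lower() not in (
                        "h+",
                        "proton",
                    )


class TestReviewQueueIo:
    def test_roundtrip(self, tmp_path):
        from metaconsensus.integrate import ReviewItem

        queue = [ReviewItem("partial_candidate", "a1", "b1", "ec=1")]
        path = tmp_path / "queue.tsv"
        write_review_queue(queue, path)
        assert read_review_decisions(path) == []  # no decision filled in
        text = path.read_text().replace("ec=1\t", "ec=1\taccept")
        path.write_text(text)
        assert read_review_decisions(path) == [("a1", "b1")]


class TestPathwayCoverage:
    def test_counts_and_percentages(self, tmp_path):
        dba, dbb = orphan_dbs()
        state = iterate_to_fixpoint(dba, dbb, name_match.heuristic_model())
        tiers = integrate.assign_tiers(dba, dbb, state)
        (tmp_path / "map.tsv").write_text(
            "pathway\tecs\nglycolysis\t2.7.1.2;9.9.9.9\nempty\t3.3.3.3\n"
        )
        pmap = read_pathway_map(tmp_path / "map.tsv")
        df = pathway_coverage(tiers, pmap)
        assert list(df["pathway"]) == ["glycolysis"]  # absent pathway dropped
        row = df.iloc[0]
        assert row["total_ecs"] == 1  # only the EC present in the data
        assert row["core_count"] == 1 and row["core_pct"] == 100.0
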