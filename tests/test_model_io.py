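from __future__ import annotations

from fractions import Fraction

import pytest

from helpers import make_recon, toy_two_reaction_recon
from metaconsensus import model_io
from metaconsensus.model_io import (
    CompoundRecord,
    MatchedCompound,
    ParseError,
    ReactionRecord,
    Reconstruction,
    check_tier_nesting,
    format_formula,
    format_stoichiometry,
    parse_formula,
    parse_stoichiometry_string,
    read_reconstruction_tsv,
    read_sbml,
    read_source_db,
    sanitize_sid,
    unsanitize_sid,
    validate_sbml,
    write_reconstruction_tsv,
    write_sbml,
    write_source_db,
)


class TestFormula:
    def test_parse_simple(self):
        assert parse_formula("C6H12O6") == {"C": 6, "H": 12, "O": 6}

    def test_parse_implicit_one(self):
        assert parse_formula("H2O") == {"H": 2, "O": 1}

    def test_parse_two_letter_element(self):
        assert parse_formula("CH3Cl") == {"C": 1, "H": 3, "Cl": 1}

    def test_empty_ok(self):
        assert parse_formula("") == {}

    def test_bad_symbol_rejected(self):
        with pytest.raises(ParseError):
            parse_formula("Xx2")

    def test_garbage_rejected(self):
        with pytest.raises(ParseError):
            parse_formula("12C")

    def test_format_hill_order(self):
        # Hill convention: with carbon — C, H, rest alphabetical; without
        # carbon — everything alphabetical (HCl is written ClH)
        assert format_formula({"O": 6, "C": 6, "H": 12}) == "C6H12O6"
        assert format_formula({"Cl": 1, "H": 1}) == "ClH"

    def test_roundtrip(self):
        for f in ("C6H12O6", "H2O", "C10H16N5O13P3", "CO2"):
            assert format_formula(parse_formula(f)) == f


class TestStoichiometryString:
    def test_parse(self):
        subs, prods = parse_stoichiometry_string("1 A + 2 B = 1 C")
        assert subs == [("A", Fraction(1)), ("B", Fraction(2))]
        assert prods == [("C", Fraction(1))]

    def test_fractional(self):
        subs, _ = parse_stoichiometry_string("1/2 A = 1 B")
        assert subs == [("A", Fraction(1, 2))]

    def test_roundtrip(self):
        s = "1 A + 3/2 B = 2 C"
        subs, prods = parse_stoichiometry_string(s)
        assert format_stoichiometry(subs, prods) == s

    def test_requires_single_equals(self):
        with pytest.raises(ParseError):
            parse_stoichiometry_string("A + B")
        with pytest.raises(ParseError):
            parse_stoichiometry_string("A = B = C")

    def test_requires_explicit_coefficient(self):
        with pytest.raises(ParseError):
            parse_stoichiometry_string("A = 1 B")


class TestRecords:
    def test_compound_invariants(self):
        with pytest.raises(ValueError):
            CompoundRecord(source_db="A", source_id="", names=("x",))
        with pytest.raises(ValueError):
            CompoundRecord(source_db="A", source_id="c1", names=())
        with pytest.raises(ValueError):
            CompoundRecord(
                source_db="A", source_id="c1", names=("x",), formula={"C": -1}
            )

    def test_generic_class_excludes_smiles(self):
        with pytest.raises(ValueError):
            CompoundRecord(
                source_db="A",
                source_id="c1",
                names=("an alcohol",),
                smiles="CCO",
                is_generic_class=True,
            )

    def test_reaction_needs_nonempty_sides(self):
        with pytest.raises(ValueError):
            ReactionRecord("A", "r1", (), (("c1", Fraction(1)),))

    def test_reaction_positive_coefficients(self):
        with pytest.raises(ValueError):
            ReactionRecord(
                "A", "r1", (("c1", Fraction(-1)),), (("c2", Fraction(1)),)
            )


class TestSourceDbRoundTrip:
    def _records(self):
        compounds = [
            CompoundRecord(
                source_db="A",
                source_id="C1",
                names=("pyruvate", "pyruvic acid"),
                formula={"C": 3, "H": 4, "O": 3},
                smiles="CC(=O)C(=O)O",
                xrefs={"ChEBI": "15361"},
            ),
            CompoundRecord(
                source_db="A", source_id="C2", names=("an alcohol",),
                is_generic_class=True,
            ),
        ]
        reactions = [
            ReactionRecord(
                "A",
                "R1",
                (("C1", Fraction(2)),),
                (("C2", Fraction(1)),),
                ec_numbers=frozenset({"1.1.1.1"}),
                reversible=False,
                pathway_tags=frozenset({"glycolysis"}),
            )
        ]
        return compounds, reactions

    def test_roundtrip(self, tmp_path):
        compounds, reactions = self._records()
        write_source_db(tmp_path / "db", compounds, reactions, header_comment="t")
        c2, r2 = read_source_db(tmp_path / "db", "A")
        assert c2 == compounds
        assert r2 == reactions

    def test_duplicate_compound_id_rejected(self, tmp_path):
        compounds, reactions = self._records()
        write_source_db(tmp_path / "db", compounds + [compounds[0]], reactions)
        with pytest.raises(ParseError, match="duplicate"):
            read_source_db(tmp_path / "db", "A")

    def test_dangling_reference_rejected(self, tmp_path):
        compounds, reactions = self._records()
        write_source_db(tmp_path / "db", compounds[:1], reactions)
        with pytest.raises(ParseError, match="unknown compound"):
            read_source_db(tmp_path / "db", "A")

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_source_db(tmp_path / "nodir", "A")


class TestReconstructionTsv:
    def test_roundtrip(self, tmp_path):
        recon = toy_two_reaction_recon()
        write_reconstruction_tsv(recon, tmp_path / "rec")
        back = read_reconstruction_tsv(tmp_path / "rec", tier="core")
        assert set(back.compounds) == set(recon.compounds)
        assert set(back.reactions) == set(recon.reactions)
        for rid in recon.reactions:
            assert back.reactions[rid].substrates == recon.reactions[rid].substrates
            assert back.reactions[rid].products == recon.reactions[rid].products

    def test_name_probability_full_precision(self, tmp_path):
        recon = toy_two_reaction_recon()
        p = 0.9123456789012345
        recon.compounds["A"] = MatchedCompound(
            local_id="A",
            id_in_A="A",
            id_in_B="bA",
            name_in_A="a",
            name_in_B="a'",
            evidence="classifier_plus_structure",
            name_probability=p,
            structure_tier="exact",
        )
        write_reconstruction_tsv(recon, tmp_path / "rec")
        back = read_reconstruction_tsv(tmp_path / "rec")
        assert back.compounds["A"].name_probability == p

    def test_validate_catches_dangling(self):
        recon = toy_two_reaction_recon()
        del recon.compounds["C"]
        with pytest.raises(ValueError):
            recon.validate()

    def test_tier_nesting_check(self):
        core = toy_two_reaction_recon()
        inter = toy_two_reaction_recon()
        inter.tier = "intermediate"
        complete = toy_two_reaction_recon()
        complete.tier = "complete"
        check_tier_nesting(core, inter, complete)
        del complete.reactions["R2"]
        with pytest.raises(ValueError, match="nesting"):
            check_tier_nesting(core, inter, complete)


class TestSid:
    def test_plain_id_passthrough(self):
        assert sanitize_sid("Ath_C0001") == "Ath_C0001"

    def test_invalid_chars_escaped_and_reversible(self):
        for raw in ("CPD-123", "2-oxoglutarate", "a b", "s_weird", "x_x41_"):
            sid = sanitize_sid(raw)
            assert model_io._SID_OK.match(sid), sid
            assert unsanitize_sid(sid) == raw

    def test_injective_on_tricky_pairs(self):
        pairs = [("a-b", "a_b"), ("CPD-1", "CPD_1"), ("s_1", "s-1")]
        for x, y in pairs:
            assert sanitize_sid(x) != sanitize_sid(y)


class TestSbml:
    def test_roundtrip_and_valid(self, tmp_path):
        recon = make_recon(
            {
                "Ath_R0001": ([("Ath_C0001", 1), ("Ath_C0002", 2)], [("Ath_C0003", 1)]),
                "Ath_R0002": ([("Ath_C0003", 1)], [("Ath_C0001", 1)]),
            }
        )
        path = tmp_path / "m.xml"
        write_sbml(
            recon,
            path,
            annotations={"Ath_C0001": [("KEGG", "C00022"), ("ChEBI", "15361")]},
        )
        assert validate_sbml(path) == 0
        back = read_sbml(path)
        assert set(back.compounds) == set(recon.compounds)
        assert set(back.reactions) == set(recon.reactions)
        for rid in recon.reactions:
            assert sorted(back.reactions[rid].substrates) == sorted(
                recon.reactions[rid].substrates
            )
        text = path.read_text()
        assert "identifiers.org/kegg.compound:C00022" in text

    def test_fractional_coefficients_survive(self, tmp_path):
        recon = make_recon({"R1": ([("A", Fraction(1, 2))], [("B", 1)])})
        write_sbml(recon, tmp_path / "m.xml")
        back = read_sbml(tmp_path / "m.xml")
        assert back.reactions["R1"].substrates == (("A", Fraction(1, 2)),)


class TestGraphExport:
    def test_graphml_roundtrip(self, tmp_path):
        from metaconsensus import topology

        recon = toy_two_reaction_recon()
        g = topology.build_graph(recon, node_tiers={"A": "yellow"})
        model_io.write_graph_export(g, tmp_path / "g.graphml", format="graphml")
        back = model_io.read_graphml(tmp_path / "g.graphml")
        assert set(back.nodes) == set(g.g.nodes)
        assert back.nodes["A"]["tier"] == "yellow"

    def test_sif(self, tmp_path):
        from metaconsensus import topology

        recon = toy_two_reaction_recon()
        g = topology.build_graph(recon)
        model_io.write_graph_export(g, tmp_path / "g.sif", format="sif")
        lines = (tmp_path / "g.sif").read_text().splitlines()
        assert "A\trr\tB" in lines
        assert "A\trr\tC" in lines

    def test_unknown_format(self, tmp_path):
        from metaconsensus import topology

        g = topology.build_graph(toy_two_reaction_recon())
        with pytest.raises(ValueError):
            model_io.write_graph_export(g, tmp_path / "g.x", format="dot")


try:
    from hypothesis import given
    from hypothesis import strategies as st

    @given(st.text(min_size=1, max_size=30))
    def test_sid_roundtrip_property(raw):
        sid = sanitize_sid(raw)
        assert model_io._SID_OK.match(sid)
        assert unsanitize_sid(sid) == raw

except ImportError:
    pass
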