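"""Domain types and file formats.

Source databases are read from a flat two-file dialect (``compounds.tsv`` +
``reactions.tsv``) modelled on KEGG-style and BioCyc-style exports.
Reconstructions are written in a matching two-file dialect, as annotated SBML
(Level 3 Version 1), and as GraphML/SIF graph exchange files.

Stoichiometric coefficients are exact :class:`fractions.Fraction` values
throughout; reaction strings always spell out unit coefficients and separate
substrates from products with ``=``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

SourceDB = str  # "A" or "B"

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# element symbols accepted in Hill-notation formulas
_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I "
    "Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt "
    "Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U R".split()
)  # "R" tolerated for generic residues


class ParseError(ValueError):
    """Raised when a source or reconstruction file cannot be parsed."""


def parse_formula(s: str) -> dict[str, int]:
    """Parse a Hill-notation formula string into an element→count map.

    >>> parse_formula("C3H4O3")
    {'C': 3, 'H': 4, 'O': 3}
    """
    s = s.strip()
    if not s:
        return {}
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _FORMULA_TOKEN.match(s, pos)
        if not m or m.start() != pos:
            raise ParseError(f"malformed formula {s!r} at position {pos}")
        sym, num = m.group(1), m.group(2)
        if sym not in _ELEMENTS:
            raise ParseError(f"unknown element symbol {sym!r} in formula {s!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        pos = m.end()
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Format an element map in Hill order (C, H, then alphabetical)."""
    if not counts:
        return ""
    symbols = sorted(counts)
    ordered: list[str] = []
    if "C" in counts:
        ordered.append("C")
        if "H" in counts:
            ordered.append("H")
        ordered += [s for s in symbols if s not in ("C", "H")]
    else:
        ordered = symbols
    return "".join(f"{s}{counts[s] if counts[s] != 1 else ''}" for s in ordered)


# ---------------------------------------------------------------------------
# source-database record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundRecord:
    """One compound entry of a source database.

    ``names`` is ordered with the preferred name first.  ``formula`` maps
    element symbols to non-negative counts and may be empty when unknown.
    ``is_generic_class`` marks placeholder entries such as "an alcohol" that
    stand for a whole compound class and carry no structure.
    """

    source_db: SourceDB
    source_id: str
    names: tuple[str, ...]
    formula: Mapping[str, int] = field(default_factory=dict)
    smiles: str | None = None
    xrefs: Mapping[str, str] = field(default_factory=dict)
    is_generic_class: bool = False

    def __post_init__(self) -> None:
        if not self.source_id:
            raise ValueError("compound source_id must be non-empty")
        if not self.names:
            raise ValueError(f"compound {self.source_id}: names must be non-empty")
        if any(v < 0 for v in self.formula.values()):
            raise ValueError(f"compound {self.source_id}: negative formula count")
        if self.is_generic_class and self.smiles:
            raise ValueError(
                f"compound {self.source_id}: generic class cannot carry a structure"
            )

    @property
    def name(self) -> str:
        return self.names[0]


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction entry of a source database.

    Substrates and products are ``(compound source_id, coefficient)`` pairs
    with strictly positive rational coefficients.
    """

    source_db: SourceDB
    source_id: str
    substrates: tuple[tuple[str, Fraction], ...]
    products: tuple[tuple[str, Fraction], ...]
    ec_numbers: frozenset[str] = frozenset()
    reversible: bool = True
    pathway_tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValueError(f"reaction {self.source_id}: both sides must be non-empty")
        for cid, coeff in (*self.substrates, *self.products):
            if coeff <= 0:
                raise ValueError(
                    f"reaction {self.source_id}: non-positive coefficient for {cid}"
                )

    @property
    def participants(self) -> set[str]:
        return {c for c, _ in self.substrates} | {c for c, _ in self.products}


# ---------------------------------------------------------------------------
# reconstruction types
# ---------------------------------------------------------------------------

TIERS = ("core", "intermediate", "complete")
TIER_COLORS = {"core": "yellow", "intermediate": "green", "complete": "blue"}

EVIDENCE_KINDS = ("seed_xref", "exact_synonym", "classifier_plus_structure", "manual")
STRUCTURE_TIERS = ("exact", "stereo", "tautomer", "charge", "similar", "formula_only", "none")


def make_local_id(prefix: str, n: int) -> str:
    """Local identifiers: prefix + zero-padded number, at least 4 digits."""
    return f"{prefix}{n:04d}"


@dataclass(frozen=True)
class MatchedCompound:
    """A compound of a reconstruction, with cross-database provenance.

    Core-tier entries carry both source identifiers; compounds introduced by
    a single database in the outer tiers carry only one.
    """

    local_id: str
    id_in_A: str | None = None
    id_in_B: str | None = None
    name_in_A: str | None = None
    name_in_B: str | None = None
    evidence: str | None = None
    name_probability: float | None = None
    structure_tier: str | None = None

    def __post_init__(self) -> None:
        if self.id_in_A is None and self.id_in_B is None:
            raise ValueError(f"{self.local_id}: at least one source id required")
        if self.evidence is not None and self.evidence not in EVIDENCE_KINDS:
            raise ValueError(f"{self.local_id}: unknown evidence {self.evidence!r}")
        if self.structure_tier is not None and self.structure_tier not in STRUCTURE_TIERS:
            raise ValueError(f"{self.local_id}: unknown structure tier")


@dataclass(frozen=True)
class MatchedReaction:
    """A reaction of a reconstruction over local compound identifiers."""

    local_id: str
    substrates: tuple[tuple[str, Fraction], ...]
    products: tuple[tuple[str, Fraction], ...]
    id_in_A: str | None = None
    id_in_B: str | None = None
    ec_numbers: frozenset[str] = frozenset()
    reversible: bool = True

    def __post_init__(self) -> None:
        if self.id_in_A is None and self.id_in_B is None:
            raise ValueError(f"{self.local_id}: at least one source id required")


@dataclass
class Reconstruction:
    """One confidence tier of the consensus model."""

    tier: str
    compounds: dict[str, MatchedCompound]
    reactions: dict[str, MatchedReaction]

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")

    def validate(self) -> None:
        """Check referential integrity of all reactions."""
        for rxn in self.reactions.values():
            for cid, _ in (*rxn.substrates, *rxn.products):
                if cid not in self.compounds:
                    raise ValueError(
                        f"reaction {rxn.local_id} references unknown compound {cid}"
                    )


# ---------------------------------------------------------------------------
# stoichiometry strings
# ---------------------------------------------------------------------------


def _parse_coeff(tok: str) -> Fraction:
    try:
        return Fraction(tok)
    except (ValueError, ZeroDivisionError) as exc:
        raise ParseError(f"bad stoichiometric coefficient {tok!r}") from exc


def parse_stoichiometry_string(
    s: str,
) -> tuple[list[tuple[str, Fraction]], list[tuple[str, Fraction]]]:
    """Parse ``"1 A + 2 B = 1 C"`` into substrate and product lists.

    The dialect requires exactly one ``=`` and an explicit coefficient on
    every term, even when it is one.
    """
    if s.count("=") != 1:
        raise ParseError(f"stoichiometry string must contain exactly one '=': {s!r}")
    left, right = s.split("=")

    def parse_side(side: str) -> list[tuple[str, Fraction]]:
        out: list[tuple[str, Fraction]] = []
        for term in side.split("+"):
            parts = term.split()
            if len(parts) != 2:
                raise ParseError(
                    f"each term must be '<coefficient> <compound>': {term.strip()!r}"
                )
            coeff = _parse_coeff(parts[0])
            if coeff <= 0:
                raise ParseError(f"coefficient must be positive in {term.strip()!r}")
            out.append((parts[1], coeff))
        return out

    return parse_side(left), parse_side(right)


def format_stoichiometry(
    substrates: Iterable[tuple[str, Fraction]],
    products: Iterable[tuple[str, Fraction]],
) -> str:
    """Format both sides with explicit coefficients and the ``=`` separator."""

    def fmt(side: Iterable[tuple[str, Fraction]]) -> str:
        return " + ".join(f"{coeff} {cid}" for cid, coeff in side)

    return f"{fmt(substrates)} = {fmt(products)}"


# ---------------------------------------------------------------------------
# source-database dialect
# ---------------------------------------------------------------------------

_COMPOUND_HEADER = ["id", "names", "formula", "smiles", "xrefs", "generic"]
_REACTION_HEADER = ["id", "stoichiometry", "ec_numbers", "reversible", "pathways"]


def _read_tsv(path: Path, expected_header: list[str]) -> list[list[str]]:
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 or (not rows and fields[0] == expected_header[0]):
                if fields != expected_header:
                    raise ParseError(
                        f"{path}: expected header {expected_header}, got {fields}"
                    )
                continue
            if len(fields) != len(expected_header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(expected_header)} columns, "
                    f"got {len(fields)}"
                )
            rows.append(fields)
    return rows


def read_source_db(
    path: str | Path, db_label: SourceDB
) -> tuple[list[CompoundRecord], list[ReactionRecord]]:
    """Read ``compounds.tsv`` + ``reactions.tsv`` from a database directory.

    Raises :class:`ParseError` on malformed rows, duplicate identifiers or
    reactions referencing unknown compounds.
    """
    path = Path(path)
    compounds: list[CompoundRecord] = []
    seen: set[str] = set()
    for row in _read_tsv(path / "compounds.tsv", _COMPOUND_HEADER):
        cid, names, formula, smiles, xrefs, generic = row
        if cid in seen:
            raise ParseError(f"duplicate compound id {cid!r} in {path}")
        seen.add(cid)
        xref_map: dict[str, str] = {}
        for item in filter(None, xrefs.split(";")):
            if ":" not in item:
                raise ParseError(f"compound {cid}: malformed xref {item!r}")
            ns, ident = item.split(":", 1)
            xref_map[ns] = ident
        compounds.append(
            CompoundRecord(
                source_db=db_label,
                source_id=cid,
                names=tuple(filter(None, names.split("|"))),
                formula=parse_formula(formula),
                smiles=smiles or None,
                xrefs=xref_map,
                is_generic_class=generic == "1",
            )
        )

    reactions: list[ReactionRecord] = []
    seen_r: set[str] = set()
    for row in _read_tsv(path / "reactions.tsv", _REACTION_HEADER):
        rid, stoich, ecs, rev, tags = row
        if rid in seen_r:
            raise ParseError(f"duplicate reaction id {rid!r} in {path}")
        seen_r.add(rid)
        try:
            subs, prods = parse_stoichiometry_string(stoich)
        except ParseError as exc:
            raise ParseError(f"reaction {rid}: {exc}") from exc
        rxn = ReactionRecord(
            source_db=db_label,
            source_id=rid,
            substrates=tuple(subs),
            products=tuple(prods),
            ec_numbers=frozenset(filter(None, ecs.split(";"))),
            reversible=rev != "0",
            pathway_tags=frozenset(filter(None, tags.split("|"))),
        )
        dangling = sorted(rxn.participants - seen)
        if dangling:
            raise ParseError(
                f"reaction {rid} references unknown compound id(s): "
                + ", ".join(dangling)
            )
        reactions.append(rxn)
    return compounds, reactions


def write_source_db(
    path: str | Path,
    compounds: Sequence[CompoundRecord],
    reactions: Sequence[ReactionRecord],
    header_comment: str | None = None,
) -> None:
    """Write records back in the source dialect (loss-free round trip)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "compounds.tsv", "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(_COMPOUND_HEADER) + "\n")
        for c in compounds:
            fh.write(
                "\t".join(
                    [
                        c.source_id,
                        "|".join(c.names),
                        format_formula(c.formula),
                        c.smiles or "",
                        ";".join(f"{ns}:{i}" for ns, i in sorted(c.xrefs.items())),
                        "1" if c.is_generic_class else "0",
                    ]
                )
                + "\n"
            )
    with open(path / "reactions.tsv", "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(_REACTION_HEADER) + "\n")
        for r in reactions:
            fh.write(
                "\t".join(
                    [
                        r.source_id,
                        format_stoichiometry(r.substrates, r.products),
                        ";".join(sorted(r.ec_numbers)),
                        "1" if r.reversible else "0",
                        "|".join(sorted(r.pathway_tags)),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# reconstruction dialect
# ---------------------------------------------------------------------------

_RECON_COMPOUND_HEADER = [
    "local_id",
    "id_in_A",
    "name_in_A",
    "id_in_B",
    "name_in_B",
    "evidence",
    "name_probability",
    "structure_tier",
]
_RECON_REACTION_HEADER = [
    "local_id",
    "id_in_A",
    "id_in_B",
    "stoichiometry",
    "ec_numbers",
    "reversible",
]


def write_reconstruction_tsv(recon: Reconstruction, path: str | Path) -> None:
    """Write a reconstruction as two TSV files, rows sorted by local id."""
    recon.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "compounds.tsv", "w", encoding="utf-8") as fh:
        fh.write("\t".join(_RECON_COMPOUND_HEADER) + "\n")
        for lid in sorted(recon.compounds):
            c = recon.compounds[lid]
            fh.write(
                "\t".join(
                    [
                        c.local_id,
                        c.id_in_A or "",
                        c.name_in_A or "",
                        c.id_in_B or "",
                        c.name_in_B or "",
                        c.evidence or "",
                        "" if c.name_probability is None else repr(c.name_probability),
                        c.structure_tier or "",
                    ]
                )
                + "\n"
            )
    with open(path / "reactions.tsv", "w", encoding="utf-8") as fh:
        fh.write("\t".join(_RECON_REACTION_HEADER) + "\n")
        for lid in sorted(recon.reactions):
            r = recon.reactions[lid]
            fh.write(
                "\t".join(
                    [
                        r.local_id,
                        r.id_in_A or "",
                        r.id_in_B or "",
                        format_stoichiometry(r.substrates, r.products),
                        ";".join(sorted(r.ec_numbers)),
                        "1" if r.reversible else "0",
                    ]
                )
                + "\n"
            )


def read_reconstruction_tsv(path: str | Path, tier: str = "core") -> Reconstruction:
    """Read a reconstruction written by :func:`write_reconstruction_tsv`."""
    path = Path(path)
    compounds: dict[str, MatchedCompound] = {}
    for row in _read_tsv(path / "compounds.tsv", _RECON_COMPOUND_HEADER):
        lid, id_a, name_a, id_b, name_b, evidence, prob, stier = row
        compounds[lid] = MatchedCompound(
            local_id=lid,
            id_in_A=id_a or None,
            id_in_B=id_b or None,
            name_in_A=name_a or None,
            name_in_B=name_b or None,
            evidence=evidence or None,
            name_probability=float(prob) if prob else None,
            structure_tier=stier or None,
        )
    reactions: dict[str, MatchedReaction] = {}
    for row in _read_tsv(path / "reactions.tsv", _RECON_REACTION_HEADER):
        lid, id_a, id_b, stoich, ecs, rev = row
        subs, prods = parse_stoichiometry_string(stoich)
        reactions[lid] = MatchedReaction(
            local_id=lid,
            substrates=tuple(subs),
            products=tuple(prods),
            id_in_A=id_a or None,
            id_in_B=id_b or None,
            ec_numbers=frozenset(filter(None, ecs.split(";"))),
            reversible=rev != "0",
        )
    recon = Reconstruction(tier=tier, compounds=compounds, reactions=reactions)
    recon.validate()
    return recon


def check_tier_nesting(
    core: Reconstruction, intermediate: Reconstruction, complete: Reconstruction
) -> None:
    """Assert core ⊆ intermediate ⊆ complete for compounds and reactions."""
    for inner, outer in ((core, intermediate), (intermediate, complete)):
        for kind in ("compounds", "reactions"):
            inner_ids = set(getattr(inner, kind))
            outer_ids = set(getattr(outer, kind))
            if not inner_ids <= outer_ids:
                missing = sorted(inner_ids - outer_ids)[:5]
                raise ValueError(
                    f"tier nesting violated for {kind}: {inner.tier} ⊄ {outer.tier} "
                    f"(e.g. {missing})"
                )


# ---------------------------------------------------------------------------
# SBML (Level 3 Version 1, MIRIAM-style annotations)
# ---------------------------------------------------------------------------

# identifiers.org collection per xref namespace
_MIRIAM_COLLECTIONS = {
    "KEGG": "kegg.compound",
    "ChEBI": "CHEBI",
    "CAS": "cas",
    "PubChem": "pubchem.compound",
    "InChI": "inchi",
    "EC": "ec-code",
    "gene": "tair.gene",
}

_SID_OK = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def sanitize_sid(raw: str) -> str:
    """Reversibly escape a string into a valid SBML SId.

    Identifiers that are already valid SIds (and cannot be mistaken for an
    escaped form) pass through unchanged.  Anything else becomes ``s_`` plus
    the original with every non-alphanumeric character escaped as
    ``_x<hex>_``.  :func:`unsanitize_sid` inverts the escaping.
    """
    if _SID_OK.match(raw) and "_x" not in raw and not raw.startswith("s_"):
        return raw
    body = "".join(
        ch if ("a" <= ch <= "z" or "A" <= ch <= "Z" or "0" <= ch <= "9")
        else f"_x{ord(ch):x}_"
        for ch in raw
    )
    sid = "s_" + body
    log.warning("sanitized identifier %r -> %r", raw, sid)
    return sid


def unsanitize_sid(sid: str) -> str:
    if not sid.startswith("s_"):
        return sid
    return re.sub(r"_x([0-9a-f]+)_", lambda m: chr(int(m.group(1), 16)), sid[2:])


def write_sbml(
    recon: Reconstruction,
    path: str | Path,
    annotations: Mapping[str, Sequence[tuple[str, str]]] | None = None,
    model_id: str = "consensus_model",
) -> None:
    """Write the reconstruction as annotated SBML L3V1.

    ``annotations`` maps a local id to ``(namespace, identifier)`` pairs;
    each becomes a MIRIAM ``bqbiol:is`` controlled-vocabulary term.  Species
    get SBO:0000247 (simple chemical), reactions SBO:0000176 (biochemical
    reaction).
    """
    import libsbml

    recon.validate()
    annotations = annotations or {}
    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId(sanitize_sid(model_id))
    model.setMetaId(f"meta_{sanitize_sid(model_id)}")
    comp = model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)

    def add_cv_terms(element, local_id: str) -> None:
        for ns, ident in annotations.get(local_id, ()):  # MIRIAM bqbiol:is
            collection = _MIRIAM_COLLECTIONS.get(ns, ns)
            cv = libsbml.CVTerm()
            cv.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
            cv.setBiologicalQualifierType(libsbml.BQB_IS)
            cv.addResource(f"https://identifiers.org/{collection}:{ident}")
            element.addCVTerm(cv)

    for lid in sorted(recon.compounds):
        c = recon.compounds[lid]
        sp = model.createSpecies()
        sid = sanitize_sid(lid)
        sp.setId(sid)
        sp.setMetaId(f"meta_{sid}")
        sp.setName(c.name_in_A or c.name_in_B or lid)
        sp.setCompartment("c")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sp.setSBOTerm("SBO:0000247")
        add_cv_terms(sp, lid)

    for lid in sorted(recon.reactions):
        r = recon.reactions[lid]
        rx = model.createReaction()
        sid = sanitize_sid(lid)
        rx.setId(sid)
        rx.setMetaId(f"meta_{sid}")
        rx.setReversible(r.reversible)
        rx.setFast(False)
        rx.setSBOTerm("SBO:0000176")
        add_cv_terms(rx, lid)
        for cid, coeff in r.substrates:
            ref = rx.createReactant()
            ref.setSpecies(sanitize_sid(cid))
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
        for cid, coeff in r.products:
            ref = rx.createProduct()
            ref.setSpecies(sanitize_sid(cid))
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)

    libsbml.writeSBMLToFile(doc, str(path))


def read_sbml(path: str | Path, tier: str = "core") -> Reconstruction:
    """Read an SBML file back into a Reconstruction (stoichiometry only)."""
    import libsbml

    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ParseError(f"SBML read errors in {path}")
    model = doc.getModel()
    compounds: dict[str, MatchedCompound] = {}
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        lid = unsanitize_sid(sp.getId())
        compounds[lid] = MatchedCompound(
            local_id=lid, id_in_A=lid, name_in_A=sp.getName() or None
        )
    reactions: dict[str, MatchedReaction] = {}
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        lid = unsanitize_sid(rx.getId())

        def side(refs) -> tuple[tuple[str, Fraction], ...]:
            out = []
            for j in range(refs.size()):
                ref = refs.get(j)
                out.append(
                    (
                        unsanitize_sid(ref.getSpecies()),
                        Fraction(ref.getStoichiometry()).limit_denominator(10**6),
                    )
                )
            return tuple(out)

        reactions[lid] = MatchedReaction(
            local_id=lid,
            substrates=side(rx.getListOfReactants()),
            products=side(rx.getListOfProducts()),
            id_in_A=lid,
            reversible=rx.getReversible(),
        )
    return Reconstruction(tier=tier, compounds=compounds, reactions=reactions)


def validate_sbml(path: str | Path) -> int:
    """Return the number of SBML consistency *errors* (warnings ignored)."""
    import libsbml

    doc = libsbml.readSBML(str(path))
    doc.checkConsistency()
    return sum(
        1
        for i in range(doc.getNumErrors())
        if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
    )


# ---------------------------------------------------------------------------
# graph exchange
# ---------------------------------------------------------------------------


def write_graph_export(graph, path: str | Path, format: str = "graphml") -> None:
    """Export a metabolic graph as GraphML or SIF.

    Node tier colors (yellow/green/blue) and self-loops are preserved.  The
    ``graph`` argument is either a :class:`topology.MetabolicGraph` or a bare
    :class:`networkx.Graph`.
    """
    import networkx as nx

    g = getattr(graph, "g", graph)
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g, path, named_key_ids=True)
    elif format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in sorted(tuple(sorted((str(a), str(b)))) for a, b in g.edges()):
                fh.write(f"{u}\trr\t{v}\n")
            for node in sorted(nx.isolates(g)):
                fh.write(f"{node}\n")
    else:
        raise ValueError(f"unknown graph export format {format!r}")


def read_graphml(path: str | Path):
    import networkx as nx

    return nx.read_graphml(path)
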