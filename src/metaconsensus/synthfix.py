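"""Deterministic generators of paired synthetic databases with ground truth.

``generate`` builds two overlapping views of one hidden reaction network and
plants the discrepancy classes seen when merging real metabolic databases:
synonym rewrites ("-ic acid" vs "-ate", Greek-letter spellings), proton-count
differences in formulas and free H⁺ in reaction sides, cofactor swaps
(ATP/ADP → GTP/GDP variants present in one source only), generic compound
classes, structure errors (a deleted heavy atom), and one-source-only
reactions.  Every shared compound is assigned a hidden positive mass (its
heavy-atom count) and every shared reaction conserves it, so the recovered
core network is stoichiometrically consistent by construction.

``tca_fixture`` hard-codes a two-database encoding of the tricarboxylic-acid
and glyoxylate cycles with the three classic disagreement cases (generic vs
specific ubiquinone, lumped vs three-step 2-oxoglutarate→succinyl-CoA, a
one-source oxalosuccinate route).  ``showcase_fixture`` encodes six small
example reactions covering each confidence-tier attribution case.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

from rdkit import Chem

from .model_io import CompoundRecord, ReactionRecord

ONE = Fraction(1)
TWO = Fraction(2)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the synthetic database pair."""

    n_shared_reactions: int = 30
    n_only_A: int = 4
    n_only_B: int = 4
    synonym_perturbation_rate: float = 0.2
    proton_discrepancy_rate: float = 0.15
    cofactor_swap_rate: float = 0.1
    generic_class_rate: float = 0.1
    structure_error_rate: float = 0.05
    xref_fraction: float = 0.5
    seed: int = 42

    def __post_init__(self) -> None:
        for name in (
            "synonym_perturbation_rate",
            "proton_discrepancy_rate",
            "cofactor_swap_rate",
            "generic_class_rate",
            "structure_error_rate",
            "xref_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_shared_reactions < 1:
            raise ValueError("n_shared_reactions must be positive")
        if min(self.n_only_A, self.n_only_B) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class GroundTruth:
    """Planted identities and expected tier attributions."""

    compound_pairs: set[tuple[str, str]] = field(default_factory=set)
    reaction_pairs: set[tuple[str, str]] = field(default_factory=set)
    expected_tier: dict[tuple[str, str], str] = field(default_factory=dict)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("kind\tid_A\tid_B\ttier\n")
            for a, b in sorted(self.compound_pairs):
                fh.write(f"compound\t{a}\t{b}\t\n")
            for a, b in sorted(self.reaction_pairs):
                fh.write(f"reaction\t{a}\t{b}\t\n")
            for (db, rid), tier in sorted(self.expected_tier.items()):
                fh.write(f"tier\t{db}\t{rid}\t{tier}\n")


# ---------------------------------------------------------------------------
# template molecules (real small-molecule SMILES; masses = heavy-atom counts)
# ---------------------------------------------------------------------------

# (stem, smiles, extra synonyms) — stems get the systematic "-ate"/"-ic acid"
# synonym treatment where chemically idiomatic; extras are kept to
# transformations the classifier is meant to learn (no free-form aliases,
# which would plant unlearnable positives in the training corpus)
TEMPLATES: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    ("pyruv", "CC(=O)C(=O)O", ()),
    ("lact", "CC(O)C(=O)O", ()),
    ("acet", "CC(=O)O", ()),
    ("succin", "OC(=O)CCC(=O)O", ()),
    ("fumar", "OC(=O)/C=C/C(=O)O", ()),
    ("mal", "OC(=O)CC(O)C(=O)O", ()),
    ("citr", "OC(=O)CC(O)(CC(=O)O)C(=O)O", ()),
    ("oxaloacet", "OC(=O)CC(=O)C(=O)O", ()),
    ("glutam", "NC(CCC(=O)O)C(=O)O", ()),
    ("aspart", "NC(CC(=O)O)C(=O)O", ()),
    ("benzo", "OC(=O)c1ccccc1", ()),
    ("shikim", "OC1CC(=CC(O)C1O)C(=O)O", ()),
    ("glycol", "OCC(=O)O", ()),
    ("oxal", "OC(=O)C(=O)O", ()),
    ("glycer", "OCC(O)CO", ()),
    ("ethanol", "CCO", ("ethyl alcohol",)),
    ("glucose", "OCC1OC(O)C(O)C(O)C1O", ()),
    ("serine", "NC(CO)C(=O)O", ()),
    ("alanine", "CC(N)C(=O)O", ()),
    ("glycine", "NCC(=O)O", ()),
)

COFACTORS: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    # (name, smiles, synonyms); ATP/ADP and GTP/GDP carry real structures so
    # that the hidden masses (heavy-atom counts) are well defined; the spelled
    # -out synonyms exercise the acronym feature the way real lists do
    ("ATP", "Nc1ncnc2c1ncn2C1OC(COP(=O)(O)OP(=O)(O)OP(=O)(O)O)C(O)C1O",
     ("adenosine triphosphate",)),
    ("ADP", "Nc1ncnc2c1ncn2C1OC(COP(=O)(O)OP(=O)(O)O)C(O)C1O",
     ("adenosine diphosphate",)),
    ("GTP", "Nc1nc2c(ncn2C2OC(COP(=O)(O)OP(=O)(O)OP(=O)(O)O)C(O)C2O)c(=O)[nH]1",
     ("guanosine triphosphate",)),
    ("GDP", "Nc1nc2c(ncn2C2OC(COP(=O)(O)OP(=O)(O)O)C(O)C2O)c(=O)[nH]1",
     ("guanosine diphosphate",)),
)

_SYLLABLES = (
    "ba do fi lu mer nat pyr quo rel sta tov xan zym cor del gan hes "
    "jor kel lom nid pol ril sem tur vos wex"
).split()


def _heavy_atoms(smiles: str) -> int:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"template SMILES invalid: {smiles!r}")
    return mol.GetNumHeavyAtoms()


def _formula_of(smiles: str) -> dict[str, int]:
    from .model_io import parse_formula

    mol = Chem.MolFromSmiles(smiles)
    from rdkit.Chem.rdMolDescriptors import CalcMolFormula

    raw = CalcMolFormula(mol)
    return parse_formula(raw.replace("+", "").replace("-", ""))


@dataclass
class _Compound:
    """Mutable working record for one hidden compound."""

    key: str
    stem: str
    smiles: str | None
    mass: int
    synonyms: list[str]
    is_cofactor: bool = False
    has_xref: bool = False
    perturbed: bool = False
    rewrite: str = ""  # suffix | greek | locant, set when perturbed
    struct_error: bool = False


def _synonym_family(stem: str, extra: tuple[str, ...] = ()) -> list[str]:
    if stem[-1] in "aeiou" or stem in ("ethanol", "glucose", "serine", "alanine", "glycine"):
        return [stem, *extra]
    return [
        stem + "ate",
        stem + "ic acid",
        "alpha-" + stem + "ate",
        "alpha-" + stem + "ic acid",
        *extra,
    ]


def _fresh_molecule(mass: int, rng: random.Random, used: set[str]) -> str:
    """A structurally valid, previously unused SMILES with `mass` heavy atoms."""
    singles = ["O", "N", "S", "P", "C"]
    for _ in range(500):
        if mass <= 1:
            cand = rng.choice(singles)
        else:
            atoms = ["C"] * mass
            for _ in range(rng.randint(1, max(1, mass // 2))):
                atoms[rng.randrange(mass)] = rng.choice("CCONS")
            cand = "".join(atoms)
            if mass >= 4 and rng.random() < 0.3:
                i = rng.randrange(1, mass - 1)
                cand = cand[:i] + "(" + cand[i] + ")" + cand[i + 1 :]
        mol = Chem.MolFromSmiles(cand)
        if mol is None or mol.GetNumHeavyAtoms() != mass:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical not in used:
            used.add(canonical)
            return canonical
    raise RuntimeError(f"could not generate a fresh molecule of {mass} heavy atoms")


def _fresh_stem(rng: random.Random, used: set[str]) -> str:
    while True:
        stem = "".join(rng.choice(_SYLLABLES) for _ in range(3))
        if stem not in used:
            used.add(stem)
            return stem


def _delete_terminal_atom(smiles: str) -> str | None:
    """Drop one degree-1 heavy atom (a planted 'missing functional group')."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumHeavyAtoms() < 3:
        return None
    rw = Chem.RWMol(mol)
    for atom in rw.GetAtoms():
        if atom.GetDegree() == 1:
            rw.RemoveAtom(atom.GetIdx())
            try:
                out = rw.GetMol()
                Chem.SanitizeMol(out)
                return Chem.MolToSmiles(out)
            except Exception:
                return None
    return None


def _styled_family(stem: str, rng: random.Random, used_stems: set[str]) -> list[str]:
    """Draw a synonym family in one of the styles seen in real databases."""
    style = rng.random()
    if style < 0.3:
        # locant-style family, as in real phosphate-ester synonym lists
        # ("D-glucose 6-phosphate" / "6-phospho-D-glucose")
        k = rng.choice((2, 3, 6))
        return [
            f"{stem}ate {k}-phosphate",
            f"{k}-phospho-{stem}ate",
            f"{stem}ic acid {k}-phosphate",
            f"{k}-phospho-{stem}ic acid",
        ]
    if style < 0.45:
        # O-ester style, as in "5-O-caffeoylshikimic acid" vs
        # "caffeoylshikimate": locant prefix dropped with suffix rewrite
        k = rng.choice((3, 5))
        return [
            f"{k}-o-{stem}ic acid",
            f"{stem}ate",
            f"{k}-o-{stem}ate",
            f"{stem}ic acid",
        ]
    if style < 0.55:
        # acronym style, as in "ATP" vs "adenosine triphosphate"
        other = _fresh_stem(rng, used_stems)
        acr = (stem[0] + other[0] + "p").upper()
        return [
            f"{stem} {other} phosphate",
            acr,
            f"{stem}-{other} phosphate",
            f"{stem} {other}phosphate",
        ]
    return _synonym_family(stem)


def synonym_corpus(n_compounds: int = 300, seed: int = 0) -> list[CompoundRecord]:
    """A compound list for training the name model at realistic corpus size.

    The integration pipeline trains on the input databases themselves; those
    hold thousands of compounds in practice.  This fixture reproduces that
    scale: each record carries a full synonym family in one of the styles
    drawn by :func:`_styled_family`, plus a synthetic formula so that
    formula-discordant negative pairs can be sampled.
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be positive")
    rng = random.Random(seed)
    used_stems: set[str] = set()
    records: list[CompoundRecord] = []
    for stem, _, extra in TEMPLATES:
        used_stems.add(stem)
        records.append(
            CompoundRecord(
                source_db="A",
                source_id=f"T{len(records):05d}",
                names=tuple(_synonym_family(stem, extra)),
                formula={"C": rng.randint(2, 20), "H": 2, "O": rng.randint(1, 8)},
            )
        )
    for name, _, syns in COFACTORS:
        records.append(
            CompoundRecord(
                source_db="A",
                source_id=f"T{len(records):05d}",
                names=(name, *syns),
                formula={"C": 10, "H": 16, "N": 5, "O": len(records), "P": 3},
            )
        )
    while len(records) < n_compounds + len(TEMPLATES) + len(COFACTORS):
        stem = _fresh_stem(rng, used_stems)
        records.append(
            CompoundRecord(
                source_db="A",
                source_id=f"T{len(records):05d}",
                names=tuple(_styled_family(stem, rng, used_stems)),
                formula={"C": rng.randint(2, 30), "H": 2, "O": rng.randint(1, 10)},
            )
        )
    return records


def generate(
    spec: FixtureSpec,
) -> tuple[
    tuple[list[CompoundRecord], list[ReactionRecord]],
    tuple[list[CompoundRecord], list[ReactionRecord]],
    GroundTruth,
]:
    """Generate the two database views and the planted ground truth."""
    rng = random.Random(spec.seed)
    used_smiles: set[str] = set()
    used_stems: set[str] = set()

    pool: list[_Compound] = []
    for idx, (stem, smiles, extra) in enumerate(TEMPLATES):
        canonical = Chem.MolToSmiles(Chem.MolFromSmiles(smiles))
        used_smiles.add(canonical)
        used_stems.add(stem)
        pool.append(
            _Compound(
                key=f"c{idx:03d}",
                stem=stem,
                smiles=canonical,
                mass=_heavy_atoms(canonical),
                synonyms=_synonym_family(stem, extra),
            )
        )
    for name, smiles, extra in COFACTORS:
        canonical = Chem.MolToSmiles(Chem.MolFromSmiles(smiles))
        used_smiles.add(canonical)
        pool.append(
            _Compound(
                key=f"cof_{name}",
                stem=name,
                smiles=canonical,
                mass=_heavy_atoms(canonical),
                synonyms=[name, *extra],
                is_cofactor=True,
                has_xref=True,
            )
        )
    by_key = {c.key: c for c in pool}

    def new_compound(mass: int) -> _Compound:
        stem = _fresh_stem(rng, used_stems)
        synonyms = _styled_family(stem, rng, used_stems)
        comp = _Compound(
            key=f"c{len(pool):03d}",
            stem=stem,
            smiles=_fresh_molecule(mass, rng, used_smiles),
            mass=mass,
            synonyms=synonyms,
        )
        pool.append(comp)
        by_key[comp.key] = comp
        return comp

    # -- hidden shared reactions (mass-conserving by construction) ----------
    atp, adp = by_key["cof_ATP"], by_key["cof_ADP"]
    gtp, gdp = by_key["cof_GTP"], by_key["cof_GDP"]
    shared_reactions: list[dict] = []
    for j in range(spec.n_shared_reactions):
        metabolic = [c for c in pool if not c.is_cofactor]
        if rng.random() < 0.25:
            # phosphoryl transfer: ATP + s -> ADP + p, masses balance via
            # the 4-heavy-atom phosphoryl difference
            s = rng.choice(metabolic)
            delta = atp.mass - adp.mass
            candidates = [
                c for c in metabolic if c.mass == s.mass + delta and c is not s
            ]
            p = candidates[0] if candidates else new_compound(s.mass + delta)
            subs, prods = [(atp.key, ONE), (s.key, ONE)], [(adp.key, ONE), (p.key, ONE)]
        else:
            s1, s2 = rng.sample(metabolic, 2)
            total = s1.mass + s2.mass
            pair = None
            shuffled = metabolic[:]
            rng.shuffle(shuffled)
            for a in shuffled:
                for b in shuffled:
                    if (
                        a is not b
                        and a not in (s1, s2)
                        and b not in (s1, s2)
                        and a.mass + b.mass == total
                    ):
                        pair = (a, b)
                        break
                if pair:
                    break
            if pair is None:
                splittable = [c for c in metabolic if 1 < c.mass < total - 1 and c not in (s1, s2)]
                p1 = rng.choice(splittable) if splittable else new_compound(max(2, total // 2))
                p2 = new_compound(total - p1.mass)
                pair = (p1, p2)
            subs = [(s1.key, ONE), (s2.key, ONE)]
            prods = [(pair[0].key, ONE), (pair[1].key, ONE)]
        shared_reactions.append(
            {
                "key": f"r{j:03d}",
                "substrates": subs,
                "products": prods,
                "ec": f"{1 + j % 6}.{1 + j % 7}.{1 + j % 9}.{j + 1}",
                "pathway": f"pathway{j % 4}",
            }
        )

    # -- choose xrefs, then perturbations ----------------------------------
    for c in pool:
        if not c.is_cofactor:
            c.has_xref = rng.random() < spec.xref_fraction

    participants: dict[str, list[dict]] = {}
    for rxn in shared_reactions:
        for key, _ in rxn["substrates"] + rxn["products"]:
            participants.setdefault(key, []).append(rxn)

    def has_clean_reaction(c: _Compound) -> bool:
        for rxn in participants.get(c.key, ()):  # a reaction can recover c
            others = [
                by_key[k]
                for k, _ in rxn["substrates"] + rxn["products"]
                if k != c.key
            ]
            if all(not o.perturbed for o in others):
                return True
        return False

    order = [c for c in pool if not c.is_cofactor and c.key in participants]
    rng.shuffle(order)
    for c in order:
        if rng.random() >= spec.synonym_perturbation_rate:
            continue
        c.perturbed = True
        # the engine can only re-derive c through a reaction whose other
        # participants are matchable; revert the perturbation otherwise
        if not (has_clean_reaction(c) and all(has_clean_reaction(o) for o in order if o.perturbed)):
            c.perturbed = False
            continue
        c.has_xref = False
        # rewrite classes mirror how real databases actually disagree on
        # names, restricted to what the compound's synonym family supports
        classes = ["greek"]
        if len(c.synonyms) >= 2 and c.synonyms[1] == c.stem + "ic acid":
            classes.append("suffix")
        if len(c.synonyms) >= 2 and c.synonyms[1].startswith(("2-", "3-", "6-")):
            classes.append("locant")
        c.rewrite = rng.choice(sorted(classes))

    for c in pool:
        if (
            not c.is_cofactor
            and not c.perturbed
            and (c.has_xref or True)  # seeded via xref or shared synonym
            and c.smiles
            and rng.random() < spec.structure_error_rate
        ):
            c.struct_error = True

    # -- emit the two views -------------------------------------------------
    id_a = {c.key: f"C{100 + i:05d}" for i, c in enumerate(pool)}
    id_b = {c.key: f"CPD-{200 + i}" for i, c in enumerate(pool)}
    truth = GroundTruth()

    compounds_a: list[CompoundRecord] = []
    compounds_b: list[CompoundRecord] = []
    proton_b = CompoundRecord(
        source_db="B",
        source_id="CPD-PROTON",
        names=("H+", "proton"),
        formula={"H": 1},
    )
    for c in pool:
        formula = _formula_of(c.smiles) if c.smiles else {}
        if c.perturbed:
            base = c.synonyms[0]
            if c.rewrite == "suffix":
                # each side still lists its own variants (real entries carry
                # several names even when the two databases disagree), but the
                # normalized name sets stay disjoint across the databases
                names_a = [c.stem + "ate", "alpha-" + c.stem + "ate"]
                names_b = [c.stem + "ic acid", "alpha-" + c.stem + "ic acid"]
            elif c.rewrite == "greek":
                names_a, names_b = ["alpha-" + base], ["α-" + base]
            else:  # locant reordering, the two orderings of the family
                names_a = [s for s in c.synonyms if not s.split(" ")[0][0].isdigit()]
                names_b = [s for s in c.synonyms if s.split(" ")[0][0].isdigit()]
        else:
            names_a = c.synonyms[: max(1, len(c.synonyms) - 1)]
            names_b = c.synonyms[:]
        smiles_b = c.smiles
        formula_b = dict(formula)
        if c.struct_error and c.smiles:
            damaged = _delete_terminal_atom(c.smiles)
            if damaged:
                smiles_b = damaged
                formula_b = _formula_of(damaged)
        elif formula_b.get("H") and rng.random() < spec.proton_discrepancy_rate:
            formula_b["H"] += rng.choice((-1, 1))
        compounds_a.append(
            CompoundRecord(
                source_db="A",
                source_id=id_a[c.key],
                names=tuple(names_a),
                formula=formula,
                smiles=c.smiles,
                xrefs={},
            )
        )
        compounds_b.append(
            CompoundRecord(
                source_db="B",
                source_id=id_b[c.key],
                names=tuple(names_b),
                formula=formula_b,
                smiles=smiles_b,
                xrefs={"KEGG": id_a[c.key]} if c.has_xref else {},
            )
        )
        truth.compound_pairs.add((id_a[c.key], id_b[c.key]))
    compounds_b.append(proton_b)

    reactions_a: list[ReactionRecord] = []
    reactions_b: list[ReactionRecord] = []

    def emit_shared(rxn: dict) -> None:
        rid_a, rid_b = f"R{int(rxn['key'][1:]) + 1:05d}", f"RXN-{rxn['key'][1:]}"
        subs_a = tuple((id_a[k], c) for k, c in rxn["substrates"])
        prods_a = tuple((id_a[k], c) for k, c in rxn["products"])
        subs_b = [(id_b[k], c) for k, c in rxn["substrates"]]
        prods_b = [(id_b[k], c) for k, c in rxn["products"]]
        if rng.random() < spec.proton_discrepancy_rate:
            prods_b.append(("CPD-PROTON", ONE))  # B writes out a free proton
        common = dict(
            ec_numbers=frozenset({rxn["ec"]}),
            reversible=True,
            pathway_tags=frozenset({rxn["pathway"]}),
        )
        reactions_a.append(
            ReactionRecord("A", rid_a, subs_a, prods_a, **common)
        )
        reactions_b.append(
            ReactionRecord("B", rid_b, tuple(subs_b), tuple(prods_b), **common)
        )
        truth.reaction_pairs.add((rid_a, rid_b))
        truth.expected_tier[("A", rid_a)] = "core"
        truth.expected_tier[("B", rid_b)] = "core"

    for rxn in shared_reactions:
        emit_shared(rxn)

    # cofactor-swap variants, present in A only, anchored entirely in shared
    # compounds -> expected intermediate
    atp_reactions = [
        r
        for r in shared_reactions
        if ("cof_ATP", ONE) in r["substrates"]
        and all(not by_key[k].perturbed for k, _ in r["substrates"] + r["products"])
    ]
    n_swaps = round(spec.cofactor_swap_rate * spec.n_shared_reactions)
    for i, base in enumerate(atp_reactions[:n_swaps]):
        rid = f"R9{i:04d}"
        subs = tuple(
            (id_a["cof_GTP"] if k == "cof_ATP" else id_a[k], c)
            for k, c in base["substrates"]
        )
        prods = tuple(
            (id_a["cof_GDP"] if k == "cof_ADP" else id_a[k], c)
            for k, c in base["products"]
        )
        reactions_a.append(
            ReactionRecord(
                "A", rid, subs, prods, ec_numbers=frozenset({base["ec"]})
            )
        )
        truth.expected_tier[("A", rid)] = "intermediate"

    # one-source-only reactions: alternately anchored (full substrate side of
    # shared, matchable compounds -> intermediate) and detached (fresh
    # compounds on both sides -> complete)
    clean = [c for c in pool if not c.is_cofactor and not c.perturbed]

    def one_source(
        db: str,
        count: int,
        compounds_out: list[CompoundRecord],
        reactions_out: list[ReactionRecord],
        ids: dict[str, str],
    ) -> None:
        for i in range(count):
            rid = f"{'RA' if db == 'A' else 'RB'}{i:04d}"
            ec = frozenset({f"9.9.{1 if db == 'A' else 2}.{i + 1}"})
            if i % 2 == 0:  # anchored
                s1, s2 = rng.sample(clean, 2)
                stem = _fresh_stem(rng, used_stems)
                new_id = f"{'X' if db == 'A' else 'Y'}{i:04d}"
                compounds_out.append(
                    CompoundRecord(
                        source_db=db,
                        source_id=new_id,
                        names=(stem + "ate",),
                        smiles=_fresh_molecule(s1.mass + s2.mass, rng, used_smiles),
                    )
                )
                reactions_out.append(
                    ReactionRecord(
                        db,
                        rid,
                        ((ids[s1.key], ONE), (ids[s2.key], ONE)),
                        ((new_id, ONE),),
                        ec_numbers=ec,
                    )
                )
                truth.expected_tier[(db, rid)] = "intermediate"
            else:  # detached
                new_ids = []
                for j in range(2):
                    stem = _fresh_stem(rng, used_stems)
                    nid = f"{'X' if db == 'A' else 'Y'}{i:04d}_{j}"
                    compounds_out.append(
                        CompoundRecord(
                            source_db=db,
                            source_id=nid,
                            names=(stem + "ate",),
                            smiles=_fresh_molecule(4 + j, rng, used_smiles),
                        )
                    )
                    new_ids.append(nid)
                reactions_out.append(
                    ReactionRecord(
                        db,
                        rid,
                        ((new_ids[0], ONE),),
                        ((new_ids[1], ONE),),
                        ec_numbers=ec,
                    )
                )
                truth.expected_tier[(db, rid)] = "complete"

    one_source("A", spec.n_only_A, compounds_a, reactions_a, id_a)
    one_source("B", spec.n_only_B, compounds_b, reactions_b, id_b)

    # generic-class reactions, one source only -> complete
    n_generic = round(spec.generic_class_rate * spec.n_shared_reactions)
    for i in range(n_generic):
        gid1, gid2 = f"GEN-{2 * i}", f"GEN-{2 * i + 1}"
        compounds_b.append(
            CompoundRecord(
                source_db="B", source_id=gid1, names=(f"an alcohol ({i})",),
                is_generic_class=True,
            )
        )
        compounds_b.append(
            CompoundRecord(
                source_db="B", source_id=gid2, names=(f"an aldehyde ({i})",),
                is_generic_class=True,
            )
        )
        rid = f"RGEN-{i}"
        reactions_b.append(
            ReactionRecord(
                "B",
                rid,
                ((gid1, ONE),),
                ((gid2, ONE),),
                ec_numbers=frozenset({"1.1.1.-"}),
            )
        )
        truth.expected_tier[("B", rid)] = "complete"

    return (compounds_a, reactions_a), (compounds_b, reactions_b), truth


# ---------------------------------------------------------------------------
# hard-coded fixtures
# ---------------------------------------------------------------------------


def _c(db: str, cid: str, names: tuple[str, ...], formula: str = "",
       xref: str | None = None, generic: bool = False) -> CompoundRecord:
    from .model_io import parse_formula

    return CompoundRecord(
        source_db=db,
        source_id=cid,
        names=names,
        formula=parse_formula(formula),
        xrefs={"KEGG": xref} if xref else {},
        is_generic_class=generic,
    )


def _r(db: str, rid: str, subs, prods, ec: str) -> ReactionRecord:
    return ReactionRecord(
        db,
        rid,
        tuple((c, Fraction(k)) for c, k in subs),
        tuple((c, Fraction(k)) for c, k in prods),
        ec_numbers=frozenset({ec}),
    )


def tca_fixture() -> tuple[
    tuple[list[CompoundRecord], list[ReactionRecord]],
    tuple[list[CompoundRecord], list[ReactionRecord]],
    GroundTruth,
]:
    """Two-database encoding of the TCA and glyoxylate cycles.

    Database A plays the KEGG role (protons written out, generic ubiquinone
    classes, the three-step 2-oxoglutarate→succinyl-CoA route and the
    oxalosuccinate route); database B plays the AraCyc role (no protons,
    specific ubiquinone-8, the direct ketoglutarate-dehydrogenase reaction).
    """
    shared = [
        # (A id, B id, names, formula)
        ("C00001", "WATER", ("water", "H2O"), "H2O"),
        ("C00042", "SUC", ("succinate",), "C4H6O4"),
        ("C00122", "FUM", ("fumarate",), "C4H4O4"),
        ("C00149", "MAL", ("malate", "(S)-malate"), "C4H6O5"),
        ("C00003", "NAD", ("NAD+", "NAD"), "C21H27N7O14P2"),
        ("C00004", "NADH", ("NADH",), "C21H29N7O14P2"),
        ("C00036", "OAA", ("oxaloacetate",), "C4H4O5"),
        ("C00024", "ACCOA", ("acetyl-CoA",), "C23H38N7O17P3S"),
        ("C00010", "COA", ("CoA", "coenzyme A"), "C21H36N7O16P3S"),
        ("C00158", "CIT", ("citrate",), "C6H8O7"),
        ("C00417", "ACON", ("cis-aconitate",), "C6H6O6"),
        ("C00311", "ICIT", ("isocitrate",), "C6H8O7"),
        ("C00048", "GLX", ("glyoxylate",), "C2H2O3"),
        ("C00026", "AKG", ("2-oxoglutarate", "alpha-ketoglutarate"), "C5H6O5"),
        ("C00011", "CO2", ("CO2", "carbon dioxide"), "CO2"),
        ("C00091", "SUCCOA", ("succinyl-CoA",), "C25H40N7O19P3S"),
        ("C00008", "ADPC", ("ADP",), "C10H15N5O10P2"),
        ("C00002", "ATPC", ("ATP",), "C10H16N5O13P3"),
        ("C00009", "PI", ("orthophosphate", "phosphate"), "H3PO4"),
        ("C00006", "NADPC", ("NADP+", "NADP"), "C21H28N7O17P3"),
        ("C00005", "NADPH", ("NADPH",), "C21H30N7O17P3"),
        ("C17568", "UQ8", ("ubiquinone-8",), "C49H74O4"),
        ("C17569", "UQH8", ("ubiquinol-8",), "C49H76O4"),
    ]
    compounds_a = [_c("A", a, names, f) for a, _, names, f in shared]
    compounds_b = [_c("B", b, names, f, xref=a) for a, b, names, f in shared]
    compounds_a += [
        _c("A", "C00399", ("ubiquinone", "a ubiquinone"), generic=True),
        _c("A", "C00390", ("ubiquinol", "a ubiquinol"), generic=True),
        _c("A", "C05379", ("oxalosuccinate",), "C6H6O7"),
        _c("A", "C00068", ("thiamine diphosphate", "ThPP"), "C12H18N4O7P2S"),
        _c("A", "C05381", ("3-carboxy-1-hydroxypropyl-ThPP",), "C17H26N4O10P2S"),
        _c("A", "C15972", ("lipoamide-E", "enzyme N6-(lipoyl)lysine")),
        _c("A", "C16254", ("succinyldihydrolipoamide-E",)),
        _c("A", "C06250", ("dihydrolipoamide-E",)),
        _c("A", "C00080", ("H+",)),
    ]
    truth = GroundTruth(compound_pairs={(a, b) for a, b, _, _ in shared})

    core = [
        # (A id, B id, substrates, products, EC); proton term added to A only
        ("R01082", "FUMHYDR-RXN", [("C00122", 1), ("C00001", 1)], [("C00149", 1)], "4.2.1.2", None),
        ("R00342", "MALATE-DH-RXN", [("C00149", 1), ("C00003", 1)], [("C00036", 1), ("C00004", 1)], "1.1.1.37", "C00080"),
        ("R00351", "CITSYN-RXN", [("C00036", 1), ("C00008", 1), ("C00009", 1), ("C00024", 1)], [("C00158", 1), ("C00002", 1), ("C00010", 1)], "2.3.3.8", None),
        ("R01325", "ACONITATEDEHYDR-RXN", [("C00158", 1)], [("C00417", 1), ("C00001", 1)], "4.2.1.3", None),
        ("R01900", "ACONITATEHYDR-RXN", [("C00417", 1), ("C00001", 1)], [("C00311", 1)], "4.2.1.3", None),
        ("R00479", "ISOCIT-CLEAV-RXN", [("C00311", 1)], [("C00042", 1), ("C00048", 1)], "4.1.3.1", None),
        ("R00472", "MALSYN-RXN", [("C00048", 1), ("C00001", 1), ("C00024", 1)], [("C00149", 1), ("C00010", 1)], "2.3.3.9", None),
        ("R00709", "ISOCITDEH-RXN", [("C00311", 1), ("C00003", 1)], [("C00026", 1), ("C00011", 1), ("C00004", 1)], "1.1.1.41", "C00080"),
        ("R00405", "SUCCCOASYN-RXN", [("C00091", 1), ("C00008", 1), ("C00009", 1)], [("C00042", 1), ("C00002", 1), ("C00010", 1)], "6.2.1.5", None),
    ]
    reactions_a, reactions_b = [], []
    for rid_a, rid_b, subs, prods, ec, proton in core:
        prods_a = prods + [(proton, 1)] if proton else prods
        reactions_a.append(_r("A", rid_a, subs, prods_a, ec))
        reactions_b.append(_r("B", rid_b, subs_to_b(subs, shared), subs_to_b(prods, shared), ec))
        truth.reaction_pairs.add((rid_a, rid_b))
        truth.expected_tier[("A", rid_a)] = "core"
        truth.expected_tier[("B", rid_b)] = "core"

    only_a = [
        ("R00268a", [("C00311", 1), ("C00006", 1)], [("C05379", 1), ("C00005", 1), ("C00080", 1)], "1.1.1.42", "intermediate"),
        ("R00268b", [("C05379", 1), ("C00006", 1)], [("C00026", 1), ("C00011", 1), ("C00005", 1), ("C00080", 1)], "1.1.1.42", "intermediate"),
        ("R00621", [("C00026", 1), ("C00068", 1)], [("C05381", 1), ("C00011", 1)], "1.2.4.2", "complete"),
        ("R03316", [("C05381", 1), ("C15972", 1)], [("C16254", 1), ("C00068", 1)], "1.2.4.2", "complete"),
        ("R02570", [("C16254", 1), ("C00010", 1)], [("C00091", 1), ("C06250", 1)], "2.3.1.61", "complete"),
        ("R02164", [("C00042", 1), ("C00399", 1)], [("C00122", 1), ("C00390", 1)], "1.3.5.1", "complete"),
    ]
    for rid, subs, prods, ec, tier in only_a:
        reactions_a.append(_r("A", rid, subs, prods, ec))
        truth.expected_tier[("A", rid)] = tier

    only_b = [
        ("2OXOGLUTARATEDEH-RXN", [("AKG", 1), ("COA", 1), ("NAD", 1)], [("SUCCOA", 1), ("CO2", 1), ("NADH", 1)], "1.2.4.2", "intermediate"),
        ("SUCCINATE-DEHYDROGENASE-UBIQUINONE-RXN", [("SUC", 1), ("UQ8", 1)], [("FUM", 1), ("UQH8", 1)], "1.3.5.1", "intermediate"),
    ]
    for rid, subs, prods, ec, tier in only_b:
        reactions_b.append(
            ReactionRecord(
                "B",
                rid,
                tuple((c, Fraction(k)) for c, k in subs),
                tuple((c, Fraction(k)) for c, k in prods),
                ec_numbers=frozenset({ec}),
            )
        )
        truth.expected_tier[("B", rid)] = tier

    return (compounds_a, reactions_a), (compounds_b, reactions_b), truth


def subs_to_b(side, shared) -> list[tuple[str, int]]:
    a2b = {a: b for a, b, _, _ in shared}
    return [(a2b[c], k) for c, k in side]


def showcase_fixture() -> tuple[
    tuple[list[CompoundRecord], list[ReactionRecord]],
    tuple[list[CompoundRecord], list[ReactionRecord]],
    GroundTruth,
]:
    """Six example reactions, one per confidence-tier attribution case.

    (a) identical in both databases → core; (b) identical up to protons →
    core; (c) a GTP/GDP cofactor variant in one database → intermediate;
    (d) a one-database reaction with its full product side in the core →
    intermediate; (e) substrate and product known to one database only →
    complete; (f) generic compound classes in one database → complete.
    """
    shared = [
        ("C02591", "S6P", ("sucrose-6-phosphate",), "C12H23O14P"),
        ("C00001", "WATER", ("water", "H2O"), "H2O"),
        ("C00089", "SUCROSE", ("sucrose",), "C12H22O11"),
        ("C00009", "PI", ("phosphate", "orthophosphate"), "H3PO4"),
        ("C01182", "RUBP", ("ribulose-1,5-bisphosphate",), "C5H12O11P2"),
        ("C00011", "CO2", ("CO2", "carbon dioxide"), "CO2"),
        ("C00197", "3PG", ("3-phosphoglycerate",), "C3H7O7P"),
        ("C00074", "PEP", ("phosphoenolpyruvate",), "C3H5O6P"),
        ("C00008", "ADPC", ("ADP",), "C10H15N5O10P2"),
        ("C00002", "ATPC", ("ATP",), "C10H16N5O13P3"),
        ("C00022", "PYR", ("pyruvate", "pyruvic acid", "pyroracemic acid"), "C3H4O3"),
        ("C00044", "GTPC", ("GTP",), "C10H16N5O14P3"),
        ("C00035", "GDPC", ("GDP",), "C10H15N5O11P2"),
        ("C00010", "COA", ("CoA", "coenzyme A"), "C21H36N7O16P3S"),
        ("C00024", "ACCOA", ("acetyl-CoA",), "C23H38N7O17P3S"),
        ("C00020", "AMP", ("AMP",), "C10H14N5O7P"),
    ]
    compounds_a = [_c("A", a, names, f) for a, _, names, f in shared]
    compounds_b = [_c("B", b, names, f, xref=a) for a, b, names, f in shared]
    compounds_a += [
        _c("A", "C05986", ("acetyl adenylate",), "C12H16N5O8P"),
        _c("A", "C00080", ("H+",)),
        _c("A", "CSL1", ("S-alkyl-L-cysteine",)),
        _c("A", "CSL2", ("an alkyl thiol",)),
        _c("A", "CSL3", ("2-aminoacrylate",)),
    ]
    compounds_b += [
        _c("B", "SPHINGO", ("a sphingolipid",), generic=True),
        _c("B", "SPHINGOSINE", ("a sphingosine",), generic=True),
        _c("B", "FATTY", ("a fatty acid",), generic=True),
    ]
    truth = GroundTruth(compound_pairs={(a, b) for a, b, _, _ in shared})

    reactions_a = [
        _r("A", "R_spp", [("C02591", 1), ("C00001", 1)], [("C00089", 1), ("C00009", 1)], "3.1.3.24"),
        _r("A", "R_rubisco", [("C01182", 1), ("C00011", 1), ("C00001", 1)], [("C00197", 2), ("C00080", 2)], "4.1.1.39"),
        _r("A", "R_pk_atp", [("C00074", 1), ("C00008", 1)], [("C00022", 1), ("C00002", 1)], "2.7.1.40"),
        _r("A", "R_pk_gtp", [("C00074", 1), ("C00035", 1)], [("C00022", 1), ("C00044", 1)], "2.7.1.40"),
        _r("A", "R_acs", [("C05986", 1), ("C00010", 1)], [("C00024", 1), ("C00020", 1)], "6.2.1.1"),
        _r("A", "R_csl", [("CSL1", 1)], [("CSL2", 1), ("CSL3", 1)], "4.4.1.10"),
    ]
    reactions_b = [
        _r("B", "RXN_spp", [("S6P", 1), ("WATER", 1)], [("SUCROSE", 1), ("PI", 1)], "3.1.3.24"),
        _r("B", "RXN_rubisco", [("RUBP", 1), ("CO2", 1), ("WATER", 1)], [("3PG", 2)], "4.1.1.39"),
        _r("B", "RXN_pk", [("PEP", 1), ("ADPC", 1)], [("PYR", 1), ("ATPC", 1)], "2.7.1.40"),
        _r("B", "RXN_sphingo", [("SPHINGO", 1), ("WATER", 1)], [("SPHINGOSINE", 1), ("FATTY", 1)], "3.1.4.12"),
    ]
    truth.reaction_pairs = {
        ("R_spp", "RXN_spp"),
        ("R_rubisco", "RXN_rubisco"),
        ("R_pk_atp", "RXN_pk"),
    }
    truth.expected_tier = {
        ("A", "R_spp"): "core",
        ("A", "R_rubisco"): "core",
        ("A", "R_pk_atp"): "core",
        ("A", "R_pk_gtp"): "intermediate",
        ("A", "R_acs"): "intermediate",
        ("A", "R_csl"): "complete",
        ("B", "RXN_sphingo"): "complete",
    }
    return (compounds_a, reactions_a), (compounds_b, reactions_b), truth
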