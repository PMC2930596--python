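"""Chemical-structure comparison ladder.

Equivalent metabolites drawn from different databases frequently differ only
in stereochemical annotation, tautomeric form, or protonation state.  The
ladder therefore compares two structures at successively relaxed levels:

1. ``exact``     — identical canonical SMILES (unambiguous);
2. ``stereo``    — identical after purging stereo descriptors;
3. ``tautomer``  — identical canonical tautomer (stereo-purged);
4. ``charge``    — identical after re-ionization at pH 7.4 (rule table over
   common ionizable groups: carboxylic, phosphoric, sulfonic acids are
   deprotonated, aliphatic amines protonated);
5. ``similar``   — circular-substructure fingerprint (radius 2, ECFP4-class)
   Tanimoto at or above a review threshold, flagging probable structural
   errors such as a missing functional group.

Only an exact match is unambiguous; every relaxed tier sets
``requires_manual_check``.  Compounds without structures fall back to a
hydrogen-blind formula comparison (``formula_only``), since databases do not
agree on protonation state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

log = logging.getLogger(__name__)

FINGERPRINT_BITS = 2048
DEFAULT_SIM_THRESHOLD = 0.8

TAUTOMER_ROUTINE = "rdkit.rdMolStandardize.TautomerEnumerator.Canonicalize"

_fp_generator = rdFingerprintGenerator.GetMorganGenerator(
    radius=2, fpSize=FINGERPRINT_BITS
)


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length bit set from a circular substructure fingerprint."""

    bits: frozenset[int]
    nbits: int = FINGERPRINT_BITS


@dataclass(frozen=True)
class StructureForms:
    """All normalized forms of one structure, used by the match ladder."""

    canonical: str
    stereo_purged: str
    tautomer_canonical: str
    ph74: str
    fingerprint: Fingerprint


@dataclass(frozen=True)
class StructMatchResult:
    tier: str  # exact|stereo|tautomer|charge|similar|formula_only|none
    tanimoto: float | None
    requires_manual_check: bool


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


# pH 7.4 re-ionization rule table: (SMARTS for the protonation-state-bearing
# atom, formal charge to set, explicit-H delta).  Deliberately coarse — it
# normalizes the common ionizable groups rather than predicting pKa.
_PH74_RULES: tuple[tuple[str, int, int], ...] = (
    # carboxylic acid O-H -> carboxylate
    ("[OX2H1][CX3](=O)", -1, -1),
    # phosphate / phosphonate O-H -> O-
    ("[OX2H1][PX4](=O)", -1, -1),
    # sulfonic / sulfuric O-H -> O-
    ("[OX2H1][SX4](=O)(=O)", -1, -1),
    # aliphatic amine N -> ammonium (not amide, not aromatic, not already charged)
    ("[NX3;H2,H1,H0;+0;!$(N-C=O);!$(N-a);!$(N=*)]", +1, +1),
)


def reionize_ph74(mol: Chem.Mol) -> Chem.Mol:
    """Apply the pH-7.4 ionization rule table and re-sanitize."""
    mol = Chem.RWMol(mol)
    seen: set[int] = set()
    for smarts, charge, h_delta in _PH74_RULES:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            idx = match[0]
            if idx in seen:
                continue
            seen.add(idx)
            atom = mol.GetAtomWithIdx(idx)
            atom.SetFormalCharge(charge)
            atom.SetNumExplicitHs(max(0, atom.GetTotalNumHs() + h_delta))
            atom.SetNoImplicit(True)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def make_forms(smiles: str) -> StructureForms:
    """Build all normalized forms plus the fingerprint for one SMILES."""
    mol = _mol_from_smiles(smiles)
    canonical = Chem.MolToSmiles(mol)

    purged = Chem.Mol(mol)
    Chem.RemoveStereochemistry(purged)
    stereo_purged = Chem.MolToSmiles(purged)

    tautomer = rdMolStandardize.TautomerEnumerator().Canonicalize(
        _mol_from_smiles(stereo_purged)
    )
    tautomer_canonical = Chem.MolToSmiles(tautomer)

    ph74 = Chem.MolToSmiles(reionize_ph74(_mol_from_smiles(tautomer_canonical)))

    fp = _fp_generator.GetFingerprint(mol)
    bits = frozenset(fp.GetOnBits())
    return StructureForms(
        canonical=canonical,
        stereo_purged=stereo_purged,
        tautomer_canonical=tautomer_canonical,
        ph74=ph74,
        fingerprint=Fingerprint(bits=bits),
    )


def tanimoto(fa: Fingerprint, fb: Fingerprint) -> float:
    """Bit-set intersection over union; 1.0 for two empty fingerprints."""
    if fa.nbits != fb.nbits:
        raise ValueError(f"fingerprint length mismatch: {fa.nbits} != {fb.nbits}")
    union = len(fa.bits | fb.bits)
    if union == 0:
        log.warning("tanimoto of two empty fingerprints, returning 1.0 by convention")
        return 1.0
    return len(fa.bits & fb.bits) / union


def match_structures(
    a: StructureForms,
    b: StructureForms,
    sim_threshold: float = DEFAULT_SIM_THRESHOLD,
) -> StructMatchResult:
    """Run the ladder; the first matching tier wins."""
    t = tanimoto(a.fingerprint, b.fingerprint)
    if a.canonical == b.canonical:
        return StructMatchResult(tier="exact", tanimoto=t, requires_manual_check=False)
    for tier, attr in (
        ("stereo", "stereo_purged"),
        ("tautomer", "tautomer_canonical"),
        ("charge", "ph74"),
    ):
        if getattr(a, attr) == getattr(b, attr):
            return StructMatchResult(tier=tier, tanimoto=t, requires_manual_check=True)
    if t >= sim_threshold:
        return StructMatchResult(tier="similar", tanimoto=t, requires_manual_check=True)
    return StructMatchResult(tier="none", tanimoto=t, requires_manual_check=True)


def formula_equal_ignoring_h(fa: Mapping[str, int], fb: Mapping[str, int]) -> bool:
    """True iff the element maps agree on every element except hydrogen.

    Databases disagree on protonation states, so proton-content differences
    between formulas are deliberately neglected.
    """
    strip = lambda f: {k: v for k, v in f.items() if k != "H" and v != 0}  # noqa: E731
    return strip(fa) == strip(fb)
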