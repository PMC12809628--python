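"""SMILES standardization and structural filtering.

Standardization runs, in order: cleanup (metal disconnection, reionization),
parent-fragment selection (salt stripping), charge neutralization,
stereochemistry removal, canonical-tautomer generation. Hydrogens are made
explicit only internally; the stored SMILES is the canonical implicit-H
form, which is what InChIKeys and fingerprints see anyway.

Structural filters then drop molecules that are permanently/internally
charged, isotope-labeled, outside the 150-800 Da window, aromatic-ring
heavy (> 5), or peptide-like (backbone match without a hexose/pentose
substructure). The verdict is order-independent; only the recorded reason
follows the canonical rule order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

log = logging.getLogger(__name__)

# RDKit is chatty about tautomers and InChI layers; keep batch runs readable.
RDLogger.DisableLog("rdApp.warning")

CHARGED_SMARTS = [
    "[#7+]", "[#7-]", "[#8+]", "[#8-]", "[#16+]", "[#16-]", "[#5+]", "[#5-]",
]
# The atom-number isotope spellings and the element-symbol ones are kept as
# synonyms; they match the same atoms.
ISOTOPE_SMARTS = [
    "[2H]", "[13#6]", "[17#8]", "[15#7]",
    "[13C]", "[17O]", "[15N]",
]
BACKBONE_SMARTS = "[$(CN)][$(C(=O)NCC(=O))]"
HEXOSE_SMARTS = "[$(C1(O)COCC(O)C1(O))]"
PENTOSE_SMARTS = "[$(C1(O)COCC1(O))]"

MOLWT_MIN = 150.0
MOLWT_MAX = 800.0
MAX_AROMATIC_RINGS = 5

_CHARGED = [Chem.MolFromSmarts(s) for s in CHARGED_SMARTS]
_ISOTOPE = [Chem.MolFromSmarts(s) for s in ISOTOPE_SMARTS]
_BACKBONE = Chem.MolFromSmarts(BACKBONE_SMARTS)
_HEXOSE = Chem.MolFromSmarts(HEXOSE_SMARTS)
_PENTOSE = Chem.MolFromSmarts(PENTOSE_SMARTS)

_TAUTOMER_ENUMERATOR = rdMolStandardize.TautomerEnumerator()


class MoleculeParseError(ValueError):
    """The input SMILES could not be parsed."""


@dataclass
class StandardizedMolecule:
    source_smiles: str
    standardized_smiles: str
    inchikey: str
    mol: Chem.Mol
    flags: set[str] = field(default_factory=set)


def standardize(smiles: str) -> StandardizedMolecule:
    """Standardize one SMILES; raises :class:`MoleculeParseError` on bad input."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"unparsable SMILES: {smiles!r}")
    mol = rdMolStandardize.Cleanup(mol)
    mol = rdMolStandardize.FragmentParent(mol)
    mol = rdMolStandardize.ChargeParent(mol)
    Chem.rdmolops.RemoveStereochemistry(mol)
    mol = _TAUTOMER_ENUMERATOR.Canonicalize(mol)
    # Hydrogens are added for the canonical form computation only; the
    # stored SMILES keeps them implicit.
    mol_h = Chem.AddHs(mol)
    inchikey = Chem.MolToInchiKey(mol_h)
    mol = Chem.RemoveHs(mol_h)
    return StandardizedMolecule(
        source_smiles=smiles,
        standardized_smiles=Chem.MolToSmiles(mol),
        inchikey=inchikey,
        mol=mol,
    )


def standardize_batch(
    smiles: Iterable[str],
) -> tuple[list[StandardizedMolecule], list[tuple[int, str, str]]]:
    """Standardize many SMILES; parse failures are collected, not raised.

    Returns (standardized molecules, rejects) where each reject is
    ``(input index, smiles, reason)``.
    """
    out, rejects = [], []
    for i, smi in enumerate(smiles):
        try:
            out.append(standardize(smi))
        except MoleculeParseError as exc:
            rejects.append((i, smi, "parse-error"))
            log.debug("record %d rejected: %s", i, exc)
    return out, rejects


@dataclass(frozen=True)
class FilterVerdict:
    keep: bool
    reason: str | None = None


def _is_charged(mol: Chem.Mol) -> bool:
    return any(mol.HasSubstructMatch(pat) for pat in _CHARGED)


def _has_isotope(mol: Chem.Mol) -> bool:
    return any(mol.HasSubstructMatch(pat) for pat in _ISOTOPE)


def _is_peptide(mol: Chem.Mol) -> bool:
    return (
        mol.HasSubstructMatch(_BACKBONE)
        and not mol.HasSubstructMatch(_HEXOSE)
        and not mol.HasSubstructMatch(_PENTOSE)
    )


# Canonical rule order: charge/isotope, then physico-chemical windows, then
# the peptide rule. The keep/drop verdict never depends on this order; only
# the reported first-failing reason does.
FILTER_RULES: list[tuple[str, callable]] = [
    ("charged-atom", _is_charged),
    ("isotope", _has_isotope),
    ("molwt<150", lambda m: Descriptors.MolWt(m) < MOLWT_MIN),
    ("molwt>800", lambda m: Descriptors.MolWt(m) > MOLWT_MAX),
    ("aromatic-rings>5", lambda m: rdMolDescriptors.CalcNumAromaticRings(m) > MAX_AROMATIC_RINGS),
    ("peptide", _is_peptide),
]


def structural_filters(
    mol: StandardizedMolecule | Chem.Mol,
    *,
    rule_order: Sequence[str] | None = None,
) -> FilterVerdict:
    """Apply all structural filters; drop if any rule fires.

    ``rule_order`` permutes rule evaluation (used to check that the verdict
    is order-independent); the first failing rule in the requested order is
    the reported reason.
    """
    rdmol = mol.mol if isinstance(mol, StandardizedMolecule) else mol
    rules = dict(FILTER_RULES)
    order = list(rules) if rule_order is None else list(rule_order)
    if set(order) != set(rules):
        raise ValueError(f"rule_order must be a permutation of {list(rules)}")
    for name in order:
        if rules[name](rdmol):
            return FilterVerdict(keep=False, reason=name)
    return FilterVerdict(keep=True)


def load_blocklist(path) -> set[str]:
    """Dataset-specific manual exclusions: one molecule id per line.

    Judgment calls (fluorescent probes, protected intermediates, known bad
    records) are supplied by the user rather than hardcoded.
    """
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}
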