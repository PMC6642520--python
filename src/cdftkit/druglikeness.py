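"""Drug-likeness profiling in the Molinspiration style, plus bioactivity bands.

Computes the classic oral-drug-likeness property block from a SMILES
string — molecular weight, heavy-atom count, H-bond acceptor/donor counts,
rotatable bonds, Ertl topological polar surface area and an atom-additive
logP — then counts Lipinski Rule-of-Five violations and classifies
externally supplied bioactivity scores.

Definitions follow the Molinspiration conventions so the block is
comparable with published property tables:

* ``nON``   — number of N and O atoms (acceptors).
* ``nOHNH`` — number of hydrogens attached to N or O (donors).
* ``nrotb`` — acyclic single bonds between two non-terminal heavy atoms,
  excluding amide C-N bonds.
* ``TPSA``  — Ertl fragment-contribution polar surface area over N/O
  environments.
* ``logP``  — Wildman-Crippen atom-contribution estimate.  This is an
  open stand-in for the proprietary miLogP model; agreement with miLogP
  is typically within about one log unit, so when a miLogP value is
  available it should be passed through and preferred for Ro5 counting.
  Molecular volume is likewise proprietary and accepted only as an input.

Bioactivity scores (GPCR ligand, ion-channel modulator, kinase inhibitor,
nuclear-receptor ligand, protease inhibitor, enzyme inhibitor) come from
external target-class models and are classified as *active* (> 0),
*moderately active* (-5.0 <= score <= 0.0) or *inactive* (< -5.0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

__all__ = [
    "SmilesError",
    "MolecularStructure",
    "DrugProfile",
    "BioactivityScores",
    "parse_smiles",
    "molecular_weight",
    "count_hba",
    "count_hbd",
    "rotatable_bonds",
    "tpsa",
    "logp",
    "ro5_violations",
    "classify_bioactivity",
    "drug_profile",
    "BIOACTIVITY_TARGETS",
]

#: Elements of the supported organic subset.
SUPPORTED_ELEMENTS = {"H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I"}

#: Canonical order of the six Molinspiration target classes.
BIOACTIVITY_TARGETS = (
    "gpcr",
    "ion_channel",
    "kinase",
    "nuclear_receptor",
    "protease",
    "enzyme",
)

_AMIDE_CN = Chem.MolFromSmarts("[NX3][CX3](=[OX1])")


class SmilesError(ValueError):
    """Raised for unparseable SMILES or elements outside the organic subset."""


@dataclass(frozen=True)
class MolecularStructure:
    """A parsed molecule: heavy atoms explicit, hydrogens implicit.

    Wraps the underlying RDKit molecule; ``source`` keeps the input SMILES
    for provenance.
    """

    source: str
    mol: Chem.Mol = field(repr=False, compare=False)

    @property
    def n_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    @property
    def formula(self) -> str:
        return rdMolDescriptors.CalcMolFormula(self.mol)


@dataclass(frozen=True)
class DrugProfile:
    """The Molinspiration-style property block for one molecule."""

    mw: float  # Da
    n_atoms: int  # heavy atoms
    n_on: int  # H-bond acceptors (N + O count)
    n_ohnh: int  # H-bond donors (H on N or O)
    n_rotb: int
    tpsa: float  # A^2
    logp: float  # computed Wildman-Crippen stand-in
    nviol: int
    milogp_input: float | None = None  # external miLogP, if supplied
    volume_input: float | None = None  # external molecular volume (A^3)

    def as_dict(self) -> dict:
        """Flat record keyed with the conventional property-table names."""
        return {
            "miLogP": self.milogp_input,
            "logP_calc": self.logp,
            "TPSA": self.tpsa,
            "nAtoms": self.n_atoms,
            "nON": self.n_on,
            "nOHNH": self.n_ohnh,
            "nviol": self.nviol,
            "nrotb": self.n_rotb,
            "volume": self.volume_input,
            "MW": self.mw,
        }


@dataclass(frozen=True)
class BioactivityScores:
    """Six externally supplied target-class scores with their activity bands."""

    gpcr: float
    ion_channel: float
    kinase: float
    nuclear_receptor: float
    protease: float
    enzyme: float

    def scores(self) -> dict[str, float]:
        return {t: getattr(self, t) for t in BIOACTIVITY_TARGETS}

    @property
    def categories(self) -> dict[str, str]:
        return {t: classify_bioactivity(s) for t, s in self.scores().items()}


def parse_smiles(s: str) -> MolecularStructure:
    """Parse a SMILES string over the supported organic subset."""
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise SmilesError(f"could not parse SMILES: {s!r}")
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in SUPPORTED_ELEMENTS:
            raise SmilesError(
                f"unsupported element {atom.GetSymbol()!r} at atom "
                f"{atom.GetIdx() + 1}"
            )
    return MolecularStructure(source=s, mol=mol)


def molecular_weight(m: MolecularStructure) -> float:
    """Average-isotope molecular weight (Da), implicit hydrogens included."""
    return float(Descriptors.MolWt(m.mol))


def count_hba(m: MolecularStructure) -> int:
    """H-bond acceptor count nON: the number of N and O atoms."""
    return sum(1 for a in m.mol.GetAtoms() if a.GetSymbol() in ("N", "O"))


def count_hbd(m: MolecularStructure) -> int:
    """H-bond donor count nOHNH: hydrogens attached to N or O."""
    return sum(
        a.GetTotalNumHs() for a in m.mol.GetAtoms() if a.GetSymbol() in ("N", "O")
    )


def rotatable_bonds(m: MolecularStructure) -> int:
    """Rotatable bonds: acyclic single bonds between non-terminal heavy
    atoms, amide C-N bonds excluded."""
    amide_bonds = set()
    for match in m.mol.GetSubstructMatches(_AMIDE_CN):
        bond = m.mol.GetBondBetweenAtoms(match[0], match[1])
        if bond is not None:
            amide_bonds.add(bond.GetIdx())
    n = 0
    for bond in m.mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        if bond.GetIdx() in amide_bonds:
            continue
        if bond.GetBeginAtom().GetDegree() < 2 or bond.GetEndAtom().GetDegree() < 2:
            continue  # terminal heavy atom
        n += 1
    return n


def tpsa(m: MolecularStructure) -> float:
    """Ertl topological polar surface area (A^2) over N/O environments."""
    return float(rdMolDescriptors.CalcTPSA(m.mol))


def logp(m: MolecularStructure) -> float:
    """Wildman-Crippen atom-additive octanol/water logP (open stand-in)."""
    return float(Crippen.MolLogP(m.mol))


def ro5_violations(
    mw: float, logp_value: float, n_ohnh: int, n_on: int
) -> int:
    """Lipinski Rule-of-Five violation count.

    A property violates its rule only when it strictly exceeds the limit
    (MW > 500, logP > 5, donors > 5, acceptors > 10); values exactly at a
    limit are compliant, per the rule's original phrasing.
    """
    for name, val in (("mw", mw), ("logp_value", logp_value),
                      ("n_ohnh", n_ohnh), ("n_on", n_on)):
        if val is None:
            raise ValueError(f"missing property {name!r} for Ro5 counting")
    return int(mw > 500) + int(logp_value > 5) + int(n_ohnh > 5) + int(n_on > 10)


def classify_bioactivity(score: float) -> str:
    """Activity band of a bioactivity score.

    > 0 → ``"active"``; -5.0 <= score <= 0.0 → ``"moderately active"``
    (both boundaries inclusive); < -5.0 → ``"inactive"``.
    """
    if score is None or not math.isfinite(score):
        raise ValueError(f"bioactivity score must be finite, got {score!r}")
    if score > 0:
        return "active"
    if score >= -5.0:
        return "moderately active"
    return "inactive"


def drug_profile(
    m: MolecularStructure,
    milogp: float | None = None,
    volume: float | None = None,
) -> DrugProfile:
    """Assemble the full property block and Ro5 violation count.

    When an external miLogP value is supplied it is used for the Ro5 logP
    rule (and reported); the computed Wildman-Crippen value is always
    retained alongside.
    """
    mw = molecular_weight(m)
    n_on = count_hba(m)
    n_ohnh = count_hbd(m)
    lp = logp(m)
    logp_for_rules = milogp if milogp is not None else lp
    return DrugProfile(
        mw=mw,
        n_atoms=m.n_heavy_atoms,
        n_on=n_on,
        n_ohnh=n_ohnh,
        n_rotb=rotatable_bonds(m),
        tpsa=tpsa(m),
        logp=lp,
        nviol=ro5_violations(mw, logp_for_rules, n_ohnh, n_on),
        milogp_input=milogp,
        volume_input=volume,
    )
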