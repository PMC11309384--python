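"""Chain and ligand classification rules.

A chain is called RNA when it has more ribonucleotides than
deoxyribonucleotides and more ribonucleotides than amino acids (strict
majorities; ties yield OTHER).  RNA chains with 10 or more nucleotides
are database entries; shorter oligo-ribonucleotide fragments can only
appear as ligands of an entry chain.

Ligand components are metal ions only when they consist of a single
atom of a metallic element: multi-atom coordination complexes such as
cobalt hexammine are small molecules, and water is never a ligand.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Union

from .model import Chain, Residue, ResidueKind
from .refdata import metal_elements

ENTRY_MIN_NUCLEOTIDES = 10


class ChainType(enum.Enum):
    RNA = "RNA"
    DNA = "DNA"
    PROTEIN = "PROTEIN"
    OTHER = "OTHER"


class LigandClass(enum.Enum):
    METAL_ION = "METAL_ION"
    SMALL_MOLECULE = "SMALL_MOLECULE"
    RNA_LIGAND = "RNA_LIGAND"
    DNA_LIGAND = "DNA_LIGAND"
    PROTEIN_LIGAND = "PROTEIN_LIGAND"
    EXCLUDED_WATER = "EXCLUDED_WATER"


@dataclass
class ComponentInfo:
    """Chemical-component metadata for a small-molecule ligand."""

    ccd_id: str
    formula: dict[str, int] = field(default_factory=dict)
    name: str = ""
    smiles: Optional[str] = None
    inchi: Optional[str] = None
    inchikey: Optional[str] = None

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.formula.values()):
            raise ValueError(f"{self.ccd_id}: formula counts must be positive")

    def atom_total(self) -> int:
        return sum(self.formula.values())


def residue_counts(chain: Chain) -> Counter:
    return Counter(r.kind for r in chain.polymer_residues())


def classify_chain(chain: Chain) -> ChainType:
    """Majority-rule chain typing over polymer residue kinds."""
    counts = residue_counts(chain)
    ribo = counts[ResidueKind.RIBONUCLEOTIDE]
    deoxy = counts[ResidueKind.DEOXYRIBONUCLEOTIDE]
    aa = counts[ResidueKind.AMINO_ACID]
    if ribo + deoxy + aa + counts[ResidueKind.OTHER] == 0:
        raise ValueError(f"chain {chain.chain_id}: no polymer residues")
    if ribo > deoxy and ribo > aa:
        return ChainType.RNA
    if deoxy > ribo and deoxy > aa:
        return ChainType.DNA
    if aa > ribo and aa > deoxy:
        return ChainType.PROTEIN
    return ChainType.OTHER


def is_entry_eligible(chain: Chain) -> bool:
    """True for RNA chains with >= 10 nucleotides (the entry rule)."""
    try:
        if classify_chain(chain) is not ChainType.RNA:
            return False
    except ValueError:
        return False
    nribo = residue_counts(chain)[ResidueKind.RIBONUCLEOTIDE]
    return nribo >= ENTRY_MIN_NUCLEOTIDES


_WATER_IDS = {"HOH", "DOD", "H2O", "WAT"}

_CHAINTYPE_TO_LIGAND = {
    ChainType.RNA: LigandClass.RNA_LIGAND,
    ChainType.DNA: LigandClass.DNA_LIGAND,
    ChainType.PROTEIN: LigandClass.PROTEIN_LIGAND,
    ChainType.OTHER: LigandClass.SMALL_MOLECULE,
}


def component_from_residue(residue: Residue) -> ComponentInfo:
    formula = Counter(a.element for a in residue.atoms)
    return ComponentInfo(ccd_id=residue.comp_id, formula=dict(formula))


def classify_ligand(component: Union[ComponentInfo, Chain, Residue]) -> LigandClass:
    """Classify an interaction partner.

    Polymer chains map through :func:`classify_chain`; single-atom
    components of metallic elements are metal ions; water is excluded;
    everything else (including metal-containing coordination complexes)
    is a small molecule.
    """
    if isinstance(component, Chain):
        return _CHAINTYPE_TO_LIGAND[classify_chain(component)]
    if isinstance(component, Residue):
        if component.kind is ResidueKind.WATER:
            return LigandClass.EXCLUDED_WATER
        component = component_from_residue(component)
    if component.ccd_id.upper() in _WATER_IDS:
        return LigandClass.EXCLUDED_WATER
    if component.atom_total() == 1:
        (element,) = component.formula
        if element in metal_elements():
            return LigandClass.METAL_ION
    return LigandClass.SMALL_MOLECULE
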