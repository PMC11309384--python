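"""Core in-memory model of a macromolecular structure.

The hierarchy is Structure -> Chain -> Residue -> Atom, mirroring the
author-chain view of an mmCIF file.  Polymer residues keep both the
polymer sequence index (``label_seq``, 1-based, ``None`` for non-polymer
components) and the author numbering (``auth_seq`` + insertion code).
Biological assemblies are stored as lists of (chain selection, 4x4 rigid
transform) operations and materialised on demand.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np


class ResidueKind(enum.Enum):
    RIBONUCLEOTIDE = "ribonucleotide"
    DEOXYRIBONUCLEOTIDE = "deoxyribonucleotide"
    AMINO_ACID = "amino_acid"
    OTHER = "other"
    WATER = "water"


@dataclass
class Atom:
    """A single atom with Cartesian coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.name}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")


@dataclass
class Residue:
    comp_id: str
    auth_seq: int
    kind: ResidueKind
    atoms: list[Atom] = field(default_factory=list)
    label_seq: Optional[int] = None
    icode: str = ""

    @property
    def is_polymer(self) -> bool:
        return self.label_seq is not None

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def locator(self) -> str:
        return f"{self.comp_id}{self.auth_seq}{self.icode}"


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_polymer]

    def nonpolymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_polymer]

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AssemblyDef:
    """One biological assembly: chain selections with rigid transforms.

    ``operations`` is a list of ``(chain_ids, transform)`` where
    ``transform`` is a 4x4 homogeneous matrix whose rotation block must be
    a proper rotation (determinant +1).
    """

    assembly_id: str
    operations: list[tuple[tuple[str, ...], np.ndarray]] = field(default_factory=list)

    def referenced_chains(self) -> set[str]:
        out: set[str] = set()
        for chains, _ in self.operations:
            out.update(chains)
        return out

    def validate(self) -> None:
        for chains, op in self.operations:
            op = np.asarray(op, float)
            if op.shape != (4, 4):
                raise ValueError("assembly transform must be 4x4")
            det = np.linalg.det(op[:3, :3])
            if abs(det - 1.0) > 1e-6:
                raise ValueError(
                    f"assembly {self.assembly_id}: transform is not a proper "
                    f"rotation (det={det:.6f})"
                )


@dataclass
class Structure:
    entry_id: str
    chains: list[Chain] = field(default_factory=list)
    assemblies: list[AssemblyDef] = field(default_factory=list)
    resolution: Optional[float] = None
    species_taxids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.entry_id}: duplicate chain ids {ids}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(
            f"{self.entry_id}: no chain {chain_id!r} "
            f"(have {[c.chain_id for c in self.chains]})"
        )

    def assembly(self, assembly_id: str) -> AssemblyDef:
        for a in self.assemblies:
            if a.assembly_id == str(assembly_id):
                return a
        raise KeyError(
            f"{self.entry_id}: no assembly {assembly_id!r} "
            f"(available: {[a.assembly_id for a in self.assemblies]})"
        )

    def atom_count(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)


def apply_transform(op: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Apply a 4x4 homogeneous transform to an (N,3) coordinate array."""
    op = np.asarray(op, float)
    return coords @ op[:3, :3].T + op[:3, 3]


def chain_sequence(chain: Chain, base_of: Optional[dict[str, str]] = None) -> str:
    """One-letter sequence of the polymer part of a chain.

    Nucleotide comp_ids are reduced to their parent base when a mapping is
    given; unknown components become 'N'.
    """
    letters = []
    for r in chain.polymer_residues():
        cid = r.comp_id.upper()
        if base_of and cid in base_of and base_of[cid] != "-":
            letters.append(base_of[cid])
        elif len(cid) == 1:
            letters.append(cid)
        else:
            letters.append("N")
    return "".join(letters)
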