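"""Ligand-RNA contacts, binding residues and binding sites.

Within a chosen biological assembly, an atomic contact is any pair of
non-hydrogen atoms, one from the query RNA and one from a ligand, whose
distance does not exceed the sum of the two van der Waals radii plus a
0.5 A margin.  A nucleotide with two or more such contacts to the same
ligand is a binding residue; two or more binding residues form a binding
site, and ligands without a site are dropped.  Waters are never ligands;
every other component in the assembly (metal ions, small molecules,
proteins, DNAs, other RNA chains including short fragments) is a
candidate partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import refdata
from .chaintypes import LigandClass, classify_ligand, is_entry_eligible
from .config import PipelineConfig
from .model import Atom, Chain, Residue, ResidueKind, Structure
from .structio import split_polymer_nonpolymer


def vdw_radius(element: str) -> float:
    """Van der Waals radius in Angstrom (packaged table, 1.80 default)."""
    return refdata.vdw_radius(element)


@dataclass(frozen=True)
class AtomRef:
    chain_id: str
    residue_index: int      # index into the owning residue list
    comp_id: str
    auth_seq: int
    icode: str
    atom_name: str
    element: str


@dataclass
class Contact:
    rna_atom: AtomRef
    ligand_atom: AtomRef
    distance: float


@dataclass
class BindingSite:
    residues: list[AtomRef]          # one reference per residue (atom_name "")
    contacts: list[Contact]

    def residue_tokens(self, base_of: Optional[dict[str, str]] = None) -> list[str]:
        """Space-separable tokens like ``G24`` (base letter + auth_seq)."""
        toks = []
        for r in self.residues:
            base = (base_of or {}).get(r.comp_id.upper(), r.comp_id)
            if len(base) != 1:
                base = r.comp_id
            toks.append(f"{base}{r.auth_seq}{r.icode}")
        return toks


@dataclass
class LigandInstance:
    klass: LigandClass
    ligand_id: str               # CCD id for components, chain id for polymers
    chain_id: str
    auth_seq: Optional[int]      # None for polymer-chain ligands
    copy_number: int
    assembly_id: str = ""

    def locator(self) -> str:
        if self.auth_seq is None:
            return f"{self.chain_id}"
        return f"{self.chain_id}:{self.auth_seq}:{self.copy_number}"


@dataclass
class InteractionRecord:
    entry_id: str
    query_chain_id: str
    assembly_id: str
    ligand: LigandInstance
    site: BindingSite

    @property
    def contact_count(self) -> int:
        return len(self.site.contacts)


# ---------------------------------------------------------------------------


def _collect_atoms(residues: Sequence[tuple[int, Residue]], chain_id: str
                   ) -> tuple[list[AtomRef], np.ndarray, np.ndarray]:
    refs: list[AtomRef] = []
    coords = []
    radii = []
    for idx, res in residues:
        for a in res.atoms:
            if a.is_hydrogen:
                continue
            refs.append(AtomRef(chain_id, idx, res.comp_id, res.auth_seq,
                                res.icode, a.name, a.element))
            coords.append(a.coords)
            radii.append(refdata.vdw_radius(a.element))
    if not coords:
        return refs, np.empty((0, 3)), np.empty((0,))
    return refs, np.asarray(coords), np.asarray(radii)


def find_contacts(rna: Chain, ligand_atoms: Sequence[tuple[AtomRef, Atom]],
                  margin: float = 0.5) -> list[Contact]:
    """All non-hydrogen inter-molecular contacts under the vdW+margin rule.

    Uses a KD-tree pre-filter at the largest possible threshold but is
    result-identical to the brute-force all-pairs definition.
    """
    rna_refs, rna_xyz, rna_r = _collect_atoms(
        list(enumerate(rna.residues)), rna.chain_id)
    lig_refs = []
    lig_xyz = []
    lig_r = []
    for ref, atom in ligand_atoms:
        if atom.is_hydrogen:
            continue
        lig_refs.append(ref)
        lig_xyz.append(atom.coords)
        lig_r.append(refdata.vdw_radius(atom.element))
    if not lig_refs or len(rna_refs) == 0:
        return []
    lig_xyz = np.asarray(lig_xyz)
    lig_r = np.asarray(lig_r)

    max_cut = rna_r.max() + lig_r.max() + margin
    tree = cKDTree(rna_xyz)
    contacts: list[Contact] = []
    neighbor_lists = tree.query_ball_point(lig_xyz, r=max_cut)
    for j, neighbors in enumerate(neighbor_lists):
        if not neighbors:
            continue
        d = np.linalg.norm(rna_xyz[neighbors] - lig_xyz[j], axis=1)
        cut = rna_r[neighbors] + lig_r[j] + margin
        for k, i in enumerate(neighbors):
            if d[k] <= cut[k]:
                contacts.append(Contact(rna_refs[i], lig_refs[j], float(d[k])))
    contacts.sort(key=lambda c: (c.rna_atom.residue_index, c.rna_atom.atom_name,
                                 c.ligand_atom.residue_index,
                                 c.ligand_atom.atom_name))
    return contacts


def binding_residues(contacts: Sequence[Contact],
                     min_contacts: int = 2) -> list[AtomRef]:
    """Residues with >= min_contacts atomic contacts, in sequence order."""
    per_res: dict[tuple, list[Contact]] = {}
    for c in contacts:
        key = (c.rna_atom.chain_id, c.rna_atom.residue_index)
        per_res.setdefault(key, []).append(c)
    out = []
    for key in sorted(per_res, key=lambda k: k[1]):
        group = per_res[key]
        if len(group) >= min_contacts:
            a = group[0].rna_atom
            out.append(AtomRef(a.chain_id, a.residue_index, a.comp_id,
                               a.auth_seq, a.icode, "", ""))
    return out


def _ligand_atom_list(chain_id: str, idx: int, res: Residue
                      ) -> list[tuple[AtomRef, Atom]]:
    return [
        (AtomRef(chain_id, idx, res.comp_id, res.auth_seq, res.icode,
                 a.name, a.element), a)
        for a in res.atoms
    ]


def extract_interactions(assembly: Structure, query_chain_id: str,
                         config: Optional[PipelineConfig] = None,
                         assembly_id: str = "") -> list[InteractionRecord]:
    """All ligand-RNA interaction records for one query chain.

    ``assembly`` must already be materialised (the biological assembly
    containing the query chain).  Partners are every non-water component
    of every chain plus every other polymer chain; records are kept only
    when the binding site has at least ``site_min_residues`` residues.
    """
    cfg = config or PipelineConfig()
    query = assembly.chain(query_chain_id)
    query_polymer, _ = split_polymer_nonpolymer(query)
    if not is_entry_eligible(query_polymer):
        raise ValueError(
            f"chain {query_chain_id} is not an eligible entry "
            f"(needs RNA type and >= {cfg.entry_min_nt} nt)")

    records: list[InteractionRecord] = []
    copy_counter: dict[str, int] = {}

    # non-polymer components from all chains
    for chain in assembly.chains:
        for idx, res in enumerate(chain.residues):
            if res.is_polymer:
                continue
            if res.kind is ResidueKind.WATER:
                continue
            klass = classify_ligand(res)
            if klass is LigandClass.EXCLUDED_WATER:
                continue
            contacts = find_contacts(
                query_polymer, _ligand_atom_list(chain.chain_id, idx, res),
                margin=cfg.contact_margin)
            site_res = binding_residues(contacts, cfg.min_contacts_per_residue)
            if len(site_res) < cfg.site_min_residues:
                continue
            copy_counter[res.comp_id] = copy_counter.get(res.comp_id, 0) + 1
            ligand = LigandInstance(
                klass=klass, ligand_id=res.comp_id, chain_id=chain.chain_id,
                auth_seq=res.auth_seq, copy_number=copy_counter[res.comp_id],
                assembly_id=assembly_id)
            records.append(InteractionRecord(
                assembly.entry_id, query_chain_id, assembly_id, ligand,
                BindingSite(site_res, contacts)))

    # polymer chains other than the query
    for chain in assembly.chains:
        if chain.chain_id == query_chain_id:
            continue
        polymer, _ = split_polymer_nonpolymer(chain)
        if not polymer.residues:
            continue
        klass = classify_ligand(polymer)
        if klass is LigandClass.EXCLUDED_WATER:
            continue
        lig_atoms = []
        for idx, res in enumerate(chain.residues):
            if res.is_polymer:
                lig_atoms.extend(_ligand_atom_list(chain.chain_id, idx, res))
        contacts = find_contacts(query_polymer, lig_atoms,
                                 margin=cfg.contact_margin)
        site_res = binding_residues(contacts, cfg.min_contacts_per_residue)
        if len(site_res) < cfg.site_min_residues:
            continue
        copy_counter[chain.chain_id] = copy_counter.get(chain.chain_id, 0) + 1
        ligand = LigandInstance(
            klass=klass, ligand_id=chain.chain_id, chain_id=chain.chain_id,
            auth_seq=None, copy_number=copy_counter[chain.chain_id],
            assembly_id=assembly_id)
        records.append(InteractionRecord(
            assembly.entry_id, query_chain_id, assembly_id, ligand,
            BindingSite(site_res, contacts)))

    return records


def interactions_table(records: Sequence[InteractionRecord]) -> list[dict]:
    """Flat rows for the per-interaction TSV output."""
    base_of = refdata.component_bases()
    rows = []
    for rec in records:
        rows.append({
            "entry_id": rec.entry_id,
            "query_chain": rec.query_chain_id,
            "assembly_id": rec.assembly_id,
            "ligand_class": rec.ligand.klass.value,
            "ligand_id": rec.ligand.ligand_id,
            "ligand_locator": rec.ligand.locator(),
            "binding_residues": " ".join(rec.site.residue_tokens(base_of)),
            "contact_count": rec.contact_count,
        })
    return rows
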