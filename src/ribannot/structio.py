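"""Structure I/O: mmCIF reading, assembly building, PDB writing.

mmCIF parsing is delegated to gemmi; this module converts the parsed
hierarchy into the light-weight :mod:`ribannot.model` types, preserving
the label_seq/auth_seq distinction that drives the polymer/non-polymer
split, and materialises biological assemblies from the
``pdbx_struct_assembly_gen`` / ``pdbx_struct_oper_list`` categories.

PDB writing is a deliberately small fixed-width writer: structures that
exceed the format's hard limits (99,999 atoms or 62 single-character
chain ids) are refused, and multi-character chain ids are renamed with
the mapping returned to the caller.
"""

from __future__ import annotations

import os
from typing import Optional

import gemmi
import numpy as np

from .model import AssemblyDef, Atom, Chain, Residue, Structure, apply_transform
from .refdata import residue_kind

PDB_MAX_ATOMS = 99_999
PDB_MAX_CHAINS = 62
_PDB_CHAIN_POOL = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


class ParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


class StructureTooLargeError(ValueError):
    """Raised when a structure does not fit in the PDB format."""


# ---------------------------------------------------------------------------
# reading


def _pick_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy conformer per atom name (ties: first)."""
    best: dict[str, gemmi.Atom] = {}
    for at in res:
        prev = best.get(at.name)
        if prev is None or at.occ > prev.occ:
            best[at.name] = at
    # preserve file order
    seen = set()
    out = []
    for at in res:
        if at.name not in seen:
            seen.add(at.name)
            out.append(best[at.name])
    return out


def _convert_residue(res: gemmi.Residue) -> Residue:
    atoms = []
    for at in _pick_altlocs(res):
        el = at.element.name
        atoms.append(
            Atom(
                name=at.name,
                element=el,
                coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                is_hydrogen=el in ("H", "D"),
            )
        )
    return Residue(
        comp_id=res.name,
        auth_seq=res.seqid.num,
        icode=(res.seqid.icode or "").strip(),
        label_seq=res.label_seq,
        kind=residue_kind(res.name, atoms),
        atoms=atoms,
    )


def _subchain_to_chain(model: gemmi.Model) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for ch in model:
        for res in ch:
            if res.subchain:
                mapping.setdefault(res.subchain, ch.name)
    return mapping


def _convert_assemblies(st: gemmi.Structure, model: gemmi.Model) -> list[AssemblyDef]:
    sub2chain = _subchain_to_chain(model)
    out = []
    for asm in st.assemblies:
        ops = []
        for gen in asm.generators:
            chains: list[str] = []
            for name in gen.chains:
                if name not in chains:
                    chains.append(name)
            for sub in gen.subchains:
                ch = sub2chain.get(sub)
                if ch is not None and ch not in chains:
                    chains.append(ch)
            if not chains:
                continue
            for oper in gen.operators:
                mat = np.eye(4)
                mat[:3, :3] = np.array(oper.transform.mat.tolist())
                mat[:3, 3] = np.array(oper.transform.vec.tolist())
                ops.append((tuple(chains), mat))
        if ops:
            out.append(AssemblyDef(assembly_id=asm.name, operations=ops))
    return out


def _entity_taxids(block: gemmi.cif.Block, st: gemmi.Structure,
                   model: gemmi.Model) -> dict[str, str]:
    """Per-chain NCBI taxonomy ids from the entity source categories."""
    entity_tax: dict[str, str] = {}
    for cat, item in (
        ("_entity_src_gen.", "pdbx_gene_src_ncbi_taxonomy_id"),
        ("_entity_src_nat.", "pdbx_ncbi_taxonomy_id"),
        ("_pdbx_entity_src_syn.", "ncbi_taxonomy_id"),
    ):
        table = block.find(cat, ["entity_id", item])
        for row in table:
            eid, tax = row[0], row[1]
            if tax not in ("?", ".", ""):
                entity_tax.setdefault(eid, tax)
    if not entity_tax:
        return {}
    sub2chain = _subchain_to_chain(model)
    chain_tax: dict[str, str] = {}
    for ent in st.entities:
        tax = entity_tax.get(ent.name)
        if tax is None:
            continue
        for sub in ent.subchains:
            ch = sub2chain.get(sub)
            if ch is not None:
                chain_tax.setdefault(ch, tax)
    return chain_tax


def _convert_structure(st: gemmi.Structure,
                       block: Optional[gemmi.cif.Block] = None,
                       infer_polymer: bool = False) -> Structure:
    if len(st) == 0:
        raise ParseError(f"{st.name or 'structure'}: no models")
    model = st[0]  # first model only
    chains = []
    for ch in model:
        residues = []
        polymer_index = 0
        for res in ch:
            converted = _convert_residue(res)
            if (infer_polymer and converted.label_seq is None
                    and res.entity_type == gemmi.EntityType.Polymer):
                # PDB input: no label_seq_id exists; polymer membership
                # comes from gemmi's entity setup instead
                polymer_index += 1
                converted.label_seq = polymer_index
            residues.append(converted)
        chains.append(Chain(chain_id=ch.name, residues=residues))
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    taxids = _entity_taxids(block, st, model) if block is not None else {}
    structure = Structure(
        entry_id=(st.name or "").lower()[:4] or "xxxx",
        chains=chains,
        assemblies=_convert_assemblies(st, model),
        resolution=resolution,
        species_taxids=taxids,
    )
    for asm in structure.assemblies:
        asm.validate()
    return structure


def read_mmcif(path: str | os.PathLike) -> Structure:
    """Read an mmCIF file (asymmetric unit or assembly file).

    Raises :class:`ParseError` if the file has no ``atom_site`` loop or a
    malformed row.
    """
    try:
        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
    except Exception as exc:  # gemmi raises RuntimeError/ValueError
        raise ParseError(f"{path}: not parseable as mmCIF ({exc})") from exc
    if not block.find_loop("_atom_site.id") and not block.find_values("_atom_site.id"):
        raise ParseError(f"{path}: missing atom_site loop")
    try:
        st = gemmi.make_structure_from_block(block)
    except Exception as exc:
        raise ParseError(f"{path}: malformed atom_site data ({exc})") from exc
    if st.name in ("", "data"):
        st.name = block.name
    return _convert_structure(st, block)


def read_pdb(path: str | os.PathLike) -> Structure:
    """Read a PDB-format file (polymer detection via gemmi entity setup)."""
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except Exception as exc:
        raise ParseError(f"{path}: not parseable as PDB ({exc})") from exc
    st.setup_entities()
    st.assign_label_seq_id()
    return _convert_structure(st, infer_polymer=True)


def read_structure(path: str | os.PathLike) -> Structure:
    """Read a structure file, dispatching on extension (.cif vs .pdb)."""
    p = str(path)
    if p.endswith((".cif", ".cif.gz", ".mmcif")):
        return read_mmcif(p)
    return read_pdb(p)


# ---------------------------------------------------------------------------
# assemblies


def build_assembly(structure: Structure, assembly_id: str) -> Structure:
    """Materialise one biological assembly as a new Structure.

    Each (chain selection, transform) operation emits transformed copies
    of the selected chains; duplicated chains get "-2", "-3", ... suffixes.
    """
    asm = structure.assembly(str(assembly_id))
    new_chains: list[Chain] = []
    copy_count: dict[str, int] = {}
    for chain_ids, op in asm.operations:
        op = np.asarray(op, float)
        identity = np.allclose(op, np.eye(4))
        for cid in chain_ids:
            src = structure.chain(cid)
            copy_count[cid] = copy_count.get(cid, 0) + 1
            new_id = cid if copy_count[cid] == 1 else f"{cid}-{copy_count[cid]}"
            residues = []
            for r in src.residues:
                atoms = []
                for a in r.atoms:
                    coords = a.coords if identity else apply_transform(op, a.coords)
                    atoms.append(Atom(a.name, a.element, np.array(coords),
                                      a.is_hydrogen))
                residues.append(Residue(r.comp_id, r.auth_seq, r.kind, atoms,
                                        r.label_seq, r.icode))
            new_chains.append(Chain(chain_id=new_id, residues=residues))
    return Structure(
        entry_id=structure.entry_id,
        chains=new_chains,
        assemblies=[],
        resolution=structure.resolution,
        species_taxids=dict(structure.species_taxids),
    )


def assembly_for_chain(structure: Structure, chain_id: str) -> Optional[str]:
    """Id of the first assembly whose selection contains the chain."""
    for asm in structure.assemblies:
        if chain_id in asm.referenced_chains():
            return asm.assembly_id
    return None


# ---------------------------------------------------------------------------
# polymer / non-polymer split


def split_polymer_nonpolymer(chain: Chain) -> tuple[Chain, list[Residue]]:
    """Split a chain into its polymer part and individual non-polymer residues.

    In mmCIF the polymer part carries numeric ``label_seq_id`` values while
    small molecules and waters carry a period; that distinction is what is
    split on here.
    """
    polymer = Chain(
        chain_id=chain.chain_id,
        residues=[r for r in chain.residues if r.is_polymer],
    )
    nonpoly = [r for r in chain.residues if not r.is_polymer]
    return polymer, nonpoly


# ---------------------------------------------------------------------------
# PDB writing


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and len(name) <= 3:
        return f" {name:<3}"
    return f"{name:<4}"


def write_pdb(structure: Structure, path: str | os.PathLike) -> dict[str, str]:
    """Write a Structure in PDB format.

    Returns the chain renaming table (original id -> single-character id).
    Structures with more than 99,999 atoms or 62 chains are refused: the
    fixed-width PDB format cannot represent them and callers should keep
    the mmCIF file instead.
    """
    natoms = structure.atom_count()
    if natoms > PDB_MAX_ATOMS:
        raise StructureTooLargeError(
            f"{structure.entry_id}: {natoms} atoms exceed the PDB limit of "
            f"{PDB_MAX_ATOMS}"
        )
    if len(structure.chains) > PDB_MAX_CHAINS:
        raise StructureTooLargeError(
            f"{structure.entry_id}: {len(structure.chains)} chains exceed the "
            f"PDB limit of {PDB_MAX_CHAINS}"
        )

    rename: dict[str, str] = {}
    used: set[str] = set()
    for ch in structure.chains:
        if len(ch.chain_id) == 1 and ch.chain_id not in used:
            rename[ch.chain_id] = ch.chain_id
            used.add(ch.chain_id)
    for ch in structure.chains:
        if ch.chain_id in rename:
            continue
        new = next(c for c in _PDB_CHAIN_POOL if c not in used)
        rename[ch.chain_id] = new
        used.add(new)

    lines = []
    serial = 0

    def emit(r, cid: str) -> None:
        nonlocal serial
        record = "ATOM  " if r.is_polymer else "HETATM"
        for a in r.atoms:
            serial += 1
            lines.append(
                f"{record}{serial:>5} {_format_atom_name(a.name, a.element)}"
                f" {r.comp_id:>3} {cid}{r.auth_seq:>4}{r.icode or ' '}   "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2}"
            )

    for ch in structure.chains:
        cid = rename[ch.chain_id]
        polymer = [r for r in ch.residues if r.is_polymer]
        for r in polymer:
            emit(r, cid)
        if polymer:  # TER closes the polymer before any ligand/water
            serial += 1
            last = polymer[-1]
            lines.append(
                f"TER   {serial:>5}      {last.comp_id:>3} {cid}"
                f"{last.auth_seq:>4}{last.icode or ' '}"
            )
        for r in ch.residues:
            if not r.is_polymer:
                emit(r, cid)
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return rename
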