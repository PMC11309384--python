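"""Synthetic full-atom RNA structures, ligand placements and toy tables.

Everything downstream is testable without downloads: helical duplexes
and hairpins are built from idealised planar nucleobase geometry (rings
constructed as regular polygons, Watson-Crick/wobble partners placed by
a one-time least-squares fit onto 2.85 A hydrogen-bond distances and a
10.4 A C1'-C1' separation) stacked with A-form-like rise 2.81 A and
twist 32.7 deg.  The fidelity target is that every designed pair passes
the package's geometric pair test at zero jitter — not crystallographic
realism.  All generators are deterministic under a fixed seed and every
structure is returned together with its ground truth.

``make_u2_snrnp_like`` builds a synthetic stand-in for the U2B"-U2A'
spliceosomal complex (PDB entry 1a9n): the real mmCIF is not bundled,
but the stand-in reproduces its published chain layout — six chains,
four protein (A, B, C, D) and two RNA (Q, R), with assembly 1 = A,B,Q
and assembly 2 = C,D,R — over synthetic coordinates.
"""

from __future__ import annotations

import functools
import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .chaintypes import ComponentInfo
from .model import AssemblyDef, Atom, Chain, Residue, ResidueKind, Structure

RISE = 2.81          # A per base pair step
TWIST = 32.7         # degrees per base pair step
C1_C1 = 10.4         # A across a pair
HBOND_TARGET = 2.85  # A donor-acceptor distance aimed for

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {"G": "U", "U": "G"}

_HBOND_ATOMS = {
    ("A", "U"): [("N6", "O4"), ("N1", "N3")],
    ("G", "C"): [("O6", "N4"), ("N1", "N3"), ("N2", "O2")],
    ("G", "U"): [("N1", "O2"), ("O6", "N3")],
}
for (x, y), prs in list(_HBOND_ATOMS.items()):
    _HBOND_ATOMS[(y, x)] = [(b, a) for a, b in prs]


# ---------------------------------------------------------------------------
# idealised base geometry


def _hexagon(names: list[str], bond: float = 1.38) -> dict[str, np.ndarray]:
    """Regular hexagon, vertices labelled counterclockwise."""
    out = {}
    r = bond  # circumradius of a regular hexagon equals the side length
    for k, name in enumerate(names):
        ang = math.radians(90 + 60 * k)
        out[name] = np.array([r * math.cos(ang), r * math.sin(ang)])
    return out


def _pentagon_on_edge(p1: np.ndarray, p2: np.ndarray, away_from: np.ndarray
                      ) -> list[np.ndarray]:
    """Remaining 3 vertices of a regular pentagon sharing edge p1-p2."""
    side = np.linalg.norm(p2 - p1)
    # interior angle 108 deg; walk around the pentagon from p2
    pts = [p1, p2]
    direction = (p2 - p1) / side
    ang = math.radians(180 - 108)
    # choose turning sign that moves away from the hexagon centre
    for sign in (1.0, -1.0):
        cand = []
        d = direction.copy()
        cur = p2.copy()
        rot = np.array([[math.cos(sign * ang), -math.sin(sign * ang)],
                        [math.sin(sign * ang), math.cos(sign * ang)]])
        for _ in range(3):
            d = rot @ d
            cur = cur + d * side
            cand.append(cur.copy())
        centroid = np.mean([p1, p2] + cand, axis=0)
        if np.linalg.norm(centroid - away_from) > 0.5:
            return cand
    raise RuntimeError("pentagon construction failed")


@functools.lru_cache(maxsize=None)
def _base_frame(base: str) -> dict[str, tuple[float, float]]:
    """Planar heavy-atom coordinates of one nucleobase plus its C1'.

    2D coordinates in the base's own frame; the glycosidic nitrogen
    (N9 for purines, N1 for pyrimidines) anchors the C1' pointing away
    from the ring centre.
    """
    if base in ("C", "U"):
        ring = _hexagon(["N1", "C2", "N3", "C4", "C5", "C6"])
        centre = np.mean(list(ring.values()), axis=0)
        frame = dict(ring)
        for src, name, bond in (("C2", "O2", 1.24),
                                ("C4", "O4" if base == "U" else "N4",
                                 1.24 if base == "U" else 1.35)):
            d = ring[src] - centre
            frame[name] = ring[src] + d / np.linalg.norm(d) * bond
        glyco = "N1"
    else:
        ring = _hexagon(["N1", "C2", "N3", "C4", "C5", "C6"])
        centre6 = np.mean(list(ring.values()), axis=0)
        n7, c8, n9 = _pentagon_on_edge(ring["C5"], ring["C4"], centre6)
        frame = dict(ring)
        frame["N7"], frame["C8"], frame["N9"] = n7, c8, n9
        centre = np.mean([frame[n] for n in
                          ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8",
                           "N9")], axis=0)
        if base == "A":
            d = ring["C6"] - centre
            frame["N6"] = ring["C6"] + d / np.linalg.norm(d) * 1.35
        else:
            d = ring["C6"] - centre
            frame["O6"] = ring["C6"] + d / np.linalg.norm(d) * 1.24
            d = ring["C2"] - centre
            frame["N2"] = ring["C2"] + d / np.linalg.norm(d) * 1.35
        glyco = "N9"
    d = frame[glyco] - centre
    frame["C1'"] = frame[glyco] + d / np.linalg.norm(d) * 1.47
    return {k: (float(v[0]), float(v[1])) for k, v in frame.items()}


def _se2(theta: float, tx: float, ty: float):
    c, s = math.cos(theta), math.sin(theta)
    R = np.array([[c, -s], [s, c]])
    t = np.array([tx, ty])
    return lambda p: R @ p + t


def _orient_base(frame: dict[str, tuple[float, float]], c1_target: np.ndarray,
                 inward: np.ndarray, mirror: bool
                 ) -> dict[str, np.ndarray]:
    """Rigidly place a base frame so C1' sits at c1_target with the ring
    centre towards ``inward``; ``mirror`` flips the base over first."""
    pts = {k: np.array(v) for k, v in frame.items()}
    if mirror:
        pts = {k: np.array([v[0], -v[1]]) for k, v in pts.items()}
    ring_names = [n for n in pts if n != "C1'"]
    centre = np.mean([pts[n] for n in ring_names], axis=0)
    d = centre - pts["C1'"]
    theta0 = math.atan2(inward[1], inward[0]) - math.atan2(d[1], d[0])
    move = _se2(theta0, 0, 0)
    pts = {k: move(v) for k, v in pts.items()}
    shift = c1_target - pts["C1'"]
    return {k: v + shift for k, v in pts.items()}


@functools.lru_cache(maxsize=None)
def _pair_frame(ptype: str) -> dict[str, dict[str, tuple[float, float]]]:
    """2D coordinates of both bases of a canonical pair, C1' midpoint at 0.

    Side 1 is fixed with its C1' at (-C1_C1/2, 0) pointing inward; side 2
    is mirrored and refined by least squares onto the canonical
    hydrogen-bond distances and the C1'-C1' separation.
    """
    b1, b2 = ptype[0], ptype[1]
    half = C1_C1 / 2.0
    side1 = _orient_base(_base_frame(b1), np.array([-half, 0.0]),
                         np.array([1.0, 0.0]), mirror=False)
    hbonds = _HBOND_ATOMS[(b1, b2)]

    def place2(params):
        theta, tx, ty = params
        base = _orient_base(_base_frame(b2), np.array([half + tx, ty]),
                            np.array([-1.0, 0.0]), mirror=True)
        move = _se2(theta, 0, 0)
        pivot = base["C1'"]
        return {k: pivot + move(v - pivot) for k, v in base.items()}

    def residuals(params):
        s2 = place2(params)
        res = []
        for a1, a2 in hbonds:
            res.append(np.linalg.norm(side1[a1] - s2[a2]) - HBOND_TARGET)
        res.append(0.3 * (np.linalg.norm(side1["C1'"] - s2["C1'"]) - C1_C1))
        return res

    fit = least_squares(residuals, x0=np.zeros(3), method="lm")
    side2 = place2(fit.x)
    for a1, a2 in hbonds:
        d = np.linalg.norm(side1[a1] - side2[a2])
        if not (2.4 <= d <= 3.3):
            raise RuntimeError(
                f"pair geometry for {ptype} failed: {a1}-{a2} at {d:.2f} A")
    return {
        "side1": {k: (float(v[0]), float(v[1])) for k, v in side1.items()},
        "side2": {k: (float(v[0]), float(v[1])) for k, v in side2.items()},
    }


_BACKBONE_OFFSETS = [
    # name, along-glycosidic multiplier, perpendicular multiplier, z offset
    ("C2'", 1.0, 0.9, -0.6),
    ("O2'", 1.9, 1.5, -1.1),
    ("C3'", 1.9, -0.4, 0.6),
    ("O3'", 3.0, -0.7, 0.9),
    ("C4'", 2.4, 0.6, 1.2),
    ("O4'", 1.3, -0.9, 0.2),
    ("C5'", 3.3, 0.9, 1.6),
    ("O5'", 4.1, 0.2, 2.0),
    ("P", 4.9, -0.5, 2.5),
    ("OP1", 5.6, 0.3, 2.9),
    ("OP2", 5.3, -1.4, 3.0),
]


def _residue_atoms(base: str, frame2d: dict[str, tuple[float, float]],
                   level: int, rise: float, twist: float) -> list[Atom]:
    """3D atoms of one nucleotide at one helical level."""
    ang = math.radians(twist) * level
    c, s = math.cos(ang), math.sin(ang)
    Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    z = np.array([0.0, 0.0, rise * level])

    pts = {k: np.array(v) for k, v in frame2d.items()}
    ring_names = [n for n in pts if n != "C1'"]
    centre = np.mean([pts[n] for n in ring_names], axis=0)
    out_dir = pts["C1'"] - centre
    out_dir = out_dir / np.linalg.norm(out_dir)
    perp = np.array([-out_dir[1], out_dir[0]])

    atoms = []
    for name, xy in pts.items():
        p3 = np.array([xy[0], xy[1], 0.0])
        atoms.append((name, p3))
    for name, along, across, dz in _BACKBONE_OFFSETS:
        xy = pts["C1'"] + out_dir * along + perp * across
        atoms.append((name, np.array([xy[0], xy[1], dz])))

    result = []
    for name, p3 in atoms:
        coords = Rz @ p3 + z
        element = name[0] if name[0] in "CNOP" else name[0]
        result.append(Atom(name=name, element=element, coords=coords))
    return result


# ---------------------------------------------------------------------------
# duplex and hairpin generators


@dataclass
class HelixSpec:
    """Specification of a synthetic duplex (strand 2 = reverse complement,
    with G:U wobbles at the named 1-based positions of strand 1)."""

    sequence: str
    rise: float = RISE
    twist: float = TWIST
    jitter_sd: float = 0.0
    seed: int = 0
    gu_positions: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        for ch in self.sequence.upper():
            if ch not in "ACGU":
                raise ValueError(f"invalid base {ch!r} in helix sequence")
        for p in self.gu_positions:
            base = self.sequence.upper()[p - 1]
            if base not in _WOBBLE:
                raise ValueError(
                    f"G:U substitution at position {p} needs G or U, "
                    f"found {base}")


@dataclass
class GroundTruth:
    """Designed facts emitted with every generated structure."""

    pairs: list[tuple[int, int, str]] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)
    ligands: list[dict] = field(default_factory=list)
    dotbracket: str = ""


def _apply_jitter(structure: Structure, sd: float, seed: int) -> None:
    """Perturb every atom by a truncated Gaussian displacement.

    The displacement magnitude is capped at ``sd``, so a 0.3 A jitter
    changes any interatomic distance by at most 0.6 A — keeping every
    designed pair inside the geometric test's tolerance windows.
    """
    if sd <= 0:
        return
    rng = np.random.default_rng(seed)
    for ch in structure.chains:
        for res in ch.residues:
            for at in res.atoms:
                step = rng.normal(0.0, sd / math.sqrt(3.0), size=3)
                norm = float(np.linalg.norm(step))
                if norm > sd:
                    step *= sd / norm
                at.coords = at.coords + step


def _make_residue(base: str, side: str, ptype: str, level: int,
                  label_seq: int, rise: float, twist: float) -> Residue:
    frame = _pair_frame(ptype)[side]
    atoms = _residue_atoms(base, frame, level, rise, twist)
    return Residue(comp_id=base, auth_seq=label_seq, label_seq=label_seq,
                   kind=ResidueKind.RIBONUCLEOTIDE, atoms=atoms)


def make_duplex(spec: HelixSpec, entry_id: str = "fdup",
                chain_ids: tuple[str, str] = ("A", "B")
                ) -> tuple[Structure, GroundTruth]:
    """Two-chain helical duplex; every designed pair is canonical.

    Ground-truth pair positions are global over chain 1 then chain 2
    (chain 1 position i pairs with global position 2n+1-i).
    """
    seq1 = spec.sequence.upper()
    n = len(seq1)
    pair_types = []
    for i, b in enumerate(seq1, start=1):
        partner = _WOBBLE[b] if i in spec.gu_positions else _COMPLEMENT[b]
        pair_types.append(b + partner)
    seq2_rev = [pt[1] for pt in pair_types]       # 3'->5' along chain 2
    seq2 = "".join(reversed(seq2_rev))            # chain 2 in 5'->3'

    chain1 = Chain(chain_ids[0])
    for i, ptype in enumerate(pair_types):
        chain1.residues.append(
            _make_residue(ptype[0], "side1", ptype, i, i + 1,
                          spec.rise, spec.twist))
    chain2 = Chain(chain_ids[1])
    for idx in range(n):                          # chain 2 5'->3'
        level = n - 1 - idx
        ptype = pair_types[level]
        chain2.residues.append(
            _make_residue(ptype[1], "side2", ptype, level, idx + 1,
                          spec.rise, spec.twist))

    asm = AssemblyDef("1", [((chain_ids[0], chain_ids[1]), np.eye(4))])
    structure = Structure(entry_id=entry_id, chains=[chain1, chain2],
                          assemblies=[asm])
    _apply_jitter(structure, spec.jitter_sd, spec.seed)

    truth = GroundTruth(
        pairs=[(i, 2 * n + 1 - i, pair_types[i - 1])
               for i in range(1, n + 1)],
        sequences={chain_ids[0]: seq1, chain_ids[1]: seq2},
    )
    return structure, truth


_LOOP_BASES = "UUCGAUCA"


def make_hairpin(stem_len: int, loop_len: int, seed: int = 0,
                 jitter_sd: float = 0.0, entry_id: str = "fhp",
                 chain_id: str = "A") -> tuple[Structure, GroundTruth]:
    """Single-chain stem-loop; stem from duplex geometry, loop on a
    rising arc that keeps every loop nucleotide unpairable (any two
    residues four or more apart in sequence end up beyond the pairing
    distance window)."""
    if stem_len < 2:
        raise ValueError("stem_len must be >= 2")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    stem5 = "".join("GC"[i % 2] for i in range(stem_len))
    loop = "".join(_LOOP_BASES[i % len(_LOOP_BASES)] for i in range(loop_len))
    stem3 = "".join(_COMPLEMENT[b] for b in reversed(stem5))
    seq = stem5 + loop + stem3
    n = len(seq)

    chain = Chain(chain_id)
    for i in range(stem_len):                      # 5' side of the stem
        ptype = stem5[i] + _COMPLEMENT[stem5[i]]
        chain.residues.append(
            _make_residue(stem5[i], "side1", ptype, i, i + 1,
                          RISE, TWIST))
    z_top = (stem_len - 1) * RISE
    for k, b in enumerate(loop):                   # rising loop arc
        level_angle = math.radians(TWIST) * (stem_len + k)
        radius = 6.5
        centre = np.array([radius * math.cos(level_angle),
                           radius * math.sin(level_angle),
                           z_top + 3.2 * (k + 1)])
        frame = _base_frame(b)
        pts = {nm: np.array(v) for nm, v in frame.items()}
        ring = [nm for nm in pts if nm != "C1'"]
        ring_centre = np.mean([pts[nm] for nm in ring], axis=0)
        outward = centre[:2] / np.linalg.norm(centre[:2])
        atoms = []
        for nm, v in pts.items():
            rel = v - ring_centre
            # base laid flat, pushed outward from the hairpin axis
            p = np.array([
                centre[0] + outward[0] * (2.0 + rel[0]),
                centre[1] + outward[1] * (2.0 + rel[0]),
                centre[2] + rel[1] * 0.6,
            ])
            atoms.append(Atom(nm, nm[0], p))
        for nm, along, across, dz in _BACKBONE_OFFSETS:
            p = np.array([
                centre[0] + outward[0] * (3.0 + 0.3 * along),
                centre[1] + outward[1] * (3.0 + 0.3 * along) + 0.3 * across,
                centre[2] + dz * 0.4,
            ])
            atoms.append(Atom(nm, nm[0], p))
        chain.residues.append(Residue(
            comp_id=b, auth_seq=stem_len + k + 1,
            label_seq=stem_len + k + 1,
            kind=ResidueKind.RIBONUCLEOTIDE, atoms=atoms))
    for i in range(stem_len):                      # 3' side of the stem
        pair_pos = stem_len - 1 - i                # pairs with 5' side pos
        ptype = stem5[pair_pos] + _COMPLEMENT[stem5[pair_pos]]
        chain.residues.append(
            _make_residue(stem3[i], "side2", ptype, pair_pos,
                          stem_len + loop_len + i + 1, RISE, TWIST))

    asm = AssemblyDef("1", [((chain_id,), np.eye(4))])
    structure = Structure(entry_id=entry_id, chains=[chain],
                          assemblies=[asm])
    _apply_jitter(structure, jitter_sd, seed)

    pairs = [(i, n + 1 - i, stem5[i - 1] + _COMPLEMENT[stem5[i - 1]])
             for i in range(1, stem_len + 1)]
    dot = ("(" * stem_len) + ("." * loop_len) + (")" * stem_len)
    return structure, GroundTruth(pairs=pairs,
                                  sequences={chain_id: seq},
                                  dotbracket=dot)


# ---------------------------------------------------------------------------
# ligand placement


def _copy_structure(structure: Structure) -> Structure:
    chains = []
    for ch in structure.chains:
        residues = []
        for r in ch.residues:
            atoms = [Atom(a.name, a.element, np.array(a.coords),
                          a.is_hydrogen) for a in r.atoms]
            residues.append(Residue(r.comp_id, r.auth_seq, r.kind, atoms,
                                    r.label_seq, r.icode))
        chains.append(Chain(ch.chain_id, residues))
    return Structure(structure.entry_id, chains,
                     [AssemblyDef(a.assembly_id, list(a.operations))
                      for a in structure.assemblies],
                     structure.resolution, dict(structure.species_taxids))


def place_ligand(structure: Structure,
                 target_atoms: Sequence[tuple[str, int, str]],
                 distance: float, component: ComponentInfo,
                 auth_seq: int = 1001) -> Structure:
    """Place a ligand so its reference atom sits at the requested distance
    (within 0.05 A) from every named target atom.

    ``target_atoms`` are (chain_id, auth_seq, atom_name) references.  The
    reference atom is the component's single metal atom when there is
    one, otherwise its first formula element; remaining heavy atoms are
    arranged octahedrally around it.  Raises when no point satisfies the
    distance constraints.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    targets = []
    for chain_id, seq, atom_name in target_atoms:
        ch = structure.chain(chain_id)
        res = next((r for r in ch.residues if r.auth_seq == seq), None)
        if res is None:
            raise KeyError(f"no residue {seq} in chain {chain_id}")
        at = res.atom(atom_name)
        if at is None:
            raise KeyError(f"no atom {atom_name} in {chain_id}:{seq}")
        targets.append(np.array(at.coords))
    T = np.asarray(targets)

    all_xyz = np.array([a.coords for c in structure.chains
                        for r in c.residues for a in r.atoms])
    outward = T.mean(axis=0) - all_xyz.mean(axis=0)
    norm = np.linalg.norm(outward)
    outward = outward / norm if norm > 1e-6 else np.array([1.0, 0.0, 0.0])

    def residuals(x):
        return np.linalg.norm(T - x, axis=1) - distance

    best = None
    for scale in (1.0, 0.3, 2.0, 0.0):
        x0 = T.mean(axis=0) + outward * distance * scale
        fit = least_squares(residuals, x0=x0)
        err = np.abs(residuals(fit.x)).max()
        if best is None or err < best[0]:
            best = (err, fit.x)
    err, centre = best
    if err > 0.05:
        raise ValueError(
            f"cannot place ligand at {distance} A from all targets "
            f"(best residual {err:.3f} A)")

    # build the ligand residue
    elements = []
    metal_first = sorted(component.formula.items(),
                         key=lambda kv: (kv[1], kv[0]))
    for el, count in metal_first:
        if el in ("H", "D"):
            continue
        elements.extend([el] * count)
    octa = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                     [0, -1, 0], [0, 0, 1], [0, 0, -1]], float) * 1.97
    atoms = [Atom(elements[0].upper(), elements[0], centre)]
    for k, el in enumerate(elements[1:]):
        offset = octa[k % 6] * (1 + k // 6)
        atoms.append(Atom(f"{el.upper()}{k+1}", el, centre + offset))

    out = _copy_structure(structure)
    ligand_res = Residue(comp_id=component.ccd_id, auth_seq=auth_seq,
                         kind=ResidueKind.OTHER, atoms=atoms, label_seq=None)
    out.chains[0].residues.append(ligand_res)
    return out


# ---------------------------------------------------------------------------
# random clouds for the contact oracle


def make_random_cloud(seed: int, n_rna_atoms: int = 150,
                      n_ligand_atoms: int = 50, box: float = 20.0
                      ) -> tuple[Chain, list]:
    """Random atom cloud pair for brute-force contact comparisons."""
    from .interactions import AtomRef

    rng = np.random.default_rng(seed)
    elements = np.array(["C", "N", "O", "P", "H"])
    chain = Chain("X")
    res_count = max(1, n_rna_atoms // 10)
    idx = 0
    for r in range(res_count):
        atoms = []
        take = n_rna_atoms // res_count if r < res_count - 1 else \
            n_rna_atoms - (res_count - 1) * (n_rna_atoms // res_count)
        for _ in range(take):
            el = str(rng.choice(elements))
            atoms.append(Atom(f"X{idx}", el,
                              rng.uniform(0, box, 3), is_hydrogen=el == "H"))
            idx += 1
        chain.residues.append(Residue("N", r + 1, ResidueKind.RIBONUCLEOTIDE,
                                      atoms, label_seq=r + 1))
    ligand = []
    for k in range(n_ligand_atoms):
        el = str(rng.choice(elements))
        at = Atom(f"L{k}", el, rng.uniform(0, box, 3), is_hydrogen=el == "H")
        ligand.append((AtomRef("L", 0, "LIG", 1, "", at.name, el), at))
    return chain, ligand


# ---------------------------------------------------------------------------
# mmCIF writing (fixture dialect; read back with structio.read_mmcif)


def _cif_quote(value: str) -> str:
    if any(ch in value for ch in " '\"") or value == "":
        return f'"{value}"'
    return value


def write_mmcif(structure: Structure, path, taxids: Optional[dict] = None
                ) -> None:
    """Write a fixture structure as mmCIF (atom_site + entities +
    assembly categories), parseable by gemmi and by structio."""
    taxids = taxids or structure.species_taxids
    lines = [f"data_{structure.entry_id}",
             f"_entry.id {structure.entry_id.upper()}"]

    # entities: one polymer entity per chain; one entity per non-polymer comp
    entity_of_chain: dict[str, str] = {}
    nonpoly_entities: dict[str, str] = {}
    next_entity = 1
    for ch in structure.chains:
        if ch.polymer_residues():
            entity_of_chain[ch.chain_id] = str(next_entity)
            next_entity += 1
    for ch in structure.chains:
        for r in ch.nonpolymer_residues():
            if r.comp_id not in nonpoly_entities:
                kind = "water" if r.kind is ResidueKind.WATER else "non-polymer"
                nonpoly_entities[r.comp_id] = str(next_entity)
                next_entity += 1
    lines += ["loop_", "_entity.id", "_entity.type"]
    for cid, eid in entity_of_chain.items():
        lines.append(f"{eid} polymer")
    for comp, eid in nonpoly_entities.items():
        kind = "water" if comp in ("HOH", "DOD") else "non-polymer"
        lines.append(f"{eid} {kind}")

    if taxids:
        lines += ["loop_", "_entity_src_gen.entity_id",
                  "_entity_src_gen.pdbx_gene_src_ncbi_taxonomy_id"]
        for cid, tax in taxids.items():
            if cid in entity_of_chain:
                lines.append(f"{entity_of_chain[cid]} {tax}")

    # label_asym per (chain, polymer/nonpoly-entity)
    label_asym: dict[tuple[str, str], str] = {}
    pool = [chr(c) for c in range(ord("A"), ord("Z") + 1)] + \
           [f"A{chr(c)}" for c in range(ord("A"), ord("Z") + 1)]
    pos = 0
    for ch in structure.chains:
        if ch.polymer_residues():
            label_asym[(ch.chain_id, "poly")] = pool[pos]
            pos += 1
    for ch in structure.chains:
        comps = {r.comp_id for r in ch.nonpolymer_residues()}
        for comp in sorted(comps):
            label_asym[(ch.chain_id, comp)] = pool[pos]
            pos += 1

    if structure.assemblies:
        lines += ["loop_", "_pdbx_struct_assembly.id",
                  "_pdbx_struct_assembly.details",
                  "_pdbx_struct_assembly.method_details",
                  "_pdbx_struct_assembly.oligomeric_details",
                  "_pdbx_struct_assembly.oligomeric_count"]
        for asm in structure.assemblies:
            nch = len(asm.referenced_chains())
            lines.append(f"{asm.assembly_id} author_defined_assembly ? ? {nch}")
        lines += ["loop_", "_pdbx_struct_assembly_gen.assembly_id",
                  "_pdbx_struct_assembly_gen.oper_expression",
                  "_pdbx_struct_assembly_gen.asym_id_list"]
        oper_ids: list[np.ndarray] = []
        for asm in structure.assemblies:
            for chains, op in asm.operations:
                op = np.asarray(op, float)
                oper_id = None
                for k, known in enumerate(oper_ids):
                    if np.allclose(known, op):
                        oper_id = k + 1
                        break
                if oper_id is None:
                    oper_ids.append(op)
                    oper_id = len(oper_ids)
                asyms = []
                for cid in chains:
                    for (c, kindkey), asym in label_asym.items():
                        if c == cid and asym not in asyms:
                            asyms.append(asym)
                lines.append(
                    f"{asm.assembly_id} {oper_id} {','.join(asyms)}")
        lines += ["loop_", "_pdbx_struct_oper_list.id",
                  "_pdbx_struct_oper_list.type",
                  "_pdbx_struct_oper_list.name"]
        for r_ in range(1, 4):
            for c_ in range(1, 4):
                lines.append(f"_pdbx_struct_oper_list.matrix[{r_}][{c_}]")
            lines.append(f"_pdbx_struct_oper_list.vector[{r_}]")
        for k, op in enumerate(oper_ids, start=1):
            kind = ("identity operation" if np.allclose(op, np.eye(4))
                    else "crystal symmetry operation")
            vals = []
            for r_ in range(3):
                vals.extend(f"{op[r_, c_]:.6f}" for c_ in range(3))
                vals.append(f"{op[r_, 3]:.6f}")
            lines.append(f"{k} {_cif_quote(kind)} {k}_555 " + " ".join(vals))

    lines += ["loop_",
              "_atom_site.group_PDB", "_atom_site.id",
              "_atom_site.type_symbol", "_atom_site.label_atom_id",
              "_atom_site.label_alt_id", "_atom_site.label_comp_id",
              "_atom_site.label_asym_id", "_atom_site.label_entity_id",
              "_atom_site.label_seq_id", "_atom_site.pdbx_PDB_ins_code",
              "_atom_site.Cartn_x", "_atom_site.Cartn_y", "_atom_site.Cartn_z",
              "_atom_site.occupancy", "_atom_site.B_iso_or_equiv",
              "_atom_site.auth_seq_id", "_atom_site.auth_asym_id",
              "_atom_site.pdbx_PDB_model_num"]
    serial = 0
    for ch in structure.chains:
        for r in ch.residues:
            if r.is_polymer:
                asym = label_asym[(ch.chain_id, "poly")]
                eid = entity_of_chain[ch.chain_id]
                seq = str(r.label_seq)
                group = "ATOM"
            else:
                asym = label_asym[(ch.chain_id, r.comp_id)]
                eid = nonpoly_entities[r.comp_id]
                seq = "."
                group = "HETATM"
            for a in r.atoms:
                serial += 1
                x, y, z = a.coords
                lines.append(
                    f"{group} {serial} {a.element} {_cif_quote(a.name)} . "
                    f"{r.comp_id} {asym} {eid} {seq} ? "
                    f"{x:.3f} {y:.3f} {z:.3f} 1.00 0.00 "
                    f"{r.auth_seq} {ch.chain_id} 1")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# synthetic stand-in for the U2B"-U2A' complex chain layout


def _protein_chain(chain_id: str, n_res: int, origin: np.ndarray) -> Chain:
    chain = Chain(chain_id)
    for i in range(n_res):
        base = origin + np.array([3.8 * i, 0.0, 0.0])
        atoms = [
            Atom("N", "N", base + np.array([0.0, 0.0, 0.0])),
            Atom("CA", "C", base + np.array([1.2, 0.8, 0.2])),
            Atom("C", "C", base + np.array([2.4, 0.2, -0.1])),
            Atom("O", "O", base + np.array([2.6, -1.0, -0.2])),
            Atom("CB", "C", base + np.array([1.3, 1.9, 1.0])),
        ]
        chain.residues.append(Residue("ALA", i + 1, ResidueKind.AMINO_ACID,
                                      atoms, label_seq=i + 1))
    return chain


def make_u2_snrnp_like() -> Structure:
    """Synthetic stand-in for the 1a9n chain/assembly layout.

    Six chains — four protein (A, B, C, D) and two RNA (Q, R) — with two
    biological assemblies: assembly 1 contains chains A, B and Q,
    assembly 2 contains chains C, D and R.  Coordinates are synthetic
    (the real structure is not bundled); only the census and the
    assembly bookkeeping mirror the real entry.
    """
    rna1, _ = make_hairpin(8, 8, entry_id="1a9n", chain_id="Q")
    rna2, _ = make_hairpin(8, 8, entry_id="1a9n", chain_id="R")
    chains = [
        _protein_chain("A", 25, np.array([40.0, 0.0, 0.0])),
        _protein_chain("B", 20, np.array([40.0, 30.0, 0.0])),
        _protein_chain("C", 25, np.array([-40.0, 0.0, 40.0])),
        _protein_chain("D", 20, np.array([-40.0, 30.0, 40.0])),
    ]
    q = rna1.chains[0]
    r = rna2.chains[0]
    for res in r.residues:
        for a in res.atoms:
            a.coords = a.coords + np.array([-60.0, 0.0, 40.0])
    chains.insert(2, q)   # order A, B, Q, C, D, R
    chains.insert(5, r)
    assemblies = [
        AssemblyDef("1", [(("A", "B", "Q"), np.eye(4))]),
        AssemblyDef("2", [(("C", "D", "R"), np.eye(4))]),
    ]
    return Structure(entry_id="1a9n", chains=chains, assemblies=assemblies,
                     resolution=2.4,
                     species_taxids={"A": "9606", "B": "9606", "C": "9606",
                                     "D": "9606", "Q": "9606", "R": "9606"})


# ---------------------------------------------------------------------------
# toy mapping tables + manifest


def make_toy_tables(outdir, seed: int = 0) -> dict:
    """Write miniature mapping tables with known joint content.

    The manifest records every annotation the pipeline is expected to
    produce for the fixture bundle; tests treat it as the oracle.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, v) for k, v in {
        "rfam_pdb": "Rfam.pdb.tsv",
        "rfam2go": "rfam2go.txt",
        "rnacentral_pdb": "pdb.tsv",
        "goa_gaf": "goa.gaf",
        "ec2go": "ec2go.txt",
        "crossref_chembl": "ccd2chembl.tsv",
        "crossref_drugbank": "ccd2drugbank.tsv",
        "pwms": "motifs_pwm.txt",
        "go_obo": "go_slim.obo",
        "manifest": "manifest.json",
    }.items()}

    with open(paths["rfam_pdb"], "w") as fh:
        fh.write("rfam_acc\tpdb_id\tchain\tpdb_start\tpdb_end\tbit_score"
                 "\tevalue_score\tcm_start\tcm_end\thex_colour\n")
        fh.write("RF90001\tft01\tA\t1\t16\t55.0\t0.001\t1\t16\tabcdef\n")
        fh.write("RF90002\tft02\tA\t1\t8\t30.0\t0.5\t1\t8\t123456\n")
    with open(paths["rfam2go"], "w") as fh:
        fh.write("Rfam:RF90001 toy_hairpin > "
                 "GO:structural constituent of ribosome ; GO:0003735\n")
        fh.write("Rfam:RF90002 toy_duplex > "
                 "GO:ribonuclease P RNA activity ; GO:0004526\n")
    with open(paths["rnacentral_pdb"], "w") as fh:
        fh.write("URS9000001\tPDB\tFT01_A\t9606\trRNA\t\n")
    with open(paths["goa_gaf"], "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        fh.write("RNAcentral\tURS9000001\ttoy\tenables\tGO:0005840\t"
                 "PMID:1\tIEA\t\tC\ttoy RNA\t\tRNA\ttaxon:9606\t20240101\t"
                 "RNAcentral\t\t\n")
        fh.write("RNAcentral\tURS9000001\ttoy\tNOT|enables\tGO:0099999\t"
                 "PMID:1\tIEA\t\tF\ttoy RNA\t\tRNA\ttaxon:9606\t20240101\t"
                 "RNAcentral\t\t\n")
    with open(paths["ec2go"], "w") as fh:
        fh.write("EC:3.1.26.5 > GO:ribonuclease P RNA activity ; "
                 "GO:0004526\n")
    with open(paths["crossref_chembl"], "w") as fh:
        fh.write("MG\tCHEMBL1200547\n")
    with open(paths["crossref_drugbank"], "w") as fh:
        fh.write("MG\tDB01378\n")
    with open(paths["pwms"], "w") as fh:
        fh.write(">TOYM1\t9606\n")
        consensus = "GCUUCGAU"
        for b in consensus:
            row = {x: 0.01 for x in "ACGU"}
            row[b] = 0.97
            fh.write("\t".join(f"{row[x]:.2f}" for x in "ACGU") + "\n")
    with open(paths["go_obo"], "w") as fh:
        fh.write("""format-version: 1.2
ontology: go-toy

[Term]
id: GO:0003735
name: structural constituent of ribosome
namespace: molecular_function
is_a: GO:0005198 ! structural molecule activity

[Term]
id: GO:0005198
name: structural molecule activity
namespace: molecular_function

[Term]
id: GO:0004526
name: ribonuclease P RNA activity
namespace: molecular_function
is_a: GO:0003824 ! catalytic activity

[Term]
id: GO:0003824
name: catalytic activity
namespace: molecular_function

[Term]
id: GO:0005840
name: ribosome
namespace: cellular_component
relationship: part_of GO:0005737 ! cytoplasm

[Term]
id: GO:0005737
name: cytoplasm
namespace: cellular_component
""")

    manifest = {
        "ft01_A": {
            "rfam": ["RF90001"],
            "go_mf": ["GO:0003735"],
            "go_bp": [],
            "go_cc": ["GO:0005840"],
            "ec": [],
            "rnacentral": "URS9000001",
            "taxid": "9606",
            "motifs": [["TOYM1", 5]],
            "mg_site_residues": [4, 5],
        },
        "ft02_A": {
            "rfam": ["RF90002"],
            "go_mf": ["GO:0004526"],
            "go_bp": [],
            "go_cc": [],
            "ec": ["3.1.26.5"],
            "rnacentral": "",
            "taxid": "",
            "motifs": [],
            "rna_ligand_chain": "B",
        },
        "crossrefs": {"MG": {"chembl": "CHEMBL1200547",
                             "drugbank": "DB01378"}},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return paths


def make_fixture_bundle(outdir, seed: int = 0) -> dict:
    """Write the two fixture structures + toy tables used end-to-end.

    ft01: hairpin (stem 6, loop 4) with an Mg ion bound at residues 4-5.
    ft02: an 8-bp duplex.  Returns the file paths plus the toy-table
    manifest path.
    """
    os.makedirs(outdir, exist_ok=True)
    hp, hp_truth = make_hairpin(6, 8, seed=seed, entry_id="ft01")
    hp_mg = place_ligand(
        hp, [("A", 4, "O2"), ("A", 5, "N9")], 2.1,
        ComponentInfo("MG", {"Mg": 1}, name="magnesium ion"))
    cif1 = os.path.join(outdir, "ft01.cif")
    write_mmcif(hp_mg, cif1, taxids={"A": "9606"})

    dup, dup_truth = make_duplex(
        HelixSpec("GGGGGCCCCC", seed=seed), entry_id="ft02")
    cif2 = os.path.join(outdir, "ft02.cif")
    write_mmcif(dup, cif2)

    tables = make_toy_tables(os.path.join(outdir, "maps"), seed=seed)
    return {"structures": [cif1, cif2], "tables": tables,
            "hairpin_truth": hp_truth, "duplex_truth": dup_truth}
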