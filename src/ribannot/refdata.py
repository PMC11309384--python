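"""Packaged reference tables: vdW radii, metal elements, component kinds."""

from __future__ import annotations

import functools
from importlib import resources

from .model import Atom, ResidueKind

DEFAULT_VDW_RADIUS = 1.80  # Angstrom, for elements outside the table


def _read_tsv(name: str) -> list[list[str]]:
    text = resources.files("ribannot.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


@functools.lru_cache(maxsize=1)
def vdw_radii() -> dict[str, float]:
    rows = _read_tsv("vdw_radii.tsv")
    assert rows[0] == ["element", "radius"]
    return {el: float(r) for el, r in rows[1:]}


@functools.lru_cache(maxsize=1)
def metal_elements() -> frozenset[str]:
    rows = _read_tsv("metals.tsv")
    assert rows[0] == ["element"]
    return frozenset(r[0] for r in rows[1:])


@functools.lru_cache(maxsize=1)
def component_kinds() -> dict[str, ResidueKind]:
    rows = _read_tsv("components.tsv")
    assert rows[0] == ["ccd_id", "kind", "base"]
    return {cid: ResidueKind(kind) for cid, kind, _ in rows[1:]}


@functools.lru_cache(maxsize=1)
def component_bases() -> dict[str, str]:
    """Parent nucleobase letter per nucleotide comp_id."""
    rows = _read_tsv("components.tsv")
    return {cid: base for cid, _, base in rows[1:] if base != "-"}


def vdw_radius(element: str) -> float:
    """Packaged van der Waals radius; unknown elements get 1.80 A."""
    el = element.capitalize() if len(element) <= 2 else element
    return vdw_radii().get(el, DEFAULT_VDW_RADIUS)


_RIBOSE_MARKERS = {"C1'", "C2'", "C3'", "C4'", "O4'"}


def residue_kind(comp_id: str, atoms: list[Atom]) -> ResidueKind:
    """Classify a residue by comp_id, falling back to atom content.

    Unknown comp_ids: a ribose ring with O2' marks a ribonucleotide, a
    ribose without O2' a deoxyribonucleotide, a CA+N+C backbone an amino
    acid; anything else is 'other'.
    """
    known = component_kinds().get(comp_id.upper())
    if known is not None:
        return known
    names = {a.name for a in atoms}
    if len(_RIBOSE_MARKERS & names) >= 4:
        if "O2'" in names:
            return ResidueKind.RIBONUCLEOTIDE
        return ResidueKind.DEOXYRIBONUCLEOTIDE
    if {"CA", "N", "C"} <= names:
        return ResidueKind.AMINO_ACID
    return ResidueKind.OTHER
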