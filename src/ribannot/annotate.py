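"""Annotation joins: Rfam families, GO terms, EC numbers, cross-references.

This module consumes standard mapping-table dialects (Rfam PDB mapping,
rfam2go, RNAcentral pdb.tsv, GAF 2.x, EC2GO, two-column cross-reference
tables, GO ontology OBO) and joins them onto RNA chains.  Rfam hits are
ordered by ascending E-value; GO terms come from the union of the
chain's Rfam families (via rfam2go) and its RNAcentral accession (via
GOA), split by ontology aspect; EC numbers are the EC2GO image of the
chain's GO terms.  The GO-set F1 similarity 2|A∩B|/(|A|+|B|) operates on
ancestor-closed sets.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

ASPECTS = ("MF", "BP", "CC")
_GAF_ASPECT = {"F": "MF", "P": "BP", "C": "CC"}
_NAMESPACE_ASPECT = {
    "molecular_function": "MF",
    "biological_process": "BP",
    "cellular_component": "CC",
}
_GO_RE = re.compile(r"GO:\d{7}")

MAPPING_KINDS = ("rfam_pdb", "rfam2go", "rnacentral_pdb", "goa_gaf",
                 "ec2go", "crossref_2col", "go_obo_edges")


@dataclass(frozen=True)
class RfamHit:
    rfam_acc: str
    e_value: float
    source: str                     # "mapping_file" or "cm_search"

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative E-value for {self.rfam_acc}")


@dataclass
class GOTermSet:
    terms: set[str] = field(default_factory=set)
    closed: bool = False

    def closure(self, ontology: "Ontology") -> "GOTermSet":
        out = set(self.terms)
        for t in self.terms:
            out |= ontology.ancestors(t)
        return GOTermSet(out, closed=True)

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class AnnotationRecord:
    entry_id: str
    chain_id: str
    sequence: str = ""
    rfam_hits: list[RfamHit] = field(default_factory=list)
    go: dict[str, GOTermSet] = field(default_factory=dict)
    ec: set[str] = field(default_factory=set)
    rnacentral_acc: str = ""
    crossrefs: dict[str, dict[str, str]] = field(default_factory=dict)
    species_taxid: str = ""
    pubmed_ids: list[str] = field(default_factory=list)
    active_sites: list = field(default_factory=list)
    motif_hits: list = field(default_factory=list)


class Ontology:
    """GO DAG wrapper: ancestor closure over is_a/part_of edges."""

    def __init__(self, graph: nx.MultiDiGraph):
        self.graph = graph

    def ancestors(self, term: str) -> set[str]:
        if term not in self.graph:
            logger.info("GO term %s absent from ontology, kept as-is", term)
            return set()
        out: set[str] = set()
        stack = [term]
        while stack:
            node = stack.pop()
            for _, parent, key in self.graph.out_edges(node, keys=True):
                if key in ("is_a", "part_of") and parent not in out:
                    out.add(parent)
                    stack.append(parent)
        return out

    def namespace(self, term: str) -> Optional[str]:
        data = self.graph.nodes.get(term)
        if data is None:
            return None
        return data.get("namespace")

    def aspect(self, term: str) -> Optional[str]:
        ns = self.namespace(term)
        return _NAMESPACE_ASPECT.get(ns) if ns else None


# ---------------------------------------------------------------------------
# mapping-table loading


def _skip_stats(kind: str, path, total: int, bad: int) -> None:
    if bad:
        logger.warning("%s %s: skipped %d malformed of %d lines",
                       kind, path, bad, total)
    if total and bad == total:
        raise ValueError(f"{path}: every line malformed for dialect {kind}")


def load_mapping(kind: str, path) -> Union[pd.DataFrame, Ontology]:
    """Load one mapping table in the named dialect.

    Returns a normalised DataFrame (an :class:`Ontology` for
    ``go_obo_edges``).  Malformed lines are logged and skipped; a file
    with no parseable line raises.
    """
    if kind not in MAPPING_KINDS:
        raise ValueError(f"unknown mapping kind {kind!r}; "
                         f"expected one of {MAPPING_KINDS}")
    if kind == "go_obo_edges":
        return Ontology(obonet.read_obo(str(path)))

    rows: list[dict] = []
    total = bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("!", "#")):
                continue
            total += 1
            try:
                parsed = _parse_line(kind, line)
            except ValueError:
                bad += 1
                continue
            if parsed is not None:
                rows.extend(parsed)
    _skip_stats(kind, path, total, bad)
    df = pd.DataFrame(rows, columns=_COLUMNS[kind])
    return df.drop_duplicates().reset_index(drop=True)


_COLUMNS = {
    "rfam_pdb": ["rfam_acc", "pdb_id", "chain", "e_value"],
    "rfam2go": ["rfam_acc", "go_id"],
    "rnacentral_pdb": ["rnacentral_acc", "pdb_id", "chain", "taxid"],
    "goa_gaf": ["accession", "go_id", "aspect"],
    "ec2go": ["ec", "go_id"],
    "crossref_2col": ["from_id", "to_id"],
}


def _parse_line(kind: str, line: str) -> Optional[list[dict]]:
    if kind == "rfam_pdb":
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(line)
        if parts[0] in ("rfam_acc",):  # header
            return None
        if not parts[0].startswith("RF"):
            raise ValueError(line)
        e_value = 0.0
        if len(parts) >= 7:
            try:
                e_value = float(parts[6])
            except ValueError:
                e_value = 0.0
        return [{"rfam_acc": parts[0], "pdb_id": parts[1].lower(),
                 "chain": parts[2], "e_value": e_value}]
    if kind == "rfam2go":
        if "Rfam:" not in line or ">" not in line:
            raise ValueError(line)
        acc = line.split("Rfam:", 1)[1].split()[0]
        gos = _GO_RE.findall(line.split(">", 1)[1])
        if not gos:
            raise ValueError(line)
        return [{"rfam_acc": acc, "go_id": go} for go in gos]
    if kind == "rnacentral_pdb":
        parts = line.split("\t")
        if len(parts) < 4 or parts[1].upper() != "PDB":
            raise ValueError(line)
        ext = parts[2]
        if "_" not in ext:
            raise ValueError(line)
        pdb_id, chain = ext.split("_", 1)
        return [{"rnacentral_acc": parts[0], "pdb_id": pdb_id.lower(),
                 "chain": chain, "taxid": parts[3]}]
    if kind == "goa_gaf":
        parts = line.split("\t")
        if len(parts) < 9:
            raise ValueError(line)
        qualifier = parts[3]
        if "NOT" in qualifier.split("|"):
            return None
        go_id = parts[4]
        if not _GO_RE.fullmatch(go_id):
            raise ValueError(line)
        aspect = _GAF_ASPECT.get(parts[8], "")
        return [{"accession": parts[1], "go_id": go_id, "aspect": aspect}]
    if kind == "ec2go":
        if not line.startswith("EC:") or ">" not in line:
            raise ValueError(line)
        ec = line.split(None, 1)[0][3:]
        gos = _GO_RE.findall(line.split(">", 1)[1])
        if not gos:
            raise ValueError(line)
        return [{"ec": ec, "go_id": go} for go in gos]
    if kind == "crossref_2col":
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise ValueError(line)
        return [{"from_id": parts[0], "to_id": parts[1]}]
    raise AssertionError(kind)


# ---------------------------------------------------------------------------
# Rfam assignment


def parse_cmscan_tblout(path) -> list[RfamHit]:
    """Hits from an Infernal ``cmscan --tblout`` file (parsed, not run)."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 16:
                raise ValueError(
                    f"{path}:{lineno}: malformed cmscan tblout row")
            acc = parts[1] if parts[1].startswith("RF") else parts[0]
            try:
                e_value = float(parts[15])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: bad E-value field {parts[15]!r}"
                ) from exc
            hits.append(RfamHit(acc, e_value, "cm_search"))
    return hits


def assign_rfam(chain_key: tuple[str, str], mapping_table: pd.DataFrame,
                cmscan_tblout=None) -> list[RfamHit]:
    """Rfam families for one chain, ascending by E-value.

    The PDB mapping file takes precedence; a chain absent from it falls
    back to hits parsed from a provided covariance-model search output.
    A chain in neither source gets no family (remote homologs can be
    genuinely missed this way).
    """
    pdb_id, chain = chain_key
    sub = mapping_table[
        (mapping_table["pdb_id"] == pdb_id.lower())
        & (mapping_table["chain"] == chain)]
    hits = [RfamHit(r.rfam_acc, float(r.e_value), "mapping_file")
            for r in sub.itertuples()]
    if not hits and cmscan_tblout is not None:
        hits = parse_cmscan_tblout(cmscan_tblout)
    hits.sort(key=lambda h: (h.e_value, h.rfam_acc))
    return hits


# ---------------------------------------------------------------------------
# GO / EC


def transfer_go(chain_key: tuple[str, str], rfam_hits: Sequence[RfamHit],
                rfam2go: pd.DataFrame, rnacentral_map: pd.DataFrame,
                goa: pd.DataFrame, ontology: Optional[Ontology] = None
                ) -> dict[str, GOTermSet]:
    """Per-aspect GO terms for one chain.

    Union of (a) rfam2go terms over the chain's families and (b) GOA
    terms of the chain's RNAcentral accession.  Aspects come from the
    ontology namespace when available, else from the GAF aspect column,
    else default to MF with a log message.
    """
    pdb_id, chain = chain_key
    term_aspect: dict[str, str] = {}

    fams = {h.rfam_acc for h in rfam_hits}
    if len(rfam2go):
        for row in rfam2go[rfam2go["rfam_acc"].isin(fams)].itertuples():
            term_aspect.setdefault(row.go_id, "")

    accs = []
    if len(rnacentral_map):
        sub = rnacentral_map[
            (rnacentral_map["pdb_id"] == pdb_id.lower())
            & (rnacentral_map["chain"] == chain)]
        accs = sorted(sub["rnacentral_acc"].unique())
    if accs and len(goa):
        for row in goa[goa["accession"].isin(accs)].itertuples():
            if row.go_id not in term_aspect or not term_aspect[row.go_id]:
                term_aspect[row.go_id] = row.aspect

    out = {a: GOTermSet() for a in ASPECTS}
    for term, gaf_aspect in term_aspect.items():
        aspect = None
        if ontology is not None:
            aspect = ontology.aspect(term)
        if aspect is None:
            aspect = gaf_aspect or None
        if aspect is None:
            logger.info("GO term %s: aspect unknown, defaulting to MF", term)
            aspect = "MF"
        out[aspect].terms.add(term)
    return out


def ec_from_go(go: Union[GOTermSet, Iterable[str]],
               ec2go: pd.DataFrame) -> set[str]:
    """EC numbers reachable from a GO term set through the EC2GO mapping."""
    terms = go.terms if isinstance(go, GOTermSet) else set(go)
    if not terms or not len(ec2go):
        return set()
    sub = ec2go[ec2go["go_id"].isin(terms)]
    return set(sub["ec"])


def go_f1(a: Union[GOTermSet, set], b: Union[GOTermSet, set]) -> float:
    """F1 = 2|A∩B| / (|A|+|B|) over ancestor-closed GO sets; 0 when both empty."""
    sa = a.terms if isinstance(a, GOTermSet) else set(a)
    sb = b.terms if isinstance(b, GOTermSet) else set(b)
    if not sa and not sb:
        return 0.0
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


# ---------------------------------------------------------------------------
# sequence dedup and summaries


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("T", "U")


def dedupe_sequences(chains: dict[tuple[str, str], str]
                     ) -> list[tuple[tuple[str, str], list[tuple[str, str]]]]:
    """Group chains by exact (normalised) sequence identity.

    Returns (representative, members) per group; the representative is
    the lexicographically smallest (entry, chain) key.
    """
    groups: dict[str, list[tuple[str, str]]] = {}
    for key, seq in chains.items():
        groups.setdefault(_normalize_seq(seq), []).append(key)
    out = []
    for seq in sorted(groups):
        members = sorted(groups[seq])
        out.append((members[0], members))
    out.sort(key=lambda g: g[0])
    return out


def summarize(records: Sequence) -> dict[str, int]:
    """Interaction counts by ligand class (an exhaustive partition)."""
    from .chaintypes import LigandClass
    counts = {lc.value: 0 for lc in LigandClass}
    for rec in records:
        counts[rec.ligand.klass.value] += 1
    return counts


# ---------------------------------------------------------------------------
# output tables


INTERACTION_COLUMNS = ["entry_id", "query_chain", "assembly_id",
                       "ligand_class", "ligand_id", "ligand_locator",
                       "binding_residues", "contact_count"]
CHAIN_COLUMNS = ["entry_id", "chain", "sequence", "rfam", "go_mf", "go_bp",
                 "go_cc", "ec", "rnacentral", "taxid", "motifs",
                 "active_sites", "crossrefs"]


def write_annotation_tables(records: Sequence, annots: dict, outdir) -> dict:
    """Write the per-interaction TSV, per-chain TSV and sequence FASTA.

    Row order is deterministic: interactions by (entry, chain, ligand
    locator), chains by (entry, chain).  Returns the written paths.
    """
    import os
    from .interactions import interactions_table

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "interactions": os.path.join(outdir, "interactions.tsv"),
        "chains": os.path.join(outdir, "chains.tsv"),
        "fasta": os.path.join(outdir, "rna_sequences.fasta"),
    }

    rows = interactions_table(records)
    rows.sort(key=lambda r: (r["entry_id"], r["query_chain"],
                             r["ligand_locator"], r["ligand_id"]))
    pd.DataFrame(rows, columns=INTERACTION_COLUMNS).to_csv(
        paths["interactions"], sep="\t", index=False)

    chain_rows = []
    for key in sorted(annots):
        a = annots[key]
        chain_rows.append({
            "entry_id": a.entry_id,
            "chain": a.chain_id,
            "sequence": a.sequence,
            "rfam": ",".join(f"{h.rfam_acc}:{h.e_value:g}"
                             for h in a.rfam_hits),
            "go_mf": ",".join(sorted(a.go.get("MF", GOTermSet()).terms)),
            "go_bp": ",".join(sorted(a.go.get("BP", GOTermSet()).terms)),
            "go_cc": ",".join(sorted(a.go.get("CC", GOTermSet()).terms)),
            "ec": ",".join(sorted(a.ec)),
            "rnacentral": a.rnacentral_acc,
            "taxid": a.species_taxid,
            "motifs": ",".join(
                f"{h.motif_id}:{h.start}-{h.end}" for h in a.motif_hits),
            "active_sites": ",".join(
                f"{s.ribozyme_type}:"
                + "+".join(str(p) for p in sorted(
                    s.transferred_positions.values()))
                for s in a.active_sites),
            "crossrefs": ";".join(
                f"{lig}:{db}={acc}"
                for lig in sorted(a.crossrefs)
                for db, acc in sorted(a.crossrefs[lig].items())),
        })
    pd.DataFrame(chain_rows, columns=CHAIN_COLUMNS).to_csv(
        paths["chains"], sep="\t", index=False)

    with open(paths["fasta"], "w") as fh:
        for key in sorted(annots):
            a = annots[key]
            if a.sequence:
                fh.write(f">{a.entry_id}_{a.chain_id}\n{a.sequence}\n")
    return paths


def read_interactions_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    df["contact_count"] = df["contact_count"].astype(int)
    return df
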