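"""End-to-end curation pipeline over structure files.

For every eligible RNA chain (RNA type, >= 10 nt) in each input
structure: materialise the biological assembly containing the chain,
extract ligand-RNA interactions, assign canonical secondary structure
(stored both with pseudoknots in extra bracket layers and pseudoknot
free), join Rfam/GO/EC/crossref annotations from a mapping-table
directory when one is provided, scan protein-binding motifs, and write
the per-chain and per-interaction tables.  Every skipped chain or
ligand is logged with the rule that fired; outputs are byte
deterministic for fixed inputs and config.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

from . import annotate, motifscan, secstruct, structio
from .chaintypes import classify_chain, is_entry_eligible
from .config import PipelineConfig
from .interactions import extract_interactions
from .model import chain_sequence
from .refdata import component_bases
from .structio import assembly_for_chain, build_assembly, split_polymer_nonpolymer

# file names expected inside a mapping-table directory
MAP_FILES = {
    "rfam_pdb": "Rfam.pdb.tsv",
    "rfam2go": "rfam2go.txt",
    "rnacentral_pdb": "pdb.tsv",
    "goa_gaf": "goa.gaf",
    "ec2go": "ec2go.txt",
    "go_obo_edges": "go_slim.obo",
}
CROSSREF_FILES = {"chembl": "ccd2chembl.tsv", "drugbank": "ccd2drugbank.tsv",
                  "zinc": "ccd2zinc.tsv"}
PWM_FILE = "motifs_pwm.txt"


def _load_maps(maps_dir: str) -> dict:
    maps: dict = {}
    for kind, fname in MAP_FILES.items():
        path = os.path.join(maps_dir, fname)
        if os.path.exists(path):
            maps[kind] = annotate.load_mapping(kind, path)
    maps["crossrefs"] = {}
    for db, fname in CROSSREF_FILES.items():
        path = os.path.join(maps_dir, fname)
        if os.path.exists(path):
            maps["crossrefs"][db] = annotate.load_mapping("crossref_2col", path)
    pwm_path = os.path.join(maps_dir, PWM_FILE)
    maps["pwms"] = motifscan.parse_pwms(pwm_path) if os.path.exists(pwm_path) \
        else []
    return maps


def run_pipeline(structure_paths: Sequence[str],
                 config: Optional[PipelineConfig] = None,
                 outdir: str = "ribannot_out",
                 maps_dir: Optional[str] = None) -> dict:
    """Run the full curation over a list of structure files.

    Returns {"records": ..., "annotations": ..., "paths": ...}; TSV and
    FASTA outputs plus a ``run.log`` of skip decisions land in
    ``outdir``.  A failure in one chain is logged and the pipeline
    continues.
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    os.makedirs(outdir, exist_ok=True)
    log_lines: list[str] = []
    maps = _load_maps(maps_dir) if maps_dir else None

    all_records = []
    annots: dict[tuple[str, str], annotate.AnnotationRecord] = {}
    dbn_records: list[str] = []
    bases = component_bases()

    for path in sorted(structure_paths):
        try:
            structure = structio.read_structure(path)
        except structio.ParseError as exc:
            log_lines.append(f"SKIP structure {path}: {exc}")
            continue
        for chain in structure.chains:
            polymer, _ = split_polymer_nonpolymer(chain)
            key = (structure.entry_id, chain.chain_id)
            if not polymer.residues:
                log_lines.append(
                    f"SKIP {key}: no polymer residues")
                continue
            ctype = classify_chain(polymer)
            if not is_entry_eligible(polymer):
                log_lines.append(
                    f"SKIP {key}: {ctype.value} chain not entry-eligible "
                    f"(entries need RNA with >= {cfg.entry_min_nt} nt)")
                continue

            try:
                asm_id = assembly_for_chain(structure, chain.chain_id)
                if asm_id is not None:
                    assembly = build_assembly(structure, asm_id)
                else:
                    assembly = structure
                    asm_id = "asym"
                    log_lines.append(
                        f"NOTE {key}: no assembly lists this chain; using "
                        f"the asymmetric unit")
                records = extract_interactions(
                    assembly, chain.chain_id, cfg, assembly_id=asm_id)
                all_records.extend(records)

                seq = chain_sequence(polymer, bases)
                pairs = secstruct.detect_base_pairs(polymer, cfg)
                ss = secstruct.to_dotbracket(pairs, len(seq))
                nested = secstruct.remove_pseudoknots(pairs)
                ss_pkfree = secstruct.to_dotbracket(nested, len(seq))
                name = f"{structure.entry_id}_{chain.chain_id}"
                dbn_records.append(
                    secstruct.dotbracket_record(name, seq, ss))
                dbn_records.append(
                    secstruct.dotbracket_record(name + "_pkfree", seq,
                                                ss_pkfree))

                rec = annotate.AnnotationRecord(
                    entry_id=structure.entry_id, chain_id=chain.chain_id,
                    sequence=seq,
                    species_taxid=structure.species_taxids.get(
                        chain.chain_id, ""))
                if maps is not None:
                    _annotate_chain(rec, key, records, maps, cfg)
                annots[key] = rec
            except Exception as exc:  # keep going; record the failure
                log_lines.append(f"ERROR {key}: {exc}")

    paths = annotate.write_annotation_tables(all_records, annots, outdir)
    paths["dotbracket"] = os.path.join(outdir, "secondary_structures.dbn")
    with open(paths["dotbracket"], "w") as fh:
        fh.write("".join(dbn_records))
    paths["log"] = os.path.join(outdir, "run.log")
    with open(paths["log"], "w") as fh:
        fh.write("\n".join(log_lines) + ("\n" if log_lines else ""))
    return {"records": all_records, "annotations": annots, "paths": paths}


def _annotate_chain(rec, key, records, maps: dict,
                    cfg: PipelineConfig) -> None:
    ontology = maps.get("go_obo_edges")
    if "rfam_pdb" in maps:
        rec.rfam_hits = annotate.assign_rfam(key, maps["rfam_pdb"])
    if all(k in maps for k in ("rfam2go", "rnacentral_pdb", "goa_gaf")):
        rec.go = annotate.transfer_go(
            key, rec.rfam_hits, maps["rfam2go"], maps["rnacentral_pdb"],
            maps["goa_gaf"], ontology)
    if "rnacentral_pdb" in maps:
        sub = maps["rnacentral_pdb"]
        match = sub[(sub["pdb_id"] == key[0].lower())
                    & (sub["chain"] == key[1])]
        if len(match):
            rec.rnacentral_acc = match["rnacentral_acc"].iloc[0]
    if "ec2go" in maps and rec.go:
        all_terms = set()
        for ts in rec.go.values():
            all_terms |= ts.terms
        rec.ec = annotate.ec_from_go(all_terms, maps["ec2go"])
    # ligand crossrefs for this chain's interaction partners
    for r in records:
        if r.query_chain_id != key[1] or r.entry_id != key[0]:
            continue
        lig = r.ligand.ligand_id
        for db, table in maps.get("crossrefs", {}).items():
            hit = table[table["from_id"] == lig]
            if len(hit):
                rec.crossrefs.setdefault(lig, {})[db] = hit["to_id"].iloc[0]
    # motif scan: background from the fixture/transcriptome tables when
    # present, else from the RNA sequences being curated
    if maps.get("pwms"):
        bg = motifscan.background_from_counts(
            {b: rec.sequence.count(b) for b in "ACGU"})
        rnas = {key: (rec.sequence, rec.species_taxid)}
        hits = motifscan.scan_by_species(rnas, maps["pwms"], bg,
                                         cfg.scan_p_cut)
        rec.motif_hits = hits[key]
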