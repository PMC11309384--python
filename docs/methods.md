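# Methods

This note documents the models and procedures implemented in
`ribannot`, the constants that matter, the synthetic data the tests run
on, and the design choices made where the design was genuinely open.

## Structure model and I/O

Structures are read with gemmi and converted to a small hierarchy
(Structure → Chain → Residue → Atom). Only the categories the pipeline
needs are consumed: `atom_site`, the assembly categories
(`pdbx_struct_assembly`, `pdbx_struct_assembly_gen`,
`pdbx_struct_oper_list`), entity/taxonomy items, and the resolution.
The polymer/non-polymer split follows `label_seq_id`: numeric values
mark the polymer, a period marks free components. Only the first model
is used; among altloc conformers the highest-occupancy one is kept
(ties: first in file). Assembly transforms must be proper rotations
(det = +1); materialising an assembly applies each (chain selection,
4×4 operator) pair and suffixes duplicated chains (`A`, `A-2`, …).
Sequence indices and residue numbering are 1-based throughout; ranges
are closed.

PDB writing refuses structures beyond the format's hard limits
(99,999 atoms, 62 chains) — callers keep mmCIF for those — and renames
multi-character chain ids to single characters, returning the renaming
table. PDB reading recovers polymer membership through gemmi's entity
setup, since the format has no `label_seq_id`.

Residue kinds come from a packaged component dictionary (~60 common
comp_ids, including modified ribonucleotides such as PSU and 1MA, which
count as ribonucleotides); unknown comp_ids fall back to atom content
(ribose with O2′ → ribonucleotide, ribose without → deoxyribonucleotide,
CA+N+C → amino acid, else other).

## Chain and ligand rules

"More ribonucleotides than deoxyribonucleotides and amino acids" is
read as two strict majorities (ribo > deoxy AND ribo > aa); ties give
OTHER. The analogous rule types DNA and protein chains. RNA chains
with ≥ 10 nt are entries; shorter oligonucleotides act only as ligands.

A component is a metal ion iff it consists of exactly one atom of an
element on the packaged metal list (alkali through actinides, plus
semi-metals). Monoatomic halides are classed as small molecules, as
are metal-containing coordination complexes (cobalt hexammine has seven
heavy atoms and therefore is not an ion). Water is never a partner.

## Ligand–RNA interactions

Contacts use Bondi-style van der Waals radii (packaged table; unknown
elements default to 1.80 Å) with a 0.5 Å margin, over non-hydrogen
atoms only. The radii table and the margin are the only geometric
constants; both are exposed in the config. The neighbour search uses a
k-d tree pre-filter at the largest possible cutoff and is
result-identical to the all-pairs definition (property-tested against
a brute-force double loop on random fixtures).

A binding residue needs ≥ 2 atomic contacts with the ligand (a
monoatomic ion touching two atoms of one residue counts: atom *pairs*
are counted, not ligand atoms). A site needs ≥ 2 binding residues and
ligands without a site are dropped — the literal reading of the curation
rule; because it silently discards single-residue binders the threshold
is configurable (`site_min_residues`). When an assembly replicates a
ligand, every copy is a separate instance with a copy index.

## Secondary structure

Canonical pairs only (A:U, G:C, G:U). The external assignment tools the
curation pipeline would normally shell out to are not reimplemented
bit-for-bit; instead a standard stereochemical screen is applied, with
every constant in the config:

- C1′–C1′ distance ∈ [8.0, 11.5] Å;
- ≥ 2 canonical donor–acceptor heavy-atom pairs at ≤ 3.6 Å
  (A:U → N6–O4, N1–N3; G:C → O6–N4, N1–N3, N2–O2; G:U → N1–O2, O6–N3);
- base-plane normal angle ≤ 65° (planes fit by SVD of the ring atoms);
- intra-chain separation j − i ≥ 4.

Each nucleotide keeps at most one partner; conflicts resolve to the
smallest mean H-bond distance, deterministically. Residues missing the
required atoms are skipped rather than modelled (no atom completion).
For RNA–RNA pairs, both the individual chains and the concatenated pair
can be assigned.

Dot-bracket output uses `()` for the nested layer and `[]{}<>` greedily
for crossing layers (more than four mutually crossing layers is an
error; never observed). Both the layered string and the
pseudoknot-free string are stored. Pseudoknot removal groups pairs into
maximal bulge-free stacked regions and accepts regions longest-first,
skipping any that cross an accepted one; equal lengths tie-break to the
5′-most start. The Stockholm writer emits a single-sequence alignment
with `SS_cons` and requires a crossing-free structure, since covariance
model builders reject pseudoknots.

## Structure alignment

Chains reduce to C3′ traces (nucleotides missing C3′ are dropped).
TM-score uses the nucleic-acid convention
`d0 = max(0.6·√(L−0.5) − 2.5, 1.0)` Å; the 1.0 Å floor matters for
chains under ~70 nt. Scores are maximised over superpositions by the
standard iterative subset refinement (seed fragments at several lengths
and offsets; superpose, rescore, re-seed on the close pairs).

The pairwise aligner is deterministic: seeds are all gapless
threadings plus the best-superposing 20-mer fragment pair, ranked by a
one-shot superposition score; the best five refine by alternating
Kabsch superposition on the close subset (d < d0) with global dynamic
programming (free end gaps) on `S_ij = 1/(1+(d_ij/d0)²)`, gap penalty
0.6, until the mapping is fixed or 30 rounds pass. Ties in the DP
traceback prefer diagonal, then up, then left. Alignment is
sequence-order-preserving; circular permutation is out of scope. The
gap penalty, iteration cap and fragment length are heuristic constants
chosen for determinism and desk-scale speed, all configurable at module
level.

Clustering is greedy longest-first: a trace joins the first
representative with TM ≥ 0.5 normalised by the *shorter* chain,
otherwise founds a cluster; representatives end up pairwise below the
cutoff (asserted directly in tests). Search ranks representatives by
query-normalised TM and reports each hit with its cluster members.
Active-site transfer aligns the template (as query) against candidates
sharing an Rfam family — plus, for templates < 100 nt, candidates with
no family at all — and emits annotations at TM ≥ 0.45, mapping site
positions through the alignment; unmapped sites are reported missing.

## Motif scanning

Log-odds scores in bits against a 0-order background
(`freq_b = (count_b + 0.1) / Σ(counts + 0.1)`, T read as U, ambiguous
letters skipped). Zero PWM probabilities are floored at 1e-4 before the
log. P-values are exact tail probabilities of the window score under
i.i.d. background windows, computed by convolving per-position score
distributions on an integer lattice of 1/20000 bit. At that resolution
the convolution reproduces exhaustive 4^k enumeration except for window
scores that tie within half a lattice step — the tests therefore
bracket the enumerated p-value by ±(k+1)/40000 bits around the observed
score. Scanning is forward-strand only (an RNA has no reverse
complement to scan) and windows containing N are skipped. The default
reporting threshold is p ≤ 1e-4, configurable. Motifs pair with RNAs by
species taxid (a plain join; motifs with no matching chain are skipped
and logged; motifs without a species apply to all chains).

## Annotation joins

Mapping dialects parsed: Rfam↔PDB TSV, rfam2go, RNAcentral pdb.tsv
(`URS… PDB pdbid_chain taxid …`), GAF 2.x (rows whose qualifier
contains NOT are skipped; all evidence codes kept), EC2GO, two-column
crossref TSVs, and GO OBO (via obonet). Malformed lines are logged and
skipped; a file with no parseable line is an error.

Rfam hits from the mapping file take precedence; chains absent from it
fall back to parsed covariance-model search output; either way hits
sort by ascending E-value. A chain in neither source stays
family-less — remote homologs can genuinely be missed this way, which
is also why the active-site transfer has its no-family fallback.

GO terms are the union of rfam2go terms over the chain's families and
GOA terms of its RNAcentral accession, split into MF/BP/CC by ontology
namespace (falling back to the GAF aspect column, then to MF with a log
message). Raw terms are stored; ancestor closure over is_a and part_of
edges is available on demand (`GOTermSet.closure`). EC numbers are the
EC2GO image of the chain's GO terms. The GO-set similarity is
`F1 = 2|A∩B|/(|A|+|B|)` over ancestor-closed sets, defined as 0 when
both sets are empty. Sequence deduplication groups exact matches after
uppercasing and T→U; the representative is the lexicographically
smallest (entry, chain) key.

Output tables (per-chain TSV, per-interaction TSV, FASTA, dot-bracket
records) have a fixed documented column order and deterministic row
order, so reruns are byte-identical.

## Synthetic data

The fixture generator emulates just enough structure for every rule to
be exercised with known ground truth; it does not attempt
crystallographic realism:

- Nucleobases are planar rings built as regular polygons (bond length
  1.38 Å) with exocyclic substituents; each canonical pair is assembled
  once by least-squares placement of the mirrored partner base onto
  2.85 Å H-bond distances and a 10.4 Å C1′–C1′ separation.
- Duplexes stack pair frames with rise 2.81 Å and twist 32.7°
  (A-form-like); hairpin loops ride a rising arc whose geometry keeps
  any two residues ≥ 4 apart in sequence beyond the pairing window, so
  loops are unpairable by construction. Backbone atoms exist and are
  deterministic but only roughly placed.
- Coordinate jitter is a truncated Gaussian displacement whose
  magnitude never exceeds the nominal value, so 0.3 Å jitter perturbs
  any interatomic distance by at most 0.6 Å and stays inside the pair
  test's tolerance windows — designed pairing is recovered exactly at
  any seed. Untruncated noise of that scale would occasionally break
  an A:U hydrogen bond, which is a statement about Gaussian tails, not
  about the detector.
- `place_ligand` positions a component's reference atom at a requested
  distance (± 0.05 Å) from named target atoms by least squares, raising
  when the constraints are infeasible.
- `make_u2_snrnp_like` is a synthetic stand-in reproducing the
  published chain/assembly layout of the U2B″–U2A′ spliceosomal complex
  (PDB 1a9n): 6 chains, 4 protein + 2 RNA, assembly 1 = A,B,Q and
  assembly 2 = C,D,R. Coordinates are synthetic; only the census and
  assembly bookkeeping mirror the real entry.
- The toy mapping tables carry a manifest of every annotation the
  pipeline must produce from them; tests treat the manifest as the
  oracle.

Because the fixtures are idealised, passing tests demonstrate the
correctness of the rules and algorithms — thresholds, orderings,
determinism, oracle agreement — not robustness to the pathologies of
real crystallographic data (missing atoms, alternate conformations
beyond simple altlocs, modelling errors, non-canonical geometry).

## Problem sizes

The test suite and the acceptance script run at desk scale: contact
oracles on 100 random ~280-atom fixtures, base-pair recovery over 20
seeds × 2 jitter levels on 16–20-nt structures, alignment checks on
~100-nt traces, motif enumeration up to k = 8 (65,536 windows), and the
end-to-end pipeline on a two-structure bundle. These sizes were chosen
so the whole suite completes in about a minute while still exercising
every rule; all of them scale with the obvious parameters.

## Known limitations

- The mmCIF subset ignores categories the pipeline does not use; NMR
  multi-model support and mmCIF writing are out of scope.
- The geometric pair test assigns no non-canonical (Leontis–Westhof)
  classes and no stacking.
- The aligner does not do multimer alignment or circular permutation
  and makes no claim of score compatibility with any external program.
- Assembly selection operates on whole author chains; an assembly that
  splits one author chain across selections would be materialised
  whole.
- Ligand biological-relevance filtering is deliberately absent: every
  non-water partner is reported.
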