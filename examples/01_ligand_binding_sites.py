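"""Extract a ligand-RNA binding site from a synthetic structure.

Builds a hairpin RNA, places a magnesium ion 2.1 A from two base atoms,
and runs the interaction extraction: atomic contacts under the
vdW-sum + 0.5 A rule, binding residues (>= 2 contacts), and the binding
site (>= 2 residues).
"""

from ribannot import fixtures
from ribannot.chaintypes import ComponentInfo
from ribannot.interactions import extract_interactions

hairpin, truth = fixtures.make_hairpin(stem_len=6, loop_len=4)
structure = fixtures.place_ligand(
    hairpin, [("A", 4, "O2"), ("A", 5, "N9")], distance=2.1,
    component=ComponentInfo("MG", {"Mg": 1}, name="magnesium ion"))

records = extract_interactions(structure, "A", assembly_id="1")
for rec in records:
    print(f"ligand {rec.ligand.ligand_id} ({rec.ligand.klass.value}) "
          f"binds chain {rec.query_chain_id}")
    print(f"  binding site residues: {' '.join(rec.site.residue_tokens())}")
    print(f"  atomic contacts: {rec.contact_count}")

# The site is exactly the two residues the ion was placed against: a
# residue needs two or more atomic contacts to count, and a ligand needs
# two or more such residues to be kept.
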