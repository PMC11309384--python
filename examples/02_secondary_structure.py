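"""Assign canonical secondary structure from 3D coordinates.

Detects Watson-Crick and G:U wobble pairs geometrically on a duplex
with a designed wobble, renders dot-bracket, and shows pseudoknot
removal by the incremental-length rule on a constructed crossing.
"""

from ribannot import fixtures, secstruct

spec = fixtures.HelixSpec("GAGGUCAC", gu_positions=frozenset([4]))
duplex, truth = fixtures.make_duplex(spec)

pairs = secstruct.detect_base_pairs(duplex.chains)
print("detected pairs (global positions over both strands):")
for p in pairs:
    print(f"  {p.i:>2} - {p.j:>2}  {p.pair_type}  "
          f"mean H-bond {p.mean_hbond_dist:.2f} A")

ss = secstruct.to_dotbracket(pairs, 16)
print("dot-bracket:", ss.dotbracket)

# pseudoknot removal: a long region crossed by a short one
knotted = [(1, 20), (2, 19), (3, 18), (6, 24)]
kept = secstruct.remove_pseudoknots(knotted)
print("knotted input :", knotted)
print("nested output :", sorted(kept))
# The 3-pair region wins (longest first); the crossing single pair is
# dropped, leaving a nesting that a covariance model builder accepts.
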