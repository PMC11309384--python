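"""TM-score structure alignment, clustering and database search.

Aligns C3' traces, clusters a small set of RNA structures into
representatives (pairwise TM < 0.5) and searches the clustered
database with a query, reporting hits with their cluster members.
"""

import numpy as np

from ribannot import fixtures
from ribannot.structalign import (
    C3Trace,
    align_structures,
    cluster_representatives,
    search_structure,
    trace_from_chain,
)

hairpin, _ = fixtures.make_hairpin(20, 6)
query = trace_from_chain(hairpin.chains[0])

rng = np.random.default_rng(0)
relative = C3Trace("relative", query.positions
                   + rng.normal(0, 0.8, query.positions.shape),
                   query.sequence)
unrelated = C3Trace("extended", np.array([[5.9 * i, 0.0, 0.0]
                                          for i in range(30)]), "G" * 30)

res = align_structures(query, relative)
print(f"query vs relative: TM(query)={res.tm_query:.3f} "
      f"rmsd={res.rmsd:.2f} A over {res.aligned_length()} nt")

clusters = cluster_representatives([query, relative, unrelated])
print(f"{len(clusters)} clusters from 3 structures")

for hit in search_structure(query, clusters, top_n=100):
    print(f"rank {hit.rank}: {hit.target_id} TM={hit.tm_query:.3f} "
          f"members={','.join(hit.cluster_members)}")
# The jittered relative clusters with the query (TM >= 0.5) and tops the
# search; the extended strand stays a separate representative with a
# low TM-score.
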