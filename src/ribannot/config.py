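"""Pipeline configuration: every tunable constant in one place.

Values are the curation rules' printed constants (0.5 A contact margin,
2-contact residue rule, 2-residue sites, 10-nt entries, TM-score 0.45
transfer / 0.5 clustering cutoffs) plus the geometric base-pair test
constants and the motif-scan p-value cutoff.  The config serialises to a
flat ``key=value`` text file and back.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass


@dataclass
class PipelineConfig:
    # ligand-RNA interaction extraction
    contact_margin: float = 0.5        # A added to the vdW-radius sum
    min_contacts_per_residue: int = 2  # atomic contacts to call a binding residue
    site_min_residues: int = 2         # binding residues to keep a site
    entry_min_nt: int = 10             # nucleotides for an RNA chain to be an entry

    # structure alignment
    tm_transfer_cutoff: float = 0.45   # active-site transfer significance
    tm_cluster_cutoff: float = 0.5     # representative clustering
    transfer_short_template_nt: int = 100  # <100 nt: also search Rfam-less chains
    search_top_n: int = 100

    # geometric base-pair test
    pair_c1_min: float = 8.0           # A, C1'-C1' distance window
    pair_c1_max: float = 11.5
    pair_hbond_max: float = 3.6        # A, donor-acceptor heavy-atom cutoff
    pair_min_hbonds: int = 2
    pair_plane_max_deg: float = 65.0   # base-plane normal angle
    pair_min_separation: int = 4       # intra-chain |j-i| minimum

    # motif scanning
    scan_p_cut: float = 1e-4
    scan_pseudocount: float = 0.1

    # mapping tables directory (optional)
    maps_dir: str = ""

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v < 0:
                raise ValueError(f"config {f.name} must be non-negative, got {v}")
        if self.pair_c1_min >= self.pair_c1_max:
            raise ValueError("pair_c1_min must be below pair_c1_max")

    def to_file(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in types:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                current = getattr(defaults, key)
                if isinstance(current, bool):
                    kwargs[key] = value.strip().lower() in ("1", "true", "yes")
                elif isinstance(current, int):
                    kwargs[key] = int(value)
                elif isinstance(current, float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value.strip()
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg
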