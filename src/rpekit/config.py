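"""Run configuration: packaged sequence elements, design bounds and scores.

Scaffold, 3' motif and linker sequences are configuration data, not
hard-coded constants: the defaults below are the standard SpCas9 sgRNA
scaffold and the trimmed evopreQ1 pseudoknot widely used to protect pegRNA
3' ends, but any run may override them from a YAML file.  Every primary
output embeds ``config_hash`` so results are reproducible bit-exact given
the same inputs, configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: standard S. pyogenes single-guide scaffold (RNA)
DEFAULT_SCAFFOLD = (
    "GUUUUAGAGCUAGAAAUAGCAAGUUAAAAUAAGGCUAGUCCGUUAUCAACUUGAAAAAGUGGCACCGAGUCGGUGC"
)
#: trimmed evopreQ1 pseudoknot used for erpegRNA 3'-end protection (RNA)
DEFAULT_MOTIF = "CGCGGUUCUAUCUAGUUACGCGUUAAACCAACUAGAA"
#: short unstructured linker between PBS and motif (RNA)
DEFAULT_LINKER = "AAUU"

#: Golden-Gate overhangs for sgRNA cloning (spacer) and extension fragments
DEFAULT_OVERHANGS = {
    "spacer_top": "CACC",
    "spacer_bottom": "AAAC",
    "extension_top": "GTGC",
    "extension_bottom": "CGCG",
}


@dataclass(frozen=True)
class RunConfig:
    scaffold_rna: str = DEFAULT_SCAFFOLD
    motif_rna: str = DEFAULT_MOTIF
    linker_rna: str = DEFAULT_LINKER
    overhangs: dict = field(default_factory=lambda: dict(DEFAULT_OVERHANGS))
    # circular-rpegRNA cassette elements (ligation/ribozyme), configurable;
    # empty by default (the split layout is a declared simplification)
    circular_elements: dict = field(default_factory=dict)
    # alignment scores (affine; a length-k gap scores open + (k-1)*extend)
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    # design bounds
    pbs_range: tuple = (10, 16)
    rtt_range: tuple = (10, 16)
    gc_bounds: tuple = (40.0, 60.0)
    min_post_edit_homology: int = 5
    prepend_g: bool = False
    # ngRNA offsets
    min_nick_offset: int = 20
    max_nick_offset: int = 120
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pbs_range"] = list(d["pbs_range"])
        d["rtt_range"] = list(d["rtt_range"])
        d["gc_bounds"] = list(d["gc_bounds"])
        return d

    @property
    def config_hash(self) -> str:
        """Stable 12-hex digest of the canonicalized configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k in ("pbs_range", "rtt_range", "gc_bounds"):
            if k in data:
                data[k] = tuple(data[k])
        return cls(**data)


DEFAULT_CONFIG = RunConfig()
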