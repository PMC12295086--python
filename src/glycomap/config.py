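"""Run configuration: every tunable with its documented default, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    reference: str = ""
    complexes: list[str] = field(default_factory=list)
    sequences: str = ""
    msa: str = ""
    output_dir: str = "glycomap_out"
    seed: int = 0

    merge_radius: float = 1.8
    reject_cutoff: float = 2.0
    max_cycles: int = 5
    linear_threshold: float = 4.0
    u_threshold: float = 2.5
    ss_cutoff: float = 2.5
    contact_cutoff: float = 3.6
    lining_cutoff: float = 4.5
    evalue_cutoff: float = 1e-40
    identity_threshold: float = 0.9
    planarity_threshold: float = 0.05
    like_threshold: float = 15.0

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
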