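"""Tunable tolerances and thresholds, loadable from YAML.

Two distinct boundary tolerances exist on purpose: ``annotation_w`` (W,
default 5 bp) for matching event features against reference annotations,
and ``quant_v`` (V, default 10 bp) for assigning transcripts to event
forms during quantification.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import IO

import yaml

__all__ = ["Config"]


@dataclass
class Config:
    annotation_w: int = 5       # W: annotation endpoint tolerance (bp)
    quant_v: int = 10           # V: quantification boundary tolerance (bp)
    wobble: int = 5             # redundancy-clustering boundary wobble (bp)
    gene_fpkm_min: float = 0.1  # minimum per-sample gene FPKM for extraction
    stable_max: float = 0.1     # Δ below this: stable
    switch_min: float = 0.5     # Δ at or above this: switch
    chrom_aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("annotation_w", "quant_v", "wobble"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.stable_max <= self.switch_min <= 1):
            raise ValueError("need 0 <= stable_max <= switch_min <= 1")

    @classmethod
    def from_yaml(cls, source: str | IO[str]) -> "Config":
        if isinstance(source, str) and ("\n" in source or ":" in source):
            data = yaml.safe_load(source)
        elif isinstance(source, str):
            with open(source) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(source)
        return cls(**(data or {}))

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)
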