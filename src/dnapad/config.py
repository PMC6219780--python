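"""Run configuration: the secret parameter set, seeds and file locations.

A config file (YAML or JSON — YAML is a superset here) aggregates
everything one encryption run needs; every CLI flag overrides the
corresponding field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .otp import Seeds, SecretKeySet

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    scheme: str = "single"
    secrets: SecretKeySet = field(
        default_factory=lambda: SecretKeySet(g=0.501, mu=3.68, table_id=1, q="ACGTA")
    )
    seeds: Seeds = field(default_factory=Seeds)
    db_path: str | None = None
    payload_width_bits: int = 16
    redundancy_len: int = 20

    def __post_init__(self) -> None:
        if self.scheme not in ("single", "double"):
            raise ValueError(f"scheme must be 'single' or 'double', got {self.scheme!r}")
        if self.payload_width_bits % 2 or self.payload_width_bits <= 0:
            raise ValueError("payload_width_bits must be a positive even number")
        if self.redundancy_len < 0:
            raise ValueError("redundancy_len must be non-negative")
        if self.db_path is not None and not Path(self.db_path).exists():
            raise FileNotFoundError(f"database FASTA not found: {self.db_path}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        secrets = SecretKeySet(**raw.get("secrets", {})) if "secrets" in raw else None
        seeds_raw = raw.get("seeds", {})
        seeds = (
            Seeds.from_root(seeds_raw)
            if isinstance(seeds_raw, int)
            else Seeds(**seeds_raw)
        )
        kwargs = {
            k: v
            for k, v in raw.items()
            if k in ("scheme", "db_path", "payload_width_bits", "redundancy_len")
        }
        if secrets is not None:
            kwargs["secrets"] = secrets
        kwargs["seeds"] = seeds
        return cls(**kwargs)
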