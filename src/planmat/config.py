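"""Flat key-value run configuration shared by the CLI stages."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class RunConfig:
    """Every tunable threshold of the pipeline, with its default.

    Unknown keys in a config file are rejected so typos cannot silently fall
    back to defaults. The effective config is echoed into every JSON report.
    """

    # annotation evidence thresholds
    domain_evalue_max: float = 0.1
    blast_evalue_max: float = 0.01
    sp_window: int = 35
    small_secreted_max_len: int = 200
    min_orf_aa: int = 30
    # module scoring
    n_bins: int = 24
    n_ctrl: int = 100
    log_transform: bool = True
    # reclustering
    n_pcs_total: int = 20
    n_pcs_use: int = 6
    perplexity: float = 40.0
    graph_k: int = 30
    resolution: float = 1.0
    # GSEA
    gsea_p: float = 1.0
    n_perm: int = 10000
    min_frac: float = 0.01
    min_level: float = 0.5
    # global
    seed: int = 0

    @classmethod
    def load(cls, path: Optional[Path] = None, **overrides) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        values: dict = {}
        if path is not None:
            raw = yaml.safe_load(Path(path).read_text()) or {}
            if not isinstance(raw, dict):
                raise ValueError(f"{path}: config must be a flat key-value mapping")
            unknown = set(raw) - known
            if unknown:
                raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
            values.update(raw)
        bad = set(overrides) - known
        if bad:
            raise ValueError(f"unknown config overrides {sorted(bad)}")
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def substream(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the run seed, so stages
        can be rerun in isolation with identical randomness (kept < 2^31)."""
        import zlib

        return (self.seed * 1000003 + zlib.adler32(stage.encode())) % (2**31 - 1)
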