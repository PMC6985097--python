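"""Run configuration: defaults, YAML round-trip, seed fan-out."""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "substream_seed"]


def substream_seed(seed: int, label: str) -> int:
    """Derive a stage-specific 31-bit seed from the global seed.

    Each pipeline stage draws from its own substream so stages are
    independently reproducible regardless of execution order.
    """
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run.

    Nested dicts hold per-stage parameters and override the dataclass
    defaults of the corresponding spec/operation (unknown keys are rejected
    where they are consumed).
    """

    seed: int = 0
    outdir: str = "astroquant_out"
    pixel_size_um: float = 0.32
    n_images: int = 3
    n_coverslips: int = 3
    image_sim: dict = field(default_factory=dict)   # ImageSimSpec overrides
    trace_sim: dict = field(default_factory=dict)   # TraceSimSpec overrides
    imaging: dict = field(default_factory=dict)     # qc_min_pcc, background_sigma, ...
    kinetics: dict = field(default_factory=dict)    # cutoff_hz, k, m, d_sustain_s, ...
    coloc_policy: str = "all"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path
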