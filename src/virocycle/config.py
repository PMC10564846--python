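"""Run configuration: analysis thresholds, seeds, paths.

Thresholds collect every cut-off the analysis applies, with the field
defaults: read identity >=0.90 for viral mapping, presence at >=75 %
genome breadth for viral scaffolds and >=90 % for MAGs, d2* host
assignment at <=0.3, CRISPR protospacer matches at >=80 % identity,
spacer lengths 20-60 bp, <=3 mismatches per direct-repeat hit, surface
wind strictly >3 m/s for trajectory "loading", and a 96 h trajectory
evaluation window.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError, ParameterError


@dataclass
class Thresholds:
    read_identity: float = 0.90
    viral_breadth: float = 0.75
    mag_breadth: float = 0.90
    mag_read_identity: float = 0.98  # 2 % error allowance for MAG mapping
    d2star: float = 0.30
    protospacer_identity: float = 0.80
    spacer_min_len: int = 20
    spacer_max_len: int = 60
    dr_max_mismatches: int = 3
    loading_wind_ms: float = 3.0
    trajectory_window_h: int = 96

    def validate(self) -> None:
        for name in (
            "read_identity",
            "viral_breadth",
            "mag_breadth",
            "mag_read_identity",
            "d2star",
            "protospacer_identity",
        ):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ParameterError(f"threshold {name}={v} outside (0, 1]")
        if self.spacer_min_len < 1 or self.spacer_max_len < self.spacer_min_len:
            raise ParameterError("invalid spacer length bounds")
        if self.dr_max_mismatches < 0:
            raise ParameterError("dr_max_mismatches must be >= 0")
        if self.loading_wind_ms < 0:
            raise ParameterError("loading_wind_ms must be >= 0")
        if self.trajectory_window_h < 1:
            raise ParameterError("trajectory_window_h must be >= 1")


@dataclass
class RunConfig:
    seed: int = 0
    synthetic: bool = True
    thresholds: Thresholds = field(default_factory=Thresholds)
    sample_sheet: Optional[str] = None
    depth_tables: Optional[str] = None
    output_dir: str = "virocycle_out"
    # synthetic-mode community design knobs (generator defaults apply)
    n_viruses: int = 20
    n_hosts: int = 4

    def validate(self) -> None:
        self.thresholds.validate()
        if not self.synthetic:
            if self.sample_sheet is None:
                raise ConfigError("real-data mode requires a sample sheet")
            if self.depth_tables is None:
                raise ConfigError(
                    "real-data mode with detection enabled requires depth tables"
                )

    # ---- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        thr = d.pop("thresholds", {})
        cfg = cls(**d, thresholds=Thresholds(**thr))
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Stable hash of the full configuration, recorded in the manifest."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministically expand one global seed into a per-stage seed.

    SHA-256 of ``"<seed>:<stage>"`` truncated below 2**31, so any stage can
    be re-run in isolation with the same stream it saw in the full run.
    """
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)
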