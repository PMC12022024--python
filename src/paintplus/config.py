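"""Run configuration with lossless YAML round-tripping."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run.

    Defaults encode the reference study conditions: 53% cytotoxicity
    threshold, BMR multipliers 1.349 x 1.4826, BMC gating at >= 4
    non-cytotoxic concentrations and >= 3 biological replicates,
    registration QC at NCC 0.8 (manual) / 0.5 (exclude).
    """

    # plate / synthesis
    n_compounds: int = 15
    n_conc: int = 8
    n_blocks: int = 3
    n_controls: int = 24
    top_conc_uM: float = 100.0
    n_biol_reps: int = 4
    n_cells_per_well: int = 100
    # registration
    registration_mode: str = "translation"  # or "similarity"
    max_shift_px: int = 50
    scale_bound: float = 0.05
    rotation_bound_deg: float = 5.0
    ncc_manual: float = 0.8
    ncc_exclude: float = 0.5
    # segmentation / features
    min_nucleus_area: int = 50
    ring_width: int = 3
    membrane_width: int = 2
    spot_relative_threshold: float = 0.2
    # profiling
    cytotox_threshold_percent: float = 53.0
    # BMC
    bmr_sd_multiplier: float = 1.349
    robust_z_constant: float = 1.4826
    min_conc_count: int = 4
    min_biol_reps: int = 3
    # reporting
    min_responding_frac: float = 0.30
    n_clusters: int = 6
    include_lyso: bool = True
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cytotox_threshold_percent < 100:
            raise ValueError("cytotoxicity threshold must be in (0, 100)")
        if not 0 <= self.ncc_exclude <= self.ncc_manual <= 1:
            raise ValueError("require 0 <= ncc_exclude <= ncc_manual <= 1")
        if self.min_conc_count < 2 or self.min_biol_reps < 1:
            raise ValueError("BMC gating parameters out of range")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
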