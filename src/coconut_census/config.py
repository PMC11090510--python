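"""Pipeline configuration.

Every threshold used by the pipeline lives here with its default. Values
can be overridden from a YAML file and again by command-line flags
(precedence: flags > file > defaults). The resolved configuration is echoed
into every report.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml


@dataclass
class PipelineConfig:
    # neighborhood census
    flank_genes: int = 10           # genes on each side of an anchored hit
    gap_nt: int = 90                # adjacency / operonic-association gap (inclusive)
    min_mcrB_aa: int = 200          # partner size gate, strict > comparison
    min_mcrC_aa: int = 150          # partner size gate, strict > comparison
    max_intervening: int = 2        # genes allowed between paired McrB/McrC
    rescue_anchor_role: str = "McrB"

    # annotation
    evalue: float = 0.001           # profile-hit E-value cutoff
    coiled_coil_window: int = 28
    coiled_coil_threshold: float = 0.5
    min_coiled_coil_aa: int = 50    # segment length defining a "long" coiled-coil
    signature_window: int = 60      # post-Walker-B window for Nx(xx)D
    insert_scan_window: int = 200   # extended window tolerating the I-A insert
    insert_min_aa: int = 80         # Walker-B-to-NxD spacing flagging the I-A insert
    midas_t_window: tuple[int, int] = (20, 80)
    midas_d_window: tuple[int, int] = (10, 60)

    # clustering
    cluster_threshold: float = 0.5
    representative_threshold: float = 0.9
    ratio_threshold: float = 0.1
    ratio_denominator: str = "max"  # "max" (conservative) or "min"
    iterations: int = 3
    gap_open: int = 11
    gap_extend: int = 1

    # classification
    superoperon_gap_nt: int = 200

    # randomness
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def valid_keys(cls) -> set[str]:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_sources(
        cls,
        file: Optional[Union[str, Path]] = None,
        overrides: Optional[dict] = None,
    ) -> "PipelineConfig":
        """Build a config from defaults, then a YAML file, then explicit
        overrides. Unknown keys raise with the list of valid keys."""
        values: dict = {}
        if file is not None:
            loaded = yaml.safe_load(Path(file).read_text()) or {}
            if not isinstance(loaded, dict):
                raise ValueError(f"config file {file} must contain a mapping")
            values.update(loaded)
        values.update(overrides or {})
        unknown = set(values) - cls.valid_keys()
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; "
                f"valid keys are {sorted(cls.valid_keys())}"
            )
        for key in ("midas_t_window", "midas_d_window"):
            if key in values and not isinstance(values[key], tuple):
                values[key] = tuple(values[key])
        return cls(**values)
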