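"""Pipeline configuration: every tunable threshold in one validated object."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml


@dataclass
class PipelineConfig:
    """Thresholds used across the pipeline.

    Defaults are the study conditions: 3-MAD QC filtering, DE kept at
    |log-FC| > 0.25 or >10% expressing in both conditions, master
    regulators at >= 30% of the network determined, signaling activation
    above 0.70 / inhibition below 0.30, cell-cell significance above the
    0.90 percentile, and a 30-cluster cap on Calinski-Harabasz selection.
    ``passthrough`` holds settings for upstream tools (e.g. hotspot
    cutoff/percentile) that this package records but never interprets.
    """

    nmads: float = 3.0
    de_lfc_min: float = 0.25
    de_pct_min: float = 0.10
    mr_threshold: float = 0.30
    sig_active: float = 0.70
    sig_inhibited: float = 0.30
    cc_significance: float = 0.90
    max_clusters: int = 30
    ora_fdr: float = 0.05
    seed: int = 0
    passthrough: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.nmads > 0:
            raise ValueError("nmads must be positive")
        if not 0 <= self.sig_inhibited < self.sig_active <= 1:
            raise ValueError("need 0 <= sig_inhibited < sig_active <= 1")
        if not 0 < self.mr_threshold <= 1:
            raise ValueError("mr_threshold must be in (0, 1]")
        if not 0 <= self.cc_significance <= 1:
            raise ValueError("cc_significance must be in [0, 1]")
        if self.max_clusters < 1:
            raise ValueError("max_clusters must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from YAML or JSON (by extension; YAML parses JSON too)."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(**(data or {}))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(asdict(self), indent=2))
        else:
            path.write_text(yaml.safe_dump(asdict(self)))
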