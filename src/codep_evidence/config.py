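"""Analysis configuration: every threshold the pipeline applies, in one place.

Defaults follow the published settings of the source analyses: dependency
threshold -0.5 (the recommended CERES cutoff), top seven co-dependent genes,
tau > 90, co-expression FDR < 0.01 with |z| > 2 over pairs detected in at
least 100 shared cell lines, co-dependency restricted to genes with at least
three dependent lines, and a lineage scan flagged at p < 0.05 with FDR < 0.1.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    dependency_threshold: float = -0.5
    top_k: int = 7
    top_k_mode: str = "absolute"  # or "positive"
    tau_threshold: float = 90.0
    coexpr_fdr: float = 0.01
    coexpr_z: float = 2.0
    min_shared_lines: int = 100
    min_dependent_lines: int = 3
    lineage_p: float = 0.05
    lineage_fdr: float = 0.1
    min_lineage_size: int = 5
    min_codep_overlap: int = 10
    ora_fdr: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        import math

        for name in (
            "dependency_threshold",
            "tau_threshold",
            "coexpr_fdr",
            "coexpr_z",
            "lineage_p",
            "lineage_fdr",
            "ora_fdr",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.top_k_mode not in ("absolute", "positive"):
            raise ValueError("top_k_mode must be 'absolute' or 'positive'")
        if self.min_shared_lines < 3:
            raise ValueError("min_shared_lines must be >= 3")
        if self.min_codep_overlap < 3:
            raise ValueError("min_codep_overlap must be >= 3")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", newline="\n") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
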