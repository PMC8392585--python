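"""Run configuration: seeds and analysis settings with lossless YAML round trip."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Settings shared by the CLI commands; every randomised step is seeded."""

    seed: int = 0
    lasso_folds: int = 5
    lasso_rule: str = "min"  # or "1se"
    lasso_path_points: int = 100
    bootstrap_resamples: int = 1000
    bootstrap_recipe: str = "full"  # "full" repeats selection; "fit" refits only
    hl_groups: int = 6
    classification_cutoff: float = 0.65
    residual_threshold: float = 0.7
    combine_grid_width: float = 0.1  # Gy
    organ_labels: dict = field(
        default_factory=lambda: {"cpg": "combined_parotids", "oc": "oral_cavity"}
    )
    dosimetric_features: str = "auto"  # "auto" = t-test screening per organ
    dvh_dialect: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lasso_rule not in ("min", "1se"):
            raise ValueError("lasso_rule must be 'min' or '1se'")
        if self.bootstrap_recipe not in ("full", "fit"):
            raise ValueError("bootstrap_recipe must be 'full' or 'fit'")
        if self.bootstrap_resamples < 0 or self.hl_groups < 3:
            raise ValueError("invalid bootstrap/HL settings")
        if not 0.0 < self.classification_cutoff < 1.0:
            raise ValueError("classification cutoff must lie in (0, 1)")

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def digest(self) -> str:
        """Short provenance hash of the configuration."""
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]
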