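"""Analysis run configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .spatial import (
    DEFAULT_ENGAGEMENT_RADIUS_UM,
    DEFAULT_G_RADIUS_UM,
    DEFAULT_R_STEP_UM,
)
from .stats import DEFAULT_FAMILIES, DEFAULT_NORMALITY_ALPHA


@dataclass(frozen=True)
class RunConfig:
    """Knobs of the analysis pipeline.

    Defaults mirror the analysis constants: 40 um engagement radius, G-curve
    AUC to 60 um on a 1 um grid, per-core metrics averaged into patients
    (``CORE_MEAN``; ``POOLED`` weights cores by reference-cell count),
    alpha = 0.05 for the Shapiro-Wilk normality gate, and BH families per
    result panel.
    """

    engagement_radius: float = DEFAULT_ENGAGEMENT_RADIUS_UM
    g_auc_radius: float = DEFAULT_G_RADIUS_UM
    r_step: float = DEFAULT_R_STEP_UM
    aggregation: str = "CORE_MEAN"
    alpha: float = DEFAULT_NORMALITY_ALPHA
    bh_families: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_FAMILIES)
    )
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.engagement_radius <= 0 or self.g_auc_radius <= 0 or self.r_step <= 0:
            raise ValueError("radii and r_step must be positive")
        n = self.g_auc_radius / self.r_step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("r_step must divide g_auc_radius")
        if self.aggregation not in ("CORE_MEAN", "POOLED"):
            raise ValueError("aggregation must be CORE_MEAN or POOLED")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "engagement_radius": self.engagement_radius,
            "g_auc_radius": self.g_auc_radius,
            "r_step": self.r_step,
            "aggregation": self.aggregation,
            "alpha": self.alpha,
            "bh_families": {k: list(v) for k, v in self.bh_families.items()},
            "output_dir": self.output_dir,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        if "bh_families" in kwargs and kwargs["bh_families"] is not None:
            kwargs["bh_families"] = {
                k: tuple(v) for k, v in kwargs["bh_families"].items()
            }
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in kwargs.items() if k in known})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def with_(self, **overrides) -> "RunConfig":
        return replace(self, **overrides)
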