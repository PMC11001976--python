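"""Pipeline configuration: defaults, YAML loading and validation.

The config file is YAML with one nesting level: top-level keys ``seed`` and
``out_dir`` plus one section per stage (``simulate``, ``deg``,
``correlate``, ``enrich``, ``reposition``).  Unknown keys anywhere are
errors, so typos never fall back to silent defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["PipelineConfig", "DegParams", "CorrelateParams", "EnrichParams", "RepositionParams"]


@dataclass
class DegParams:
    alpha: float = 0.05
    lfc_min: float = 0.25
    mt_method: str = "bh"
    scale_factor: float = 1e4
    n_variable: int = 3000

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"deg.alpha must lie in (0, 1), got {self.alpha!r}")
        if self.lfc_min < 0:
            raise ValueError(f"deg.lfc_min must be nonnegative, got {self.lfc_min!r}")
        if self.mt_method.lower() not in {"bh", "bonferroni"}:
            raise ValueError(f"deg.mt_method must be bh or bonferroni, got {self.mt_method!r}")
        if self.scale_factor <= 0:
            raise ValueError(f"deg.scale_factor must be positive, got {self.scale_factor!r}")
        if self.n_variable <= 0:
            raise ValueError(f"deg.n_variable must be positive, got {self.n_variable!r}")


@dataclass
class CorrelateParams:
    r_min: float = 0.3
    alpha: float = 0.05
    top_n: int = 50

    def validate(self) -> None:
        if not -1.0 <= self.r_min <= 1.0:
            raise ValueError(f"correlate.r_min must lie in [-1, 1], got {self.r_min!r}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"correlate.alpha must lie in (0, 1), got {self.alpha!r}")
        if self.top_n <= 0:
            raise ValueError(f"correlate.top_n must be positive, got {self.top_n!r}")


@dataclass
class EnrichParams:
    alpha: float = 0.05
    top_terms: int = 5
    guard_term_patterns: list[str] = field(default_factory=lambda: ["MHC"])

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"enrich.alpha must lie in (0, 1), got {self.alpha!r}")
        if self.top_terms <= 0:
            raise ValueError(f"enrich.top_terms must be positive, got {self.top_terms!r}")
        if not self.guard_term_patterns:
            raise ValueError("enrich.guard_term_patterns must be nonempty")


@dataclass
class RepositionParams:
    dose: str = "10 uM"
    time: str = "24 h"
    k: int = 10
    tau: float = 0.5
    pseudocount: float = 0.0

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError(f"reposition.k must be >= 1, got {self.k!r}")
        if self.tau < 0:
            raise ValueError(f"reposition.tau must be nonnegative, got {self.tau!r}")
        if self.pseudocount < 0:
            raise ValueError(f"reposition.pseudocount must be nonnegative, got {self.pseudocount!r}")


def _update_dataclass(obj: Any, data: Mapping[str, Any], section: str) -> None:
    valid = {f.name for f in fields(obj)}
    for key, value in data.items():
        if key not in valid:
            raise ValueError(f"unknown config key {section}.{key!r}")
        setattr(obj, key, value)


@dataclass
class PipelineConfig:
    """All stage parameters plus the master seed and output directory."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    simulate: dict = field(default_factory=dict)  # overrides of the default fixture
    deg: DegParams = field(default_factory=DegParams)
    correlate: CorrelateParams = field(default_factory=CorrelateParams)
    enrich: EnrichParams = field(default_factory=EnrichParams)
    reposition: RepositionParams = field(default_factory=RepositionParams)

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")
        self.deg.validate()
        self.correlate.validate()
        self.enrich.validate()
        self.reposition.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        cfg = cls()
        sections = {
            "deg": cfg.deg,
            "correlate": cfg.correlate,
            "enrich": cfg.enrich,
            "reposition": cfg.reposition,
        }
        for key, value in data.items():
            if key in {"seed", "out_dir"}:
                setattr(cfg, key, value)
            elif key == "simulate":
                cfg.simulate = dict(value or {})
            elif key in sections:
                _update_dataclass(sections[key], value or {}, key)
            else:
                raise ValueError(f"unknown config key {key!r}")
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "simulate": dict(self.simulate),
            "deg": asdict(self.deg),
            "correlate": asdict(self.correlate),
            "enrich": asdict(self.enrich),
            "reposition": asdict(self.reposition),
        }
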