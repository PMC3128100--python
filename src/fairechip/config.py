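"""Pipeline configuration: one dataclass per stage, YAML-serializable.

Defaults reproduce the vendor-style peak-calling settings used throughout
(300 bp window, >=4 above-cutoff probes, cutoff series 90% -> 15% of the
per-chromosome hypothetical maximum in 0.5% steps) and the standard proxy
filters (r2 >= 0.8, MAF >= 0.05).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

__all__ = [
    "PeakCallParams",
    "LdParams",
    "AnnotationParams",
    "EqtlParams",
    "DeParams",
    "NetworkParams",
    "PipelineConfig",
]


@dataclass
class PeakCallParams:
    window_bp: int = 300
    min_probes: int = 4
    gap_probes: int = 2
    p_start: float = 90.0
    p_end: float = 15.0
    p_step: float = 0.5
    #: optional cap on the number of cutoffs, counted from p_start downward;
    #: None means the full arithmetic series (151 values at the defaults).
    max_steps: Optional[int] = None
    sd_mult: float = 6.0
    require_scaled: bool = True

    def __post_init__(self) -> None:
        if self.p_end > self.p_start:
            raise ValueError("p_end must be <= p_start")
        for name in ("window_bp", "min_probes", "p_step", "sd_mult"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gap_probes < 0:
            raise ValueError("gap_probes must be >= 0")


@dataclass
class LdParams:
    r2_min: float = 0.8
    maf_min: float = 0.05


@dataclass
class AnnotationParams:
    tss_window_bp: int = 20_000
    gene_flank_bp: int = 2_000
    promoter_bp: int = 2_000


@dataclass
class EqtlParams:
    window_bp: int = 1_000_000


@dataclass
class DeParams:
    #: linear-scale fold-change threshold; a gene passes iff
    #: abs(log2 fold-change) >= log2(fc_min)
    fc_min: float = 1.5
    #: set True to instead require abs(log2 fold-change) >= fc_min
    fc_on_log2_scale: bool = False


@dataclass
class NetworkParams:
    detection_p_max: float = 0.01
    filter_cores: bool = False


@dataclass
class PipelineConfig:
    seed: int = 0
    peaks: PeakCallParams = field(default_factory=PeakCallParams)
    ld: LdParams = field(default_factory=LdParams)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    eqtl: EqtlParams = field(default_factory=EqtlParams)
    de: DeParams = field(default_factory=DeParams)
    network: NetworkParams = field(default_factory=NetworkParams)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        blocks = {
            "peaks": PeakCallParams,
            "ld": LdParams,
            "annotation": AnnotationParams,
            "eqtl": EqtlParams,
            "de": DeParams,
            "network": NetworkParams,
        }
        for key, value in data.items():
            if key in blocks:
                kwargs[key] = blocks[key](**value)
            elif key == "seed":
                kwargs[key] = int(value)
            else:
                raise ValueError(f"unknown config block {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
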