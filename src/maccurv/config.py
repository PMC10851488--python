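"""Pipeline configuration.

All numeric defaults reproduce the published construction: 0.014 mm lateral
pitch (100 px = 1.4 mm), 1.4 mm chord offset, 100-column ROI margins,
12 radial scans per eye, MC reference 40 with the empirical gray zone
[37.5, 42.7] between the highest no-staphyloma and lowest definite-staphyloma
index observed clinically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass(frozen=True)
class PipelineConfig:
    px_h_mm: float = 0.014
    chord_offset_mm: float = 1.4
    roi_margin_cols: int = 100
    mc_reference: float = 40.0
    indeterminate_band: tuple[float, float] | None = (37.5, 42.7)
    expected_scans: int = 12
    # RPE detector settings
    smooth_halfwidth: int = 5
    min_contrast: float = 0.3
    column_smooth_sigma_px: float = 2.0
    # aggregation: "mean" is the published construction; "median" is a
    # robustness option and deliberately not the default
    aggregate: str = "mean"
    out_dir: str = "results"
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.px_h_mm <= 0 or self.chord_offset_mm <= 0:
            raise ConfigurationError("pitches and chord offset must be positive")
        if self.indeterminate_band is not None:
            lo, hi = self.indeterminate_band
            if lo > hi:
                raise ConfigurationError(
                    f"indeterminate band low {lo} exceeds high {hi}"
                )
            object.__setattr__(self, "indeterminate_band", (float(lo), float(hi)))
        if self.aggregate not in ("mean", "median"):
            raise ConfigurationError(f"unknown aggregate {self.aggregate!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["indeterminate_band"] is not None:
            d["indeterminate_band"] = list(d["indeterminate_band"])
        return d

    def config_hash(self) -> str:
        """Stable hash of the configuration, embedded in every results file."""
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        band = d.get("indeterminate_band")
        if band is not None:
            d["indeterminate_band"] = tuple(band)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        return cls.from_dict(raw)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
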