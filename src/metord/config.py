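"""Pipeline configuration: every knob of one analysis run in one object."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .ordination import METRICS
from .preprocessing import NORMALIZATION_METHODS, SCALING_METHODS

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Full parameter set of one run; validated before any I/O happens."""

    input_path: str = ""
    dialect: str = "gnps"                       # gnps | plain | plain_features
    metadata_path: str = ""
    id_column: str = "sample_id"
    blank_column: str = "sample_type"
    blank_value: str = "blank"
    drop_blanks_before_ordination: bool = False
    filter_enabled: bool = False
    fold_threshold: float = 3.0
    min_nonblank_fraction: float = 0.9
    normalization: str = "tic"                  # tic | pqn | none
    scaling: str = "auto"                       # auto | pareto | none
    metric: str = "braycurtis"
    num_axes: int = 3
    color_by: str | None = None
    shape_by: str | None = None
    output_dir: str = "metord_output"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dialect not in ("gnps", "plain", "plain_features"):
            raise ValueError(
                f"unknown dialect {self.dialect!r}; choose gnps, plain or "
                "plain_features"
            )
        if self.normalization not in NORMALIZATION_METHODS:
            raise ValueError(
                f"unknown normalization {self.normalization!r}; choose from "
                f"{NORMALIZATION_METHODS}"
            )
        if self.scaling not in SCALING_METHODS:
            raise ValueError(
                f"unknown scaling {self.scaling!r}; choose from {SCALING_METHODS}"
            )
        if self.metric not in METRICS:
            raise ValueError(
                f"unknown metric {self.metric!r}; valid metrics: "
                + ", ".join(sorted(METRICS))
            )
        if self.filter_enabled:
            if not self.fold_threshold > 0:
                raise ValueError("fold_threshold must be > 0")
            if not 0 < self.min_nonblank_fraction <= 1:
                raise ValueError("min_nonblank_fraction must be in (0, 1]")
        if not (self.num_axes == "all" or int(self.num_axes) >= 1):
            raise ValueError("num_axes must be >= 1 or 'all'")

    def as_dict(self) -> dict:
        return asdict(self)


def load_config(path=None, **overrides) -> PipelineConfig:
    """Build a config from defaults < YAML file < keyword overrides."""
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config file must be a YAML mapping")
        known = {f.name for f in fields(PipelineConfig)}
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values)
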