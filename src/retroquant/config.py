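"""YAML pipeline configuration and resolved-config provenance.

A run is fully described by a flat YAML mapping with three optional
sections: ``kinetics`` (model parameters), ``acquisition`` (imaging
protocol / camera), and ``pipeline`` (thresholds, channel mapping, fit
window, labels, seed). Every command writes back the fully resolved
configuration it actually used, so any output can be regenerated from its
sidecar file alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError
from .kinetics import KineticParams
from .synthetic import AcquisitionParams
from .segmentation import ThresholdSpec


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    kinetics: KineticParams = field(default_factory=KineticParams)
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    n_cells: int = 3
    image_shape: tuple[int, int] = (512, 512)
    channel_map: dict[str, int] = field(
        default_factory=lambda: {"gfp": 0, "red": 1, "lyso": 2}
    )
    thresholds: ThresholdSpec | None = None  # None -> Otsu auto-thresholds
    fit_window_min: tuple[float, float] = (90.0, 360.0)
    condition_label: str = "control"
    control_label: str = "control"
    rng_seed: int = 0
    outdir: Path = Path("retroquant_out")

    def __post_init__(self) -> None:
        idx = list(self.channel_map.values())
        if sorted(self.channel_map) != ["gfp", "lyso", "red"] or len(set(idx)) != 3:
            raise ConfigError(
                "channel_map must assign distinct indices to gfp, red and lyso"
            )
        lo, hi = self.fit_window_min
        if not lo < hi:
            raise ConfigError("fit window must satisfy start < end")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed config {path}: {exc}") from exc
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        kw: dict[str, Any] = {}
        raw = dict(raw)
        if "kinetics" in raw:
            kw["kinetics"] = KineticParams.from_dict(raw.pop("kinetics"))
        if "acquisition" in raw:
            try:
                kw["acquisition"] = AcquisitionParams(**raw.pop("acquisition"))
            except TypeError as exc:
                raise ConfigError(f"bad acquisition section: {exc}") from exc
        if raw.get("thresholds") is not None:
            try:
                kw["thresholds"] = ThresholdSpec(**raw.pop("thresholds"))
            except TypeError as exc:
                raise ConfigError(f"bad thresholds section: {exc}") from exc
        else:
            raw.pop("thresholds", None)
        for key in (
            "n_cells",
            "condition_label",
            "control_label",
            "rng_seed",
            "outdir",
        ):
            if key in raw:
                kw[key] = raw.pop(key)
        if "image_shape" in raw:
            kw["image_shape"] = tuple(raw.pop("image_shape"))
        if "fit_window_min" in raw:
            kw["fit_window_min"] = tuple(raw.pop("fit_window_min"))
        if "channel_map" in raw:
            kw["channel_map"] = dict(raw.pop("channel_map"))
        if raw:
            raise ConfigError(f"unknown config key(s): {sorted(raw)}")
        try:
            return cls(**kw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict[str, Any]:
        d = {
            "kinetics": asdict(self.kinetics),
            "acquisition": asdict(self.acquisition),
            "n_cells": self.n_cells,
            "image_shape": list(self.image_shape),
            "channel_map": dict(self.channel_map),
            "thresholds": asdict(self.thresholds) if self.thresholds else None,
            "fit_window_min": list(self.fit_window_min),
            "condition_label": self.condition_label,
            "control_label": self.control_label,
            "rng_seed": self.rng_seed,
            "outdir": str(self.outdir),
        }
        d["acquisition"]["bleach_per_min"] = list(
            d["acquisition"]["bleach_per_min"]
        )
        return d

    def write_resolved(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
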