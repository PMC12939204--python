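"""Flat key=value pipeline configuration with strict key checking.

Every tunable of the segmentation/measurement/grading pipeline lives here
so that a run can echo its full resolved configuration (including defaulted
keys) before processing — the automatic-threshold and particle-size choices
in particular must be auditable per run.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any, Mapping

from .errors import ConfigError

__all__ = ["PipelineConfig", "DEFAULTS"]

DEFAULTS: dict[str, Any] = {
    # RGB -> 8-bit conversion: "unweighted" mean of R,G,B or "luma" weights.
    "grayscale.mode": "unweighted",
    # Fraction of pixels saturated (split between both tails) by auto-contrast.
    "autocontrast.saturation": 0.0035,
    # "isodata" (automatic intermeans) or "fixed" with threshold.fixed_value.
    "threshold.method": "isodata",
    "threshold.fixed_value": None,
    # Particle size window in calibrated cm^2.  The 0.5 cm^2 floor filters
    # tiny impurities (dust, fascia fragments) out of the marbling count.
    "particles.min_cm2": 0.5,
    "particles.max_cm2": math.inf,
    # Components smaller than this are bench debris, not rib-eye.
    "cleanup.min_object_cm2": 1.0,
    # Minimum gray-level separation between lean and fat class means for a
    # marbling split to be accepted (guards against splitting pure noise).
    "marbling.min_separation": 20.0,
    # "oriented_box" (minimum-area rotated rectangle) or "feret".
    "measurement.length_method": "oriented_box",
    # Channel means over the whole ribeye ("ribeye") or lean only ("lean_only").
    "measurement.channel_scope": "ribeye",
    # Grade combination rule: majority_marbling | marbling_only | minimum.
    "grading.strategy": "majority_marbling",
    # Clamp sub-scale areas (< 40 cm^2) to grade A1 instead of flagging.
    "grading.clamp_below_scale": False,
}

_CHOICES: dict[str, tuple[Any, ...]] = {
    "grayscale.mode": ("unweighted", "luma"),
    "threshold.method": ("isodata", "fixed"),
    "measurement.length_method": ("oriented_box", "feret"),
    "measurement.channel_scope": ("ribeye", "lean_only"),
    "grading.strategy": ("majority_marbling", "marbling_only", "minimum"),
}


class PipelineConfig(Mapping[str, Any]):
    """Immutable view over the defaults with validated overrides."""

    def __init__(self, overrides: Mapping[str, Any] | None = None) -> None:
        values = dict(DEFAULTS)
        for key, value in (overrides or {}).items():
            if key not in DEFAULTS:
                raise ConfigError(f"unknown configuration key {key!r}")
            if key in _CHOICES and value not in _CHOICES[key]:
                raise ConfigError(
                    f"{key}={value!r} not one of {_CHOICES[key]}"
                )
            values[key] = value
        if values["autocontrast.saturation"] is not None and not (
            0.0 <= float(values["autocontrast.saturation"]) < 0.5
        ):
            raise ConfigError("autocontrast.saturation must lie in [0, 0.5)")
        self._values = values

    @classmethod
    def ensure(cls, config: "PipelineConfig | Mapping[str, Any] | None") -> "PipelineConfig":
        if isinstance(config, cls):
            return config
        return cls(config)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load overrides from a flat JSON object file."""
        try:
            data = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config {path!s}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path!s} must hold a flat JSON object")
        return cls(data)

    def to_dict(self) -> dict[str, Any]:
        return dict(self._values)

    def describe(self) -> str:
        """One key=value per line, for run-start logging."""
        return "\n".join(f"{k}={self._values[k]}" for k in sorted(self._values))

    def __getitem__(self, key: str) -> Any:
        return self._values[key]

    def __iter__(self):
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)
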