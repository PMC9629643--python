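"""Run configuration: the key-value surface between users and the solver.

A run is described by a flat mapping (YAML file and/or CLI overrides) in
laboratory units — millimetres, microlitres/millilitres, percent oxygen —
and converted here into the SI-unit solver objects.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .params import (
    InvalidGeometryError,
    SurfaceOxygen,
    TransportParams,
    WellSystem,
    media_depth_from_volume,
    standard_placements,
)

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range configuration values."""


@dataclass
class RunConfig:
    """Complete, serialisable description of one solver run."""

    d_media: float = 4.85e-9            # [m^2/s]
    d_tissue: float = 1.6e-9            # [m^2/s]
    uptake_rate: float = 0.057          # [1/s]
    well_diameter_mm: float = 22.1
    well_depth_mm: float = 17.5
    media_volume_ml: float | None = None
    media_depth_mm: float = 3.4
    slice_diameter_mm: float = 5.0
    slice_thickness_um: float = 250.0
    oxygen_percent: float = 21.0
    placement: str = "middle"           # bottom | middle | top | "custom <h1_mm>"
    truncation_M: int = 7

    def validate(self) -> None:
        checks = [
            ("d_media", self.d_media > 0),
            ("d_tissue", self.d_tissue > 0),
            ("uptake_rate", self.uptake_rate >= 0),
            ("well_diameter_mm", self.well_diameter_mm > 0),
            ("slice_diameter_mm", 0 < self.slice_diameter_mm <= self.well_diameter_mm),
            ("slice_thickness_um", self.slice_thickness_um > 0),
            ("oxygen_percent", 0 <= self.oxygen_percent <= 100),
            ("truncation_M", self.truncation_M >= 1),
        ]
        for key, ok in checks:
            if not ok:
                raise ConfigError(f"configuration key {key!r} is out of range "
                                  f"(value {getattr(self, key)!r})")
        name = self.placement.split()[0] if self.placement.strip() else ""
        if name not in ("bottom", "middle", "top", "custom"):
            raise ConfigError(f"configuration key 'placement' must be bottom, middle, "
                              f"top or 'custom <h1_mm>'; got {self.placement!r}")
        if name == "custom":
            parts = self.placement.split()
            if len(parts) != 2:
                raise ConfigError("custom placement must be written 'custom <h1_mm>'")
            try:
                float(parts[1])
            except ValueError as exc:
                raise ConfigError(f"custom placement height {parts[1]!r} is not a number") from exc

    # -- conversion --------------------------------------------------------
    def media_depth(self) -> float:
        """Media depth H [m]; derived from the volume when one is given."""
        if self.media_volume_ml is not None:
            return media_depth_from_volume(self.media_volume_ml * 1e-6,
                                           self.well_diameter_mm * 1e-3 / 2.0)
        return self.media_depth_mm * 1e-3

    def build(self) -> tuple[WellSystem, TransportParams, SurfaceOxygen]:
        self.validate()
        H = self.media_depth()
        t = self.slice_thickness_um * 1e-6
        name = self.placement.split()[0]
        if name == "custom":
            h1 = float(self.placement.split()[1]) * 1e-3
            h2 = h1 + t
        else:
            h1, h2 = standard_placements(H, t)[name]
        system = WellSystem(
            well_radius=self.well_diameter_mm * 1e-3 / 2.0,
            well_depth=self.well_depth_mm * 1e-3,
            media_depth=H,
            media_volume=None if self.media_volume_ml is None else self.media_volume_ml * 1e-6,
            slice_radius=self.slice_diameter_mm * 1e-3 / 2.0,
            h1=h1,
            h2=h2,
        )
        transport = TransportParams(d_media=self.d_media, d_tissue=self.d_tissue,
                                    uptake_rate=self.uptake_rate)
        surface = SurfaceOxygen.from_fraction(self.oxygen_percent / 100.0)
        return system, transport, surface

    def as_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    Unknown keys raise :class:`ConfigError` naming the offending key.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a key-value mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg
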