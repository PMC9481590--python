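"""Declarative run configuration (YAML) and its validation.

A run is described by one YAML document; CLI flags override individual
fields and the merged, effective configuration is echoed to the log so every
output directory is reproducible from its log alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["RunConfig", "load_config", "DEFAULT_THRESHOLDS_MIN"]

log = logging.getLogger(__name__)

# Travel-time thresholds (minutes) at which coverage is reported.
DEFAULT_THRESHOLDS_MIN = (30, 60, 90, 120, 150, 180)


@dataclass
class RunConfig:
    """Validated run parameters.

    ``world`` holds the synthetic-world generator parameters (passed through
    to :class:`geoaccess.synthetic.WorldConfig`); ``schemes`` the population
    allocation schemes to build, one dataset each; ``datasets`` an explicit
    registry name → population raster path for runs on pre-existing rasters.
    """

    thresholds_min: tuple[int, ...] = DEFAULT_THRESHOLDS_MIN
    admin_levels: tuple[int, ...] = (0, 1, 2)
    seed: int = 0
    scenario_path: str | None = None
    world: dict[str, Any] = field(default_factory=dict)
    schemes: list[dict[str, Any]] = field(default_factory=list)
    datasets: dict[str, str] = field(default_factory=dict)
    snap_radius_cells: int = 5

    def __post_init__(self) -> None:
        t = tuple(self.thresholds_min)
        if not t:
            raise ValueError("at least one travel-time threshold is required")
        if any(x <= 0 for x in t) or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError(
                f"thresholds must be strictly increasing and positive, got {t}"
            )
        self.thresholds_min = t
        levels = tuple(self.admin_levels)
        if not set(levels) <= {0, 1, 2}:
            raise ValueError(f"admin_levels must be a subset of {{0,1,2}}, got {levels}")
        self.admin_levels = levels

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def load_config(path, overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Load YAML config, apply non-None overrides, validate, and log it."""
    doc: dict[str, Any] = {}
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
    for key, value in (overrides or {}).items():
        if value is not None:
            doc[key] = value
    known = RunConfig.__dataclass_fields__.keys()
    unknown = set(doc) - set(known)
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    cfg = RunConfig(**doc)
    log.info("effective config: %s", yaml.safe_dump(cfg.to_dict(), sort_keys=True).strip())
    return cfg
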