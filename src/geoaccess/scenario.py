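"""Travel scenarios: the mapping from merged land-cover classes to speeds.

A scenario row assigns one class code a travel mode and a speed.  ``road``
rows are motorized, ``offroad`` rows are walking, and ``barrier`` rows mark
impassable classes (permanent waterbodies) and carry no speed.  A fallback
table of average road speeds fills classes the scenario omits, mirroring the
practice of substituting a regional average when no class-specific speed is
known.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ScenarioRow",
    "ScenarioTable",
    "read_scenario",
    "write_scenario",
    "DEFAULT_SCENARIO",
    "DEFAULT_ROAD_FALLBACK_KMH",
    "ScenarioError",
]

log = logging.getLogger(__name__)

MODES = ("road", "offroad", "barrier")


class ScenarioError(ValueError):
    """Invalid scenario table contents."""


@dataclass(frozen=True)
class ScenarioRow:
    class_code: int
    label: str
    mode: str
    speed_kmh: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ScenarioError(f"unknown mode {self.mode!r} for class {self.class_code}")
        if self.mode == "barrier":
            if self.speed_kmh is not None:
                raise ScenarioError(
                    f"barrier class {self.class_code} must not carry a speed"
                )
        else:
            if self.speed_kmh is None or not self.speed_kmh > 0:
                raise ScenarioError(
                    f"class {self.class_code} ({self.label}): speed must be > 0 km/h, "
                    f"got {self.speed_kmh!r}"
                )


class ScenarioTable:
    """Validated class → (mode, speed) table with unique class codes."""

    def __init__(self, rows: Iterable[ScenarioRow]):
        self.rows: list[ScenarioRow] = list(rows)
        seen: set[int] = set()
        for row in self.rows:
            if row.class_code in seen:
                raise ScenarioError(f"duplicate class_code {row.class_code}")
            seen.add(row.class_code)
        self._by_code = {r.class_code: r for r in self.rows}

    def __len__(self) -> int:
        return len(self.rows)

    def __contains__(self, class_code: int) -> bool:
        return class_code in self._by_code

    @property
    def classes(self) -> set[int]:
        return set(self._by_code)

    def mode(self, class_code: int) -> str:
        return self._by_code[class_code].mode

    def speed(self, class_code: int) -> float:
        row = self._by_code[class_code]
        if row.mode == "barrier":
            raise ScenarioError(f"class {class_code} is a barrier; it has no speed")
        return float(row.speed_kmh)  # type: ignore[arg-type]

    def speeds(self) -> dict[int, float]:
        """Class → speed for all non-barrier classes."""
        return {r.class_code: float(r.speed_kmh) for r in self.rows if r.mode != "barrier"}

    def barrier_classes(self) -> set[int]:
        return {r.class_code for r in self.rows if r.mode == "barrier"}

    def with_rows(self, extra: Iterable[ScenarioRow]) -> "ScenarioTable":
        return ScenarioTable([*self.rows, *extra])


def _rows_from_records(records: Iterable[Mapping]) -> list[ScenarioRow]:
    rows = []
    for rec in records:
        speed = rec.get("speed_kmh")
        if speed in ("", None, "-", "NA"):
            speed = None
        rows.append(
            ScenarioRow(
                class_code=int(rec["class_code"]),
                label=str(rec["label"]),
                mode=str(rec["mode"]),
                speed_kmh=None if speed is None else float(speed),
            )
        )
    return rows


def read_scenario(path) -> ScenarioTable:
    """Read a scenario from CSV (columns class_code,label,mode,speed_kmh) or YAML."""
    path = Path(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        records = yaml.safe_load(path.read_text())
        if not isinstance(records, list):
            raise ScenarioError(f"{path}: YAML scenario must be a list of rows")
    else:
        with open(path, newline="") as fh:
            records = list(csv.DictReader(fh))
    return ScenarioTable(_rows_from_records(records))


def write_scenario(path, table: ScenarioTable) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class_code", "label", "mode", "speed_kmh"])
        for row in table.rows:
            writer.writerow(
                [row.class_code, row.label, row.mode, "" if row.speed_kmh is None else row.speed_kmh]
            )
    return path


# Land-cover class codes used throughout the synthetic pipeline.
CLASS_OPEN = 1
CLASS_FOREST = 2
CLASS_SETTLEMENT = 3
CLASS_ROAD_PRIMARY = 10
CLASS_ROAD_SECONDARY = 11
CLASS_ROAD_TERTIARY = 12
CLASS_WATER = 200

# Default travel scenario: motorized speeds on roads, walking speeds off-road,
# water as an impassable barrier.  Walking at 5 km/h on open terrain and 2 km/h
# through dense forest; road speeds follow common class averages.
DEFAULT_SCENARIO = ScenarioTable(
    [
        ScenarioRow(CLASS_OPEN, "open terrain", "offroad", 5.0),
        ScenarioRow(CLASS_FOREST, "dense forest", "offroad", 2.0),
        ScenarioRow(CLASS_SETTLEMENT, "settlement", "offroad", 5.0),
        ScenarioRow(CLASS_ROAD_PRIMARY, "primary road", "road", 80.0),
        ScenarioRow(CLASS_ROAD_SECONDARY, "secondary road", "road", 50.0),
        ScenarioRow(CLASS_ROAD_TERTIARY, "tertiary road", "road", 30.0),
        ScenarioRow(CLASS_WATER, "waterbody", "barrier", None),
    ]
)

# Continental average speeds per road class, used to fill scenario gaps.
DEFAULT_ROAD_FALLBACK_KMH: dict[int, float] = {
    CLASS_ROAD_PRIMARY: 80.0,
    CLASS_ROAD_SECONDARY: 50.0,
    CLASS_ROAD_TERTIARY: 30.0,
}
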