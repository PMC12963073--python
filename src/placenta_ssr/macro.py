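"""Automated gross-examination calculations.

Three calculations accompany the macroscopy tab: the umbilical coiling
index (coils per centimetre of cord), placental-weight-for-gestation
percentile banding, and cord-diameter-for-gestation banding.  Percentile
banding compares a measurement against a per-completed-week reference
table (p3/p10/p50/p90/p97 columns) supplied as CSV; lookup uses the
nearest tabulated week (ties toward the lower week) since published
reference tables are indexed by completed week.

Boundary semantics follow the grading scheme's "< 10th percentile":
``below_p10`` is strict, so a weight exactly on the p10 curve does not
qualify as low; the upper bands symmetrically use value >= p90 / >= p97.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from enum import Enum
from pathlib import Path
from typing import Optional, Union

from .config import SsrConfig

__all__ = [
    "ReferenceKind",
    "ReferenceTable",
    "Band",
    "PercentileAssessment",
    "ReferenceRangeError",
    "coiling_index",
    "classify_coiling",
    "assess_against_reference",
    "load_reference_table",
    "synthetic_weight_reference",
    "synthetic_cord_diameter_reference",
]

_PERCENTILE_LABELS = ("p3", "p10", "p50", "p90", "p97")


class ReferenceKind(str, Enum):
    PLACENTAL_WEIGHT = "placental_weight"
    CORD_DIAMETER = "cord_diameter"


class Band(str, Enum):
    """Percentile band of a measurement, ordered from low to high."""

    BELOW_P3 = "below_p3"
    P3_P10 = "p3_p10"
    P10_P90 = "p10_p90"
    P90_P97 = "p90_p97"
    ABOVE_P97 = "above_p97"

    @property
    def rank(self) -> int:
        return list(Band).index(self)


class ReferenceRangeError(ValueError):
    """Gestational age outside the reference table's tabulated range."""


@dataclass(frozen=True)
class ReferenceRow:
    ga_weeks: int
    values: dict  # percentile label -> measurement


@dataclass(frozen=True)
class ReferenceTable:
    kind: ReferenceKind
    rows: tuple

    def __post_init__(self) -> None:
        gas = [r.ga_weeks for r in self.rows]
        if gas != sorted(set(gas)):
            raise ValueError("reference gestational ages must be strictly increasing")
        for r in self.rows:
            vals = [r.values[p] for p in _PERCENTILE_LABELS]
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValueError(
                    f"percentile values must be non-decreasing within week {r.ga_weeks}"
                )

    @property
    def ga_range(self) -> tuple[int, int]:
        return self.rows[0].ga_weeks, self.rows[-1].ga_weeks

    def row_for(self, ga_weeks: float) -> ReferenceRow:
        lo, hi = self.ga_range
        if not (lo <= ga_weeks <= hi):
            raise ReferenceRangeError(
                f"gestational age {ga_weeks} outside supported range [{lo}, {hi}] weeks"
            )
        # nearest tabulated week; ties resolve toward the lower week
        return min(self.rows, key=lambda r: (abs(r.ga_weeks - ga_weeks), r.ga_weeks))


@dataclass(frozen=True)
class PercentileAssessment:
    value: float
    ga_weeks: float
    band: Band
    below_p10: bool
    deviation_from_p50: float
    reference_week: int


def coiling_index(coil_count: int, cord_length_cm: float) -> float:
    """Umbilical coiling index: complete coils per cm of cord.

    Rounded half-even to 3 decimals.
    """
    if cord_length_cm <= 0:
        raise ValueError("cord_length_cm must be > 0 to compute a coiling index")
    if coil_count < 0:
        raise ValueError("coil_count must be >= 0")
    ratio = Decimal(coil_count) / Decimal(str(cord_length_cm))
    return float(ratio.quantize(Decimal("0.001"), rounding=ROUND_HALF_EVEN))


def classify_coiling(index: float, config: Optional[SsrConfig] = None) -> str:
    """Classify a coiling index as hypocoiled / normocoiled / hypercoiled
    against the configured normal range."""
    cfg = config or SsrConfig()
    if index < cfg.coiling_low_cut:
        return "hypocoiled"
    if index > cfg.coiling_high_cut:
        return "hypercoiled"
    return "normocoiled"


def assess_against_reference(
    value: float, ga_weeks: float, table: ReferenceTable
) -> PercentileAssessment:
    """Band a measurement against the gestational-age percentile reference."""
    if value <= 0:
        raise ValueError("measurement must be > 0")
    row = table.row_for(ga_weeks)
    v = row.values
    if value < v["p3"]:
        band = Band.BELOW_P3
    elif value < v["p10"]:
        band = Band.P3_P10
    elif value < v["p90"]:
        band = Band.P10_P90
    elif value < v["p97"]:
        band = Band.P90_P97
    else:
        band = Band.ABOVE_P97
    return PercentileAssessment(
        value=value,
        ga_weeks=ga_weeks,
        band=band,
        below_p10=value < v["p10"],
        deviation_from_p50=value - v["p50"],
        reference_week=row.ga_weeks,
    )


def load_reference_table(path: Union[str, Path], kind: ReferenceKind) -> ReferenceTable:
    """Load a percentile reference from CSV with columns
    ga_weeks,p3,p10,p50,p90,p97 (``#`` comment lines allowed)."""
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    reader = csv.DictReader(lines)
    expected = {"ga_weeks", *_PERCENTILE_LABELS}
    if reader.fieldnames is None or set(reader.fieldnames) != expected:
        raise ValueError(f"{path}: expected columns {sorted(expected)}")
    for rec in reader:
        rows.append(
            ReferenceRow(
                ga_weeks=int(rec["ga_weeks"]),
                values={p: float(rec[p]) for p in _PERCENTILE_LABELS},
            )
        )
    return ReferenceTable(kind=kind, rows=tuple(rows))


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("placenta_ssr"))) / "data" / name


def synthetic_weight_reference() -> ReferenceTable:
    """Bundled synthetic placental-weight curve (round numbers, for tests
    and demos only — not population norms)."""
    return load_reference_table(
        _data_path("synthetic_weight_reference.csv"), ReferenceKind.PLACENTAL_WEIGHT
    )


def synthetic_cord_diameter_reference() -> ReferenceTable:
    """Bundled synthetic cord-diameter curve (synthetic, non-clinical)."""
    return load_reference_table(
        _data_path("synthetic_cord_diameter_reference.csv"), ReferenceKind.CORD_DIAMETER
    )
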