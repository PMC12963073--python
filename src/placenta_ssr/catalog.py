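"""Controlled vocabulary of placental lesions.

Every lesion the microscopy layer can record lives in a versioned CSV
catalog bundled with the package.  A lesion is bound to exactly one of the
five anatomical compartments and one of the five injury patterns
(acute inflammation, chronic inflammation, fetal vascular malperfusion,
maternal vascular malperfusion, other significant pathology).  Scoring
attributes — maternal-vascular-malperfusion points, the single-character
"other significant pathology" suffix letter, and mutual-exclusivity
groups — are carried on the catalog row so that grading thresholds can
evolve without touching code.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional, Union

__all__ = [
    "Compartment",
    "Category",
    "LesionDef",
    "LesionCatalog",
    "CatalogError",
    "OTHER_LETTER_ORDER",
    "load_catalog",
]

#: Canonical ordering of the "other significant pathology" suffix letters.
OTHER_LETTER_ORDER = "hijksnopqr"


class Compartment(str, Enum):
    """The five anatomical sites a lesion is assigned to."""

    MEMBRANES = "membranes"
    UMBILICAL_CORD = "umbilical_cord"
    CHORIONIC_PLATE = "chorionic_plate"
    BASAL_PLATE = "basal_plate"
    VILLOUS_INTERVILLOUS = "villous_intervillous"


class Category(str, Enum):
    """The five injury patterns of the grading scheme."""

    ACUTE_INFLAMMATION = "acute_inflammation"
    CHRONIC_INFLAMMATION = "chronic_inflammation"
    FVM = "fvm"
    MVM = "mvm"
    OTHER_SIGNIFICANT = "other_significant"


class CatalogError(ValueError):
    """Raised when a catalog file is malformed."""


@dataclass(frozen=True)
class LesionDef:
    """One catalog entry.

    Parameters
    ----------
    lesion_id
        Stable snake-case key used in case records and serialisations.
    display_name
        Human-readable lesion name as used in reports.
    compartment, category
        Anatomical site and injury pattern; exactly one each.
    mvm_points
        Contribution to the maternal-vascular-malperfusion score
        (0, 1 or 2).  Non-zero only for MVM lesions and for increased
        perivillous fibrin deposition, which scores 1 MVM point while
        remaining an "other significant pathology" lesion.
    other_letter
        Suffix letter (h/i/j/k/s/n/o/p/q/r) for "other significant
        pathology" lesions; ``None`` otherwise.
    exclusivity_group
        Lesions sharing a group are graded escalations of one finding
        (e.g. single vs multiple infarcts) and may not co-occur.
    """

    lesion_id: str
    display_name: str
    compartment: Compartment
    category: Category
    mvm_points: int = 0
    other_letter: Optional[str] = None
    exclusivity_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mvm_points not in (0, 1, 2):
            raise CatalogError(
                f"{self.lesion_id}: mvm_points must be 0, 1 or 2, got {self.mvm_points}"
            )
        if self.mvm_points > 0 and self.category not in (Category.MVM,) and (
            self.lesion_id != "increased_perivillous_fibrin"
        ):
            raise CatalogError(
                f"{self.lesion_id}: mvm_points set on non-MVM lesion"
            )
        if self.other_letter is not None:
            if self.other_letter not in OTHER_LETTER_ORDER:
                raise CatalogError(
                    f"{self.lesion_id}: invalid other_letter {self.other_letter!r}"
                )
            if self.category is not Category.OTHER_SIGNIFICANT:
                raise CatalogError(
                    f"{self.lesion_id}: other_letter set outside other-pathology list"
                )


class LesionCatalog:
    """Immutable, order-stable collection of :class:`LesionDef`.

    Lookup by ``lesion_id`` is total over the shipped vocabulary; the
    catalog also partitions into (compartment, category) cells, which the
    per-compartment microscopy checklists are built from.
    """

    def __init__(self, lesions: list[LesionDef], version: str = "unversioned"):
        self.version = version
        self._lesions: tuple[LesionDef, ...] = tuple(lesions)
        self._by_id: dict[str, LesionDef] = {}
        for lesion in self._lesions:
            if lesion.lesion_id in self._by_id:
                raise CatalogError(f"duplicate lesion_id {lesion.lesion_id!r}")
            self._by_id[lesion.lesion_id] = lesion
        letters = [l.other_letter for l in self._lesions if l.other_letter]
        dup = {x for x in letters if letters.count(x) > 1}
        if dup:
            raise CatalogError(f"suffix letter bound to more than one lesion: {sorted(dup)}")

    def __len__(self) -> int:
        return len(self._lesions)

    def __iter__(self) -> Iterator[LesionDef]:
        return iter(self._lesions)

    def __contains__(self, lesion_id: str) -> bool:
        return lesion_id in self._by_id

    def __getitem__(self, lesion_id: str) -> LesionDef:
        try:
            return self._by_id[lesion_id]
        except KeyError:
            raise KeyError(f"unknown lesion_id {lesion_id!r}") from None

    def get(self, lesion_id: str) -> Optional[LesionDef]:
        return self._by_id.get(lesion_id)

    def lesions_for(
        self,
        compartment: Optional[Compartment] = None,
        category: Optional[Category] = None,
    ) -> tuple[LesionDef, ...]:
        """Catalog subset for one (compartment, category) cell.

        Either filter may be ``None`` to select a whole row or column of
        the partition; the union over all 25 cells is the full catalog.
        """
        return tuple(
            l
            for l in self._lesions
            if (compartment is None or l.compartment is compartment)
            and (category is None or l.category is category)
        )

    @property
    def letter_lesions(self) -> tuple[LesionDef, ...]:
        """The ten suffix-letter-bearing lesions in canonical letter order."""
        with_letters = [l for l in self._lesions if l.other_letter]
        return tuple(sorted(with_letters, key=lambda l: OTHER_LETTER_ORDER.index(l.other_letter)))

    @property
    def mvm_scoring_lesions(self) -> tuple[LesionDef, ...]:
        return tuple(l for l in self._lesions if l.mvm_points > 0)


_REQUIRED_COLUMNS = [
    "lesion_id",
    "display_name",
    "compartment",
    "category",
    "mvm_points",
    "other_letter",
    "exclusivity_group",
]


def _default_catalog_path() -> Path:
    return Path(str(importlib.resources.files("placenta_ssr"))) / "data" / "lesion_catalog.csv"


def load_catalog(source: Union[str, Path, None] = None) -> LesionCatalog:
    """Load a lesion catalog from CSV (the bundled default if ``source`` is None).

    The file may begin with ``#`` comment lines; a ``# catalog_version=...``
    comment sets the catalog version string.  Raises :class:`CatalogError`
    naming the offending line on malformed rows or duplicate ids.
    """
    path = Path(source) if source is not None else _default_catalog_path()
    version = "unversioned"
    lesions: list[LesionDef] = []
    with open(path, newline="", encoding="utf-8") as fh:
        # peel leading comment lines (line numbers are kept 1-based for errors)
        rows: list[tuple[int, str]] = []
        for lineno, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if body.startswith("catalog_version="):
                    version = body.split("=", 1)[1].strip()
                continue
            if stripped:
                rows.append((lineno, raw))
    if not rows:
        raise CatalogError(f"{path}: no catalog rows found")
    header_line, header_raw = rows[0]
    header = next(csv.reader([header_raw]))
    if header != _REQUIRED_COLUMNS:
        raise CatalogError(
            f"{path}:{header_line}: expected columns {_REQUIRED_COLUMNS}, got {header}"
        )
    for lineno, raw in rows[1:]:
        fields = next(csv.reader([raw]))
        if len(fields) != len(_REQUIRED_COLUMNS):
            raise CatalogError(f"{path}:{lineno}: expected {len(_REQUIRED_COLUMNS)} fields")
        rec = dict(zip(_REQUIRED_COLUMNS, (f.strip() for f in fields)))
        try:
            lesion = LesionDef(
                lesion_id=rec["lesion_id"],
                display_name=rec["display_name"],
                compartment=Compartment(rec["compartment"]),
                category=Category(rec["category"]),
                mvm_points=int(rec["mvm_points"] or 0),
                other_letter=rec["other_letter"] or None,
                exclusivity_group=rec["exclusivity_group"] or None,
            )
        except (ValueError, KeyError) as exc:
            raise CatalogError(f"{path}:{lineno}: {exc}") from exc
        if lesion.lesion_id in {l.lesion_id for l in lesions}:
            raise CatalogError(f"{path}:{lineno}: duplicate lesion_id {lesion.lesion_id!r}")
        lesions.append(lesion)
    return LesionCatalog(lesions, version=version)
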