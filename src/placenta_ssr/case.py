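"""Structured placental case records.

A :class:`CaseRecord` mirrors the tabs of a structured placental report:
demographics (with cross-accession linkage for multiple births),
macroscopy (gross measurements) and microscopy (per-compartment lesion
selections from the controlled catalog plus the discrete counts the
grading rules need).  Records serialise to JSON (canonical) or YAML and
round-trip losslessly.

Structural validity (types, ranges, required identity fields) is enforced
at parse time by pydantic; completeness of core items and cross-field
consistency are checked by :func:`validate_case`, which returns issues
rather than raising so a partially-filled case can be inspected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .catalog import Category, Compartment, LesionCatalog
from .config import SsrConfig

__all__ = [
    "FetusStatus",
    "Completeness",
    "Shape",
    "CordInsertion",
    "Septum",
    "AnastomosisKind",
    "Anastomosis",
    "MultiGestation",
    "Demographics",
    "Macroscopy",
    "Finding",
    "Microscopy",
    "CaseRecord",
    "ValidationIssue",
    "CaseParseError",
    "validate_case",
    "read_case",
    "write_case",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1.0"


class FetusStatus(str, Enum):
    LIVEBORN = "liveborn"
    STILLBORN = "stillborn"


class Completeness(str, Enum):
    COMPLETE = "complete"
    INCOMPLETE = "incomplete"
    FRAGMENTED = "fragmented"


class Shape(str, Enum):
    DISCOID = "discoid"
    BILOBED = "bilobed"
    SUCCENTURIATE = "succenturiate"
    MEMBRANACEA = "membranacea"
    OTHER = "other"


class CordInsertion(str, Enum):
    CENTRAL = "central"
    ECCENTRIC = "eccentric"
    MARGINAL = "marginal"
    VELAMENTOUS = "velamentous"
    FURCATE = "furcate"


class Septum(str, Enum):
    PRESENT_DICHORIONIC = "present_dichorionic"
    PRESENT_DIAMNIOTIC = "present_diamniotic"
    ABSENT = "absent"


class AnastomosisKind(str, Enum):
    ARTERIO_ARTERIAL = "arterio_arterial"
    VENO_VENOUS = "veno_venous"
    ARTERIO_VENOUS = "arterio_venous"


class Anastomosis(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: AnastomosisKind
    note: str = ""


class MultiGestation(BaseModel):
    """Shared-placenta details recorded for twin (and higher) gestations."""

    model_config = ConfigDict(extra="forbid")
    septum: Septum
    estimated_share_percent: float = Field(gt=0, lt=100)
    anastomoses: list[Anastomosis] = Field(default_factory=list)


class Demographics(BaseModel):
    model_config = ConfigDict(extra="forbid")
    accession: str = Field(min_length=1)
    linked_accessions: list[str] = Field(default_factory=list)
    study_code: Optional[str] = None
    date_of_birth: Optional[date] = None
    gestational_age_weeks: float = Field(ge=4, le=45)
    fetus_count: int = Field(default=1, ge=1)
    fetus_status: list[FetusStatus] = Field(default_factory=list)

    @field_validator("linked_accessions")
    @classmethod
    def _no_self_link(cls, v: list[str], info) -> list[str]:
        accession = info.data.get("accession")
        if accession is not None and accession in v:
            raise ValueError("linked_accessions must not contain the case's own accession")
        return v


class Macroscopy(BaseModel):
    """Gross examination.  Measurement fields are ``None`` when not recorded;
    completeness of core measurements is judged by :func:`validate_case`,
    not at parse time."""

    model_config = ConfigDict(extra="forbid")
    trimmed: Optional[bool] = None
    weight_g: Optional[float] = Field(default=None, gt=0)
    completeness: Optional[Completeness] = None
    shape: Optional[Shape] = None
    cord_length_cm: Optional[float] = Field(default=None, ge=0)
    cord_coil_count: Optional[int] = Field(default=None, ge=0)
    cord_diameter_mm: Optional[float] = Field(default=None, gt=0)
    cord_insertion: Optional[CordInsertion] = None
    multi: Optional[MultiGestation] = None


class Finding(BaseModel):
    """One recorded microscopic lesion, referenced by catalog key."""

    model_config = ConfigDict(extra="forbid")
    lesion_id: str = Field(min_length=1)
    compartment: Compartment
    note: Optional[str] = None


class Microscopy(BaseModel):
    model_config = ConfigDict(extra="forbid")
    findings: list[Finding] = Field(default_factory=list)
    #: Amsterdam maternal/fetal acute-inflammation stages (0 = absent).
    ai_maternal_stage: int = Field(default=0, ge=0, le=3)
    ai_fetal_stage: int = Field(default=0, ge=0, le=3)
    #: Discrete counts feeding the high-grade FVM criterion.
    avascular_villi_focus_count: int = Field(default=0, ge=0)
    avascular_villi_max_focus_size: int = Field(default=0, ge=0)
    fvm_thrombus_count: int = Field(default=0, ge=0)


class CaseRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")
    demographics: Demographics
    macroscopy: Macroscopy = Field(default_factory=Macroscopy)
    microscopy: Microscopy = Field(default_factory=Microscopy)
    schema_version: str = SCHEMA_VERSION


@dataclass(frozen=True)
class ValidationIssue:
    path: str
    severity: str  # "error" | "warning"
    message: str

    def __str__(self) -> str:  # pragma: no cover - display convenience
        return f"[{self.severity}] {self.path}: {self.message}"


class CaseParseError(ValueError):
    """Schema violation while reading a case file; carries field paths."""

    def __init__(self, message: str, paths: Optional[list[str]] = None):
        super().__init__(message)
        self.paths = paths or []


def _get_path(case: CaseRecord, dotted: str):
    obj = case
    for part in dotted.split("."):
        obj = getattr(obj, part, None)
        if obj is None:
            return None
    return obj


_NONCORE_ITEMS = [
    "demographics.study_code",
    "demographics.date_of_birth",
]


def validate_case(
    case: CaseRecord,
    catalog: LesionCatalog,
    level: str = "core",
    config: Optional[SsrConfig] = None,
) -> list[ValidationIssue]:
    """Check completeness of core items and internal consistency.

    Returns a (possibly empty) list of :class:`ValidationIssue`; never
    raises and never mutates the case.  ``level="core"`` checks the
    mandatory items from the configured core profile plus consistency
    rules; ``level="full"`` additionally flags absent optional items as
    warnings.
    """
    if level not in ("core", "full"):
        raise ValueError(f"level must be 'core' or 'full', got {level!r}")
    cfg = config or SsrConfig()
    issues: list[ValidationIssue] = []

    # --- core completeness -------------------------------------------------
    for dotted in cfg.core_items:
        value = _get_path(case, dotted)
        missing = value is None or (dotted.endswith("fetus_status") and value == [])
        if missing:
            issues.append(ValidationIssue(dotted, "error", "core item not recorded"))

    demo, macro, micro = case.demographics, case.macroscopy, case.microscopy

    # --- cross-field consistency ------------------------------------------
    if demo.fetus_status and len(demo.fetus_status) != demo.fetus_count:
        issues.append(
            ValidationIssue(
                "demographics.fetus_status",
                "error",
                f"{len(demo.fetus_status)} statuses recorded for fetus_count={demo.fetus_count}",
            )
        )
    if demo.fetus_count >= 2 and macro.multi is None:
        issues.append(
            ValidationIssue(
                "macroscopy.multi",
                "error",
                "multiple gestation details required when fetus_count >= 2",
            )
        )
    if demo.fetus_count == 1 and macro.multi is not None:
        issues.append(
            ValidationIssue(
                "macroscopy.multi",
                "error",
                "multiple gestation details forbidden for a singleton",
            )
        )
    if macro.cord_coil_count == 0 and macro.cord_length_cm is None:
        issues.append(
            ValidationIssue(
                "macroscopy.cord_coil_count",
                "error",
                "a coil count of 0 requires the cord length to be recorded",
            )
        )

    # --- microscopy vs catalog --------------------------------------------
    seen_groups: dict[str, str] = {}
    acute_lesion_present = False
    fvm_lesion_present = False
    for i, finding in enumerate(micro.findings):
        path = f"microscopy.findings[{i}]"
        lesion = catalog.get(finding.lesion_id)
        if lesion is None:
            issues.append(
                ValidationIssue(path, "error", f"unknown lesion_id {finding.lesion_id!r}")
            )
            continue
        if lesion.compartment is not finding.compartment:
            issues.append(
                ValidationIssue(
                    path,
                    "error",
                    f"compartment {finding.compartment.value} does not match catalog "
                    f"({lesion.compartment.value}) for {finding.lesion_id}",
                )
            )
        if lesion.exclusivity_group:
            other = seen_groups.get(lesion.exclusivity_group)
            if other is not None and other != lesion.lesion_id:
                issues.append(
                    ValidationIssue(
                        path,
                        "error",
                        f"{lesion.lesion_id} and {other} are mutually exclusive "
                        f"(group {lesion.exclusivity_group})",
                    )
                )
            else:
                seen_groups[lesion.exclusivity_group] = lesion.lesion_id
        if lesion.category is Category.ACUTE_INFLAMMATION:
            acute_lesion_present = True
        if lesion.category is Category.FVM:
            fvm_lesion_present = True

    if (micro.ai_maternal_stage > 0 or micro.ai_fetal_stage > 0) and not acute_lesion_present:
        issues.append(
            ValidationIssue(
                "microscopy.ai_maternal_stage",
                "error",
                "acute-inflammation stage recorded without any acute-inflammation lesion",
            )
        )
    if micro.fvm_thrombus_count > 0 and not fvm_lesion_present:
        issues.append(
            ValidationIssue(
                "microscopy.fvm_thrombus_count",
                "warning",
                "thrombus count recorded without an accompanying FVM lesion",
            )
        )

    # --- optional detail (full depth only) ---------------------------------
    if level == "full":
        for dotted in _NONCORE_ITEMS:
            if _get_path(case, dotted) is None:
                issues.append(ValidationIssue(dotted, "warning", "optional item not recorded"))

    return issues


def _format_pydantic_error(exc: ValidationError) -> CaseParseError:
    paths = []
    parts = []
    for err in exc.errors():
        dotted = ".".join(str(p) for p in err["loc"])
        paths.append(dotted)
        parts.append(f"{dotted}: {err['msg']}")
    return CaseParseError("; ".join(parts), paths=paths)


def read_case(path: Union[str, Path]) -> CaseRecord:
    """Read a case from JSON (``.json``) or YAML (``.yaml``/``.yml``)."""
    p = Path(path)
    text = p.read_text(encoding="utf-8")
    if p.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    try:
        return CaseRecord.model_validate(data)
    except ValidationError as exc:
        raise _format_pydantic_error(exc) from exc


def write_case(case: CaseRecord, path: Union[str, Path]) -> None:
    """Write a case as JSON or YAML depending on the file suffix."""
    p = Path(path)
    data = case.model_dump(mode="json", exclude_none=True)
    if p.suffix.lower() in (".yaml", ".yml"):
        p.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
    else:
        p.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
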