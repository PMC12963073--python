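"""The four-pattern lesion grading engine.

Each placenta receives a grade in {none, low, high} for the four injury
patterns, computed — never entered by hand — from the recorded findings:

* **Acute inflammation**: high when the maximum of the maternal and
  fetal Amsterdam stages reaches the configured high-stage threshold
  (default stage 2 of 1-3); low when any acute-inflammation lesion is
  recorded below that; none otherwise.
* **Chronic inflammation**: graded by the number of *distinct* anatomical
  compartments containing at least one chronic-inflammation lesion:
  >= 2 compartments high, 1 low, 0 none.
* **Fetal vascular malperfusion (FVM)**: high on more than one focus of
  avascular villi (foci of >= 45 villi) or >= 2 occlusive/nonocclusive
  thrombi in the chorionic plate or stem villi; low for any other fetal
  vascular lesion; none otherwise.
* **Maternal vascular malperfusion (MVM)**: a point score summed over
  the recorded MVM-scoring lesions (1 or 2 points each, from the
  catalog); score >= 4 high, 2-3 low, 0-1 none.  Low placental
  weight/hypoplasia (trimmed weight strictly below the 10th percentile
  for gestation) contributes its 2 points only in the presence of at
  least one other MVM-scoring lesion; isolated hypoplasia is not scored.

"Other significant pathology" lesions are not graded; their suffix
letters are collected in canonical order h,i,j,k,s,n,o,p,q,r.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .case import CaseRecord, Microscopy, validate_case
from .catalog import Category, LesionCatalog, LesionDef, OTHER_LETTER_ORDER
from .config import SsrConfig
from .macro import PercentileAssessment, ReferenceTable, assess_against_reference

__all__ = [
    "Grade",
    "GradeSet",
    "CaseValidationError",
    "HYPOPLASIA_LESION_ID",
    "grade_acute",
    "grade_chronic",
    "grade_fvm",
    "score_mvm",
    "mvm_grade_from_score",
    "chronic_grade_from_count",
    "collect_other_letters",
    "grade_case",
]

#: Catalog key of the low-placental-weight/hypoplasia entry; its point
#: value lives in the catalog, its presence is derived from the weight
#: percentile assessment (or an explicit finding).
HYPOPLASIA_LESION_ID = "placental_hypoplasia"


class Grade(str, Enum):
    """Severity grade with the total order none < low < high."""

    NONE = "none"
    LOW = "low"
    HIGH = "high"

    @property
    def rank(self) -> int:
        return ("none", "low", "high").index(self.value)

    def __lt__(self, other: "Grade") -> bool:  # type: ignore[override]
        return self.rank < other.rank

    def __le__(self, other: "Grade") -> bool:  # type: ignore[override]
        return self.rank <= other.rank


@dataclass(frozen=True)
class GradeSet:
    """The computed grades for one case."""

    acute: Grade
    chronic: Grade
    fvm: Grade
    mvm: Grade
    mvm_score: int = 0
    chronic_compartment_count: int = 0
    other_letters: tuple[str, ...] = field(default_factory=tuple)

    @property
    def levels(self) -> tuple[Grade, Grade, Grade, Grade]:
        return (self.acute, self.chronic, self.fvm, self.mvm)


class CaseValidationError(ValueError):
    """Raised by :func:`grade_case` when the case fails core validation."""

    def __init__(self, issues):
        self.issues = list(issues)
        super().__init__(
            "case failed core validation: " + "; ".join(str(i) for i in self.issues)
        )


def _recorded(microscopy: Microscopy, catalog: LesionCatalog) -> list[LesionDef]:
    """Distinct catalog entries recorded in the case (duplicates collapse)."""
    seen: dict[str, LesionDef] = {}
    for f in microscopy.findings:
        lesion = catalog.get(f.lesion_id)
        if lesion is not None:
            seen.setdefault(lesion.lesion_id, lesion)
    return list(seen.values())


def grade_acute(
    microscopy: Microscopy, catalog: LesionCatalog, config: Optional[SsrConfig] = None
) -> Grade:
    """Grade acute inflammation from the combined maternal/fetal stages."""
    cfg = config or SsrConfig()
    acute = [l for l in _recorded(microscopy, catalog) if l.category is Category.ACUTE_INFLAMMATION]
    if not acute:
        return Grade.NONE
    if max(microscopy.ai_maternal_stage, microscopy.ai_fetal_stage) >= cfg.ai_high_stage_threshold:
        return Grade.HIGH
    return Grade.LOW


def chronic_grade_from_count(count: int, config: Optional[SsrConfig] = None) -> Grade:
    cfg = config or SsrConfig()
    if count >= cfg.ci_high_compartments:
        return Grade.HIGH
    return Grade.LOW if count >= 1 else Grade.NONE


def grade_chronic(
    microscopy: Microscopy, catalog: LesionCatalog, config: Optional[SsrConfig] = None
) -> tuple[Grade, int]:
    """Grade chronic inflammation by distinct involved compartments."""
    compartments = {
        l.compartment
        for l in _recorded(microscopy, catalog)
        if l.category is Category.CHRONIC_INFLAMMATION
    }
    count = len(compartments)
    return chronic_grade_from_count(count, config), count


def grade_fvm(
    microscopy: Microscopy, catalog: LesionCatalog, config: Optional[SsrConfig] = None
) -> Grade:
    """Grade fetal vascular malperfusion."""
    cfg = config or SsrConfig()
    high = (
        microscopy.avascular_villi_focus_count >= cfg.fvm_avascular_focus_high_count
        and microscopy.avascular_villi_max_focus_size >= cfg.avascular_focus_min_villi
    ) or microscopy.fvm_thrombus_count >= cfg.fvm_thrombus_high_count
    if high:
        return Grade.HIGH
    any_fvm = any(l.category is Category.FVM for l in _recorded(microscopy, catalog))
    return Grade.LOW if any_fvm else Grade.NONE


def mvm_grade_from_score(score: int, config: Optional[SsrConfig] = None) -> Grade:
    cfg = config or SsrConfig()
    if score >= cfg.mvm_high_cut:
        return Grade.HIGH
    return Grade.LOW if score >= cfg.mvm_low_cut else Grade.NONE


def score_mvm(
    microscopy: Microscopy,
    catalog: LesionCatalog,
    weight_assessment: Optional[PercentileAssessment] = None,
    config: Optional[SsrConfig] = None,
) -> tuple[int, Grade]:
    """Sum MVM points and map the score to a grade.

    Hypoplasia (trimmed weight < p10, or an explicit hypoplasia finding)
    contributes its catalog points only when at least one other
    MVM-scoring lesion is recorded.
    """
    recorded = _recorded(microscopy, catalog)
    base = sum(
        l.mvm_points for l in recorded if l.mvm_points > 0 and l.lesion_id != HYPOPLASIA_LESION_ID
    )
    hypoplasia_present = (weight_assessment is not None and weight_assessment.below_p10) or any(
        l.lesion_id == HYPOPLASIA_LESION_ID for l in recorded
    )
    score = base
    if hypoplasia_present and base > 0:
        hypo = catalog.get(HYPOPLASIA_LESION_ID)
        score += hypo.mvm_points if hypo is not None else 2
    return score, mvm_grade_from_score(score, config)


def collect_other_letters(microscopy: Microscopy, catalog: LesionCatalog) -> tuple[str, ...]:
    """Suffix letters of recorded other-pathology lesions, deduplicated,
    in canonical order."""
    letters = {
        l.other_letter for l in _recorded(microscopy, catalog) if l.other_letter is not None
    }
    return tuple(sorted(letters, key=OTHER_LETTER_ORDER.index))


def grade_case(
    case: CaseRecord,
    catalog: LesionCatalog,
    config: Optional[SsrConfig] = None,
    weight_reference: Optional[ReferenceTable] = None,
    validate: bool = True,
) -> GradeSet:
    """Compute the full :class:`GradeSet` for a validated case.

    The weight-percentile assessment feeding the hypoplasia rule is
    computed from macroscopy when a weight reference is supplied and the
    recorded weight is a trimmed weight; otherwise hypoplasia never
    contributes via the weight pathway.
    """
    cfg = config or SsrConfig()
    if validate:
        errors = [
            i for i in validate_case(case, catalog, level="core", config=cfg) if i.severity == "error"
        ]
        if errors:
            raise CaseValidationError(errors)

    weight_assessment: Optional[PercentileAssessment] = None
    macro = case.macroscopy
    if (
        weight_reference is not None
        and macro.weight_g is not None
        and macro.trimmed is True
    ):
        weight_assessment = assess_against_reference(
            macro.weight_g, case.demographics.gestational_age_weeks, weight_reference
        )

    micro = case.microscopy
    acute = grade_acute(micro, catalog, cfg)
    chronic, ci_count = grade_chronic(micro, catalog, cfg)
    fvm = grade_fvm(micro, catalog, cfg)
    mvm_score, mvm = score_mvm(micro, catalog, weight_assessment, cfg)
    letters = collect_other_letters(micro, catalog)
    return GradeSet(
        acute=acute,
        chronic=chronic,
        fvm=fvm,
        mvm=mvm,
        mvm_score=mvm_score,
        chronic_compartment_count=ci_count,
        other_letters=letters,
    )
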