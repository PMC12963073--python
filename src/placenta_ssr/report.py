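"""End-to-end case processing and synoptic report rendering.

``run_case`` reads a case, validates it, computes the macroscopic
calculations, the four pattern grades, the phenotype code and the
prognostic group, and returns an :class:`SsrResult` that serialises to a
stable JSON document; ``render_synoptic`` turns the same result into a
human-readable synoptic report in which every core item appears with its
value or an explicit "not recorded" marker.  Identical inputs and
configuration always produce byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from . import __version__
from .case import CaseRecord, ValidationIssue, read_case, validate_case
from .catalog import LesionCatalog, load_catalog
from .config import SsrConfig
from .grading import GradeSet, grade_case
from .macro import (
    PercentileAssessment,
    ReferenceTable,
    assess_against_reference,
    classify_coiling,
    coiling_index,
)
from .phenotype import GroupAssignment, PhenotypeCode, assign_group, build_code

__all__ = ["SsrResult", "process_case", "run_case", "run_batch", "render_synoptic"]

RESULT_SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class SsrResult:
    """Complete machine-readable outcome for one case."""

    accession: str
    issues: tuple[ValidationIssue, ...]
    coiling_index: Optional[float]
    coiling_class: Optional[str]
    weight_assessment: Optional[PercentileAssessment]
    cord_diameter_assessment: Optional[PercentileAssessment]
    grade_set: Optional[GradeSet]
    phenotype: Optional[PhenotypeCode]
    group: Optional[GroupAssignment]
    tool_version: str
    catalog_version: str
    config_digest: str

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def to_dict(self) -> dict:
        def _assessment(a: Optional[PercentileAssessment]):
            if a is None:
                return None
            return {
                "value": a.value,
                "ga_weeks": a.ga_weeks,
                "reference_week": a.reference_week,
                "band": a.band.value,
                "below_p10": a.below_p10,
                "deviation_from_p50": round(a.deviation_from_p50, 3),
            }

        gs = self.grade_set
        return {
            "result_schema_version": RESULT_SCHEMA_VERSION,
            "accession": self.accession,
            "ok": self.ok,
            "issues": [
                {"path": i.path, "severity": i.severity, "message": i.message}
                for i in self.issues
            ],
            "macro": {
                "coiling_index": self.coiling_index,
                "coiling_class": self.coiling_class,
                "weight": _assessment(self.weight_assessment),
                "cord_diameter": _assessment(self.cord_diameter_assessment),
            },
            "grades": None
            if gs is None
            else {
                "acute": gs.acute.value,
                "chronic": gs.chronic.value,
                "fvm": gs.fvm.value,
                "mvm": gs.mvm.value,
                "mvm_score": gs.mvm_score,
                "chronic_compartment_count": gs.chronic_compartment_count,
                "other_letters": list(gs.other_letters),
            },
            "phenotype": None
            if self.phenotype is None
            else {
                "core": self.phenotype.core,
                "suffix": self.phenotype.suffix,
                "full": self.phenotype.full,
            },
            "group": None
            if self.group is None
            else {"group_id": self.group.group_id, "rule_trace": self.group.rule_trace},
            "versions": {
                "tool": self.tool_version,
                "catalog": self.catalog_version,
                "config_digest": self.config_digest,
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def process_case(
    case: CaseRecord,
    catalog: Optional[LesionCatalog] = None,
    config: Optional[SsrConfig] = None,
    weight_reference: Optional[ReferenceTable] = None,
    cord_reference: Optional[ReferenceTable] = None,
) -> SsrResult:
    """Validate and fully process an in-memory case.

    When validation finds errors the grading/phenotype fields are left
    unset and the issues are reported; macroscopic calculations are
    still attempted on whatever measurements are present.
    """
    catalog = catalog or load_catalog()
    cfg = config or SsrConfig()
    issues = tuple(validate_case(case, catalog, level="core", config=cfg))
    macro = case.macroscopy
    ga = case.demographics.gestational_age_weeks

    ci = ci_class = None
    if macro.cord_coil_count is not None and macro.cord_length_cm and macro.cord_length_cm > 0:
        ci = coiling_index(macro.cord_coil_count, macro.cord_length_cm)
        ci_class = classify_coiling(ci, cfg)

    weight_assessment = None
    if weight_reference is not None and macro.weight_g is not None and macro.trimmed:
        weight_assessment = assess_against_reference(macro.weight_g, ga, weight_reference)
    cord_assessment = None
    if cord_reference is not None and macro.cord_diameter_mm is not None:
        cord_assessment = assess_against_reference(macro.cord_diameter_mm, ga, cord_reference)

    grade_set = phenotype = group = None
    if not any(i.severity == "error" for i in issues):
        grade_set = grade_case(
            case, catalog, cfg, weight_reference=weight_reference, validate=False
        )
        phenotype = build_code(grade_set)
        group = assign_group(grade_set)

    return SsrResult(
        accession=case.demographics.accession,
        issues=issues,
        coiling_index=ci,
        coiling_class=ci_class,
        weight_assessment=weight_assessment,
        cord_diameter_assessment=cord_assessment,
        grade_set=grade_set,
        phenotype=phenotype,
        group=group,
        tool_version=__version__,
        catalog_version=catalog.version,
        config_digest=cfg.digest(),
    )


def run_case(
    case_path: Union[str, Path],
    catalog: Optional[LesionCatalog] = None,
    config: Optional[SsrConfig] = None,
    weight_reference: Optional[ReferenceTable] = None,
    cord_reference: Optional[ReferenceTable] = None,
    out_dir: Union[str, Path, None] = None,
) -> SsrResult:
    """Process a case file; optionally write ``<stem>.result.json`` and a
    ``<stem>.synoptic.txt`` sidecar to ``out_dir``."""
    case = read_case(case_path)
    result = process_case(case, catalog, config, weight_reference, cord_reference)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = Path(case_path).stem
        (out / f"{stem}.result.json").write_text(result.to_json(), encoding="utf-8")
        (out / f"{stem}.synoptic.txt").write_text(
            render_synoptic(result, case), encoding="utf-8"
        )
    return result


def run_batch(
    case_paths: list[Union[str, Path]],
    catalog: Optional[LesionCatalog] = None,
    config: Optional[SsrConfig] = None,
    weight_reference: Optional[ReferenceTable] = None,
    cord_reference: Optional[ReferenceTable] = None,
    out_dir: Union[str, Path, None] = None,
) -> tuple[list[SsrResult], list[tuple[str, str]], dict[str, int]]:
    """Process many cases, isolating per-case failures.

    Returns (results, failures, group_counts) where failures are
    (path, message) pairs for unreadable/unparseable files and
    group_counts tallies assigned groups over successful cases.
    """
    if not case_paths:
        raise ValueError("run_batch requires at least one case")
    results: list[SsrResult] = []
    failures: list[tuple[str, str]] = []
    counts: dict[str, int] = {}
    for path in case_paths:
        try:
            result = run_case(path, catalog, config, weight_reference, cord_reference, out_dir)
        except Exception as exc:  # noqa: BLE001 - per-case isolation is the contract
            failures.append((str(path), str(exc)))
            continue
        results.append(result)
        if result.group is not None:
            counts[result.group.group_id] = counts.get(result.group.group_id, 0) + 1
    return results, failures, counts


def _fmt(value, unit: str = "") -> str:
    if value is None:
        return "not recorded"
    if hasattr(value, "value"):
        value = value.value
    return f"{value}{unit}"


def render_synoptic(result: SsrResult, case: CaseRecord) -> str:
    """Render the human-readable synoptic report for one processed case."""
    d, m = case.demographics, case.macroscopy
    lines = [
        "PLACENTAL PATHOLOGY - SYNOPTIC REPORT",
        "=" * 46,
        f"Accession:              {d.accession}",
        f"Linked accessions:      {', '.join(d.linked_accessions) or 'none'}",
        f"Gestational age:        {_fmt(d.gestational_age_weeks, ' weeks')}",
        f"Fetus count:            {_fmt(d.fetus_count)}",
        f"Fetus status:           {', '.join(s.value for s in d.fetus_status) or 'not recorded'}",
        "",
        "MACROSCOPY",
        f"  Weight:               {_fmt(m.weight_g, ' g')}"
        + (" (trimmed)" if m.trimmed else " (untrimmed)" if m.trimmed is False else ""),
        f"  Completeness:         {_fmt(m.completeness)}",
        f"  Shape:                {_fmt(m.shape)}",
        f"  Cord length:          {_fmt(m.cord_length_cm, ' cm')}",
        f"  Cord coil count:      {_fmt(m.cord_coil_count)}",
        f"  Cord diameter:        {_fmt(m.cord_diameter_mm, ' mm')}",
        f"  Cord insertion:       {_fmt(m.cord_insertion)}",
        f"  Coiling index:        {_fmt(result.coiling_index, ' coils/cm')}"
        + (f" ({result.coiling_class})" if result.coiling_class else ""),
    ]
    if result.weight_assessment is not None:
        a = result.weight_assessment
        lines.append(
            f"  Weight percentile:    band {a.band.value}"
            f" (reference week {a.reference_week}; p50 {a.value - a.deviation_from_p50:.0f} g;"
            f" deviation {a.deviation_from_p50:+.1f} g)"
        )
    if result.cord_diameter_assessment is not None:
        a = result.cord_diameter_assessment
        lines.append(f"  Cord diameter band:   {a.band.value} (reference week {a.reference_week})")
    if m.multi is not None:
        lines += [
            "  Multiple gestation:",
            f"    Septum:             {m.multi.septum.value}",
            f"    Estimated share:    {m.multi.estimated_share_percent}%",
            f"    Anastomoses:        {', '.join(a.kind.value for a in m.multi.anastomoses) or 'none'}",
        ]
    lines += ["", "MICROSCOPY"]
    if case.microscopy.findings:
        for f in case.microscopy.findings:
            lines.append(f"  - {f.lesion_id} [{f.compartment.value}]")
    else:
        lines.append("  No lesions recorded")
    gs = result.grade_set
    if gs is not None and result.phenotype is not None and result.group is not None:
        lines += [
            "",
            "GRADING (computed)",
            f"  Acute inflammation:   {gs.acute.value}",
            f"  Chronic inflammation: {gs.chronic.value}"
            f" ({gs.chronic_compartment_count} compartment(s))",
            f"  Fetal vasc. malperf.: {gs.fvm.value}",
            f"  Maternal vasc. malp.: {gs.mvm.value} (score {gs.mvm_score})",
            f"  Other pathology:      {''.join(gs.other_letters) or 'none'}",
            "",
            "PHENOTYPE AND GROUP",
            f"  Phenotype code:       {result.phenotype.full or '(none)'}",
            f"  Group:                {result.group.group_id} [{result.group.rule_trace}]",
        ]
    if result.issues:
        lines += ["", "VALIDATION"]
        lines += [f"  {i}" for i in result.issues]
    lines += [
        "",
        "Comment/conclusion:     (not auto-populated)",
        f"Tool {result.tool_version} | catalog {result.catalog_version}"
        f" | config {result.config_digest}",
        "",
    ]
    return "\n".join(lines)
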