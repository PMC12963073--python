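"""Deterministic synthetic case generator.

Builds valid (and deliberately invalid) case records for tests, demos
and the exhaustive 81-combination enumeration suite.  Construction is
*minimal*: each target grade is achieved with the smallest lesion set
that satisfies its rule (e.g. high-grade chronic inflammation = chronic
lesions in exactly two compartments), so the generated suite probes both
sensitivity and specificity of the grading rules.  A noisy mode adds
grade-neutral other-pathology findings that carry no suffix letter.

The generator emulates report *structure*, not lesion epidemiology:
gestational ages and gross measurements are drawn uniformly from
plausible third-trimester ranges and lesion co-occurrence is dictated by
the requested target, not by clinical prevalence.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from .case import (
    CaseRecord,
    Completeness,
    CordInsertion,
    Demographics,
    FetusStatus,
    Finding,
    Macroscopy,
    Microscopy,
    MultiGestation,
    Septum,
    Shape,
)
from .catalog import LesionCatalog, load_catalog
from .grading import Grade

__all__ = ["FixtureProfile", "FixtureError", "make_case", "enumeration_suite", "GRADE_TRIPLETS"]

GRADE_TRIPLETS = (Grade.NONE, Grade.LOW, Grade.HIGH)

#: Minimal lesion recipes per (pattern, grade).  Chosen to be disjoint in
#: grading effect: none of these lesions carries MVM points outside the
#: mvm recipes, a suffix letter, or a second pattern's category.
_ACUTE_LOW = [("acute_chorioamnionitis", "membranes")]
_ACUTE_HIGH = [("necrotizing_acute_chorioamnionitis", "membranes")]
_CHRONIC_LOW = [("chronic_deciduitis", "basal_plate")]
_CHRONIC_HIGH = [
    ("chronic_deciduitis", "basal_plate"),
    ("chronic_villitis", "villous_intervillous"),
]
_FVM_LOW = [("umbilical_vein_thrombus", "umbilical_cord")]
_FVM_HIGH = [("fetal_vascular_thrombi", "chorionic_plate")]
_MVM_LOW = [
    ("distal_villous_hypoplasia", "villous_intervillous"),
    ("villous_agglutination", "villous_intervillous"),
]
_MVM_HIGH = _MVM_LOW + [
    ("fibrinoid_necrosis_acute_atherosis", "basal_plate"),
    ("accelerated_villous_maturation", "villous_intervillous"),
]
#: Grade-neutral noise: other-pathology lesions without suffix letters
#: or MVM points.
_NOISE = [
    ("intervillous_thrombus", "villous_intervillous"),
    ("meconium_laden_macrophages", "membranes"),
    ("chorion_nodosum", "chorionic_plate"),
]


class FixtureError(ValueError):
    """Unsatisfiable or malformed fixture profile."""


@dataclass(frozen=True)
class FixtureProfile:
    """Recipe for one synthetic case.

    ``target`` is a (acute, chronic, fvm, mvm) grade tuple; ``letters``
    requests other-pathology suffix letters; ``invalidity`` produces a
    case failing validation with exactly that issue class.
    """

    seed: int = 0
    target: Optional[tuple[Grade, Grade, Grade, Grade]] = None
    letters: tuple[str, ...] = field(default_factory=tuple)
    invalidity: Optional[str] = None  # missing_core | exclusivity_violation | multi_mismatch
    noisy: bool = False
    twin: bool = False


def _rng_for(profile: FixtureProfile) -> random.Random:
    target = profile.target or (Grade.NONE,) * 4
    key = (
        f"{profile.seed}|{'/'.join(g.value for g in target)}|{''.join(profile.letters)}"
        f"|{profile.invalidity}|{profile.noisy}|{profile.twin}"
    )
    return random.Random(key)


def make_case(profile: FixtureProfile, catalog: Optional[LesionCatalog] = None) -> CaseRecord:
    """Generate one case; identical profile (incl. seed) → identical case."""
    catalog = catalog or load_catalog()
    if profile.invalidity not in (None, "missing_core", "exclusivity_violation", "multi_mismatch"):
        raise FixtureError(f"unknown invalidity class {profile.invalidity!r}")
    rng = _rng_for(profile)
    target = profile.target or (Grade.NONE, Grade.NONE, Grade.NONE, Grade.NONE)
    acute, chronic, fvm, mvm = target

    letter_map = {l.other_letter: l for l in catalog.letter_lesions}
    for letter in profile.letters:
        if letter not in letter_map:
            raise FixtureError(f"unknown suffix letter {letter!r}")
    groups = [
        letter_map[l].exclusivity_group
        for l in profile.letters
        if letter_map[l].exclusivity_group
    ]
    if len(groups) != len(set(groups)):
        raise FixtureError("requested letters include mutually exclusive lesions")

    findings: list[Finding] = []
    micro_kwargs = dict(
        ai_maternal_stage=0,
        ai_fetal_stage=0,
        avascular_villi_focus_count=0,
        avascular_villi_max_focus_size=0,
        fvm_thrombus_count=0,
    )

    def add(recipe: list[tuple[str, str]]) -> None:
        for lesion_id, _ in recipe:
            lesion = catalog[lesion_id]
            findings.append(Finding(lesion_id=lesion_id, compartment=lesion.compartment))

    if acute is not Grade.NONE:
        add(_ACUTE_LOW if acute is Grade.LOW else _ACUTE_HIGH)
        micro_kwargs["ai_maternal_stage"] = 1 if acute is Grade.LOW else 3
    if chronic is not Grade.NONE:
        add(_CHRONIC_LOW if chronic is Grade.LOW else _CHRONIC_HIGH)
    if fvm is not Grade.NONE:
        if fvm is Grade.LOW:
            add(_FVM_LOW)
            micro_kwargs["fvm_thrombus_count"] = 1
        else:
            add(_FVM_HIGH)
            micro_kwargs["fvm_thrombus_count"] = 2
    if mvm is not Grade.NONE:
        add(_MVM_LOW if mvm is Grade.LOW else _MVM_HIGH)
    for letter in profile.letters:
        lesion = letter_map[letter]
        findings.append(Finding(lesion_id=lesion.lesion_id, compartment=lesion.compartment))
    if profile.noisy:
        add(rng.sample(_NOISE, k=rng.randint(1, len(_NOISE))))
    if profile.invalidity == "exclusivity_violation":
        add([("single_infarct", ""), ("multiple_infarcts", "")])

    ga = round(rng.uniform(34.0, 41.5), 1)
    # weight drawn around the bundled synthetic p50 so a generated case is
    # never incidentally below the 10th percentile (hypoplasia is opted
    # into by targets, not by chance)
    p50 = 100 + 25 * (int(round(ga)) - 20)
    weight = round(p50 * rng.uniform(0.9, 1.2))
    cord_length = round(rng.uniform(40.0, 70.0), 1)
    coils = rng.randint(3, 18)
    diameter = round(rng.uniform(9.0, 15.0), 1)

    fetus_count = 2 if profile.twin or profile.invalidity == "multi_mismatch" else 1
    multi = None
    if fetus_count >= 2 and profile.invalidity != "multi_mismatch":
        multi = MultiGestation(
            septum=Septum.PRESENT_DIAMNIOTIC,
            estimated_share_percent=round(rng.uniform(35, 65), 1),
            anastomoses=[],
        )

    macro = Macroscopy(
        trimmed=True,
        weight_g=None if profile.invalidity == "missing_core" else weight,
        completeness=Completeness.COMPLETE,
        shape=Shape.DISCOID,
        cord_length_cm=cord_length,
        cord_coil_count=coils,
        cord_diameter_mm=diameter,
        cord_insertion=CordInsertion.ECCENTRIC,
        multi=multi,
    )
    accession = f"SSR-{profile.seed}-{rng.randrange(10**6):06d}"
    demo = Demographics(
        accession=accession,
        linked_accessions=[f"{accession}-B"] if fetus_count >= 2 else [],
        gestational_age_weeks=ga,
        fetus_count=fetus_count,
        fetus_status=[FetusStatus.LIVEBORN] * fetus_count,
    )
    return CaseRecord(
        demographics=demo,
        macroscopy=macro,
        microscopy=Microscopy(findings=findings, **micro_kwargs),
    )


def enumeration_suite(seed: int = 0, catalog: Optional[LesionCatalog] = None) -> list[CaseRecord]:
    """One valid case per (A, C, F, M) grade combination — 81 in all,
    in deterministic lexicographic order none < low < high."""
    catalog = catalog or load_catalog()
    cases = []
    for a in GRADE_TRIPLETS:
        for c in GRADE_TRIPLETS:
            for f in GRADE_TRIPLETS:
                for m in GRADE_TRIPLETS:
                    cases.append(
                        make_case(FixtureProfile(seed=seed, target=(a, c, f, m)), catalog)
                    )
    return cases
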