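"""Freedman-Ernst phenotype codes and prognostic group assignment.

The four pattern grades are encoded as a letter string in fixed order
A/a (acute inflammation), C/c (chronic inflammation), F/f (fetal
vascular malperfusion), M/m (maternal vascular malperfusion): a letter
is present iff its grade is not none and uppercase iff the grade is
high, so e.g. low-grade acute + high-grade chronic/fetal/maternal gives
"aCFM".  Suffix letters for ungraded other pathology (h..r) follow the
core code.

Group assignment is a first-match decision tree over the grade levels,
from combined high-grade patterns (group 1, the "triple threat" 1a)
down through isolated high grades, low-grade combinations, isolated
acute inflammation (9a/9b), other pathology only (8) and histologically
normal (10).  The tree is total and unambiguous over all 3^4 = 81 grade
combinations, which :func:`enumerate_all_codes` makes explicit.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict

from .grading import Grade, GradeSet

__all__ = ["PhenotypeCode", "GroupAssignment", "GROUP_IDS", "build_code", "assign_group", "enumerate_all_codes"]

GROUP_IDS = (
    "1a", "1b", "1c", "1d", "2", "3a", "3b", "4a", "4b", "4c", "4d",
    "5", "6a", "6b", "7a", "7b", "7c", "8", "9a", "9b", "10",
)

_CATEGORY_LETTERS = (("acute", "a"), ("chronic", "c"), ("fvm", "f"), ("mvm", "m"))


@dataclass(frozen=True)
class PhenotypeCode:
    """Canonical letter code: core pattern letters plus other-pathology suffix."""

    core: str
    suffix: str = ""

    @property
    def full(self) -> str:
        return self.core + self.suffix

    def __str__(self) -> str:  # pragma: no cover - display convenience
        return self.full or "(none)"


@dataclass(frozen=True)
class GroupAssignment:
    group_id: str
    rule_trace: str


def build_code(grades: GradeSet) -> PhenotypeCode:
    """Assemble the phenotype code from a grade set."""
    core = ""
    for attr, letter in _CATEGORY_LETTERS:
        g: Grade = getattr(grades, attr)
        if g is Grade.HIGH:
            core += letter.upper()
        elif g is Grade.LOW:
            core += letter
    return PhenotypeCode(core=core, suffix="".join(grades.other_letters))


def _assign(a: Grade, c: Grade, f: Grade, m: Grade, has_letters: bool) -> GroupAssignment:
    HIGH, LOW, NONE = Grade.HIGH, Grade.LOW, Grade.NONE

    if c is HIGH and f is HIGH and m is HIGH:
        return GroupAssignment("1a", "C,F,M all high (triple threat)")
    if f is HIGH and m is HIGH:
        return GroupAssignment("1b", "F and M high")
    if c is HIGH and m is HIGH:
        return GroupAssignment("1c", "C and M high")
    if c is HIGH and f is HIGH:
        if a is HIGH:
            return GroupAssignment("2", "A and F high (with high C)")
        return GroupAssignment("1d", "C and F high")
    if f is HIGH:
        if a is HIGH:
            return GroupAssignment("2", "A and F high")
        if c is LOW or m is LOW:
            return GroupAssignment("3b", "F high with low c and/or m")
        return GroupAssignment("3a", "F high alone (± low a)")
    if c is HIGH:
        any_acute = a is not NONE
        if any_acute and m is LOW:
            return GroupAssignment("4d", "C high with acute and low m")
        if m is LOW:
            return GroupAssignment("4c", "C high with low m")
        if any_acute:
            return GroupAssignment("4b", "C high with acute")
        return GroupAssignment("4a", "C high (± low f)")
    if m is HIGH:
        return GroupAssignment("5", "M high (± acute and other low-grade)")
    # no high among C/F/M from here on
    low_cf = (c is LOW) + (f is LOW)
    if m is NONE and low_cf == 1:
        if a is HIGH:
            return GroupAssignment("6b", "single low c or f with high A")
        return GroupAssignment("6a", "single low c or f (± low a)")
    if m is LOW or low_cf == 2:
        if a is HIGH:
            return GroupAssignment("7c", "low m and/or c+f with high A")
        if a is LOW:
            return GroupAssignment("7b", "low m and/or c+f with low a")
        return GroupAssignment("7a", "low m and/or c+f without acute")
    # c, f, m all none
    if a is HIGH:
        return GroupAssignment("9a", "high-grade acute inflammation alone")
    if a is LOW:
        return GroupAssignment("9b", "low-grade acute inflammation alone")
    if has_letters:
        return GroupAssignment("8", "other significant pathology only")
    return GroupAssignment("10", "histologically normal")


def assign_group(grades: GradeSet) -> GroupAssignment:
    """Assign exactly one prognostic group to a grade set.

    Other-pathology suffix letters never change the group when any core
    pattern is present; group 8 requires an empty core code plus at
    least one suffix letter.
    """
    return _assign(
        grades.acute, grades.chronic, grades.fvm, grades.mvm, bool(grades.other_letters)
    )


def enumerate_all_codes() -> Dict[str, str]:
    """Map every possible core code (all 81 grade combinations, no suffix
    letters) to its group id.  The exhaustive oracle behind the partition
    tests and the ``ssr enumerate`` command."""
    out: Dict[str, str] = {}
    for a, c, f, m in product(Grade, repeat=4):
        gs = GradeSet(acute=a, chronic=c, fvm=f, mvm=m)
        out[build_code(gs).core] = assign_group(gs).group_id
    return out
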