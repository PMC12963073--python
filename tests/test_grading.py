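"""Pattern grading rules: thresholds, scoring, gating, monotonicity."""

import random

import pytest

from placenta_ssr.case import Finding, Microscopy
from placenta_ssr.catalog import Category, Compartment
from placenta_ssr.config import SsrConfig
from placenta_ssr.grading import (
    HYPOPLASIA_LESION_ID,
    CaseValidationError,
    Grade,
    chronic_grade_from_count,
    collect_other_letters,
    grade_acute,
    grade_case,
    grade_chronic,
    grade_fvm,
    mvm_grade_from_score,
    score_mvm,
)
from placenta_ssr.macro import assess_against_reference


def _micro(catalog, lesion_ids=(), **kwargs):
    findings = [
        Finding(lesion_id=lid, compartment=catalog[lid].compartment) for lid in lesion_ids
    ]
    return Microscopy(findings=findings, **kwargs)


# --- acute inflammation -----------------------------------------------------


def test_acute_none_without_lesions(catalog):
    assert grade_acute(_micro(catalog), catalog) is Grade.NONE


def test_acute_low_below_stage_threshold(catalog):
    micro = _micro(catalog, ["acute_chorioamnionitis"], ai_maternal_stage=1)
    assert grade_acute(micro, catalog) is Grade.LOW


def test_acute_high_on_high_stage_maternal_or_fetal(catalog):
    micro = _micro(catalog, ["necrotizing_acute_chorioamnionitis"], ai_maternal_stage=3)
    assert grade_acute(micro, catalog) is Grade.HIGH
    # fetal stage alone can carry the case over the threshold
    micro = _micro(catalog, ["acute_funisitis"], ai_fetal_stage=2)
    assert grade_acute(micro, catalog) is Grade.HIGH


def test_acute_threshold_is_configurable(catalog):
    micro = _micro(catalog, ["acute_chorioamnionitis"], ai_maternal_stage=2)
    assert grade_acute(micro, catalog, SsrConfig(ai_high_stage_threshold=3)) is Grade.LOW


# --- chronic inflammation ---------------------------------------------------


def test_chronic_counts_distinct_compartments(catalog):
    assert grade_chronic(_micro(catalog, ["chronic_deciduitis"]), catalog) == (Grade.LOW, 1)
    assert grade_chronic(
        _micro(catalog, ["chronic_villitis", "chronic_chorioamnionitis"]), catalog
    ) == (Grade.HIGH, 2)
    # two lesions in the same compartment count once
    assert grade_chronic(
        _micro(catalog, ["chronic_deciduitis", "chronic_basal_villitis"]), catalog
    ) == (Grade.LOW, 1)


@pytest.mark.parametrize(
    "count, expected",
    [(0, Grade.NONE), (1, Grade.LOW), (2, Grade.HIGH), (3, Grade.HIGH), (4, Grade.HIGH), (5, Grade.HIGH)],
)
def test_chronic_grade_over_all_compartment_counts(count, expected):
    assert chronic_grade_from_count(count) is expected


def test_chronic_grade_depends_only_on_compartment_set(catalog):
    """Permutation/multiplicity invariance of chronic grading."""
    lesions = ["chronic_villitis", "chronic_deciduitis", "chronic_deciduitis"]
    baseline = grade_chronic(_micro(catalog, lesions), catalog)
    for perm in (lesions[::-1], lesions * 2):
        assert grade_chronic(_micro(catalog, perm), catalog) == baseline


# --- fetal vascular malperfusion --------------------------------------------


def test_fvm_none_without_lesions(catalog):
    assert grade_fvm(_micro(catalog), catalog) is Grade.NONE


def test_fvm_single_thrombus_is_low(catalog):
    micro = _micro(catalog, ["umbilical_vein_thrombus"], fvm_thrombus_count=1)
    assert grade_fvm(micro, catalog) is Grade.LOW


def test_fvm_two_thrombi_is_high(catalog):
    micro = _micro(catalog, ["fetal_vascular_thrombi"], fvm_thrombus_count=2)
    assert grade_fvm(micro, catalog) is Grade.HIGH


def test_fvm_avascular_villi_focus_size_qualifier(catalog):
    kwargs = dict(avascular_villi_focus_count=2)
    low = _micro(catalog, ["avascular_villi"], avascular_villi_max_focus_size=44, **kwargs)
    high = _micro(catalog, ["avascular_villi"], avascular_villi_max_focus_size=45, **kwargs)
    assert grade_fvm(low, catalog) is Grade.LOW
    assert grade_fvm(high, catalog) is Grade.HIGH
    # "more than one focus": a single qualifying focus stays low
    one = _micro(
        catalog,
        ["avascular_villi"],
        avascular_villi_focus_count=1,
        avascular_villi_max_focus_size=60,
    )
    assert grade_fvm(one, catalog) is Grade.LOW


# --- maternal vascular malperfusion -----------------------------------------


@pytest.mark.parametrize(
    "score, expected",
    [(s, Grade.NONE) for s in (0, 1)]
    + [(s, Grade.LOW) for s in (2, 3)]
    + [(s, Grade.HIGH) for s in range(4, 13)],
)
def test_mvm_threshold_map_exhaustive(score, expected):
    assert mvm_grade_from_score(score) is expected


def test_each_one_point_lesion_scores_one(catalog):
    one_pointers = [
        l.lesion_id
        for l in catalog.mvm_scoring_lesions
        if l.mvm_points == 1
    ]
    # ten published point-list entries; fibrinoid necrosis/acute atherosis
    # is catalogued at both its sites (membranes and basal plate), so the
    # catalog carries 11 one-point rows
    assert len(one_pointers) == 11
    for lid in one_pointers:
        score, grade = score_mvm(_micro(catalog, [lid]), catalog)
        assert (score, grade) == (1, Grade.NONE), lid


def test_each_two_point_lesion_scores_two(catalog):
    two_pointers = [
        l.lesion_id
        for l in catalog.mvm_scoring_lesions
        if l.mvm_points == 2 and l.lesion_id != HYPOPLASIA_LESION_ID
    ]
    assert sorted(two_pointers) == [
        "multiple_infarcts",
        "retroplacental_hematoma_with_hemosiderin_or_infarct",
    ]
    for lid in two_pointers:
        score, grade = score_mvm(_micro(catalog, [lid]), catalog)
        assert (score, grade) == (2, Grade.LOW), lid


def test_four_one_point_lesions_are_high(catalog):
    micro = _micro(
        catalog,
        [
            "fibrinoid_necrosis_acute_atherosis",
            "distal_villous_hypoplasia",
            "villous_agglutination",
            "accelerated_villous_maturation",
        ],
    )
    assert score_mvm(micro, catalog) == (4, Grade.HIGH)


def test_two_plus_two_points_are_high(catalog):
    micro = _micro(
        catalog, ["multiple_infarcts", "retroplacental_hematoma_with_hemosiderin_or_infarct"]
    )
    assert score_mvm(micro, catalog) == (4, Grade.HIGH)


def test_duplicate_findings_score_once(catalog):
    micro = _micro(catalog, ["single_infarct", "single_infarct"])
    assert score_mvm(micro, catalog) == (1, Grade.NONE)


def test_isolated_hypoplasia_is_not_scored(catalog, synthetic_weight_table):
    below = assess_against_reference(250, 30, synthetic_weight_table)
    assert below.below_p10
    assert score_mvm(_micro(catalog), catalog, weight_assessment=below) == (0, Grade.NONE)
    # the same holds when hypoplasia is recorded as an explicit finding
    assert score_mvm(_micro(catalog, [HYPOPLASIA_LESION_ID]), catalog) == (0, Grade.NONE)


def test_hypoplasia_adds_two_points_alongside_other_mvm_lesions(catalog, synthetic_weight_table):
    below = assess_against_reference(250, 30, synthetic_weight_table)
    micro = _micro(catalog, ["single_infarct", "villous_agglutination"])
    assert score_mvm(micro, catalog) == (2, Grade.LOW)
    assert score_mvm(micro, catalog, weight_assessment=below) == (4, Grade.HIGH)


def test_hypoplasia_gating_over_random_lesion_sets(catalog):
    """score(with hypoplasia) - score(without) is 2 exactly when another
    MVM-scoring lesion is present, else 0."""
    rng = random.Random(20250920)
    pool = [l for l in catalog.mvm_scoring_lesions if l.lesion_id != HYPOPLASIA_LESION_ID]
    # include non-scoring distractors
    pool += [catalog["chronic_villitis"], catalog["amnion_nodosum"], catalog["avascular_villi"]]
    for _ in range(200):
        chosen, groups = [], set()
        for lesion in rng.sample(pool, rng.randint(0, 5)):
            if lesion.exclusivity_group and lesion.exclusivity_group in groups:
                continue
            groups.add(lesion.exclusivity_group)
            chosen.append(lesion.lesion_id)
        micro = _micro(catalog, chosen)
        without, _ = score_mvm(micro, catalog)
        with_hypo, _ = score_mvm(
            _micro(catalog, chosen + [HYPOPLASIA_LESION_ID]), catalog
        )
        other_present = without > 0
        assert with_hypo - without == (2 if other_present else 0), chosen


# --- other letters and whole-case grading ------------------------------------


def test_letters_collected_in_canonical_order(catalog):
    micro = _micro(catalog, ["delayed_villous_maturation", "amnion_nodosum"])
    assert collect_other_letters(micro, catalog) == ("h", "p")


def test_letters_deduplicate(catalog):
    micro = Microscopy(
        findings=[
            Finding(lesion_id="villous_chorangiosis", compartment=Compartment.VILLOUS_INTERVILLOUS, note="focus 1"),
            Finding(lesion_id="villous_chorangiosis", compartment=Compartment.VILLOUS_INTERVILLOUS, note="focus 2"),
        ]
    )
    assert collect_other_letters(micro, catalog) == ("q",)


def test_lesion_free_case_grades_all_none(base_case, catalog):
    gs = grade_case(base_case, catalog)
    assert gs.levels == (Grade.NONE,) * 4
    assert gs.mvm_score == 0 and gs.other_letters == ()


def test_grade_case_rejects_invalid_case(base_case, catalog):
    case = base_case.model_copy(deep=True)
    case.macroscopy.weight_g = None
    with pytest.raises(CaseValidationError):
        grade_case(case, catalog)


def test_untrimmed_weight_never_triggers_hypoplasia(base_case, catalog, synthetic_weight_table):
    case = base_case.model_copy(deep=True)
    case.demographics.gestational_age_weeks = 30.0
    case.macroscopy.weight_g = 250.0  # below p10 of the test table
    case.macroscopy.trimmed = False
    case.microscopy = _micro(catalog, ["single_infarct", "villous_agglutination"])
    gs = grade_case(case, catalog, weight_reference=synthetic_weight_table)
    assert gs.mvm_score == 2
    case.macroscopy.trimmed = True
    gs = grade_case(case, catalog, weight_reference=synthetic_weight_table)
    assert gs.mvm_score == 4


def test_adding_mvm_lesion_never_lowers_score_or_grade(catalog):
    rng = random.Random(7)
    scorers = [l for l in catalog.mvm_scoring_lesions if l.lesion_id != HYPOPLASIA_LESION_ID]
    for _ in range(100):
        base = []
        groups = set()
        for lesion in rng.sample(scorers, rng.randint(0, 4)):
            if lesion.exclusivity_group and lesion.exclusivity_group in groups:
                continue
            groups.add(lesion.exclusivity_group)
            base.append(lesion.lesion_id)
        s0, g0 = score_mvm(_micro(catalog, base), catalog)
        for lesion in scorers:
            if lesion.exclusivity_group and lesion.exclusivity_group in groups and lesion.lesion_id not in base:
                continue
            s1, g1 = score_mvm(_micro(catalog, base + [lesion.lesion_id]), catalog)
            assert s1 >= s0 and g1.rank >= g0.rank


def test_adding_chronic_compartment_never_lowers_grade(catalog):
    by_compartment = {
        "basal_plate": "chronic_deciduitis",
        "villous_intervillous": "chronic_villitis",
        "membranes": "chronic_chorioamnionitis",
        "umbilical_cord": "eosinophilic_t_cell_vasculitis",
        "chorionic_plate": "chronic_chorionitis",
    }
    lesions = list(by_compartment.values())
    for k in range(len(lesions)):
        g0, c0 = grade_chronic(_micro(catalog, lesions[:k]), catalog)
        g1, c1 = grade_chronic(_micro(catalog, lesions[: k + 1]), catalog)
        assert c1 == c0 + 1 and g1.rank >= g0.rank
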