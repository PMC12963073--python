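"""Case record validation, serialization round trips, parse errors."""

import copy

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from placenta_ssr.case import (
    CaseParseError,
    Finding,
    MultiGestation,
    read_case,
    validate_case,
    write_case,
)
from placenta_ssr.fixtures import GRADE_TRIPLETS, FixtureProfile, make_case


def _finding(catalog, lesion_id):
    return Finding(lesion_id=lesion_id, compartment=catalog[lesion_id].compartment)


def test_complete_singleton_passes_core(base_case, catalog):
    assert validate_case(base_case, catalog, level="core") == []


def test_twin_without_multi_details_is_an_error(base_case, catalog):
    case = base_case.model_copy(deep=True)
    case.demographics.fetus_count = 2
    case.demographics.fetus_status = ["liveborn", "liveborn"]
    issues = validate_case(case, catalog)
    assert [i.path for i in issues if i.severity == "error"] == ["macroscopy.multi"]


def test_singleton_with_multi_details_is_an_error(base_case, catalog):
    case = base_case.model_copy(deep=True)
    case.macroscopy.multi = MultiGestation(septum="absent", estimated_share_percent=50)
    errors = [i for i in validate_case(case, catalog) if i.severity == "error"]
    assert len(errors) == 1 and errors[0].path == "macroscopy.multi"


def test_exclusive_infarct_findings_rejected(base_case, catalog):
    case = base_case.model_copy(deep=True)
    case.microscopy.findings = [
        _finding(catalog, "single_infarct"),
        _finding(catalog, "multiple_infarcts"),
    ]
    errors = [i for i in validate_case(case, catalog) if i.severity == "error"]
    assert len(errors) == 1
    assert "mutually exclusive" in errors[0].message


def test_unknown_lesion_and_wrong_compartment_flagged(base_case, catalog):
    case = base_case.model_copy(deep=True)
    case.microscopy.findings = [
        Finding(lesion_id="no_such_lesion", compartment="membranes"),
        Finding(lesion_id="chronic_villitis", compartment="membranes"),
    ]
    messages = [i.message for i in validate_case(case, catalog) if i.severity == "error"]
    assert any("unknown lesion_id" in m for m in messages)
    assert any("does not match catalog" in m for m in messages)


def test_ai_stage_without_acute_lesion_is_inconsistent(base_case, catalog):
    case = base_case.model_copy(deep=True)
    case.microscopy.ai_maternal_stage = 2
    errors = [i for i in validate_case(case, catalog) if i.severity == "error"]
    assert errors and errors[0].path == "microscopy.ai_maternal_stage"


def test_missing_core_items_reported_by_path(base_case, catalog):
    case = base_case.model_copy(deep=True)
    case.macroscopy.weight_g = None
    case.macroscopy.cord_diameter_mm = None
    paths = {i.path for i in validate_case(case, catalog) if i.severity == "error"}
    assert paths == {"macroscopy.weight_g", "macroscopy.cord_diameter_mm"}


def test_validate_is_pure_and_full_extends_core(base_case, catalog):
    snapshot = copy.deepcopy(base_case.model_dump())
    core = validate_case(base_case, catalog, level="core")
    full = validate_case(base_case, catalog, level="full")
    assert base_case.model_dump() == snapshot  # no mutation
    assert validate_case(base_case, catalog, level="core") == core  # idempotent
    # full only adds warnings: a case accepted at full is accepted at core
    assert {i for i in core} <= {i for i in full}
    assert all(i.severity == "warning" for i in set(full) - set(core))


@pytest.mark.parametrize("suffix", ["json", "yaml"])
def test_write_read_round_trip(tmp_path, base_case, suffix):
    path = tmp_path / f"case.{suffix}"
    write_case(base_case, path)
    assert read_case(path) == base_case


def test_read_missing_required_field_names_path(tmp_path, base_case):
    path = tmp_path / "case.json"
    write_case(base_case, path)
    import json

    data = json.loads(path.read_text())
    del data["demographics"]["gestational_age_weeks"]
    path.write_text(json.dumps(data))
    with pytest.raises(CaseParseError) as exc:
        read_case(path)
    assert "demographics.gestational_age_weeks" in exc.value.paths


def test_self_link_rejected_at_parse(tmp_path, base_case):
    path = tmp_path / "case.json"
    write_case(base_case, path)
    import json

    data = json.loads(path.read_text())
    data["demographics"]["linked_accessions"] = [data["demographics"]["accession"]]
    path.write_text(json.dumps(data))
    with pytest.raises(CaseParseError):
        read_case(path)


@settings(derandomize=True, max_examples=30)
@given(
    seed=st.integers(0, 10_000),
    target=st.tuples(*([st.sampled_from(GRADE_TRIPLETS)] * 4)),
    twin=st.booleans(),
)
def test_generated_cases_serialize_losslessly(tmp_path_factory, seed, target, twin):
    """Any generated valid case survives a JSON round trip unchanged."""
    case = make_case(FixtureProfile(seed=seed, target=target, twin=twin))
    path = tmp_path_factory.mktemp("rt") / "case.json"
    write_case(case, path)
    assert read_case(path) == case
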