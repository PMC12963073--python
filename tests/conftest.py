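import csv
from pathlib import Path

import pytest

from placenta_ssr.case import CaseRecord, Demographics, Macroscopy, Microscopy
from placenta_ssr.catalog import load_catalog
from placenta_ssr.config import SsrConfig
from placenta_ssr.macro import (
    ReferenceKind,
    ReferenceRow,
    ReferenceTable,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def config():
    return SsrConfig()


@pytest.fixture(scope="session")
def table2_rows():
    """Corrected published code->group fixture (81 rows)."""
    with open(DATA_DIR / "table2_codes.csv", newline="", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.lstrip().startswith("#")]
    return list(csv.DictReader(lines))


@pytest.fixture
def base_case():
    """A complete, lesion-free singleton case."""
    return CaseRecord(
        demographics=Demographics(
            accession="T-001",
            gestational_age_weeks=38.0,
            fetus_count=1,
            fetus_status=["liveborn"],
        ),
        macroscopy=Macroscopy(
            trimmed=True,
            weight_g=480.0,
            completeness="complete",
            shape="discoid",
            cord_length_cm=55.0,
            cord_coil_count=10,
            cord_diameter_mm=12.0,
            cord_insertion="central",
        ),
        microscopy=Microscopy(),
    )


@pytest.fixture(scope="session")
def synthetic_weight_table():
    """Tiny hand-built weight reference (week 30: p10=300 etc.)."""
    return ReferenceTable(
        kind=ReferenceKind.PLACENTAL_WEIGHT,
        rows=(
            ReferenceRow(ga_weeks=28, values={"p3": 180, "p10": 220, "p50": 310, "p90": 400, "p97": 450}),
            ReferenceRow(ga_weeks=30, values={"p3": 250, "p10": 300, "p50": 380, "p90": 480, "p97": 540}),
            ReferenceRow(ga_weeks=32, values={"p3": 290, "p10": 340, "p50": 430, "p90": 540, "p97": 600}),
        ),
    )
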