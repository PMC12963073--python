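"""Engine configuration: grading thresholds and core-item profile.

All numeric cutoffs the grading engine applies are gathered here so a
deployment can adjust them (e.g. if consensus criteria evolve) without
touching the rule code.  The defaults reproduce the published grading
scheme; where the scheme prints no number (the acute-inflammation
"high stage" boundary, the coiling-index normal range) the default is a
documented, conventional choice.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Union

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["SsrConfig", "load_config", "DEFAULT_CORE_ITEMS"]

#: Macroscopy/demographics items whose absence is a validation *error*
#: ("core" items); everything else is optional detail flagged only as a
#: warning under full-depth validation.
DEFAULT_CORE_ITEMS = [
    "demographics.gestational_age_weeks",
    "demographics.fetus_count",
    "demographics.fetus_status",
    "macroscopy.weight_g",
    "macroscopy.trimmed",
    "macroscopy.completeness",
    "macroscopy.shape",
    "macroscopy.cord_length_cm",
    "macroscopy.cord_coil_count",
    "macroscopy.cord_diameter_mm",
    "macroscopy.cord_insertion",
]


class SsrConfig(BaseModel):
    """Thresholds and profile options for grading and macroscopic assessment."""

    model_config = ConfigDict(extra="forbid")

    #: Amsterdam stage (1-3) at or above which maternal/fetal acute
    #: inflammation counts as high grade.  Not fixed by the published
    #: scheme; 2 is the package default and is configurable.
    ai_high_stage_threshold: int = Field(default=2, ge=1, le=3)

    #: Minimum villi per focus for an avascular-villi focus to count
    #: toward high-grade fetal vascular malperfusion.
    avascular_focus_min_villi: int = Field(default=45, ge=1)

    #: Occlusive/nonocclusive thrombus count (chorionic plate or stem
    #: villi) at or above which FVM is high grade.
    fvm_thrombus_high_count: int = Field(default=2, ge=1)

    #: Avascular-villi focus count above which ("more than one focus")
    #: FVM is high grade, given foci of qualifying size.
    fvm_avascular_focus_high_count: int = Field(default=2, ge=1)

    #: MVM point score at or above which the grade is high.
    mvm_high_cut: int = Field(default=4, ge=1)
    #: MVM point score at or above which (but below ``mvm_high_cut``)
    #: the grade is low.
    mvm_low_cut: int = Field(default=2, ge=1)

    #: Number of distinct compartments with chronic inflammation at or
    #: above which chronic inflammation is high grade.
    ci_high_compartments: int = Field(default=2, ge=1)

    #: Umbilical coiling index normal range, coils/cm.  Below the low
    #: cut is hypocoiled, above the high cut hypercoiled.  The
    #: conventional normal range is used as default; deployments may
    #: substitute a local standard.
    coiling_low_cut: float = Field(default=0.07, gt=0)
    coiling_high_cut: float = Field(default=0.30, gt=0)

    #: Dotted field paths treated as core (mandatory) items.
    core_items: list[str] = Field(default_factory=lambda: list(DEFAULT_CORE_ITEMS))

    def digest(self) -> str:
        """Short stable digest of the configuration, recorded in results."""
        canonical = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:12]


def load_config(path: Union[str, Path, None] = None) -> SsrConfig:
    """Load a config from YAML/JSON, or return defaults when ``path`` is None."""
    if path is None:
        return SsrConfig()
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    return SsrConfig.model_validate(data)
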