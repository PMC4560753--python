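"""Domain types and factor weights for the gynaecological Adhesion Risk Score.

The Adhesion Risk Score (ARS) is a consensus-weighted additive index that
quantifies a woman's risk of developing post-surgical adhesions after
gynaecological surgery.  It consists of two sub-scores built from 20 risk
factors, each carrying an integer weight between 0 and 4:

* the **Preoperative** sub-score (range 0-36) aggregates ten factors known
  before surgery: prior abdominal/pelvic operations and their sequelae,
  adhesion history, inflammation/infection, endometriosis severity (rASRM
  stage), cancer, radiation therapy and keloid scarring;
* the **Perioperative** (also called intraoperative) sub-score (range 3-31)
  aggregates ten factors observed during the current operation: quality and
  extent of pre-existing adhesions (Knightly categories), bleeding, procedure
  duration and complexity, the type and anatomical site of the surgery,
  coagulated area, foreign-body placement, electrical scalpel use and
  peritoneal closing.

This module defines the profile types (validated with pydantic), the weight
tables, and per-factor point lookups.  Summation and risk classification live
in :mod:`adhesionrisk.scoring`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

from pydantic import BaseModel, ConfigDict, model_validator


# ---------------------------------------------------------------------------
# Factor level enums
# ---------------------------------------------------------------------------

class Endometriosis(enum.StrEnum):
    """Endometriosis severity; rASRM stages I-IV map to minimal-severe."""

    ABSENT = "absent"
    MINIMAL = "minimal"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


class Cancer(enum.StrEnum):
    ABSENT = "absent"
    GYNAECOLOGIC = "gynaecologic"
    PERITONEAL_CARCINOMATOSIS = "peritoneal_carcinomatosis"
    LOCAL_NON_GYNAECOLOGICAL = "local_non_gynaecological"
    METASTATIC_EXTRAPELVIC = "metastatic_extrapelvic"


class Radiation(enum.StrEnum):
    """Radiation therapy in intra-abdominal cancer."""

    ABSENT = "absent"
    LOCAL = "local"
    DISTANT = "distant"


class AdhesionQuality(enum.StrEnum):
    NONE = "none"
    FILMY = "filmy"
    VASCULAR = "vascular"
    DENSE = "dense"


class AdhesionSeverity(enum.StrEnum):
    """Extent of pre-existing adhesions, after Knightly's categories."""

    NONE = "none"
    SINGLE = "single"
    TWO_OR_THREE = "two_or_three"
    MORE_THAN_THREE = "more_than_three"
    BOWEL_INVOLVEMENT = "bowel_involvement"


class SurgeryTypeSite(enum.StrEnum):
    """Type (laparoscopy/open) and anatomical site of the current operation."""

    LAPAROSCOPY_FALLOPIAN_TUBE = "laparoscopy_fallopian_tube"
    OPEN_UTERUS = "open_uterus"
    OPEN_FALLOPIAN_TUBE = "open_fallopian_tube"
    LAPAROSCOPY_ADHESIOLYSIS_UTERUS = "laparoscopy_adhesiolysis_uterus"
    LAPAROSCOPY_OTHER = "laparoscopy_other"
    OPEN_OVARY = "open_ovary"


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

#: preoperative factors that are sequelae of previous operations; they may
#: only be positive when previous_surgery_count >= 1.
PRIOR_OPERATION_SEQUELAE = (
    "prior_intraperitoneal_bleeding",
    "prior_postoperative_complications",
    "prior_postoperative_infection",
)

#: canonical field order, matching the published factor order.
PREOPERATIVE_FIELDS = (
    "previous_surgery_count",
    "history_postsurgical_adhesions",
    "concomitant_inflammation_or_infection",
    "endometriosis",
    "cancer",
    "radiation",
    "keloid_scarring",
    "prior_intraperitoneal_bleeding",
    "prior_postoperative_complications",
    "prior_postoperative_infection",
)

PERIOPERATIVE_FIELDS = (
    "adhesion_quality",
    "adhesion_severity",
    "bleeding_over_500ml",
    "duration_minutes",
    "complex_or_multiquadrant",
    "excessive_coagulation",
    "surgery_type_site",
    "foreign_body_placement",
    "electrical_scalpel",
    "peritoneal_closing",
)


class PreoperativeProfile(BaseModel):
    """The ten preoperative risk-factor values for one patient.

    All fields default to absent/zero, so an empty profile is the published
    minimum-risk patient.  Sequelae of previous operations (intraperitoneal
    bleeding with an unexpected Hb drop >=2 g%, postoperative complications
    such as fistulas or abscesses, postoperative infection >=38 degC for >=2
    days) are rejected when ``previous_surgery_count`` is zero: by definition
    they can only follow a prior operation.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    previous_surgery_count: int = 0
    history_postsurgical_adhesions: bool = False
    concomitant_inflammation_or_infection: bool = False
    endometriosis: Endometriosis = Endometriosis.ABSENT
    cancer: Cancer = Cancer.ABSENT
    radiation: Radiation = Radiation.ABSENT
    keloid_scarring: bool = False
    prior_intraperitoneal_bleeding: bool = False
    prior_postoperative_complications: bool = False
    prior_postoperative_infection: bool = False

    @model_validator(mode="after")
    def _check_cross_field(self) -> "PreoperativeProfile":
        if self.previous_surgery_count < 0:
            raise ValueError("previous_surgery_count must be >= 0")
        if self.previous_surgery_count == 0:
            offending = [f for f in PRIOR_OPERATION_SEQUELAE if getattr(self, f)]
            if offending:
                raise ValueError(
                    "sequelae of previous operations require "
                    f"previous_surgery_count >= 1: {', '.join(offending)}"
                )
        return self


class PerioperativeProfile(BaseModel):
    """The ten intraoperative risk-factor values for one patient.

    ``duration_minutes`` and ``surgery_type_site`` are mandatory: every
    operation has a duration and a type/site, and the published sub-score
    minimum of 3 (= 2 for duration under 90 min + 1 for laparoscopy of the
    fallopian tube) is only reachable because both always contribute.
    Adhesion quality and severity must agree on the absence of adhesions:
    ``quality == none`` if and only if ``severity == none``.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    duration_minutes: float
    surgery_type_site: SurgeryTypeSite
    adhesion_quality: AdhesionQuality = AdhesionQuality.NONE
    adhesion_severity: AdhesionSeverity = AdhesionSeverity.NONE
    bleeding_over_500ml: bool = False
    complex_or_multiquadrant: bool = False
    excessive_coagulation: bool = False
    foreign_body_placement: bool = False
    electrical_scalpel: bool = False
    peritoneal_closing: bool = False

    @model_validator(mode="after")
    def _check_cross_field(self) -> "PerioperativeProfile":
        if not self.duration_minutes > 0:
            raise ValueError("duration_minutes must be > 0")
        quality_none = self.adhesion_quality is AdhesionQuality.NONE
        severity_none = self.adhesion_severity is AdhesionSeverity.NONE
        if quality_none != severity_none:
            raise ValueError(
                "adhesion_quality and adhesion_severity must both be 'none' "
                "or both report adhesions "
                f"(got quality={self.adhesion_quality}, "
                f"severity={self.adhesion_severity})"
            )
        return self


# ---------------------------------------------------------------------------
# Weight tables
# ---------------------------------------------------------------------------

# Band tokens for the two numeric factors.  Previous surgeries are banded
# 0 / 1 / >1; procedure duration <90 min / 90 min-2 h / >2 h (the 120-minute
# boundary belongs to the middle band because the top band is strictly
# "over 2 hours").
SURGERY_COUNT_BANDS = ("0", "1", ">1")
DURATION_BANDS = ("<90", "90-120", ">120")

_TRUE, _FALSE = "true", "false"


def _bool_weights(points_if_true: int) -> dict[str, int]:
    return {_FALSE: 0, _TRUE: points_if_true}


@dataclass(frozen=True)
class WeightTable:
    """Factor -> level-token -> points mapping for one sub-score.

    Level tokens are strings: enum values, ``"true"``/``"false"`` for binary
    factors, and band labels for the two numeric factors.  Every declared
    level of every factor has exactly one entry, and all points lie in 0-4.
    """

    kind: str
    factors: Mapping[str, Mapping[str, int]]

    def points(self, factor: str, level: str) -> int:
        try:
            levels = self.factors[factor]
        except KeyError:
            raise KeyError(f"unknown factor {factor!r} in {self.kind} table") from None
        try:
            return levels[level]
        except KeyError:
            raise KeyError(
                f"unknown level {level!r} for factor {factor!r}; "
                f"declared levels: {sorted(levels)}"
            ) from None

    def max_points(self, factor: str) -> int:
        return max(self.factors[factor].values())

    def min_points(self, factor: str) -> int:
        return min(self.factors[factor].values())

    def max_total(self) -> int:
        """Score of the all-maximal profile (each factor at its heaviest level)."""
        return sum(self.max_points(f) for f in self.factors)

    def min_total(self) -> int:
        """Score of the all-minimal profile."""
        return sum(self.min_points(f) for f in self.factors)


PREOPERATIVE_TABLE = WeightTable(
    kind="preoperative",
    factors={
        "previous_surgery_count": {"0": 0, "1": 3, ">1": 4},
        "history_postsurgical_adhesions": _bool_weights(4),
        "concomitant_inflammation_or_infection": _bool_weights(4),
        "endometriosis": {
            Endometriosis.ABSENT: 0,
            Endometriosis.MINIMAL: 1,
            Endometriosis.MILD: 2,
            Endometriosis.MODERATE: 3,
            Endometriosis.SEVERE: 4,
        },
        "cancer": {
            Cancer.ABSENT: 0,
            Cancer.GYNAECOLOGIC: 2,
            Cancer.PERITONEAL_CARCINOMATOSIS: 2,
            Cancer.LOCAL_NON_GYNAECOLOGICAL: 3,
            Cancer.METASTATIC_EXTRAPELVIC: 2,
        },
        "radiation": {
            Radiation.ABSENT: 0,
            Radiation.LOCAL: 4,
            Radiation.DISTANT: 1,
        },
        "keloid_scarring": _bool_weights(3),
        "prior_intraperitoneal_bleeding": _bool_weights(2),
        "prior_postoperative_complications": _bool_weights(4),
        "prior_postoperative_infection": _bool_weights(4),
    },
)

PERIOPERATIVE_TABLE = WeightTable(
    kind="perioperative",
    factors={
        "adhesion_quality": {
            AdhesionQuality.NONE: 0,
            AdhesionQuality.FILMY: 2,
            AdhesionQuality.VASCULAR: 3,
            AdhesionQuality.DENSE: 4,
        },
        "adhesion_severity": {
            AdhesionSeverity.NONE: 0,
            AdhesionSeverity.SINGLE: 1,
            AdhesionSeverity.TWO_OR_THREE: 2,
            AdhesionSeverity.MORE_THAN_THREE: 3,
            AdhesionSeverity.BOWEL_INVOLVEMENT: 4,
        },
        "bleeding_over_500ml": _bool_weights(4),
        "duration_minutes": {"<90": 2, "90-120": 3, ">120": 4},
        "complex_or_multiquadrant": _bool_weights(3),
        "excessive_coagulation": _bool_weights(2),
        "surgery_type_site": {
            SurgeryTypeSite.LAPAROSCOPY_FALLOPIAN_TUBE: 1,
            SurgeryTypeSite.OPEN_UTERUS: 3,
            SurgeryTypeSite.OPEN_FALLOPIAN_TUBE: 2,
            SurgeryTypeSite.LAPAROSCOPY_ADHESIOLYSIS_UTERUS: 3,
            SurgeryTypeSite.LAPAROSCOPY_OTHER: 2,
            SurgeryTypeSite.OPEN_OVARY: 4,
        },
        "foreign_body_placement": _bool_weights(3),
        "electrical_scalpel": _bool_weights(2),
        "peritoneal_closing": _bool_weights(1),
    },
)


# ---------------------------------------------------------------------------
# Per-factor point lookups
# ---------------------------------------------------------------------------

def surgery_count_band(count: int) -> str:
    """Band label for a previous-surgery count (0, 1 or >1)."""
    if count < 0:
        raise ValueError("previous surgery count must be >= 0")
    if count == 0:
        return "0"
    return "1" if count == 1 else ">1"


def duration_band(duration_minutes: float) -> str:
    """Band label for a procedure duration in minutes.

    Bands are under 90 minutes, 90 minutes to 2 hours inclusive, and strictly
    over 2 hours.
    """
    if not duration_minutes > 0:
        raise ValueError("duration_minutes must be > 0")
    if duration_minutes < 90:
        return "<90"
    return "90-120" if duration_minutes <= 120 else ">120"


def weight_previous_surgery(count: int) -> int:
    """Points for the count of prior abdominal/pelvic surgeries: 0/3/4."""
    return PREOPERATIVE_TABLE.points("previous_surgery_count", surgery_count_band(count))


def weight_endometriosis(stage: Endometriosis | str) -> int:
    return PREOPERATIVE_TABLE.points("endometriosis", Endometriosis(stage))


def weight_cancer(category: Cancer | str) -> int:
    """Points for the single applicable cancer category (never a sum)."""
    return PREOPERATIVE_TABLE.points("cancer", Cancer(category))


def weight_radiation(kind: Radiation | str) -> int:
    return PREOPERATIVE_TABLE.points("radiation", Radiation(kind))


def weight_duration(duration_minutes: float) -> int:
    """Points for procedure duration: <90 min -> 2, 90-120 min -> 3, >2 h -> 4."""
    return PERIOPERATIVE_TABLE.points("duration_minutes", duration_band(duration_minutes))


def weight_adhesion_quality(quality: AdhesionQuality | str) -> int:
    return PERIOPERATIVE_TABLE.points("adhesion_quality", AdhesionQuality(quality))


def weight_adhesion_severity(severity: AdhesionSeverity | str) -> int:
    return PERIOPERATIVE_TABLE.points("adhesion_severity", AdhesionSeverity(severity))


def weight_surgery_type_site(choice: SurgeryTypeSite | str) -> int:
    return PERIOPERATIVE_TABLE.points("surgery_type_site", SurgeryTypeSite(choice))


def level_token(field: str, value: object) -> str:
    """Canonical weight-table token for a profile field value."""
    if field == "previous_surgery_count":
        return surgery_count_band(int(value))  # type: ignore[arg-type]
    if field == "duration_minutes":
        return duration_band(float(value))  # type: ignore[arg-type]
    if isinstance(value, bool):
        return _TRUE if value else _FALSE
    return str(value)
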