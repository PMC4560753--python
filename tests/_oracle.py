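"""Independent brute-force oracle for the Adhesion Risk Score tests.

The weights below are transcribed here a second time, on purpose, as plain
literals and arithmetic — no imports from the package's weight tables — so
tests compare two independent transcriptions of the published score.
"""

from __future__ import annotations

import itertools

# --- preoperative ----------------------------------------------------------

ORACLE_ENDOMETRIOSIS = {"absent": 0, "minimal": 1, "mild": 2, "moderate": 3, "severe": 4}
ORACLE_CANCER = {
    "absent": 0, "gynaecologic": 2, "peritoneal_carcinomatosis": 2,
    "local_non_gynaecological": 3, "metastatic_extrapelvic": 2,
}
ORACLE_RADIATION = {"absent": 0, "local": 4, "distant": 1}


def oracle_preoperative_score(
    count: int, history: bool, inflammation: bool, endometriosis: str,
    cancer: str, radiation: str, keloid: bool, bleeding: bool,
    complications: bool, infection: bool,
) -> int:
    pts = 0 if count == 0 else (3 if count == 1 else 4)
    pts += 4 * history + 4 * inflammation
    pts += ORACLE_ENDOMETRIOSIS[endometriosis]
    pts += ORACLE_CANCER[cancer] + ORACLE_RADIATION[radiation]
    pts += 3 * keloid + 2 * bleeding + 4 * complications + 4 * infection
    return pts


def oracle_enumerate_preoperative():
    """All valid preoperative combinations with their oracle scores."""
    for combo in itertools.product(
        (0, 1, 2), (False, True), (False, True),
        ORACLE_ENDOMETRIOSIS, ORACLE_CANCER, ORACLE_RADIATION,
        (False, True), (False, True), (False, True), (False, True),
    ):
        count, _, _, _, _, _, _, bleed, comp, infe = combo
        if count == 0 and (bleed or comp or infe):
            continue
        yield combo, oracle_preoperative_score(*combo)


# --- perioperative ---------------------------------------------------------

ORACLE_QUALITY = {"none": 0, "filmy": 2, "vascular": 3, "dense": 4}
ORACLE_SEVERITY = {
    "none": 0, "single": 1, "two_or_three": 2,
    "more_than_three": 3, "bowel_involvement": 4,
}
ORACLE_SITE = {
    "laparoscopy_fallopian_tube": 1, "open_uterus": 3, "open_fallopian_tube": 2,
    "laparoscopy_adhesiolysis_uterus": 3, "laparoscopy_other": 2, "open_ovary": 4,
}


def oracle_duration_points(minutes: float) -> int:
    if minutes < 90:
        return 2
    return 3 if minutes <= 120 else 4


def oracle_perioperative_score(
    quality: str, severity: str, bleeding500: bool, minutes: float,
    complexity: bool, coagulation: bool, site: str, foreign: bool,
    scalpel: bool, closing: bool,
) -> int:
    pts = ORACLE_QUALITY[quality] + ORACLE_SEVERITY[severity]
    pts += 4 * bleeding500 + oracle_duration_points(minutes)
    pts += 3 * complexity + 2 * coagulation + ORACLE_SITE[site]
    pts += 3 * foreign + 2 * scalpel + 1 * closing
    return pts


def oracle_enumerate_perioperative():
    """All valid perioperative combinations with their oracle scores."""
    for combo in itertools.product(
        ORACLE_QUALITY, ORACLE_SEVERITY, (False, True), (60.0, 100.0, 180.0),
        (False, True), (False, True), ORACLE_SITE,
        (False, True), (False, True), (False, True),
    ):
        quality, severity = combo[0], combo[1]
        if (quality == "none") != (severity == "none"):
            continue
        yield combo, oracle_perioperative_score(*combo)
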