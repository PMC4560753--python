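"""Seeded synthetic cohorts and the exhaustive profile enumerator.

No patient-level dataset accompanies the Adhesion Risk Score, so the
pipeline is exercised on synthetic cohorts: every factor is drawn
independently from a configurable marginal prevalence (the default
:class:`PrevalenceSpec` sketches a plausible gynaecological surgical
population — mostly benign indications, endometriosis in a minority,
cancer and radiation rare).  Cross-field rules are repaired
deterministically in a fixed draw order so a seed fully determines the
cohort:

* ``previous_surgery_count`` is drawn first; sequelae of previous
  operations are forced false wherever the count is zero;
* ``adhesion_quality`` is drawn first; severity is then drawn from the
  positive-severity levels (renormalised) where adhesions exist and forced
  to ``none`` where they do not, keeping the quality/severity invariant.

:func:`enumerate_profiles` walks every combination of declared factor
levels (14,400 preoperative, 11,520 perioperative, before cross-field
exclusion) and serves as the brute-force oracle for the achievable score
range of each sub-score.
"""

from __future__ import annotations

import itertools
from typing import Iterable

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .io_batch import CohortRecord
from .risk_model import (
    DURATION_BANDS,
    PERIOPERATIVE_TABLE,
    PREOPERATIVE_TABLE,
    SURGERY_COUNT_BANDS,
    AdhesionQuality,
    AdhesionSeverity,
    Cancer,
    Endometriosis,
    PerioperativeProfile,
    PreoperativeProfile,
    Radiation,
    SurgeryTypeSite,
)
from .scoring import PERIOPERATIVE, PREOPERATIVE, canonical_kind

#: representative duration (minutes) drawn uniformly within each band.
_DURATION_RANGES = {"<90": (30, 90), "90-120": (90, 121), ">120": (121, 241)}

#: one representative duration per band, used by the exhaustive enumerator.
ENUMERATION_DURATIONS = {"<90": 60.0, "90-120": 100.0, ">120": 180.0}

_LEVEL_KEYS = {
    "previous_surgery_count": SURGERY_COUNT_BANDS,
    "endometriosis": tuple(Endometriosis),
    "cancer": tuple(Cancer),
    "radiation": tuple(Radiation),
    "adhesion_quality": tuple(AdhesionQuality),
    "adhesion_severity": tuple(AdhesionSeverity),
    "duration_band": DURATION_BANDS,
    "surgery_type_site": tuple(SurgeryTypeSite),
}


class PrevalenceSpec(BaseModel):
    """Marginal prevalence of every risk factor, plus the random seed.

    Boolean factors take a single probability; ordinal/categorical factors
    take a probability vector over their declared levels (must sum to 1
    within 1e-9).  ``previous_surgery_count`` is specified over the bands
    0 / 1 / >1 (the score only distinguishes those three); a draw of ``>1``
    yields a count of 2.  ``adhesion_coupling`` is an optional correlation
    hook, off by default: with the given probability, a patient with
    moderate or severe endometriosis has her adhesion quality upgraded one
    level, emulating the clinical association between endometriosis and
    pelvic adhesions.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    previous_surgery_count: dict[str, float] = {"0": 0.50, "1": 0.30, ">1": 0.20}
    history_postsurgical_adhesions: float = 0.15
    concomitant_inflammation_or_infection: float = 0.10
    endometriosis: dict[str, float] = {
        "absent": 0.70, "minimal": 0.08, "mild": 0.08, "moderate": 0.08, "severe": 0.06,
    }
    cancer: dict[str, float] = {
        "absent": 0.90, "gynaecologic": 0.05, "peritoneal_carcinomatosis": 0.01,
        "local_non_gynaecological": 0.02, "metastatic_extrapelvic": 0.02,
    }
    radiation: dict[str, float] = {"absent": 0.95, "local": 0.03, "distant": 0.02}
    keloid_scarring: float = 0.05
    prior_intraperitoneal_bleeding: float = 0.05
    prior_postoperative_complications: float = 0.08
    prior_postoperative_infection: float = 0.08
    adhesion_quality: dict[str, float] = {
        "none": 0.50, "filmy": 0.20, "vascular": 0.15, "dense": 0.15,
    }
    adhesion_severity: dict[str, float] = {
        "none": 0.50, "single": 0.15, "two_or_three": 0.15,
        "more_than_three": 0.10, "bowel_involvement": 0.10,
    }
    bleeding_over_500ml: float = 0.08
    duration_band: dict[str, float] = {"<90": 0.45, "90-120": 0.35, ">120": 0.20}
    complex_or_multiquadrant: float = 0.15
    excessive_coagulation: float = 0.15
    surgery_type_site: dict[str, float] = {
        "laparoscopy_fallopian_tube": 0.15, "open_uterus": 0.15,
        "open_fallopian_tube": 0.10, "laparoscopy_adhesiolysis_uterus": 0.15,
        "laparoscopy_other": 0.30, "open_ovary": 0.15,
    }
    foreign_body_placement: float = 0.05
    electrical_scalpel: float = 0.60
    peritoneal_closing: float = 0.30
    adhesion_coupling: float = 0.0

    @model_validator(mode="after")
    def _check_probabilities(self) -> "PrevalenceSpec":
        for name in (
            "history_postsurgical_adhesions", "concomitant_inflammation_or_infection",
            "keloid_scarring", "prior_intraperitoneal_bleeding",
            "prior_postoperative_complications", "prior_postoperative_infection",
            "bleeding_over_500ml", "complex_or_multiquadrant", "excessive_coagulation",
            "foreign_body_placement", "electrical_scalpel", "peritoneal_closing",
            "adhesion_coupling",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}: probability {p} outside [0, 1]")
        for name, expected in _LEVEL_KEYS.items():
            vec = getattr(self, name)
            expected_keys = tuple(str(k) for k in expected)
            if tuple(vec) != expected_keys:
                raise ValueError(
                    f"{name}: levels must be exactly {list(expected_keys)} in order, "
                    f"got {list(vec)}"
                )
            if any(not 0.0 <= p <= 1.0 for p in vec.values()):
                raise ValueError(f"{name}: probabilities must lie in [0, 1]")
            if abs(sum(vec.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name}: probabilities sum to {sum(vec.values())}, not 1")
        return self


def _draw_levels(rng: np.random.Generator, vec: dict[str, float], n: int) -> np.ndarray:
    keys = np.array(list(vec), dtype=object)
    return rng.choice(keys, size=n, p=list(vec.values()))


def _upgrade_quality(q: str) -> str:
    order = [str(v) for v in AdhesionQuality]
    i = order.index(q)
    return order[min(i + 1, len(order) - 1)]


def generate_cohort(
    n: int, spec: PrevalenceSpec | None = None, seed: int | None = None
) -> list[CohortRecord]:
    """Generate ``n`` synthetic patients with both profiles.

    The same seed and spec always produce the identical cohort.  ``seed``
    overrides ``spec.seed`` when given.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec if spec is not None else PrevalenceSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    # --- preoperative columns, in published factor order -------------------
    count_band = _draw_levels(rng, spec.previous_surgery_count, n)
    counts = np.array([{"0": 0, "1": 1, ">1": 2}[b] for b in count_band])
    history = rng.random(n) < spec.history_postsurgical_adhesions
    inflammation = rng.random(n) < spec.concomitant_inflammation_or_infection
    endo = _draw_levels(rng, spec.endometriosis, n)
    cancer = _draw_levels(rng, spec.cancer, n)
    radiation = _draw_levels(rng, spec.radiation, n)
    keloid = rng.random(n) < spec.keloid_scarring
    bleeding_prior = rng.random(n) < spec.prior_intraperitoneal_bleeding
    complications = rng.random(n) < spec.prior_postoperative_complications
    infection = rng.random(n) < spec.prior_postoperative_infection
    # repair: sequelae require at least one previous operation
    no_prior = counts == 0
    bleeding_prior[no_prior] = False
    complications[no_prior] = False
    infection[no_prior] = False

    # --- perioperative columns --------------------------------------------
    quality = _draw_levels(rng, spec.adhesion_quality, n)
    if spec.adhesion_coupling > 0:
        endo_high = np.isin(endo, ("moderate", "severe"))
        upgrade = (rng.random(n) < spec.adhesion_coupling) & endo_high
        quality = np.array(
            [_upgrade_quality(q) if up else q for q, up in zip(quality, upgrade)],
            dtype=object,
        )
    has_adhesions = quality != "none"
    positive = {k: v for k, v in spec.adhesion_severity.items() if k != "none"}
    mass = sum(positive.values())
    if has_adhesions.any():
        if mass <= 0:
            raise ValueError(
                "adhesion_severity must give positive mass to non-'none' levels "
                "when adhesion_quality can be non-'none'"
            )
        positive = {k: v / mass for k, v in positive.items()}
        severity_pos = _draw_levels(rng, positive, n)
        severity = np.where(has_adhesions, severity_pos, "none")
    else:
        severity = np.full(n, "none", dtype=object)
    bleeding500 = rng.random(n) < spec.bleeding_over_500ml
    band = _draw_levels(rng, spec.duration_band, n)
    lo = np.array([_DURATION_RANGES[b][0] for b in band])
    hi = np.array([_DURATION_RANGES[b][1] for b in band])
    duration = rng.integers(lo, hi).astype(float)
    complexity = rng.random(n) < spec.complex_or_multiquadrant
    coagulation = rng.random(n) < spec.excessive_coagulation
    site = _draw_levels(rng, spec.surgery_type_site, n)
    foreign = rng.random(n) < spec.foreign_body_placement
    scalpel = rng.random(n) < spec.electrical_scalpel
    closing = rng.random(n) < spec.peritoneal_closing

    records = []
    for i in range(n):
        records.append(CohortRecord(
            patient_id=f"P{i + 1:05d}",
            preoperative=PreoperativeProfile(
                previous_surgery_count=int(counts[i]),
                history_postsurgical_adhesions=bool(history[i]),
                concomitant_inflammation_or_infection=bool(inflammation[i]),
                endometriosis=endo[i],
                cancer=cancer[i],
                radiation=radiation[i],
                keloid_scarring=bool(keloid[i]),
                prior_intraperitoneal_bleeding=bool(bleeding_prior[i]),
                prior_postoperative_complications=bool(complications[i]),
                prior_postoperative_infection=bool(infection[i]),
            ),
            perioperative=PerioperativeProfile(
                adhesion_quality=quality[i],
                adhesion_severity=str(severity[i]),
                bleeding_over_500ml=bool(bleeding500[i]),
                duration_minutes=float(duration[i]),
                complex_or_multiquadrant=bool(complexity[i]),
                excessive_coagulation=bool(coagulation[i]),
                surgery_type_site=site[i],
                foreign_body_placement=bool(foreign[i]),
                electrical_scalpel=bool(scalpel[i]),
                peritoneal_closing=bool(closing[i]),
            ),
        ))
    return records


_BOOLS = (False, True)


def enumerate_profiles(kind: str) -> tuple[list, int]:
    """Every combination of declared factor levels for one sub-score.

    Returns ``(profiles, n_excluded)`` where ``n_excluded`` counts the
    combinations violating a cross-field rule (preoperative: sequelae with
    no previous operation; perioperative: quality/severity disagreeing on
    the absence of adhesions).  Numeric factors are enumerated over their
    bands via one representative value per band, which is exhaustive for
    the score.  Sizes before exclusion: 14,400 preoperative, 11,520
    perioperative.
    """
    kind = canonical_kind(kind)
    profiles: list = []
    excluded = 0
    if kind == PREOPERATIVE:
        combos = itertools.product(
            (0, 1, 2), _BOOLS, _BOOLS, Endometriosis, Cancer, Radiation,
            _BOOLS, _BOOLS, _BOOLS, _BOOLS,
        )
        for (count, hist, infl, endo, cancer, rad, kel, bleed, comp, infe) in combos:
            if count == 0 and (bleed or comp or infe):
                excluded += 1
                continue
            # valid by construction (the only cross-field rule is excluded
            # above), so skip re-validation for speed
            profiles.append(PreoperativeProfile.model_construct(
                previous_surgery_count=count,
                history_postsurgical_adhesions=hist,
                concomitant_inflammation_or_infection=infl,
                endometriosis=endo,
                cancer=cancer,
                radiation=rad,
                keloid_scarring=kel,
                prior_intraperitoneal_bleeding=bleed,
                prior_postoperative_complications=comp,
                prior_postoperative_infection=infe,
            ))
    else:
        combos = itertools.product(
            AdhesionQuality, AdhesionSeverity, _BOOLS, DURATION_BANDS,
            _BOOLS, _BOOLS, SurgeryTypeSite, _BOOLS, _BOOLS, _BOOLS,
        )
        for (qual, sev, bleed, band, comp, coag, site, foreign, scalp, close) in combos:
            if (qual is AdhesionQuality.NONE) != (sev is AdhesionSeverity.NONE):
                excluded += 1
                continue
            profiles.append(PerioperativeProfile.model_construct(
                adhesion_quality=qual,
                adhesion_severity=sev,
                bleeding_over_500ml=bleed,
                duration_minutes=ENUMERATION_DURATIONS[band],
                complex_or_multiquadrant=comp,
                excessive_coagulation=coag,
                surgery_type_site=site,
                foreign_body_placement=foreign,
                electrical_scalpel=scalp,
                peritoneal_closing=close,
            ))
    return profiles, excluded


def score_range(kind: str) -> tuple[int, int, int]:
    """(min, max, n_enumerated) sub-score over the exhaustive enumeration."""
    from .scoring import score_perioperative, score_preoperative

    kind = canonical_kind(kind)
    profiles, excluded = enumerate_profiles(kind)
    scorer = score_preoperative if kind == PREOPERATIVE else score_perioperative
    scores = [scorer(p).score for p in profiles]
    return min(scores), max(scores), len(profiles) + excluded
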