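"""Sub-score summation, risk stratification and the combined ARS.

Each sub-score is the plain sum of its ten per-factor points.  Risk
categories (low / medium / high) come from fixed integer thresholds:
preoperative 0-12 / 13-24 / 25-36 and perioperative 3-17 / 18-28 / 29-31.
The preoperative cutpoints are the tertiles of the achievable range; the
perioperative cutpoints were adjusted by the consensus panel after field
testing and deviate from exact tertiles — the printed values are
authoritative and are used as-is.  The combined ARS (preoperative +
perioperative) is descriptive only: no combined threshold is defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .risk_model import (
    PERIOPERATIVE_FIELDS,
    PERIOPERATIVE_TABLE,
    PREOPERATIVE_FIELDS,
    PREOPERATIVE_TABLE,
    PerioperativeProfile,
    PreoperativeProfile,
    WeightTable,
    level_token,
)

PREOPERATIVE = "preoperative"
PERIOPERATIVE = "perioperative"
#: the perioperative sub-score is also published as "intraoperative".
KIND_ALIASES = {"intraoperative": PERIOPERATIVE, "pre": PREOPERATIVE, "peri": PERIOPERATIVE}

RISK_CATEGORIES = ("low", "medium", "high")


def canonical_kind(kind: str) -> str:
    """Resolve a sub-score name, accepting the intraoperative alias."""
    k = KIND_ALIASES.get(kind.lower(), kind.lower())
    if k not in (PREOPERATIVE, PERIOPERATIVE):
        raise ValueError(f"unknown sub-score kind {kind!r}")
    return k


@dataclass(frozen=True)
class ThresholdTable:
    """Ordered, non-overlapping low/medium/high intervals per sub-score.

    Intervals are inclusive on both ends and must partition the achievable
    range of each sub-score with no gaps or overlaps.
    """

    preoperative: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"low": (0, 12), "medium": (13, 24), "high": (25, 36)}
    )
    perioperative: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"low": (3, 17), "medium": (18, 28), "high": (29, 31)}
    )

    def __post_init__(self) -> None:
        for kind, table in ((PREOPERATIVE, PREOPERATIVE_TABLE), (PERIOPERATIVE, PERIOPERATIVE_TABLE)):
            intervals = getattr(self, kind)
            if tuple(intervals) != RISK_CATEGORIES:
                raise ValueError(f"{kind} thresholds must define {RISK_CATEGORIES} in order")
            lo, hi = table.min_total(), table.max_total()
            expected_next = lo
            for cat in RISK_CATEGORIES:
                a, b = intervals[cat]
                if a != expected_next or b < a:
                    raise ValueError(
                        f"{kind} {cat} interval {a}-{b} leaves a gap or overlap "
                        f"(expected to start at {expected_next})"
                    )
                expected_next = b + 1
            if expected_next != hi + 1:
                raise ValueError(f"{kind} thresholds must end at {hi}")

    def intervals(self, kind: str) -> Mapping[str, tuple[int, int]]:
        return getattr(self, canonical_kind(kind))


DEFAULT_THRESHOLDS = ThresholdTable()


@dataclass(frozen=True)
class ScoreResult:
    """One sub-score for one patient: total, per-factor breakdown, category."""

    sub_score_kind: str
    score: int
    breakdown: Mapping[str, int]
    risk_category: str

    def __post_init__(self) -> None:
        if self.score != sum(self.breakdown.values()):
            raise ValueError("score must equal the sum of the breakdown")


def classify(score: int, kind: str, thresholds: ThresholdTable = DEFAULT_THRESHOLDS) -> str:
    """Risk category for a sub-score; boundaries are inclusive.

    An out-of-range score raises (it signals a scoring bug upstream and is
    never clamped).
    """
    kind = canonical_kind(kind)
    for category, (lo, hi) in thresholds.intervals(kind).items():
        if lo <= score <= hi:
            return category
    table = PREOPERATIVE_TABLE if kind == PREOPERATIVE else PERIOPERATIVE_TABLE
    raise ValueError(
        f"{kind} score {score} outside achievable range "
        f"[{table.min_total()}, {table.max_total()}]"
    )


def _breakdown(profile, fields: tuple[str, ...], table: WeightTable) -> dict[str, int]:
    return {f: table.points(f, level_token(f, getattr(profile, f))) for f in fields}


def preoperative_breakdown(profile: PreoperativeProfile) -> dict[str, int]:
    """Per-factor points for the ten preoperative factors, in published order."""
    return _breakdown(profile, PREOPERATIVE_FIELDS, PREOPERATIVE_TABLE)


def perioperative_breakdown(profile: PerioperativeProfile) -> dict[str, int]:
    """Per-factor points for the ten intraoperative factors, in published order."""
    return _breakdown(profile, PERIOPERATIVE_FIELDS, PERIOPERATIVE_TABLE)


def score_preoperative(
    profile: PreoperativeProfile, thresholds: ThresholdTable = DEFAULT_THRESHOLDS
) -> ScoreResult:
    """Preoperative Adhesion Risk Score (0-36) with breakdown and category."""
    if not isinstance(profile, PreoperativeProfile):
        profile = PreoperativeProfile.model_validate(profile)
    breakdown = preoperative_breakdown(profile)
    score = sum(breakdown.values())
    return ScoreResult(PREOPERATIVE, score, breakdown, classify(score, PREOPERATIVE, thresholds))


def score_perioperative(
    profile: PerioperativeProfile, thresholds: ThresholdTable = DEFAULT_THRESHOLDS
) -> ScoreResult:
    """Perioperative (intraoperative) Adhesion Risk Score (3-31)."""
    if not isinstance(profile, PerioperativeProfile):
        profile = PerioperativeProfile.model_validate(profile)
    breakdown = perioperative_breakdown(profile)
    score = sum(breakdown.values())
    return ScoreResult(PERIOPERATIVE, score, breakdown, classify(score, PERIOPERATIVE, thresholds))


def total_ars(pre: ScoreResult, peri: ScoreResult) -> int:
    """Combined ARS = preoperative + perioperative score.

    Informational only: it carries no risk category because no combined
    threshold is defined.
    """
    if pre.sub_score_kind != PREOPERATIVE or peri.sub_score_kind != PERIOPERATIVE:
        raise ValueError(
            "total_ars expects (preoperative, perioperative) results, got "
            f"({pre.sub_score_kind}, {peri.sub_score_kind})"
        )
    return pre.score + peri.score
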