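"""Cohort-level summaries of scored records.

For each sub-score present in the cohort, :func:`summarize` tabulates the
low/medium/high risk distribution, a score histogram over the full
achievable range (zero-count bins included), and the factors ranked by mean
contributed points.  Percentages are reported to one decimal; any rounding
residue is assigned to the largest category so the displayed column sums to
100.0.  Summaries depend only on the multiset of records, not their order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io_batch import ScoredRecord
from .risk_model import PERIOPERATIVE_TABLE, PREOPERATIVE_TABLE
from .scoring import PERIOPERATIVE, PREOPERATIVE, RISK_CATEGORIES, ScoreResult


@dataclass(frozen=True)
class SubScoreSummary:
    """Distribution of one sub-score over the scored patients."""

    kind: str
    n: int
    category_counts: Mapping[str, int]
    category_percentages: Mapping[str, float]
    histogram: Mapping[int, int]
    mean_factor_points: tuple[tuple[str, float], ...]  # sorted, heaviest first


@dataclass(frozen=True)
class CohortSummary:
    n_patients: int
    preoperative: SubScoreSummary | None
    perioperative: SubScoreSummary | None

    @property
    def is_empty(self) -> bool:
        """True for the summary of an empty cohort (no crash, no tables)."""
        return self.n_patients == 0


def _percentages(counts: Mapping[str, int], n: int) -> dict[str, float]:
    pcts = {cat: round(100.0 * c / n, 1) for cat, c in counts.items()}
    residue = round(100.0 - sum(pcts.values()), 1)
    if residue:
        largest = max(counts, key=lambda c: (counts[c], -RISK_CATEGORIES.index(c)))
        pcts[largest] = round(pcts[largest] + residue, 1)
    return pcts


def _summarize_kind(kind: str, results: Sequence[ScoreResult]) -> SubScoreSummary | None:
    if not results:
        return None
    table = PREOPERATIVE_TABLE if kind == PREOPERATIVE else PERIOPERATIVE_TABLE
    lo, hi = table.min_total(), table.max_total()
    counts = {cat: 0 for cat in RISK_CATEGORIES}
    histogram = {s: 0 for s in range(lo, hi + 1)}
    factor_totals = {f: 0 for f in table.factors}
    for res in results:
        counts[res.risk_category] += 1
        histogram[res.score] += 1
        for f, pts in res.breakdown.items():
            factor_totals[f] += pts
    n = len(results)
    means = sorted(
        ((f, round(total / n, 3)) for f, total in factor_totals.items()),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return SubScoreSummary(
        kind=kind,
        n=n,
        category_counts=counts,
        category_percentages=_percentages(counts, n),
        histogram=histogram,
        mean_factor_points=tuple(means),
    )


def summarize(scored: Sequence[ScoredRecord]) -> CohortSummary:
    """Summarize a scored cohort; an empty cohort yields an empty marker."""
    pre = [sr.preoperative for sr in scored if sr.preoperative is not None]
    peri = [sr.perioperative for sr in scored if sr.perioperative is not None]
    return CohortSummary(
        n_patients=len(scored),
        preoperative=_summarize_kind(PREOPERATIVE, pre),
        perioperative=_summarize_kind(PERIOPERATIVE, peri),
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def summary_frame(summary: CohortSummary) -> pd.DataFrame:
    """Machine-readable tidy table: one row per (sub_score, metric, key)."""
    rows = []
    for sub in (summary.preoperative, summary.perioperative):
        if sub is None:
            continue
        for cat in RISK_CATEGORIES:
            rows.append((sub.kind, "category_count", cat, sub.category_counts[cat]))
            rows.append((sub.kind, "category_percentage", cat, sub.category_percentages[cat]))
        for score, count in sub.histogram.items():
            rows.append((sub.kind, "score_count", str(score), count))
        for factor, mean in sub.mean_factor_points:
            rows.append((sub.kind, "mean_factor_points", factor, mean))
    return pd.DataFrame(rows, columns=["sub_score", "metric", "key", "value"])


def render_text(summary: CohortSummary, top_factors: int = 5) -> str:
    """Plain-text report of the risk distribution and top contributing factors."""
    if summary.is_empty:
        return "Empty cohort: no patients to summarize.\n"
    lines = [f"Cohort of {summary.n_patients} patient(s)", ""]
    for sub in (summary.preoperative, summary.perioperative):
        if sub is None:
            continue
        lines.append(f"{sub.kind.capitalize()} Adhesion Risk Score (n={sub.n})")
        for cat in RISK_CATEGORIES:
            lines.append(
                f"  {cat:>6} risk: {sub.category_counts[cat]:5d}  "
                f"({sub.category_percentages[cat]:5.1f} %)"
            )
        scores = [s for s, c in sub.histogram.items() for _ in range(c)]
        lines.append(
            f"  scores observed: min {min(scores)}, max {max(scores)}, "
            f"mean {sum(scores) / len(scores):.1f}"
        )
        lines.append("  top contributing factors (mean points):")
        for factor, mean in sub.mean_factor_points[:top_factors]:
            lines.append(f"    {factor:<40} {mean:5.2f}")
        lines.append("")
    return "\n".join(lines)
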