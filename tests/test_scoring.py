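"""Sub-score summation, classification thresholds, and the enumeration oracle."""

from collections import Counter

import pytest
from _oracle import (
    oracle_enumerate_perioperative,
    oracle_enumerate_preoperative,
)
from _perturb import raised_variants

from adhesionrisk import (
    PerioperativeProfile,
    PreoperativeProfile,
    ScoreResult,
    ThresholdTable,
    classify,
    score_perioperative,
    score_preoperative,
    total_ars,
)
from adhesionrisk.synthetic_cohort import (
    PrevalenceSpec,
    enumerate_profiles,
    generate_cohort,
)


class TestWorkedProfiles:
    def test_all_absent_preoperative_scores_zero(self):
        result = score_preoperative(PreoperativeProfile())
        assert result.score == 0
        assert result.risk_category == "low"
        assert len(result.breakdown) == 10
        assert all(pts == 0 for pts in result.breakdown.values())

    def test_maximal_preoperative_scores_36(self, max_preoperative):
        result = score_preoperative(max_preoperative)
        assert result.score == 36
        assert result.risk_category == "high"

    def test_minimal_perioperative_scores_3(self, min_perioperative):
        result = score_perioperative(min_perioperative)
        assert result.score == 3
        assert result.risk_category == "low"
        assert result.breakdown["duration_minutes"] == 2
        assert result.breakdown["surgery_type_site"] == 1

    def test_maximal_perioperative_scores_31(self, max_perioperative):
        result = score_perioperative(max_perioperative)
        assert result.score == 31
        assert result.risk_category == "high"

    def test_single_factor_contributions(self, min_perioperative):
        only_history = score_preoperative(
            PreoperativeProfile(history_postsurgical_adhesions=True)
        )
        assert only_history.score == 4
        with_scalpel = score_perioperative(
            min_perioperative.model_copy(update={"electrical_scalpel": True})
        )
        assert with_scalpel.score == 5


class TestClassify:
    @pytest.mark.parametrize("score, kind, expected", [
        (0, "preoperative", "low"), (12, "preoperative", "low"),
        (13, "preoperative", "medium"), (24, "preoperative", "medium"),
        (25, "preoperative", "high"), (36, "preoperative", "high"),
        (3, "perioperative", "low"), (17, "perioperative", "low"),
        (18, "perioperative", "medium"), (28, "perioperative", "medium"),
        (29, "perioperative", "high"), (31, "perioperative", "high"),
    ])
    def test_published_boundaries_inclusive(self, score, kind, expected):
        assert classify(score, kind) == expected

    @pytest.mark.parametrize("score, kind", [
        (-1, "preoperative"), (37, "preoperative"),
        (2, "perioperative"), (32, "perioperative"),
    ])
    def test_out_of_range_raises_never_clamps(self, score, kind):
        with pytest.raises(ValueError, match="outside achievable range"):
            classify(score, kind)

    def test_intraoperative_alias_accepted(self):
        assert classify(29, "intraoperative") == "high"
        with pytest.raises(ValueError, match="unknown sub-score"):
            classify(5, "postoperative")

    def test_classification_total_and_exclusive(self):
        """Every achievable integer maps to exactly one category."""
        for kind, rng in (("preoperative", range(0, 37)), ("perioperative", range(3, 32))):
            cats = [classify(s, kind) for s in rng]
            assert set(cats) == {"low", "medium", "high"}
            # ordered: low block, then medium, then high
            assert cats == sorted(cats, key=["low", "medium", "high"].index)

    def test_threshold_table_rejects_gaps_and_overlaps(self):
        with pytest.raises(ValueError, match="gap or overlap"):
            ThresholdTable(preoperative={"low": (0, 12), "medium": (14, 24), "high": (25, 36)})
        with pytest.raises(ValueError, match="gap or overlap"):
            ThresholdTable(perioperative={"low": (3, 18), "medium": (18, 28), "high": (29, 31)})
        with pytest.raises(ValueError, match="must end"):
            ThresholdTable(perioperative={"low": (3, 17), "medium": (18, 28), "high": (29, 30)})


class TestTotalArs:
    def test_sum_of_published_extremes(self, max_preoperative, max_perioperative,
                                       min_perioperative):
        pre0 = score_preoperative(PreoperativeProfile())
        assert total_ars(pre0, score_perioperative(min_perioperative)) == 3
        assert total_ars(
            score_preoperative(max_preoperative),
            score_perioperative(max_perioperative),
        ) == 67

    def test_total_carries_no_category(self, min_perioperative):
        total = total_ars(
            score_preoperative(PreoperativeProfile()),
            score_perioperative(min_perioperative),
        )
        assert isinstance(total, int) and not hasattr(total, "risk_category")

    def test_mismatched_kinds_rejected(self, min_perioperative):
        peri = score_perioperative(min_perioperative)
        with pytest.raises(ValueError, match="preoperative, perioperative"):
            total_ars(peri, peri)

    def test_score_result_requires_consistent_breakdown(self):
        with pytest.raises(ValueError, match="sum of the breakdown"):
            ScoreResult("preoperative", 5, {"a": 1, "b": 1}, "low")


class TestEnumerationOracle:
    def test_preoperative_distribution_matches_brute_force(self):
        """Exhaustive enumeration scores agree with an independent transcription."""
        oracle = Counter(score for _, score in oracle_enumerate_preoperative())
        profiles, excluded = enumerate_profiles("preoperative")
        ours = Counter(score_preoperative(p).score for p in profiles)
        assert ours == oracle
        assert min(ours) == 0 and max(ours) == 36
        assert len(profiles) + excluded == 3 * 2 * 2 * 5 * 5 * 3 * 2 * 2 * 2 * 2

    def test_perioperative_distribution_matches_brute_force(self):
        oracle = Counter(score for _, score in oracle_enumerate_perioperative())
        profiles, excluded = enumerate_profiles("perioperative")
        ours = Counter(score_perioperative(p).score for p in profiles)
        assert ours == oracle
        assert min(ours) == 3 and max(ours) == 31
        assert len(profiles) + excluded == 4 * 5 * 2 * 3 * 2 * 2 * 6 * 2 * 2 * 2

    def test_every_intermediate_score_achievable(self):
        pre_scores = {s for _, s in oracle_enumerate_preoperative()}
        peri_scores = {s for _, s in oracle_enumerate_perioperative()}
        assert pre_scores == set(range(0, 37))
        assert peri_scores == set(range(3, 32))


@pytest.fixture(scope="module")
def random_cohort():
    return generate_cohort(200, PrevalenceSpec(seed=11))


class TestProperties:
    def test_monotonic_in_every_factor(self, random_cohort):
        """Raising any single factor to a heavier level never lowers the score."""
        checked = 0
        for rec in random_cohort:
            base_pre = score_preoperative(rec.preoperative).score
            for factor, variant in raised_variants(rec.preoperative):
                assert score_preoperative(variant).score >= base_pre, factor
                checked += 1
            base_peri = score_perioperative(rec.perioperative).score
            for factor, variant in raised_variants(rec.perioperative):
                assert score_perioperative(variant).score >= base_peri, factor
                checked += 1
        assert checked > 1000

    def test_breakdown_conserves_score(self, random_cohort):
        for rec in random_cohort:
            for result in (score_preoperative(rec.preoperative),
                           score_perioperative(rec.perioperative)):
                assert result.score == sum(result.breakdown.values())
                assert len(result.breakdown) == 10
                assert all(0 <= pts <= 4 for pts in result.breakdown.values())
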