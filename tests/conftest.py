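import pytest

from adhesionrisk import PerioperativeProfile, PreoperativeProfile
from adhesionrisk.io_batch import score_cohort
from adhesionrisk.synthetic_cohort import PrevalenceSpec, generate_cohort


@pytest.fixture
def max_preoperative() -> PreoperativeProfile:
    """The published worst-risk preoperative patient (scores 36)."""
    return PreoperativeProfile(
        previous_surgery_count=2,
        history_postsurgical_adhesions=True,
        concomitant_inflammation_or_infection=True,
        endometriosis="severe",
        cancer="local_non_gynaecological",
        radiation="local",
        keloid_scarring=True,
        prior_intraperitoneal_bleeding=True,
        prior_postoperative_complications=True,
        prior_postoperative_infection=True,
    )


@pytest.fixture
def min_perioperative() -> PerioperativeProfile:
    """The published best-case operation (scores 3 = 2 duration + 1 site)."""
    return PerioperativeProfile(
        duration_minutes=60,
        surgery_type_site="laparoscopy_fallopian_tube",
    )


@pytest.fixture
def max_perioperative() -> PerioperativeProfile:
    """The published worst-case operation (scores 31)."""
    return PerioperativeProfile(
        adhesion_quality="dense",
        adhesion_severity="bowel_involvement",
        bleeding_over_500ml=True,
        duration_minutes=180,
        complex_or_multiquadrant=True,
        excessive_coagulation=True,
        surgery_type_site="open_ovary",
        foreign_body_placement=True,
        electrical_scalpel=True,
        peritoneal_closing=True,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """100 seeded synthetic patients with both profiles."""
    return generate_cohort(100, PrevalenceSpec(seed=42))


@pytest.fixture(scope="session")
def small_scored(small_cohort):
    return score_cohort(small_cohort)
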