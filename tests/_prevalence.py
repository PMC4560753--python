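"""Shared empirical-prevalence convergence check for generated cohorts."""

from __future__ import annotations

import math

from adhesionrisk.risk_model import level_token
from adhesionrisk.synthetic_cohort import PrevalenceSpec

_BOOLEAN_FIELDS = (
    ("history_postsurgical_adhesions", "pre"),
    ("concomitant_inflammation_or_infection", "pre"),
    ("keloid_scarring", "pre"),
    ("bleeding_over_500ml", "peri"),
    ("complex_or_multiquadrant", "peri"),
    ("excessive_coagulation", "peri"),
    ("foreign_body_placement", "peri"),
    ("electrical_scalpel", "peri"),
    ("peritoneal_closing", "peri"),
)

_LEVEL_FIELDS = (
    ("previous_surgery_count", "pre", "previous_surgery_count"),
    ("endometriosis", "pre", "endometriosis"),
    ("cancer", "pre", "cancer"),
    ("radiation", "pre", "radiation"),
    ("adhesion_quality", "peri", "adhesion_quality"),
    ("duration_minutes", "peri", "duration_band"),
    ("surgery_type_site", "peri", "surgery_type_site"),
)


def _within(phat: float, p: float, m: int, n_se: float) -> bool:
    se = math.sqrt(max(p * (1 - p), 1e-12) / m)
    return abs(phat - p) <= n_se * se + 1e-9


def convergence_failures(records, spec: PrevalenceSpec, n_se: float = 3.0) -> list:
    """Factors/levels whose empirical prevalence strays beyond ``n_se`` SEs.

    Masked factors are checked conditionally: prior-operation sequelae among
    patients with at least one previous surgery, and positive severity
    levels among patients with existing adhesions.
    """
    n = len(records)
    pre = [r.preoperative for r in records]
    peri = [r.perioperative for r in records]
    groups = {"pre": pre, "peri": peri}
    failures = []
    for field, which in _BOOLEAN_FIELDS:
        profiles = groups[which]
        phat = sum(getattr(x, field) for x in profiles) / n
        if not _within(phat, getattr(spec, field), n, n_se):
            failures.append((field, phat))
    for field, which, spec_name in _LEVEL_FIELDS:
        profiles = groups[which]
        for token, p in getattr(spec, spec_name).items():
            phat = sum(level_token(field, getattr(x, field)) == token
                       for x in profiles) / n
            if not _within(phat, p, n, n_se):
                failures.append((field, token, phat))
    with_prior = [x for x in pre if x.previous_surgery_count >= 1]
    m = len(with_prior)
    for field in ("prior_intraperitoneal_bleeding",
                  "prior_postoperative_complications",
                  "prior_postoperative_infection"):
        phat = sum(getattr(x, field) for x in with_prior) / m
        if not _within(phat, getattr(spec, field), m, n_se):
            failures.append((field, phat))
    with_adh = [x for x in peri if str(x.adhesion_quality) != "none"]
    m = len(with_adh)
    pos_mass = sum(v for k, v in spec.adhesion_severity.items() if k != "none")
    for token, p in spec.adhesion_severity.items():
        if token == "none":
            continue
        phat = sum(str(x.adhesion_severity) == token for x in with_adh) / m
        if not _within(phat, p / pos_mass, m, n_se):
            failures.append(("adhesion_severity", token, phat))
    return failures
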