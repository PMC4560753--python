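"""Single-factor perturbation helper for monotonicity checks."""

from __future__ import annotations

import pydantic

from adhesionrisk.risk_model import (
    PERIOPERATIVE_TABLE,
    PREOPERATIVE_TABLE,
    PerioperativeProfile,
    PreoperativeProfile,
    level_token,
)

#: a representative raw value for each band token.
_BAND_VALUES = {
    "previous_surgery_count": {"0": 0, "1": 1, ">1": 2},
    "duration_minutes": {"<90": 60.0, "90-120": 100.0, ">120": 180.0},
}


def raised_variants(profile):
    """Yield copies of ``profile`` with one factor moved to a heavier level.

    Variants that violate a cross-field rule (e.g. setting a sequela of a
    previous operation on a patient with none) are skipped: they are not
    reachable states.
    """
    cls = type(profile)
    table = PREOPERATIVE_TABLE if cls is PreoperativeProfile else PERIOPERATIVE_TABLE
    data = profile.model_dump()
    for factor, levels in table.factors.items():
        current = levels[level_token(factor, getattr(profile, factor))]
        for token, pts in levels.items():
            if pts <= current:
                continue
            if factor in _BAND_VALUES:
                raw = _BAND_VALUES[factor][token]
            elif token in ("true", "false"):
                raw = token == "true"
            else:
                raw = token
            try:
                yield factor, cls(**{**data, factor: raw})
            except pydantic.ValidationError:
                continue
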