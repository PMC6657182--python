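"""The five-class smoking-status label set and its risk-precedence order.

Clinical smoking documentation distinguishes five situations: the patient
smokes now (CURRENT), smoked in the past (FORMER), is documented as a smoker
without temporal anchoring (SMOKER_TEMPORALITY_UNKNOWN), has never smoked
(NEVER), or the record carries no usable smoking information (UNKNOWN).

When two record sources disagree, registries keep the *worst* label — the
one implying the highest health risk — under the total order

    CURRENT > FORMER > SMOKER_TEMPORALITY_UNKNOWN > NEVER > UNKNOWN.

That order is encoded here once, as an integer ``precedence``, so every
merge is a plain maximum over it.
"""

from __future__ import annotations

import enum


class SmokingStatus(enum.Enum):
    CURRENT = "current"
    FORMER = "former"
    SMOKER_TEMPORALITY_UNKNOWN = "smoker_temporality_unknown"
    NEVER = "never"
    UNKNOWN = "unknown"

    @property
    def precedence(self) -> int:
        """Risk rank; higher wins a worst-label merge."""
        return _PRECEDENCE[self]

    @classmethod
    def from_string(cls, value: str) -> "SmokingStatus":
        v = value.strip().lower()
        if v in _ALIASES:
            return _ALIASES[v]
        raise ValueError(f"unrecognized smoking status: {value!r}")

    def __str__(self) -> str:  # serialized form
        return self.value


_PRECEDENCE = {
    SmokingStatus.UNKNOWN: 0,
    SmokingStatus.NEVER: 1,
    SmokingStatus.SMOKER_TEMPORALITY_UNKNOWN: 2,
    SmokingStatus.FORMER: 3,
    SmokingStatus.CURRENT: 4,
}

_ALIASES = {
    "current": SmokingStatus.CURRENT,
    "current smoker": SmokingStatus.CURRENT,
    "former": SmokingStatus.FORMER,
    "former smoker": SmokingStatus.FORMER,
    "smoker_temporality_unknown": SmokingStatus.SMOKER_TEMPORALITY_UNKNOWN,
    "smoker temporality unknown": SmokingStatus.SMOKER_TEMPORALITY_UNKNOWN,
    "smoker": SmokingStatus.SMOKER_TEMPORALITY_UNKNOWN,
    "never": SmokingStatus.NEVER,
    "never smoker": SmokingStatus.NEVER,
    "unknown": SmokingStatus.UNKNOWN,
}

#: The four labels a trained classifier may emit; UNKNOWN is assigned by the
#: deterministic no-hotspot rule upstream of any model.
INFORMATIVE_STATUSES = (
    SmokingStatus.CURRENT,
    SmokingStatus.FORMER,
    SmokingStatus.SMOKER_TEMPORALITY_UNKNOWN,
    SmokingStatus.NEVER,
)
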