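"""Worst-label merging of record sources and screening-eligibility rules.

A registry entry combines the NLP-derived behaviors with the semi-structured
EHR fields. Discordant statuses resolve to the *worst* label (the maximum
under CURRENT > FORMER > SMOKER_TEMPORALITY_UNKNOWN > NEVER > UNKNOWN), and
discordant pack-year estimates to the highest value — both choices favor
sensitivity for smoking-related services.

Lung-cancer-screening eligibility follows the guideline phenotype: a current
smoker, or a former smoker who quit within the past 15 years, with at least
a 30 pack-year history. A documented smoker of unknown temporality is
treated as a smoker (it outranks NEVER in the precedence order) and, like a
former smoker with no recorded quit date, is assumed recently quit when
``assume_recent_quit`` is set — the stance taken when no cessation dates are
available to check the 15-year window.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass
from typing import Optional

from .status import SmokingStatus

DEFAULT_PACK_YEAR_THRESHOLD = 30.0
DEFAULT_QUIT_WINDOW_YEARS = 15


def merge_status(a: SmokingStatus, b: Optional[SmokingStatus]) -> SmokingStatus:
    """Worst-label merge: precedence-maximum of the available statuses."""
    if b is None:
        return a
    return a if a.precedence >= b.precedence else b


def merge_pack_years(a: Optional[float], b: Optional[float]) -> Optional[float]:
    """Highest pack-year estimate across sources; None when both absent."""
    for v in (a, b):
        if v is not None and v < 0:
            raise ValueError("pack years must be non-negative")
    present = [v for v in (a, b) if v is not None]
    return max(present) if present else None


def collapse_ever_never(s: SmokingStatus) -> str:
    """Ever/never simplification; any documented smoker counts as ever."""
    if s is SmokingStatus.NEVER:
        return "never"
    if s is SmokingStatus.UNKNOWN:
        return "unknown"
    return "ever"


@dataclass(frozen=True)
class SmokingProfile:
    """Merged per-patient registry record."""

    patient_id: str
    status_nlp: SmokingStatus
    status_semi: Optional[SmokingStatus] = None
    pack_years_nlp: Optional[float] = None
    pack_years_semi: Optional[float] = None
    cessation_date: Optional[dt.date] = None
    note_source: bool = True
    semi_source: bool = False

    @property
    def status_merged(self) -> SmokingStatus:
        return merge_status(self.status_nlp, self.status_semi)

    @property
    def pack_years_merged(self) -> Optional[float]:
        return merge_pack_years(self.pack_years_nlp, self.pack_years_semi)


class Verdict(enum.Enum):
    ELIGIBLE = "eligible"
    NOT_ELIGIBLE = "not_eligible"
    MISSING_DATA = "missing_data"


class Reason(enum.Enum):
    STATUS_UNKNOWN = "status_unknown"
    NO_PACK_YEARS = "no_pack_years"
    BELOW_THRESHOLD = "below_threshold"
    NEVER_SMOKER = "never_smoker"
    MEETS_CRITERIA = "meets_criteria"
    QUIT_TOO_LONG_AGO = "quit_too_long_ago"


@dataclass(frozen=True)
class EligibilityResult:
    verdict: Verdict
    reason: Reason

    def __post_init__(self) -> None:
        missing = self.reason in (Reason.STATUS_UNKNOWN, Reason.NO_PACK_YEARS)
        assert (self.verdict is Verdict.MISSING_DATA) == missing


def assess_eligibility(
    profile: SmokingProfile,
    *,
    threshold: float = DEFAULT_PACK_YEAR_THRESHOLD,
    inclusive: bool = True,
    quit_window_years: int = DEFAULT_QUIT_WINDOW_YEARS,
    assume_recent_quit: bool = True,
    reference_date: Optional[dt.date] = None,
) -> EligibilityResult:
    """Screening-eligibility verdict for a merged profile.

    ``inclusive`` controls whether exactly ``threshold`` pack years counts
    as meeting the history criterion (default: it does). ``reference_date``
    anchors the quit window; it defaults to today when unset, but pipeline
    callers pass the note date (cross-sectional design).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    status = profile.status_merged
    if status is SmokingStatus.UNKNOWN:
        return EligibilityResult(Verdict.MISSING_DATA, Reason.STATUS_UNKNOWN)
    if status is SmokingStatus.NEVER:
        return EligibilityResult(Verdict.NOT_ELIGIBLE, Reason.NEVER_SMOKER)
    py = profile.pack_years_merged
    if py is None:
        return EligibilityResult(Verdict.MISSING_DATA, Reason.NO_PACK_YEARS)
    meets_history = py >= threshold if inclusive else py > threshold
    if not meets_history:
        return EligibilityResult(Verdict.NOT_ELIGIBLE, Reason.BELOW_THRESHOLD)
    if status is SmokingStatus.CURRENT:
        return EligibilityResult(Verdict.ELIGIBLE, Reason.MEETS_CRITERIA)
    # FORMER or SMOKER_TEMPORALITY_UNKNOWN: the quit window applies.
    if profile.cessation_date is not None:
        ref = reference_date or dt.date.today()
        cutoff_year_date = dt.date(
            ref.year - quit_window_years, ref.month, min(ref.day, 28)
        )
        if profile.cessation_date >= cutoff_year_date:
            return EligibilityResult(Verdict.ELIGIBLE, Reason.MEETS_CRITERIA)
        return EligibilityResult(Verdict.NOT_ELIGIBLE, Reason.QUIT_TOO_LONG_AGO)
    if assume_recent_quit:
        return EligibilityResult(Verdict.ELIGIBLE, Reason.MEETS_CRITERIA)
    return EligibilityResult(Verdict.NOT_ELIGIBLE, Reason.QUIT_TOO_LONG_AGO)


def build_profile(
    patient_id: str,
    status_nlp: SmokingStatus,
    pack_years_nlp: Optional[float],
    cessation_date: Optional[dt.date],
    semi: Optional["SemiStructuredRecord"] = None,
) -> SmokingProfile:
    """Assemble a profile from pipeline outputs and an optional coded record."""
    return SmokingProfile(
        patient_id=patient_id,
        status_nlp=status_nlp,
        status_semi=None if semi is None else semi.status,
        pack_years_nlp=pack_years_nlp,
        pack_years_semi=None if semi is None else semi.pack_years,
        cessation_date=cessation_date,
        note_source=True,
        semi_source=semi is not None,
    )
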