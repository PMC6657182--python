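"""Worst-label merging, ever/never collapse, and screening eligibility."""

import datetime as dt
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smokereg.merge import (
    Reason,
    SmokingProfile,
    Verdict,
    assess_eligibility,
    collapse_ever_never,
    merge_pack_years,
    merge_status,
)
from smokereg.status import SmokingStatus

ALL = list(SmokingStatus)
REF = dt.date(2016, 4, 1)


def test_merge_status_is_max_over_total_order():
    for a, b in itertools.product(ALL, ALL):
        assert merge_status(a, b) is max(a, b, key=lambda s: s.precedence)


def test_merge_status_algebraic_properties():
    for a, b in itertools.product(ALL, ALL):
        assert merge_status(a, b) is merge_status(b, a)
        assert merge_status(a, a) is a
        for c in ALL:
            assert merge_status(merge_status(a, b), c) is merge_status(a, merge_status(b, c))
    assert merge_status(SmokingStatus.UNKNOWN, None) is SmokingStatus.UNKNOWN


def test_worst_label_examples():
    assert (
        merge_status(SmokingStatus.SMOKER_TEMPORALITY_UNKNOWN, SmokingStatus.CURRENT)
        is SmokingStatus.CURRENT
    )
    assert merge_status(SmokingStatus.NEVER, SmokingStatus.FORMER) is SmokingStatus.FORMER


def test_merge_pack_years():
    assert merge_pack_years(25, 40) == 40
    assert merge_pack_years(None, 10) == 10
    assert merge_pack_years(None, None) is None
    with pytest.raises(ValueError):
        merge_pack_years(-1, 10)


def test_collapse_ever_never():
    assert collapse_ever_never(SmokingStatus.CURRENT) == "ever"
    assert collapse_ever_never(SmokingStatus.FORMER) == "ever"
    assert collapse_ever_never(SmokingStatus.SMOKER_TEMPORALITY_UNKNOWN) == "ever"
    assert collapse_ever_never(SmokingStatus.NEVER) == "never"
    assert collapse_ever_never(SmokingStatus.UNKNOWN) == "unknown"


def _profile(status, pack_years=None, cessation=None):
    return SmokingProfile(
        patient_id="p",
        status_nlp=status,
        pack_years_nlp=pack_years,
        cessation_date=cessation,
    )


@pytest.mark.parametrize(
    "profile,verdict,reason",
    [
        (_profile(SmokingStatus.CURRENT, 35), Verdict.ELIGIBLE, Reason.MEETS_CRITERIA),
        (_profile(SmokingStatus.FORMER, 40), Verdict.ELIGIBLE, Reason.MEETS_CRITERIA),
        (
            _profile(SmokingStatus.FORMER, 50, dt.date(1996, 4, 1)),
            Verdict.NOT_ELIGIBLE,
            Reason.QUIT_TOO_LONG_AGO,
        ),
        (_profile(SmokingStatus.CURRENT), Verdict.MISSING_DATA, Reason.NO_PACK_YEARS),
        (_profile(SmokingStatus.UNKNOWN), Verdict.MISSING_DATA, Reason.STATUS_UNKNOWN),
        (_profile(SmokingStatus.NEVER), Verdict.NOT_ELIGIBLE, Reason.NEVER_SMOKER),
        (_profile(SmokingStatus.CURRENT, 12), Verdict.NOT_ELIGIBLE, Reason.BELOW_THRESHOLD),
        (
            _profile(SmokingStatus.FORMER, 45, dt.date(2010, 6, 1)),
            Verdict.ELIGIBLE,
            Reason.MEETS_CRITERIA,
        ),
    ],
)
def test_eligibility_cases(profile, verdict, reason):
    r = assess_eligibility(profile, reference_date=REF)
    assert (r.verdict, r.reason) == (verdict, reason)


def test_threshold_boundary_inclusive_by_default():
    at = _profile(SmokingStatus.CURRENT, 30.0)
    assert assess_eligibility(at, reference_date=REF).verdict is Verdict.ELIGIBLE
    strict = assess_eligibility(at, inclusive=False, reference_date=REF)
    assert strict.verdict is Verdict.NOT_ELIGIBLE


def test_semi_structured_source_participates_in_merge():
    p = SmokingProfile(
        patient_id="p",
        status_nlp=SmokingStatus.SMOKER_TEMPORALITY_UNKNOWN,
        status_semi=SmokingStatus.CURRENT,
        pack_years_nlp=10.0,
        pack_years_semi=35.0,
    )
    assert p.status_merged is SmokingStatus.CURRENT
    assert p.pack_years_merged == 35.0
    assert assess_eligibility(p, reference_date=REF).verdict is Verdict.ELIGIBLE


@settings(deadline=None)
@given(
    st.sampled_from(ALL),
    st.floats(0, 120, allow_nan=False),
    st.floats(0, 80, allow_nan=False),
)
def test_eligibility_monotone_in_pack_years(status, py, bump):
    """Raising pack years never flips an eligible profile to not eligible."""
    lo = assess_eligibility(_profile(status, py), reference_date=REF)
    hi = assess_eligibility(_profile(status, py + bump), reference_date=REF)
    if lo.verdict is Verdict.ELIGIBLE:
        assert hi.verdict is Verdict.ELIGIBLE
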