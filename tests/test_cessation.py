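"""Quit-sentence selection and cessation-date normalization."""

import datetime as dt

import pytest

from smokereg.cessation import (
    DateResolution,
    extract_cessation_date,
    note_cessation_date,
    select_quit_sentences,
)

NOTE_DATE = dt.date(2016, 4, 1)


def test_quit_selection_requires_smoking_root():
    sentences = [
        "Quit smoking in 2005.",
        "Stop taking aspirin before surgery.",
        "Metoprolol 25 mg qd.",
        "Stopped all tobacco use last year.",
    ]
    assert [i for i, _ in select_quit_sentences(sentences)] == [0, 3]
    ungated = select_quit_sentences(sentences, require_smoking_root=False)
    assert [i for i, _ in ungated] == [0, 1, 2, 3]


@pytest.mark.parametrize(
    "sentence,date,resolution,relative",
    [
        ("quit smoking in 2005", dt.date(2005, 1, 1), DateResolution.YEAR, False),
        ("quit 10 years ago", dt.date(2006, 1, 1), DateResolution.YEAR, True),
        ("quit smoking ten years ago", dt.date(2006, 1, 1), DateResolution.YEAR, True),
        ("quit smoking 6 months ago", dt.date(2015, 10, 1), DateResolution.MONTH, True),
        ("quit smoking January 2005", dt.date(2005, 1, 1), DateResolution.MONTH, False),
        ("quit smoking on 3/15/2010", dt.date(2010, 3, 15), DateResolution.DAY, False),
    ],
)
def test_date_normalization(sentence, date, resolution, relative):
    f = extract_cessation_date(sentence, NOTE_DATE)
    assert f is not None
    assert (f.date, f.resolution, f.relative) == (date, resolution, relative)


def test_no_date_and_ambiguous_forms_yield_absent():
    assert extract_cessation_date("quit smoking for good", NOTE_DATE) is None
    # two-digit years are ambiguous and rejected
    assert extract_cessation_date("quit smoking in '05", NOTE_DATE) is None


def test_future_dates_rejected():
    assert extract_cessation_date("quit smoking in 2020", NOTE_DATE) is None
    assert extract_cessation_date("quit smoking 12/31/2016", NOTE_DATE) is None


def test_most_recent_quit_date_retained():
    text = "Quit smoking in 1999. Restarted, then quit smoking again in 2010."
    f = note_cessation_date(text, NOTE_DATE)
    assert f is not None and f.date == dt.date(2010, 1, 1)


def test_medication_traps_do_not_produce_findings():
    text = "Metoprolol 25 mg qd. Stop aspirin 7 days before the procedure."
    assert note_cessation_date(text, NOTE_DATE) is None


def test_extraction_never_after_note_date_and_deterministic():
    text = "Quit smoking 2 years ago."
    f1 = note_cessation_date(text, NOTE_DATE)
    f2 = note_cessation_date(text, NOTE_DATE)
    assert f1 == f2
    assert f1.date <= NOTE_DATE
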