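"""Quit-statement detection and cessation-date normalization.

Sentences carrying a quit cue ("quit", "qd", "stop...") are scanned for a
date, which is normalized to a calendar date at its native resolution:
full dates keep the day, month+year forms pin the day to 1, bare four-digit
years pin to January 1. Relative forms ("quit 10 years ago") are resolved
against the note date. Because "stop" and "qd" saturate medication text
("stop aspirin", "metoprolol 25 mg qd"), quit sentences are additionally
gated on containing a smoking hotspot root; the gate is toggleable.

Extracted dates later than the note date are rejected — a clinical note
cannot report a quit that has not happened yet.
"""

from __future__ import annotations

import calendar
import datetime as dt
import enum
import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .hotspots import DEFAULT_ROOTS, tokenize
from .packyears import _TENS, _UNITS, split_sentences

DEFAULT_CUES: tuple[str, ...] = ("quit", "qd", "stop")


class DateResolution(enum.Enum):
    DAY = "day"
    MONTH = "month"
    YEAR = "year"


@dataclass(frozen=True)
class CessationFinding:
    date: dt.date
    resolution: DateResolution
    relative: bool
    sentence_index: int


_MONTHS = {name.lower(): i for i, name in enumerate(calendar.month_name) if name}
_MONTHS.update({name.lower(): i for i, name in enumerate(calendar.month_abbr) if name})

_FULL_DATE_RE = re.compile(r"\b(\d{1,2})[/-](\d{1,2})[/-](\d{4})\b")
_MONTH_YEAR_NUM_RE = re.compile(r"\b(\d{1,2})[/-](\d{4})\b")
_YEAR_RE = re.compile(r"\b(19\d{2}|20\d{2})\b")
_NUM_WORDS = sorted(
    {"a", *_UNITS, *_TENS, *(f"{t} {u}" for t in _TENS for u in _UNITS if _UNITS[u] < 10)},
    key=len,
    reverse=True,
)
_RELATIVE_RE = re.compile(
    r"\b(\d{1,3}|"
    + "|".join(w.replace(" ", "[ -]") for w in _NUM_WORDS)
    + r")\s+(years?|yrs?|months?|mos?)\s+ago\b"
)


def select_quit_sentences(
    sentences: Sequence[str],
    cues: Sequence[str] = DEFAULT_CUES,
    *,
    require_smoking_root: bool = True,
    roots: Sequence[str] = DEFAULT_ROOTS,
) -> list[tuple[int, str]]:
    """Indexed sentences with a quit cue ("qd" exact; others token-prefix).

    With the default gate on, the sentence must also contain a smoking
    hotspot root — otherwise medication lines ("stop aspirin", "25 mg qd")
    dominate the output.
    """
    exact = {c for c in cues if len(c) <= 2}
    prefixes = tuple(c for c in cues if len(c) > 2)
    out = []
    for i, sent in enumerate(sentences):
        tokens = tokenize(sent)
        cued = any(t in exact or (prefixes and t.startswith(prefixes)) for t in tokens)
        if not cued:
            continue
        if require_smoking_root and not any(
            t.startswith(tuple(roots)) for t in tokens
        ):
            continue
        out.append((i, sent))
    return out


def _word_number(phrase: str) -> Optional[int]:
    toks = re.split(r"[ -]", phrase.strip().lower())
    if len(toks) == 1:
        if toks[0] in _UNITS:
            return _UNITS[toks[0]]
        if toks[0] in _TENS:
            return _TENS[toks[0]]
        if toks[0] == "a":  # "a year ago"
            return 1
        return None
    if len(toks) == 2 and toks[0] in _TENS and toks[1] in _UNITS:
        return _TENS[toks[0]] + _UNITS[toks[1]]
    return None


def _months_back(note_date: dt.date, n: int) -> dt.date:
    total = note_date.year * 12 + (note_date.month - 1) - n
    return dt.date(total // 12, total % 12 + 1, 1)


def extract_cessation_date(
    sentence: str,
    note_date: dt.date,
    *,
    sentence_index: int = 0,
) -> Optional[CessationFinding]:
    """Normalize the date in a quit-selected sentence; None when absent.

    Tried in order: relative ("N years/months ago"), full numeric date,
    month-name + year, numeric month/year, bare four-digit year. Two-digit
    years are never accepted (ambiguous century), and any resolved date
    after the note date is rejected.
    """
    low = sentence.lower()

    m = _RELATIVE_RE.search(low)
    if m:
        qty: Optional[int]
        if m.group(1).isdigit():
            qty = int(m.group(1))
        else:
            qty = _word_number(m.group(1))
        if qty is not None:
            unit = m.group(2)
            if unit.startswith(("year", "yr")):
                date = dt.date(note_date.year - qty, 1, 1)
                res = DateResolution.YEAR
            else:
                date = _months_back(note_date, qty)
                res = DateResolution.MONTH
            if date <= note_date:
                return CessationFinding(date, res, True, sentence_index)
            return None

    m = _FULL_DATE_RE.search(low)
    if m:
        mo, day, yr = int(m.group(1)), int(m.group(2)), int(m.group(3))
        try:
            date = dt.date(yr, mo, day)
        except ValueError:
            date = None
        if date is not None and date <= note_date:
            return CessationFinding(date, DateResolution.DAY, False, sentence_index)
        return None

    m = re.search(r"\b([a-z]+)\.?,?\s+(\d{1,2})?,?\s*(19\d{2}|20\d{2})\b", low)
    if m and m.group(1) in _MONTHS:
        mo, yr = _MONTHS[m.group(1)], int(m.group(3))
        if m.group(2):
            try:
                date = dt.date(yr, mo, int(m.group(2)))
                res = DateResolution.DAY
            except ValueError:
                date, res = None, None
        else:
            date, res = dt.date(yr, mo, 1), DateResolution.MONTH
        if date is not None and date <= note_date:
            return CessationFinding(date, res, False, sentence_index)
        return None

    m = _MONTH_YEAR_NUM_RE.search(low)
    if m and 1 <= int(m.group(1)) <= 12:
        date = dt.date(int(m.group(2)), int(m.group(1)), 1)
        if date <= note_date:
            return CessationFinding(date, DateResolution.MONTH, False, sentence_index)
        return None

    m = _YEAR_RE.search(low)
    if m:
        date = dt.date(int(m.group(1)), 1, 1)
        if date <= note_date:
            return CessationFinding(date, DateResolution.YEAR, False, sentence_index)
        return None

    return None


def note_cessation_date(
    text: str,
    note_date: dt.date,
    *,
    cues: Sequence[str] = DEFAULT_CUES,
    require_smoking_root: bool = True,
) -> Optional[CessationFinding]:
    """Most recent cessation finding in a note (latest quit governs
    screening windows); None when no quit date is found."""
    sentences = split_sentences(text)
    findings = []
    for idx, sent in select_quit_sentences(
        sentences, cues, require_smoking_root=require_smoking_root
    ):
        f = extract_cessation_date(sent, note_date, sentence_index=idx)
        if f is not None:
            findings.append(f)
    if not findings:
        return None
    return max(findings, key=lambda f: f.date)
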