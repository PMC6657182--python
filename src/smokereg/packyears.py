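"""Pack-year extraction from clinical-note sentences.

A pack year is cumulative exposure: packs smoked per day × years smoked,
with one pack = 20 cigarettes. Notes state this history in wildly varied
surface forms — "2 ppd x 20 yrs", "40 pack year history", "smoked twenty
cigarettes a day for thirty years" — so extraction is staged:

1. split the note into sentences (terminator-based, with guards for common
   clinical abbreviations);
2. keep sentences containing one of the pack-year stems
   (``cig smok pk ppd pack pak pkyr``);
3. parse numbers out of each kept sentence, accepting numerals, decimals,
   simple fractions, and spelled-out numbers up to one hundred;
4. interpret: two numbers ⇒ frequency × duration product (cigarette
   frequencies divided by 20 first); one number ⇒ classified by adjacent
   unit cues as a stated pack-year total, a bare frequency, or a bare
   duration — the last two carry no pack-year value on their own;
5. optionally drop low stated values (a precision heuristic: very small
   "pack year" statements are usually partial histories misread as totals;
   computed products are exempt because both components were observed).

The document-level value is the maximum over surviving full findings,
mirroring the registry's keep-the-highest merge rule.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .hotspots import tokenize

#: Sentence-selection stems. Stems of length >= 3 match as token prefixes;
#: the short, collision-prone "pk" and "ppd" require an exact token.
DEFAULT_STEMS: tuple[str, ...] = ("cig", "smok", "pk", "ppd", "pack", "pak", "pkyr")

#: Cigarettes per pack, for converting cigarette frequencies.
CIGARETTES_PER_PACK = 20.0

#: Numbers above this are rejected as pack-year candidates (dates, labs).
MAX_PLAUSIBLE_VALUE = 200.0

#: Default low-value cutoff: lower bound of the 5-15 heuristic range.
DEFAULT_CUTOFF = 5.0


class FindingKind(enum.Enum):
    COMPUTED_PRODUCT = "computed_product"
    STATED_PACK_YEARS = "stated_pack_years"
    FREQUENCY_ONLY = "frequency_only"
    DURATION_ONLY = "duration_only"


@dataclass(frozen=True)
class PackYearFinding:
    """An extracted pack-year quantity with its provenance."""

    kind: FindingKind
    sentence_index: int
    matched_stem: str
    pack_years: Optional[float] = None
    packs_per_day: Optional[float] = None
    years_smoked: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind is FindingKind.COMPUTED_PRODUCT:
            assert self.pack_years is not None
        if self.kind in (FindingKind.FREQUENCY_ONLY, FindingKind.DURATION_ONLY):
            assert self.pack_years is None


# ---------------------------------------------------------------------------
# Sentence splitting

# Periods after these tokens do not end a sentence.
_ABBREVIATIONS = {
    "pt", "hx", "dr", "mr", "mrs", "ms", "st", "vs", "approx", "etc",
    "dx", "rx", "fx", "tx", "no",
}

_TERMINATOR_RE = re.compile(r"[.!?\n]")
_WORD_BEFORE_RE = re.compile(r"([A-Za-z]+)$")


def split_sentences(text: str) -> list[str]:
    """Deterministic terminator-based sentence splitting.

    ``.`` is a boundary unless it sits inside a decimal number, follows a
    single letter (covers dotted abbreviations like "b.i.d."), or follows a
    guarded clinical abbreviation ("pt.", "hx.", ...).
    """
    sentences: list[str] = []
    start = 0
    for m in _TERMINATOR_RE.finditer(text):
        i = m.start()
        ch = m.group()
        if ch == ".":
            before = text[start:i]
            after = text[i + 1 : i + 2]
            if before and before[-1].isdigit() and after.isdigit():
                continue  # decimal point
            w = _WORD_BEFORE_RE.search(before)
            if w and (len(w.group(1)) == 1 or w.group(1).lower() in _ABBREVIATIONS):
                continue
        chunk = text[start:i].strip()
        if chunk:
            sentences.append(chunk)
        start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def select_packyear_sentences(
    sentences: Sequence[str], stems: Sequence[str] = DEFAULT_STEMS
) -> list[tuple[int, str]]:
    """Indexed subset of sentences containing a pack-year stem."""
    exact = {s for s in stems if len(s) < 3}
    prefixes = tuple(s for s in stems if len(s) >= 3)
    out = []
    for i, sent in enumerate(sentences):
        for tok in tokenize(sent):
            if tok in exact or tok.startswith(prefixes):
                out.append((i, sent))
                break
    return out


def _matched_stem(sentence: str, stems: Sequence[str] = DEFAULT_STEMS) -> str:
    exact = {s for s in stems if len(s) < 3}
    for tok in tokenize(sentence):
        for s in stems:
            if (len(s) < 3 and tok == s) or (len(s) >= 3 and tok.startswith(s)):
                return s
    return ""


# ---------------------------------------------------------------------------
# Number parsing

_UNITS = {
    "one": 1, "two": 2, "three": 3, "four": 4, "five": 5, "six": 6,
    "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11,
    "twelve": 12, "thirteen": 13, "fourteen": 14, "fifteen": 15,
    "sixteen": 16, "seventeen": 17, "eighteen": 18, "nineteen": 19,
}
_TENS = {
    "twenty": 20, "thirty": 30, "forty": 40, "fifty": 50,
    "sixty": 60, "seventy": 70, "eighty": 80, "ninety": 90,
}

_FRACTION_RE = re.compile(r"^(\d+)/(\d)$")


@dataclass(frozen=True)
class ParsedNumber:
    value: float
    surface: str  # "numeral" or "word"
    token_end: int  # index one past the last token of the number


def parse_numbers(sentence: str) -> list[ParsedNumber]:
    """Document-order numbers in a sentence: numerals, decimals, simple
    fractions ("1/2", "half"), and spelled numbers one through one hundred."""
    # Fractions like 1/2 are split by the tokenizer, so detect them on the
    # raw text first and substitute their decimal value.
    sentence = _FRACTION_SUB_RE.sub(lambda m: str(int(m.group(1)) / int(m.group(2))), sentence)
    tokens = tokenize(sentence)
    out: list[ParsedNumber] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if re.fullmatch(r"\d+(\.\d+)?", tok):
            out.append(ParsedNumber(float(tok), "numeral", i + 1))
            i += 1
            continue
        if tok == "half":
            # "half a pack" / "a half pack"
            out.append(ParsedNumber(0.5, "word", i + 1))
            i += 1
            continue
        if tok in _TENS:
            value, j = _TENS[tok], i + 1
            if j < len(tokens) and tokens[j] in _UNITS and _UNITS[tokens[j]] < 10:
                value += _UNITS[tokens[j]]
                j += 1
            out.append(ParsedNumber(float(value), "word", j))
            i = j
            continue
        if tok in _UNITS:
            value, j = _UNITS[tok], i + 1
            if tok == "one" and j < len(tokens) and tokens[j] == "hundred":
                value, j = 100, j + 1
            out.append(ParsedNumber(float(value), "word", j))
            i = j
            continue
        i += 1
    return out


_FRACTION_SUB_RE = re.compile(r"\b(\d)\s*/\s*([234])\b")


def cigarettes_to_packs(cigs_per_day: float) -> float:
    """Convert a cigarettes-per-day frequency to packs per day (20/pack)."""
    if cigs_per_day < 0:
        raise ValueError("cigarettes per day must be non-negative")
    return cigs_per_day / CIGARETTES_PER_PACK


# ---------------------------------------------------------------------------
# Sentence interpretation

# Unit-cue lexicons, matched in the few tokens following a number.
_PACKYEAR_CUES = (
    ("pack", "year"), ("pack", "years"), ("pkyr",), ("pkyrs",), ("py",),
    ("pk", "yr"), ("pk", "yrs"), ("pack", "yr"), ("pack", "yrs"),
)
_FREQ_PACK_CUES = (
    ("ppd",), ("packs", "per", "day"), ("pack", "per", "day"),
    ("packs", "a", "day"), ("pack", "a", "day"), ("packs", "day"),
    ("pack", "day"), ("packs", "daily"), ("pack", "daily"), ("ppds",),
)
_FREQ_CIG_CUES = (
    ("cigarettes", "per", "day"), ("cigarettes", "a", "day"),
    ("cigarettes", "daily"), ("cigs", "per", "day"), ("cigs", "a", "day"),
    ("cigs", "daily"), ("cpd",), ("cigarettes", "each", "day"),
)
_DURATION_CUES = (("years",), ("year",), ("yrs",), ("yr",))


def _cue_after(tokens: list[str], pos: int, cues, reach: int = 4) -> bool:
    window = tokens[pos : pos + reach]
    for cue in cues:
        for start in range(len(window) - len(cue) + 1):
            if tuple(window[start : start + len(cue)]) == cue:
                return True
    return False


def interpret_sentence(
    sentence: str,
    numbers: Optional[list[ParsedNumber]] = None,
    *,
    sentence_index: int = 0,
    stems: Sequence[str] = DEFAULT_STEMS,
) -> Optional[PackYearFinding]:
    """Classify a stem-selected sentence into a pack-year finding.

    Two usable numbers give a frequency × duration product (a cigarette
    frequency is converted to packs first). With no decisive unit cues the
    first number is taken as frequency and the second as duration; cues win
    where present. A single number is routed by its adjacent cue to a stated
    pack-year total, a bare frequency, or a bare duration. Anything else —
    no numbers, implausible magnitudes, irreconcilable cues — yields None.
    """
    if numbers is None:
        numbers = parse_numbers(sentence)
    numbers = [n for n in numbers if 0 <= n.value <= MAX_PLAUSIBLE_VALUE]
    if not numbers:
        return None
    sub = _FRACTION_SUB_RE.sub(
        lambda m: str(int(m.group(1)) / int(m.group(2))), sentence
    )
    tokens = tokenize(sub)
    stem = _matched_stem(sentence, stems)

    roles: list[Optional[str]] = []
    for num in numbers:
        if _cue_after(tokens, num.token_end, _PACKYEAR_CUES):
            roles.append("packyear")
        elif _cue_after(tokens, num.token_end, _FREQ_CIG_CUES):
            roles.append("freq_cig")
        elif _cue_after(tokens, num.token_end, _FREQ_PACK_CUES):
            roles.append("freq_pack")
        elif _cue_after(tokens, num.token_end, _DURATION_CUES):
            roles.append("duration")
        else:
            roles.append(None)

    def finding(kind, pack_years=None, ppd=None, yrs=None):
        return PackYearFinding(
            kind=kind,
            sentence_index=sentence_index,
            matched_stem=stem,
            pack_years=pack_years,
            packs_per_day=ppd,
            years_smoked=yrs,
        )

    stated = [n for n, r in zip(numbers, roles) if r == "packyear"]
    freqs = [
        (cigarettes_to_packs(n.value) if r == "freq_cig" else n.value)
        for n, r in zip(numbers, roles)
        if r in ("freq_cig", "freq_pack")
    ]
    durations = [n.value for n, r in zip(numbers, roles) if r == "duration"]

    if stated:
        # An explicit pack-year total outranks any co-occurring frequency or
        # duration mention in the same sentence.
        return finding(
            FindingKind.STATED_PACK_YEARS,
            pack_years=max(n.value for n in stated),
        )

    if len(numbers) == 2 and not stated:
        a, b = numbers
        ra, rb = roles
        if ra is None and rb is None:
            # No cues at all: frequency assumed to precede duration.
            ppd, yrs = a.value, b.value
        elif len(freqs) == 1 and len(durations) == 1:
            ppd, yrs = freqs[0], durations[0]
        elif len(freqs) == 1 and len(durations) == 0:
            ppd = freqs[0]
            yrs = (b if roles.index(None) == 1 else a).value if None in roles else None
        elif len(durations) == 1 and len(freqs) == 0:
            yrs = durations[0]
            ppd = (b if roles.index(None) == 1 else a).value if None in roles else None
        else:
            return None
        if ppd is None or yrs is None:
            return None
        return finding(
            FindingKind.COMPUTED_PRODUCT,
            pack_years=ppd * yrs,
            ppd=ppd,
            yrs=yrs,
        )

    if len(numbers) > 2 and len(freqs) == 1 and len(durations) >= 1 and not stated:
        return finding(
            FindingKind.COMPUTED_PRODUCT,
            pack_years=freqs[0] * durations[0],
            ppd=freqs[0],
            yrs=durations[0],
        )

    if len(numbers) == 1:
        if freqs:
            return finding(FindingKind.FREQUENCY_ONLY, ppd=freqs[0])
        if durations:
            return finding(FindingKind.DURATION_ONLY, yrs=durations[0])
        return None

    return None


def apply_low_value_filter(
    findings: Sequence[PackYearFinding],
    cutoff: float = DEFAULT_CUTOFF,
    enabled: bool = True,
) -> list[PackYearFinding]:
    """Drop sub-cutoff findings except computed products.

    Small single-number "pack year" statements usually encode only a
    frequency or a duration; a product computed from both components is
    trusted at any magnitude.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    if not enabled:
        return list(findings)
    return [
        f
        for f in findings
        if f.kind is FindingKind.COMPUTED_PRODUCT
        or f.pack_years is None
        or f.pack_years >= cutoff
    ]


@dataclass(frozen=True)
class PackYearConfig:
    stems: tuple[str, ...] = DEFAULT_STEMS
    cutoff: float = DEFAULT_CUTOFF
    filter_enabled: bool = True


def note_findings(text: str, config: PackYearConfig = PackYearConfig()) -> list[PackYearFinding]:
    """All surviving pack-year findings for a note, for audit export."""
    sentences = split_sentences(text)
    findings = []
    for idx, sent in select_packyear_sentences(sentences, config.stems):
        f = interpret_sentence(sent, sentence_index=idx, stems=config.stems)
        if f is not None:
            findings.append(f)
    return apply_low_value_filter(findings, config.cutoff, config.filter_enabled)


def note_pack_years(text: str, config: PackYearConfig = PackYearConfig()) -> Optional[float]:
    """Document-level pack years: max over full findings; None if none."""
    values = [
        f.pack_years
        for f in note_findings(text, config)
        if f.kind in (FindingKind.COMPUTED_PRODUCT, FindingKind.STATED_PACK_YEARS)
        and f.pack_years is not None
    ]
    return max(values) if values else None
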