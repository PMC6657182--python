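"""Synthetic clinical-note corpora with gold-standard smoking behaviors.

Real smokers'-registry data cannot leave the health system, so the package
ships a generator that emulates all three record sources — free-text notes,
semi-structured EHR fields, and an external questionnaire — against a known
gold record per patient. The defaults mirror the validation study's
observed conditions: a current/former/never mix of 247/614/643 (out of
1,504), 73% of notes carrying no smoking information, semi-structured
status available for ~15% of visits, and ~11% of smokers declining the
questionnaire's pack-year questions.

Notes are realized from an editable template library (three sets:
``unambiguous``, ``varied``, ``adversarial``); pack-year quantities are
rendered in a randomly chosen surface form (packs/day, cigarettes/day,
spelled-out numbers, or a stated pack-year total), and quit dates as
absolute years or "N years ago" phrases. Optional distractor sentences
reproduce the classic trap phrases ("if you currently smoke", "stop
aspirin", "metoprolol qd", "packed cells") that must never change a gold
label. The questionnaire is error-free ground truth by default (the
validation design's assumption); semi-structured status disagrees with gold
at a configurable misrecording rate to exercise the worst-label merge.

Identical seeds produce byte-identical corpora.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from .hotspots import FeatureText, note_feature_text
from .io import ClinicalNote, QuestionnaireRecord, SemiStructuredRecord
from .status import INFORMATIVE_STATUSES, SmokingStatus

#: Status mix observed in the validation cohort (current, former, never).
DEFAULT_STATUS_PROBS = (247 / 1504, 614 / 1504, 643 / 1504)

_PPD_CHOICES = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
_WORD_FOR_INT = {
    1: "one", 2: "two", 3: "three", 4: "four", 5: "five", 6: "six",
    7: "seven", 8: "eight", 9: "nine", 10: "ten", 11: "eleven",
    12: "twelve", 13: "thirteen", 14: "fourteen", 15: "fifteen",
    16: "sixteen", 17: "seventeen", 18: "eighteen", 19: "nineteen",
}
_TENS_WORD = {20: "twenty", 30: "thirty", 40: "forty", 50: "fifty"}


def _spell(n: int) -> Optional[str]:
    if n in _WORD_FOR_INT:
        return _WORD_FOR_INT[n]
    tens, unit = divmod(n, 10)
    if tens * 10 in _TENS_WORD:
        word = _TENS_WORD[tens * 10]
        return word if unit == 0 else f"{word} {_WORD_FOR_INT[unit]}"
    return None


@dataclass(frozen=True)
class GoldRecord:
    """Ground truth for one simulated patient."""

    patient_id: str
    true_status: SmokingStatus  # CURRENT / FORMER / NEVER
    true_packs_per_day: Optional[float] = None
    true_years_smoked: Optional[float] = None
    true_quit_date: Optional[dt.date] = None
    note_has_info: bool = True
    semi_available: bool = False
    questionnaire_declined: bool = False

    @property
    def true_pack_years(self) -> Optional[float]:
        if self.true_packs_per_day is None or self.true_years_smoked is None:
            return None
        return self.true_packs_per_day * self.true_years_smoked


@dataclass
class GeneratorConfig:
    n_patients: int = 1504
    status_probabilities: tuple[float, float, float] = DEFAULT_STATUS_PROBS
    p_note_info: float = 0.27
    p_semi_available: float = 222 / 1504
    p_semi_pack_years: float = 67 / 222
    p_decline: float = 96 / 861
    semi_misrecording_rate: float = 0.05
    questionnaire_noise: float = 0.0
    template_set: str = "unambiguous"
    distractor_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.status_probabilities, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("status_probabilities must be a 3-simplex")
        for name in (
            "p_note_info", "p_semi_available", "p_semi_pack_years",
            "p_decline", "semi_misrecording_rate", "questionnaire_noise",
            "distractor_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SimulatedCorpus:
    notes: list[ClinicalNote] = field(default_factory=list)
    semi_records: list[SemiStructuredRecord] = field(default_factory=list)
    questionnaire: list[QuestionnaireRecord] = field(default_factory=list)
    gold: list[GoldRecord] = field(default_factory=list)


def _templates() -> dict:
    with resources.files("smokereg.data").joinpath("templates.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        return yaml.safe_load(fh)


_STATUS_KEY = {
    SmokingStatus.CURRENT: "current",
    SmokingStatus.FORMER: "former",
    SmokingStatus.NEVER: "never",
    SmokingStatus.SMOKER_TEMPORALITY_UNKNOWN: "smoker_temporality_unknown",
}


def _fmt(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else str(value)


def _pick(rng: np.random.Generator, items: Sequence[str]) -> str:
    return items[int(rng.integers(len(items)))]


def realize_note(
    gold: GoldRecord,
    note_date: dt.date,
    rng: np.random.Generator,
    *,
    template_set: str = "unambiguous",
    templates: Optional[dict] = None,
) -> str:
    """Render one note's text consistent with its gold record.

    Without smoking information the note is assembled purely from hotspot-free
    filler. With information, a status sentence is always present; smokers
    with quantities get a pack-year sentence in a random surface form, and
    former smokers a quit sentence matching their gold cessation year.
    """
    t = templates or _templates()
    filler = t["no_info_sentences"]
    if not gold.note_has_info:
        k = 1 + int(rng.integers(2))
        idx = rng.choice(len(filler), size=k, replace=False)
        return " ".join(filler[int(i)] for i in idx)

    parts = [_pick(rng, t["status_sentences"][template_set][_STATUS_KEY[gold.true_status]])]
    parts.insert(0, _pick(rng, filler))

    if gold.true_pack_years is not None:
        parts.append(_packyear_sentence(gold, rng, t))

    if gold.true_status is SmokingStatus.FORMER and gold.true_quit_date is not None:
        if rng.random() < 0.5:
            tmpl = _pick(rng, t["quit_sentences"]["absolute"])
            parts.append(tmpl.format(year=gold.true_quit_date.year))
        else:
            n = note_date.year - gold.true_quit_date.year
            tmpl = _pick(rng, t["quit_sentences"]["relative"])
            parts.append(tmpl.format(n=n))
    return " ".join(parts)


def _packyear_sentence(gold: GoldRecord, rng: np.random.Generator, t: dict) -> str:
    ppd = gold.true_packs_per_day
    years = int(gold.true_years_smoked)
    verb = "Smokes" if gold.true_status is SmokingStatus.CURRENT else "Smoked"
    surfaces = ["ppd", "cigarettes", "stated"]
    spelled_ok = float(ppd).is_integer() or ppd == 0.5
    if spelled_ok and _spell(years):
        surfaces.append("spelled")
    surface = _pick(rng, surfaces)
    if surface == "stated":
        tmpl = _pick(rng, t["packyear_sentences"]["stated"])
        return tmpl.format(py=_fmt(gold.true_pack_years))
    if surface == "cigarettes":
        freq = f"{int(ppd * 20)} cigarettes a day"
    elif surface == "spelled":
        if ppd == 0.5:
            freq = "half a pack a day"
        else:
            freq = f"{_spell(int(ppd))} packs a day"
        tmpl = _pick(rng, t["packyear_sentences"]["product"])
        return tmpl.format(verb=verb, freq=freq, years=_spell(years))
    else:
        freq = f"{_fmt(ppd)} packs per day"
    tmpl = _pick(rng, t["packyear_sentences"]["product"])
    return tmpl.format(verb=verb, freq=freq, years=years)


def inject_distractors(text: str, rate: float, rng: np.random.Generator,
                       templates: Optional[dict] = None) -> str:
    """Append trap sentences (generic instructions, medication lines) that
    carry hotspot roots or quit cues but must not change gold labels."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    if rate == 0 or rng.random() >= rate:
        return text
    bank = (templates or _templates())["distractors"]
    trap = _pick(rng, bank)
    return f"{text} {trap}" if text else trap


def generate_corpus(config: GeneratorConfig) -> SimulatedCorpus:
    """Generate notes, semi-structured records, questionnaire responses, and
    gold records for ``config.n_patients`` patients; seeded and repeatable."""
    rng = np.random.default_rng(config.seed)
    templates = _templates()
    corpus = SimulatedCorpus()
    statuses = (SmokingStatus.CURRENT, SmokingStatus.FORMER, SmokingStatus.NEVER)
    base_date = dt.date(2016, 4, 1)

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        note_date = base_date - dt.timedelta(days=int(rng.integers(0, 365)))
        status = statuses[int(rng.choice(3, p=config.status_probabilities))]

        ppd = years = quit_date = None
        if status in (SmokingStatus.CURRENT, SmokingStatus.FORMER):
            ppd = float(_PPD_CHOICES[int(rng.integers(len(_PPD_CHOICES)))])
            years = float(rng.integers(10, 51))
        if status is SmokingStatus.FORMER:
            quit_date = dt.date(note_date.year - int(rng.integers(1, 31)), 1, 1)

        gold = GoldRecord(
            patient_id=pid,
            true_status=status,
            true_packs_per_day=ppd,
            true_years_smoked=years,
            true_quit_date=quit_date,
            note_has_info=bool(rng.random() < config.p_note_info),
            semi_available=bool(rng.random() < config.p_semi_available),
            questionnaire_declined=bool(
                status is not SmokingStatus.NEVER and rng.random() < config.p_decline
            ),
        )
        corpus.gold.append(gold)

        text = realize_note(
            gold, note_date, rng,
            template_set=config.template_set, templates=templates,
        )
        text = inject_distractors(text, config.distractor_rate, rng, templates)
        corpus.notes.append(
            ClinicalNote(note_id=f"N{i:05d}", patient_id=pid, note_date=note_date, text=text)
        )

        if gold.semi_available:
            semi_status = status
            if rng.random() < config.semi_misrecording_rate:
                others = [s for s in INFORMATIVE_STATUSES if s is not status]
                semi_status = others[int(rng.integers(len(others)))]
            semi_py = None
            if gold.true_pack_years is not None and rng.random() < config.p_semi_pack_years:
                semi_py = gold.true_pack_years
            corpus.semi_records.append(
                SemiStructuredRecord(
                    patient_id=pid, record_date=note_date,
                    status=semi_status, pack_years=semi_py,
                )
            )

        q_status = status
        if config.questionnaire_noise and rng.random() < config.questionnaire_noise:
            others = [s for s in statuses if s is not status]
            q_status = others[int(rng.integers(len(others)))]
        declined = gold.questionnaire_declined
        corpus.questionnaire.append(
            QuestionnaireRecord(
                patient_id=pid,
                status=q_status,
                packs_per_day=None if declined else ppd,
                years_smoked=None if declined else years,
                declined=declined,
            )
        )
    return corpus


def make_training_corpus(
    n_per_class: int,
    *,
    template_set: str = "unambiguous",
    seed: int = 0,
) -> list[tuple[FeatureText, SmokingStatus]]:
    """Labeled hotspot feature texts over all four informative statuses,
    for training the document-level classifier."""
    rng = np.random.default_rng(seed)
    templates = _templates()
    base_date = dt.date(2016, 4, 1)
    examples: list[tuple[FeatureText, SmokingStatus]] = []
    for status in INFORMATIVE_STATUSES:
        for j in range(n_per_class):
            ppd = years = quit = None
            if status in (SmokingStatus.CURRENT, SmokingStatus.FORMER):
                ppd = float(_PPD_CHOICES[int(rng.integers(len(_PPD_CHOICES)))])
                years = float(rng.integers(10, 51))
            if status is SmokingStatus.FORMER:
                quit = dt.date(base_date.year - int(rng.integers(1, 31)), 1, 1)
            gold = GoldRecord(
                patient_id=f"T{status.value}{j}",
                true_status=status,
                true_packs_per_day=ppd,
                true_years_smoked=years,
                true_quit_date=quit,
                note_has_info=True,
            )
            text = realize_note(
                gold, base_date, rng,
                template_set=template_set, templates=templates,
            )
            ft = note_feature_text(text)
            if ft.window_count == 0:  # every template carries a hotspot
                continue
            examples.append((ft, status))
    return examples
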