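"""Synthetic-corpus generator: determinism, gold consistency, traps."""

import datetime as dt

import numpy as np
import pytest

from smokereg.cessation import note_cessation_date
from smokereg.hotspots import note_feature_text
from smokereg.simulate import (
    GeneratorConfig,
    GoldRecord,
    generate_corpus,
    inject_distractors,
    realize_note,
)
from smokereg.status import SmokingStatus


def test_zero_patients_gives_empty_collections():
    c = generate_corpus(GeneratorConfig(n_patients=0))
    assert (c.notes, c.semi_records, c.questionnaire, c.gold) == ([], [], [], [])


def test_same_seed_gives_identical_corpora():
    a = generate_corpus(GeneratorConfig(n_patients=120, seed=7))
    b = generate_corpus(GeneratorConfig(n_patients=120, seed=7))
    assert a.notes == b.notes
    assert a.semi_records == b.semi_records
    assert a.questionnaire == b.questionnaire
    assert a.gold == b.gold


def test_invalid_simplex_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(status_probabilities=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        GeneratorConfig(p_note_info=1.5)


def test_status_frequencies_match_configured_simplex():
    cfg = GeneratorConfig(n_patients=5000, seed=2)
    c = generate_corpus(cfg)
    counts = {s: 0 for s in (SmokingStatus.CURRENT, SmokingStatus.FORMER, SmokingStatus.NEVER)}
    for g in c.gold:
        counts[g.true_status] += 1
    for p, s in zip(cfg.status_probabilities, counts):
        se = np.sqrt(p * (1 - p) / cfg.n_patients)
        assert abs(counts[s] / cfg.n_patients - p) < 3 * se


def test_gold_invariants():
    c = generate_corpus(GeneratorConfig(n_patients=400, seed=5))
    for g in c.gold:
        if g.true_status is SmokingStatus.NEVER:
            assert g.true_pack_years is None and g.true_quit_date is None
        if g.true_status is SmokingStatus.FORMER:
            assert g.true_quit_date is not None
        if g.true_pack_years is not None:
            assert g.true_pack_years == g.true_packs_per_day * g.true_years_smoked
    # questionnaire status always equals gold (error-free reference standard)
    for g, q in zip(c.gold, c.questionnaire):
        assert q.status is g.true_status
        if g.questionnaire_declined:
            assert q.packs_per_day is None and q.years_smoked is None


def test_no_info_notes_contain_no_hotspot():
    c = generate_corpus(GeneratorConfig(n_patients=400, p_note_info=0.3, seed=9))
    for g, note in zip(c.gold, c.notes):
        if not g.note_has_info:
            assert note_feature_text(note.text).window_count == 0
        else:
            assert note_feature_text(note.text).window_count > 0


def test_distractor_injection():
    rng = np.random.default_rng(0)
    assert inject_distractors("Base text.", 0.0, rng) == "Base text."
    rng = np.random.default_rng(0)
    out = inject_distractors("Base text.", 1.0, rng)
    assert out.startswith("Base text.") and len(out) > len("Base text.")


def test_medication_trap_does_not_create_cessation_finding():
    rng = np.random.default_rng(1)
    text = "Patient has never smoked. Metoprolol 25 mg qd."
    assert note_cessation_date(text, dt.date(2016, 4, 1)) is None


def test_never_smoker_unambiguous_note_has_no_numbers():
    rng = np.random.default_rng(4)
    gold = GoldRecord(patient_id="x", true_status=SmokingStatus.NEVER)
    for _ in range(10):
        text = realize_note(gold, dt.date(2016, 4, 1), rng)
        status_part = text.split(". ", 1)[-1]  # first sentence is neutral filler
        assert not any(ch.isdigit() for ch in status_part)
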