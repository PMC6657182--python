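"""Pack-year extraction: sentence selection, number parsing, interpretation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smokereg.packyears import (
    FindingKind,
    PackYearConfig,
    PackYearFinding,
    apply_low_value_filter,
    cigarettes_to_packs,
    interpret_sentence,
    note_pack_years,
    parse_numbers,
    select_packyear_sentences,
    split_sentences,
)


@pytest.mark.parametrize(
    "text,n",
    [
        ("Smokes 1 ppd. Quit ETOH.", 2),
        ("", 0),
        ("Hx. of COPD. Smokes.", 2),  # "Hx." guarded
        ("Takes aspirin b.i.d. for pain. Smokes.", 2),
        ("BP 120/80. A1c 6.5 today.", 2),  # decimal point not a boundary
    ],
)
def test_split_sentences(text, n):
    assert len(split_sentences(text)) == n


def test_stem_selection():
    sentences = [
        "40 pack year history.",
        "Packed red blood cells given.",
        "No alcohol use.",
        "Smokes 1 ppd.",
    ]
    picked = select_packyear_sentences(sentences)
    assert [i for i, _ in picked] == [0, 1, 3]
    # the "packed cells" false-positive surface is then rejected by the parser
    assert interpret_sentence("Packed red blood cells given.") is None


@pytest.mark.parametrize(
    "sentence,values",
    [
        ("two packs a day for 30 years", [2.0, 30.0]),
        ("smokes occasionally", []),
        ("half a pack per day", [0.5]),
        ("1/2 pack per day", [0.5]),
        ("twenty five cigarettes a day", [25.0]),
        ("one hundred", [100.0]),
    ],
)
def test_parse_numbers(sentence, values):
    assert [p.value for p in parse_numbers(sentence)] == values


def test_cigarette_conversion():
    assert cigarettes_to_packs(20) == 1.0
    assert cigarettes_to_packs(0) == 0.0
    assert cigarettes_to_packs(10) == 0.5
    with pytest.raises(ValueError):
        cigarettes_to_packs(-1)


@pytest.mark.parametrize(
    "sentence,kind,pack_years",
    [
        ("2 packs per day for 20 years", FindingKind.COMPUTED_PRODUCT, 40.0),
        ("20 cigarettes a day for 10 years", FindingKind.COMPUTED_PRODUCT, 10.0),
        ("30 pack year smoking history", FindingKind.STATED_PACK_YEARS, 30.0),
        ("smokes 1 ppd", FindingKind.FREQUENCY_ONLY, None),
        ("smoked for 20 years", FindingKind.DURATION_ONLY, None),
    ],
)
def test_interpret_sentence(sentence, kind, pack_years):
    f = interpret_sentence(sentence)
    assert f is not None and f.kind is kind
    assert f.pack_years == pack_years


def test_interpret_rejects_implausible_and_empty():
    assert interpret_sentence("smoking cessation discussed") is None
    # a bare year is not a pack-year quantity
    assert interpret_sentence("smoked until 1995") is None


def _finding(kind, py):
    return PackYearFinding(kind=kind, sentence_index=0, matched_stem="smok", pack_years=py)


def test_low_value_filter():
    stated2 = _finding(FindingKind.STATED_PACK_YEARS, 2.0)
    product2 = PackYearFinding(
        kind=FindingKind.COMPUTED_PRODUCT, sentence_index=0, matched_stem="smok",
        pack_years=2.0, packs_per_day=0.1, years_smoked=20.0,
    )
    assert apply_low_value_filter([stated2], cutoff=5) == []
    assert apply_low_value_filter([product2], cutoff=5) == [product2]
    assert apply_low_value_filter([stated2], cutoff=5, enabled=False) == [stated2]


def test_note_level_reduction_is_max_over_full_findings():
    text = "Has a 30 pack year smoking history. Smoked 2 packs per day for 20 years."
    assert note_pack_years(text) == 40.0
    assert note_pack_years("No relevant history.") is None
    assert note_pack_years("Has a 25 pack year smoking history.") == 25.0


@settings(deadline=None)
@given(st.integers(0, 200))
def test_cigarette_path_equivalence(n_cigs):
    cfg = PackYearConfig(filter_enabled=False)
    a = note_pack_years(f"Smoked {n_cigs} cigarettes a day for 10 years.", cfg)
    b = note_pack_years(f"Smoked {n_cigs / 20} packs per day for 10 years.", cfg)
    assert a == b


@settings(deadline=None)
@given(st.floats(0.25, 3.0, allow_nan=False), st.integers(1, 60))
def test_product_scales_linearly_in_frequency(ppd, years):
    cfg = PackYearConfig(filter_enabled=False)
    single = note_pack_years(f"Smoked {ppd} packs per day for {years} years.", cfg)
    double = note_pack_years(f"Smoked {2 * ppd} packs per day for {years} years.", cfg)
    assert single is not None and double == pytest.approx(2 * single)


def test_extraction_is_deterministic_and_idempotent():
    text = "Smokes 1.5 packs per day for 22 years. Quit ETOH."
    first = note_pack_years(text)
    assert all(note_pack_years(text) == first for _ in range(3))
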