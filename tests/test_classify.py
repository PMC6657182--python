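"""Status classifier: training contracts, the UNKNOWN rule, determinism."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smokereg.classify import StatusModel, classify_feature_text, classify_note, train
from smokereg.hotspots import FeatureText, note_feature_text
from smokereg.io import ClinicalNote
from smokereg.status import SmokingStatus

NOTE_DATE = dt.date(2016, 4, 1)


def _note(text):
    return ClinicalNote("n1", "p1", NOTE_DATE, text)


def _toy_examples():
    """Linearly separable corpus: each class has a disjoint cue token."""
    cues = {
        SmokingStatus.CURRENT: "current smoker now",
        SmokingStatus.FORMER: "former smoker quit",
        SmokingStatus.SMOKER_TEMPORALITY_UNKNOWN: "smoker unspecified",
        SmokingStatus.NEVER: "never smoked denies",
    }
    return [
        (FeatureText(f"{text} filler{j}", 1), label)
        for label, text in cues.items()
        for j in range(10)
    ]


def test_separable_toy_corpus_trains_to_perfect_accuracy():
    model = train(_toy_examples(), seed=1)
    assert model.metadata["training_accuracy"] == 1.0
    assert model.metadata["n_examples"] == 40


def test_training_preconditions():
    with pytest.raises(ValueError):
        train([])
    one_class = [(FeatureText("current smoker", 1), SmokingStatus.CURRENT)] * 5
    with pytest.raises(ValueError):
        train(one_class)
    with pytest.raises(ValueError):
        train([(FeatureText("", 0), SmokingStatus.CURRENT)] + _toy_examples())
    with pytest.raises(ValueError):
        train([(FeatureText("x", 1), SmokingStatus.UNKNOWN)] + _toy_examples())


def test_same_seed_gives_identical_predictions():
    probe = ["current smoker now", "former smoker quit", "smoker unspecified"]
    m1 = train(_toy_examples(), seed=7)
    m2 = train(_toy_examples(), seed=7)
    assert [m1.predict(t) for t in probe] == [m2.predict(t) for t in probe]
    assert (m1.coef == m2.coef).all()


def test_no_hotspot_note_is_unknown_without_consulting_model():
    note = _note("Blood pressure stable. Continue lisinopril.")
    # model=None proves the model is never consulted on hotspot-free notes
    assert classify_note(None, note) is SmokingStatus.UNKNOWN
    assert classify_note(None, _note("")) is SmokingStatus.UNKNOWN


def test_hotspot_note_requires_model():
    from smokereg.classify import UntrainedModelError

    with pytest.raises(UntrainedModelError):
        classify_note(None, _note("Patient is a current smoker."))


def test_current_smoker_note_classified_current(trained_model):
    note = _note("Patient is a current smoker, 1 ppd.")
    assert classify_note(trained_model, note) is SmokingStatus.CURRENT


@settings(deadline=None, max_examples=50)
@given(st.text(alphabet="abdefhjklpqruvwxyz ., 0123456789", max_size=120))
def test_random_text_without_roots_is_unknown(text):
    assert classify_feature_text(None, note_feature_text(text)) is SmokingStatus.UNKNOWN


def test_model_serialization_round_trip(tmp_path, trained_model):
    path = tmp_path / "model.json"
    trained_model.save(path)
    loaded = StatusModel.load(path)
    probes = [
        "current smoker quit smoking former never denies tobacco",
        "smokes 2 ppd currently",
    ]
    assert [loaded.predict(p) for p in probes] == [trained_model.predict(p) for p in probes]
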