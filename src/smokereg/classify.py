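"""Document-level smoking-status classification.

A multi-class linear support-vector machine assigns one of the four
informative labels (current / former / smoker-temporality-unknown / never)
to a note's hotspot feature text. Notes with no hotspot never reach the
model: they are UNKNOWN by rule, because a note with no smoking-related
token carries no information to classify.

Features are binary unigram presence over the concatenated hotspot windows
(bigrams available behind a flag); the multi-class reduction is one-vs-rest
with ties broken first by margin, then by the status precedence order.
Models serialize to a single versioned JSON file (vocabulary + dense weight
arrays) so a trained classifier travels without pickles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.svm import LinearSVC

from .hotspots import DEFAULT_ROOTS, FeatureText, note_feature_text
from .io import ClinicalNote
from .status import INFORMATIVE_STATUSES, SmokingStatus

#: Default RNG seed (April 2016, the registry's reference extract month).
DEFAULT_SEED = 20160401

_FORMAT_VERSION = 1


class UntrainedModelError(RuntimeError):
    pass


@dataclass
class StatusModel:
    """Learned one-vs-rest linear decision functions over a token vocabulary."""

    vocabulary: dict[str, int]
    coef: np.ndarray  # (n_classes, n_features)
    intercept: np.ndarray  # (n_classes,)
    classes: tuple[SmokingStatus, ...]
    bigrams: bool = False
    metadata: dict = field(default_factory=dict)

    def decision_scores(self, feature_text: str) -> np.ndarray:
        x = _vectorize([feature_text], self.vocabulary, self.bigrams)
        return (x @ self.coef.T + self.intercept)[0]

    def predict(self, feature_text: str) -> SmokingStatus:
        scores = self.decision_scores(feature_text)
        best = scores.max()
        # Margin decides; exact ties fall back to the worst-label precedence.
        tied = [c for c, s in zip(self.classes, scores) if s == best]
        return max(tied, key=lambda c: c.precedence)

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        payload = {
            "format_version": _FORMAT_VERSION,
            "model": "linear_svm_one_vs_rest",
            "classes": [str(c) for c in self.classes],
            "bigrams": self.bigrams,
            "vocabulary": self.vocabulary,
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "StatusModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format_version") != _FORMAT_VERSION:
            raise ValueError("unsupported model file version")
        return cls(
            vocabulary=payload["vocabulary"],
            coef=np.asarray(payload["coef"], dtype=float),
            intercept=np.asarray(payload["intercept"], dtype=float),
            classes=tuple(SmokingStatus.from_string(c) for c in payload["classes"]),
            bigrams=payload.get("bigrams", False),
            metadata=payload.get("metadata", {}),
        )


def _vectorize(texts: Sequence[str], vocabulary: dict[str, int], bigrams: bool):
    vec = CountVectorizer(
        binary=True,
        vocabulary=vocabulary,
        ngram_range=(1, 2) if bigrams else (1, 1),
        token_pattern=r"(?u)\b\w+\b",
    )
    return vec.transform(texts)


def train(
    examples: Sequence[tuple[FeatureText, SmokingStatus]],
    *,
    C: float = 1.0,
    bigrams: bool = False,
    seed: int = DEFAULT_SEED,
) -> StatusModel:
    """Fit the one-vs-rest linear SVM on (feature text, label) pairs.

    Labels must come from the four informative statuses; UNKNOWN examples
    are rejected because UNKNOWN is a pre-classification rule, not a class.
    Training is deterministic for a given seed and input order.
    """
    if not examples:
        raise ValueError("empty training set")
    for ft, label in examples:
        if label not in INFORMATIVE_STATUSES:
            raise ValueError(f"label {label} is not trainable (UNKNOWN is rule-assigned)")
        if not ft.text:
            raise ValueError("training example with empty feature text")
    labels = [label for _, label in examples]
    if len(set(labels)) < 2:
        raise ValueError("training requires at least two distinct labels")

    texts = [ft.text for ft, _ in examples]
    vec = CountVectorizer(
        binary=True,
        ngram_range=(1, 2) if bigrams else (1, 1),
        token_pattern=r"(?u)\b\w+\b",
    )
    X = vec.fit_transform(texts)
    y = np.array([label.value for label in labels])

    svm = LinearSVC(C=C, random_state=seed)
    svm.fit(X, y)

    classes = tuple(SmokingStatus.from_string(c) for c in svm.classes_)
    coef = np.atleast_2d(svm.coef_)
    intercept = np.atleast_1d(svm.intercept_)
    if len(classes) == 2:
        # Binary LinearSVC stores one decision row; expand to one-vs-rest form.
        coef = np.vstack([-coef[0], coef[0]])
        intercept = np.array([-intercept[0], intercept[0]])

    model = StatusModel(
        vocabulary={t: int(i) for t, i in vec.vocabulary_.items()},
        coef=coef,
        intercept=intercept,
        classes=classes,
        bigrams=bigrams,
        metadata={
            "n_examples": len(examples),
            "class_counts": {str(c): int(sum(1 for l in labels if l is c)) for c in classes},
            "C": C,
            "seed": seed,
        },
    )
    preds = [model.predict(t) for t in texts]
    model.metadata["training_accuracy"] = float(
        np.mean([p is l for p, l in zip(preds, labels)])
    )
    return model


def classify_feature_text(model: Optional[StatusModel], ft: FeatureText) -> SmokingStatus:
    """UNKNOWN when no hotspot window exists; otherwise the model's label."""
    if ft.window_count == 0:
        return SmokingStatus.UNKNOWN
    if model is None:
        raise UntrainedModelError("a trained model is required for hotspot-bearing notes")
    return model.predict(ft.text)


def classify_note(
    model: Optional[StatusModel],
    note: ClinicalNote,
    roots: Sequence[str] = DEFAULT_ROOTS,
) -> SmokingStatus:
    """Classify one clinical note at the document level."""
    return classify_feature_text(model, note_feature_text(note.text, roots))
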