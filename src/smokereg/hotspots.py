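"""Hotspot detection and context-window feature construction.

Smoking information in clinical narrative clusters around a handful of word
roots. A *hotspot* is any token whose prefix matches one of the configured
roots (default: ``smok``, ``cig``, ``tobac``, ``nicoti``). Each hotspot
anchors a window of up to five tokens on either side (truncated at the note
boundaries, so a window holds at most 11 tokens), and the windows from one
note are appended, in document order, into a single feature text that the
document-level status classifier consumes. A note with no hotspot produces
an empty feature text — the downstream signal for "no smoking information".
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

#: Word roots anchoring smoking-related context windows.
DEFAULT_ROOTS: tuple[str, ...] = ("smok", "cig", "tobac", "nicoti")

#: Tokens kept each side of a hotspot.
WINDOW_RADIUS = 5

# Word tokens and numbers; decimals survive as one token, punctuation splits.
_TOKEN_RE = re.compile(r"\d+\.\d+|\d+|[a-z]+")


def tokenize(text: str) -> list[str]:
    """Lowercase word/number tokenization; punctuation (incl. hyphens) splits."""
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class HotspotWindow:
    """A matched hotspot token with its surrounding context tokens."""

    root: str
    token_index: int
    window_tokens: tuple[str, ...]


@dataclass(frozen=True)
class FeatureText:
    """Concatenation of a note's hotspot windows, in order of appearance."""

    text: str
    window_count: int


def find_hotspots(
    tokens: Sequence[str],
    roots: Iterable[str] = DEFAULT_ROOTS,
    *,
    substring: bool = False,
) -> list[HotspotWindow]:
    """Locate hotspot tokens and carve their ±5-token context windows.

    Matching is case-insensitive prefix matching by default ("smok" matches
    "smoker" but not "nonsmoker"); set ``substring=True`` for the looser
    contains-anywhere semantics.
    """
    roots = tuple(r.lower() for r in roots)
    if not roots:
        raise ValueError("hotspot root set must not be empty")
    match = (
        (lambda tok: any(r in tok for r in roots))
        if substring
        else (lambda tok: any(tok.startswith(r) for r in roots))
    )
    windows: list[HotspotWindow] = []
    for i, tok in enumerate(tokens):
        if not match(tok):
            continue
        root = next(
            r for r in roots if (r in tok if substring else tok.startswith(r))
        )
        lo = max(0, i - WINDOW_RADIUS)
        hi = min(len(tokens), i + WINDOW_RADIUS + 1)
        windows.append(HotspotWindow(root, i, tuple(tokens[lo:hi])))
    return windows


def build_feature_text(windows: Sequence[HotspotWindow]) -> FeatureText:
    """Append window token sequences (space-joined) into one classifier input."""
    parts = [" ".join(w.window_tokens) for w in windows]
    return FeatureText(" ".join(parts), len(windows))


def note_feature_text(
    text: str,
    roots: Iterable[str] = DEFAULT_ROOTS,
    *,
    substring: bool = False,
) -> FeatureText:
    """Tokenize → find hotspots → concatenate windows, in one call."""
    return build_feature_text(find_hotspots(tokenize(text), roots, substring=substring))
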