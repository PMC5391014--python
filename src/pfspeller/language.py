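"""Word-prefix count language model.

The model counts, for every prefix string ``s``, how many corpus words begin
with ``s`` (``c(s)``), plus how many words equal ``s`` exactly.  The
transition distribution after typing a word fragment ``s`` is the count ratio
``c(s + ch) / c(s)`` for each grid character, with the completed-word count
supplying the probability of the word separator, mixed with a uniform
smoothing floor so that no grid character is ever unreachable.

History resets at the separator: proposals condition only on the fragment of
the current word, matching a model defined over word-initial substrings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import DEFAULT_GRID_CHARACTERS

logger = logging.getLogger(__name__)

#: Character treated as the word separator in corpora and histories.
SEPARATOR = " "

#: Total probability mass spread uniformly over the vocabulary by default.
DEFAULT_SMOOTHING_FLOOR = 0.05


@dataclass
class LanguageModel:
    """Prefix-count model over a fixed speller vocabulary.

    Attributes
    ----------
    vocabulary : str
        Ordered grid characters, including the separator.
    prefix_counts : dict[str, int]
        ``c(s)`` = number of corpus words beginning with ``s`` (``s`` never
        contains the separator).
    word_counts : dict[str, int]
        Number of corpus words exactly equal to ``s``; drives the separator
        probability after fragment ``s``.
    total_words : int
        Number of words in the normalized corpus (the empty-fragment
        denominator).
    smoothing_floor : float
        Total uniform mass in [0, 1) mixed into every distribution.
    """

    vocabulary: str
    prefix_counts: dict[str, int]
    word_counts: dict[str, int]
    total_words: int
    smoothing_floor: float = DEFAULT_SMOOTHING_FLOOR

    def __post_init__(self) -> None:
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValueError("vocabulary has duplicate characters")
        if not 0.0 <= self.smoothing_floor < 1.0:
            raise ValueError("smoothing_floor must be in [0, 1)")
        self._char_index = {ch: i for i, ch in enumerate(self.vocabulary)}

    def char_index(self, char: str) -> int:
        return self._char_index[char]


def normalize_corpus(corpus_text: str, vocabulary: str) -> list[str]:
    """Uppercase-fold the corpus and split it into vocabulary-only words.

    Characters outside the vocabulary (and the separator itself) act as word
    boundaries; dropped characters are reported once via a logged warning.
    """
    vocab = set(vocabulary)
    folded = corpus_text.upper()
    dropped = {ch for ch in folded if ch not in vocab and not ch.isspace()}
    if dropped:
        logger.warning(
            "dropping %d non-vocabulary character(s) from corpus: %s",
            len(dropped), "".join(sorted(dropped)),
        )
    pieces: list[str] = []
    current: list[str] = []
    for ch in folded:
        if ch in vocab and ch != SEPARATOR:
            current.append(ch)
        else:
            if current:
                pieces.append("".join(current))
            current = []
    if current:
        pieces.append("".join(current))
    return pieces


def build_language_model(
    corpus_text: str,
    vocabulary: str = DEFAULT_GRID_CHARACTERS,
    smoothing_floor: float = DEFAULT_SMOOTHING_FLOOR,
) -> LanguageModel:
    """Count word prefixes in ``corpus_text`` and return the model.

    Raises
    ------
    ValueError
        If no word survives normalization, if the vocabulary has duplicates,
        or if it lacks the separator character.
    """
    if len(set(vocabulary)) != len(vocabulary):
        raise ValueError("vocabulary has duplicate characters")
    if SEPARATOR not in vocabulary:
        raise ValueError("vocabulary must include the word separator")
    words = normalize_corpus(corpus_text, vocabulary)
    if not words:
        raise ValueError("empty corpus: no vocabulary word survives normalization")
    prefix_counts: dict[str, int] = {}
    word_counts: dict[str, int] = {}
    for word in words:
        for end in range(1, len(word) + 1):
            prefix = word[:end]
            prefix_counts[prefix] = prefix_counts.get(prefix, 0) + 1
        word_counts[word] = word_counts.get(word, 0) + 1
    return LanguageModel(
        vocabulary=vocabulary,
        prefix_counts=prefix_counts,
        word_counts=word_counts,
        total_words=len(words),
        smoothing_floor=smoothing_floor,
    )


def uniform_language_model(
    vocabulary: str = DEFAULT_GRID_CHARACTERS,
) -> LanguageModel:
    """A model with no corpus evidence: every history yields the uniform
    distribution (the no-language-model baseline)."""
    if SEPARATOR not in vocabulary:
        raise ValueError("vocabulary must include the word separator")
    return LanguageModel(
        vocabulary=vocabulary,
        prefix_counts={},
        word_counts={},
        total_words=0,
        smoothing_floor=1.0 - 1e-12,  # effectively uniform
    )


def word_fragment(history: str) -> str:
    """Suffix of ``history`` since the last separator (the current word)."""
    _, _, fragment = history.rpartition(SEPARATOR)
    return fragment


def transition_probabilities(model: LanguageModel, history: str) -> np.ndarray:
    """Next-character distribution given a typed history.

    The history may be a full output string; only the fragment of the current
    word conditions the counts.  Returns a probability vector aligned with
    ``model.vocabulary``, summing to 1, with every entry at least
    ``smoothing_floor / |V|``.  An unseen fragment falls back to the exact
    uniform distribution (logged).
    """
    for ch in history:
        if ch not in model._char_index:
            raise ValueError(f"history character {ch!r} not in vocabulary")
    fragment = word_fragment(history)
    n = len(model.vocabulary)
    denom = model.total_words if not fragment else model.prefix_counts.get(fragment, 0)
    if denom == 0:
        logger.info("unseen history %r: falling back to uniform", fragment)
        return np.full(n, 1.0 / n)
    raw = np.zeros(n)
    for i, ch in enumerate(model.vocabulary):
        if ch == SEPARATOR:
            # separator = the fragment completes a word
            raw[i] = model.word_counts.get(fragment, 0) if fragment else 0
        else:
            raw[i] = model.prefix_counts.get(fragment + ch, 0)
    raw /= denom
    floor = model.smoothing_floor
    return (1.0 - floor) * raw + floor / n


# ---------------------------------------------------------------------------
# Persistence: versioned plain-text key-value format, round-trip exact.
# ---------------------------------------------------------------------------

_FORMAT_HEADER = "pfspeller-lm\t1"


def save_language_model(model: LanguageModel, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{_FORMAT_HEADER}\n")
        fh.write(f"vocabulary\t{model.vocabulary}\n")
        fh.write(f"smoothing_floor\t{model.smoothing_floor!r}\n")
        fh.write(f"total_words\t{model.total_words}\n")
        for prefix in sorted(model.prefix_counts):
            fh.write(f"P\t{prefix}\t{model.prefix_counts[prefix]}\n")
        for word in sorted(model.word_counts):
            fh.write(f"W\t{word}\t{model.word_counts[word]}\n")


def load_language_model(path: str) -> LanguageModel:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != _FORMAT_HEADER:
            raise ValueError(f"unrecognized language-model file header: {header!r}")
        vocabulary = fh.readline().rstrip("\n").split("\t", 1)[1]
        floor = float(fh.readline().rstrip("\n").split("\t", 1)[1])
        total_words = int(fh.readline().rstrip("\n").split("\t", 1)[1])
        prefix_counts: dict[str, int] = {}
        word_counts: dict[str, int] = {}
        for line in fh:
            kind, key, count = line.rstrip("\n").split("\t")
            if kind == "P":
                prefix_counts[key] = int(count)
            elif kind == "W":
                word_counts[key] = int(count)
            else:
                raise ValueError(f"unrecognized record kind {kind!r}")
    return LanguageModel(
        vocabulary=vocabulary,
        prefix_counts=prefix_counts,
        word_counts=word_counts,
        total_words=total_words,
        smoothing_floor=floor,
    )
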