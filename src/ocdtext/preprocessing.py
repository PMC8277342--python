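"""From raw entries to the frequency-ranked, POS-filtered analysis vocabulary.

The pipeline order is fixed: outlier-user removal -> phrase assembly
(concatenate obsession + trigger + exposure + compulsion, lowercase, strip
punctuation, apply spelling corrections) -> lemmatization -> vocabulary
construction (token frequencies, ranked) -> top-fraction selection ->
part-of-speech filtering -> exclusion-list filtering.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .lexicon import (DEFAULT_EXCLUDED_TAGS, default_lemmatizer,
                      default_tagger)
from .synthetic import UserEntry

__all__ = [
    "Phrase",
    "Vocabulary",
    "remove_outlier_users",
    "assemble_phrases",
    "lemmatize",
    "build_vocabulary",
    "select_top_fraction",
    "pos_filter",
    "apply_exclusion_list",
    "build_analysis_vocabulary",
    "read_wordlist",
    "write_vocabulary_tsv",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class Phrase:
    """One entry's cleaned token sequence, tagged with its provenance."""

    tokens: tuple[str, ...]
    user_id: str
    timestamp: datetime


@dataclass(frozen=True)
class Vocabulary:
    """Words ranked by descending frequency (ties broken lexicographically).

    ``index`` maps each word to its rank 0..N-1 and ``frequency`` to its
    total token-occurrence count across the corpus.
    """

    index: dict[str, int]
    frequency: dict[str, int]

    def __post_init__(self) -> None:
        n = len(self.index)
        if sorted(self.index.values()) != list(range(n)):
            raise ValueError("indices must be a bijection onto 0..N-1")
        if set(self.index) != set(self.frequency):
            raise ValueError("index and frequency must cover the same words")
        if any(f < 1 for f in self.frequency.values()):
            raise ValueError("frequencies must be >= 1")

    @property
    def size(self) -> int:
        return len(self.index)

    @property
    def words(self) -> list[str]:
        """Words in index (rank) order."""
        return sorted(self.index, key=self.index.__getitem__)

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def __len__(self) -> int:
        return len(self.index)


def remove_outlier_users(entries: Sequence[UserEntry],
                         max_entries: int) -> list[UserEntry]:
    """Drop every entry from users contributing more than ``max_entries``.

    Mirrors the removal of extreme outlier contributors (users submitting
    hundreds of entries) before analysis; order of surviving entries is
    preserved.
    """
    if max_entries < 1:
        raise ValueError("max_entries must be >= 1")
    counts = Counter(e.user_id for e in entries)
    return [e for e in entries if counts[e.user_id] <= max_entries]


def assemble_phrases(entries: Sequence[UserEntry],
                     corrections: Mapping[str, str] | None = None,
                     ) -> list[Phrase]:
    """Concatenate each entry's texts into one cleaned phrase.

    Obsession, trigger, exposure and compulsion texts are joined, lowercased
    and split on any non-alphanumeric character; the spelling-correction map
    is then applied token-wise. Entries yielding no tokens are dropped.
    """
    corrections = corrections or {}
    phrases: list[Phrase] = []
    for e in entries:
        parts = [t for t in (e.obsession, e.trigger, e.exposure,
                             e.compulsion) if t]
        tokens = _TOKEN_RE.findall(" ".join(parts).lower())
        tokens = [corrections.get(t, t) for t in tokens]
        if tokens:
            phrases.append(Phrase(tuple(tokens), e.user_id, e.timestamp))
    return phrases


def lemmatize(phrases: Sequence[Phrase],
              lemmatizer: Callable[[str], str] = default_lemmatizer,
              ) -> list[Phrase]:
    """Replace every token by its lemma, preserving phrase structure."""
    return [Phrase(tuple(lemmatizer(t) for t in p.tokens),
                   p.user_id, p.timestamp) for p in phrases]


def build_vocabulary(phrases: Sequence[Phrase]) -> Vocabulary:
    """Count token occurrences and rank words by descending frequency."""
    freq = Counter(t for p in phrases for t in p.tokens)
    if not freq:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    ranked = sorted(freq, key=lambda w: (-freq[w], w))
    return Vocabulary(index={w: i for i, w in enumerate(ranked)},
                      frequency=dict(freq))


def select_top_fraction(vocab: Vocabulary, fraction: float) -> list[str]:
    """Keep the most frequent ``ceil(fraction * N)`` words, in rank order."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    # round first so e.g. 0.07 * 100 = 7.000000000000001 keeps 7 words
    n_keep = math.ceil(round(fraction * vocab.size, 9))
    return vocab.words[:n_keep]


def pos_filter(words: Sequence[str],
               tagger: Callable[[str], str] = default_tagger,
               excluded_tags: Iterable[str] = DEFAULT_EXCLUDED_TAGS,
               ) -> list[str]:
    """Remove words whose part-of-speech tag is in ``excluded_tags``.

    The default exclusion set covers adverbs, modals, third-person-singular
    present verbs, gerunds, past participles, "to", prepositions and
    subordinating conjunctions, and personal pronouns (Penn Treebank tags
    RB, RBR, RBS, MD, VBZ, VBG, VBN, TO, IN, PRP).
    """
    excluded = frozenset(excluded_tags)
    return [w for w in words if tagger(w) not in excluded]


def apply_exclusion_list(words: Sequence[str],
                         stoplist: Iterable[str]) -> list[str]:
    """Drop words on the (clinician-curated) exclusion list, keeping order."""
    stop = frozenset(stoplist)
    return [w for w in words if w not in stop]


def build_analysis_vocabulary(phrases: Sequence[Phrase],
                              top_fraction: float = 0.07,
                              tagger: Callable[[str], str] = default_tagger,
                              excluded_tags: Iterable[str] = DEFAULT_EXCLUDED_TAGS,
                              stoplist: Iterable[str] = (),
                              ) -> tuple[Vocabulary, list[str]]:
    """Vocabulary plus the final filtered analysis word list."""
    vocab = build_vocabulary(phrases)
    words = select_top_fraction(vocab, top_fraction)
    words = pos_filter(words, tagger, excluded_tags)
    words = apply_exclusion_list(words, stoplist)
    return vocab, words


def read_wordlist(path: str | Path) -> list[str]:
    """One word per line, UTF-8; blank lines and '#' comments ignored."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            word = line.strip()
            if word and not word.startswith("#"):
                out.append(word)
    return out


def write_vocabulary_tsv(vocab: Vocabulary, words: Sequence[str],
                         path: str | Path) -> None:
    """Write the selected words as TSV columns (word, frequency, index)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("word\tfrequency\tindex\n")
        for w in words:
            fh.write(f"{w}\t{vocab.frequency[w]}\t{vocab.index[w]}\n")
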