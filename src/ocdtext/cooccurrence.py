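"""Phrase-level co-occurrence counting.

Two words co-occur when they appear in the same phrase: the window is the
whole phrase, every pair gets a unit increment, and there is no distance
weighting (unlike the sliding-window scheme used to train general-purpose
embeddings on running text — app entries are short, unordered bags of
symptom words). By default duplicate tokens inside a phrase count once
(set semantics); ``count_duplicates=True`` switches to token-pair
multiplicities.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import scipy.sparse as sp

from .preprocessing import Phrase, Vocabulary

__all__ = ["CooccurrenceMatrix", "build_cooccurrence",
           "write_cooccurrence_tsv", "read_cooccurrence_tsv"]


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Symmetric nonnegative-count matrix over a vocabulary.

    ``matrix`` is a sparse CSR matrix with zero diagonal; row/column ``i``
    corresponds to the word with vocabulary index ``i``.
    """

    matrix: sp.csr_matrix
    vocab: Vocabulary

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != self.vocab.size:
            raise ValueError("matrix shape must match vocabulary size")
        if (m != m.T).nnz != 0:
            raise ValueError("co-occurrence matrix must be symmetric")
        if m.diagonal().any():
            raise ValueError("diagonal must be zero")
        if (m.data < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def size(self) -> int:
        return self.matrix.shape[0]

    def count(self, word_i: str, word_j: str) -> int:
        return int(self.matrix[self.vocab.index[word_i],
                               self.vocab.index[word_j]])

    def nonzero_entries(self) -> Iterator[tuple[str, str, int]]:
        """Yield (word_i, word_j, count) for i < j."""
        words = self.vocab.words
        coo = sp.triu(self.matrix, k=1).tocoo()
        for i, j, v in zip(coo.row, coo.col, coo.data):
            yield words[i], words[j], int(v)

    def __add__(self, other: "CooccurrenceMatrix") -> "CooccurrenceMatrix":
        if other.vocab is not self.vocab and other.vocab.index != self.vocab.index:
            raise ValueError("can only add matrices over the same vocabulary")
        return CooccurrenceMatrix((self.matrix + other.matrix).tocsr(),
                                  self.vocab)


def build_cooccurrence(phrases: Sequence[Phrase], vocab: Vocabulary,
                       count_duplicates: bool = False) -> CooccurrenceMatrix:
    """One pass over the phrases, incrementing each co-occurring pair.

    Out-of-vocabulary tokens are ignored. With the default set semantics a
    pair of distinct words is incremented once per phrase containing both.
    """
    if vocab.size == 0:
        raise ValueError("vocabulary must be non-empty")
    rows: list[int] = []
    cols: list[int] = []
    for p in phrases:
        ids = [vocab.index[t] for t in p.tokens if t in vocab.index]
        if not count_duplicates:
            ids = sorted(set(ids))
        for a, b in combinations(ids, 2):
            if a == b:
                continue
            rows.extend((a, b))
            cols.extend((b, a))
    n = vocab.size
    m = sp.coo_matrix((np.ones(len(rows), dtype=np.int64), (rows, cols)),
                      shape=(n, n)).tocsr()
    m.sum_duplicates()
    return CooccurrenceMatrix(m, vocab)


def write_cooccurrence_tsv(cooc: CooccurrenceMatrix,
                           path: str | Path) -> None:
    """Write nonzero upper-triangle entries as (word_i, word_j, count) TSV.

    A vocabulary sidecar ``<path>.vocab.tsv`` records (word, frequency,
    index) so the matrix can be reconstructed standalone.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("word_i\tword_j\tcount\n")
        for wi, wj, c in cooc.nonzero_entries():
            fh.write(f"{wi}\t{wj}\t{c}\n")
    with open(path.with_suffix(path.suffix + ".vocab.tsv"), "w",
              encoding="utf-8") as fh:
        fh.write("word\tfrequency\tindex\n")
        for w in cooc.vocab.words:
            fh.write(f"{w}\t{cooc.vocab.frequency[w]}\t{cooc.vocab.index[w]}\n")


def read_cooccurrence_tsv(path: str | Path) -> CooccurrenceMatrix:
    path = Path(path)
    index: dict[str, int] = {}
    freq: dict[str, int] = {}
    with open(path.with_suffix(path.suffix + ".vocab.tsv"),
              encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            w, f, i = line.rstrip("\n").split("\t")
            index[w] = int(i)
            freq[w] = int(f)
    vocab = Vocabulary(index=index, frequency=freq)
    rows, cols, data = [], [], []
    with open(path, encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            wi, wj, c = line.rstrip("\n").split("\t")
            i, j = index[wi], index[wj]
            rows.extend((i, j))
            cols.extend((j, i))
            data.extend((int(c), int(c)))
    n = vocab.size
    m = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    return CooccurrenceMatrix(m, vocab)
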