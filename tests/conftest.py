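from datetime import datetime, timedelta

import numpy as np
import pytest
import scipy.sparse as sp

from ocdtext import CooccurrenceMatrix, Phrase, UserEntry, Vocabulary


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_1d_clusters():
    """The classic 1D two-cluster toy {0, 1 | 10, 11}."""
    X = np.array([[0.0], [1.0], [10.0], [11.0]])
    y = np.array([0, 0, 1, 1])
    return X, y


@pytest.fixture
def tiny_vocab():
    return Vocabulary(index={"a": 0, "b": 1, "c": 2},
                      frequency={"a": 5, "b": 3, "c": 2})


@pytest.fixture
def random_cooccurrence(rng):
    """Random symmetric 5-word co-occurrence matrix."""
    words = ["a", "b", "c", "d", "e"]
    vocab = Vocabulary(index={w: i for i, w in enumerate(words)},
                       frequency={w: 5 for w in words})
    upper = np.triu(rng.integers(0, 8, size=(5, 5)), k=1)
    return CooccurrenceMatrix(sp.csr_matrix(upper + upper.T), vocab)


def make_entries(texts, user_ids=None, start=None):
    """Entry list with evenly spaced timestamps, for preprocessing tests."""
    start = start or datetime(2019, 1, 1)
    user_ids = user_ids or [f"u{i}" for i in range(len(texts))]
    return [UserEntry(user_id=u, timestamp=start + timedelta(hours=i),
                      obsession=t)
            for i, (u, t) in enumerate(zip(user_ids, texts))]


def make_phrases(token_lists):
    start = datetime(2019, 1, 1)
    return [Phrase(tuple(toks), f"u{i}", start + timedelta(hours=i))
            for i, toks in enumerate(token_lists)]
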