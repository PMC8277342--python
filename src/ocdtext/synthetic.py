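"""Synthetic obsession-report corpora with planted semantic themes.

Real obsession reports from a treatment app cannot be redistributed, so every
downstream stage of the pipeline is exercised on synthetic corpora instead.
The generator emulates the salient statistical structure of such data:

* many anonymous users, each contributing a heavy-tailed number of short
  free-text entries (mode 1, ~95% contributing five or fewer, with optional
  extreme outlier users);
* a small number of latent semantic themes (e.g. contamination, checking,
  harm), each with its own lexicon;
* a shared "harm-like" core lexicon drawn into entries of every theme,
  creating the central convergence observed in real obsession vocabularies;
* a matching synthetic "pretrained" embedding table whose vector geometry
  carries the planted themes, standing in for general-purpose pretrained
  word vectors.

Everything is deterministic given ``SyntheticSpec.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "UserEntry",
    "generate_corpus",
    "generate_pretrained_embeddings",
    "theme_lexicons",
    "core_lexicon",
    "write_entries_csv",
    "write_entries_jsonl",
    "read_entries_csv",
    "read_entries_jsonl",
]

#: default distribution of entries per user: mode at one entry, ~96% at <=5,
#: thin tail spread over 6..10. Approximates the shape of per-user entry
#: histograms seen in symptom-tracking apps.
DEFAULT_ENTRIES_PER_USER = {
    1: 0.67, 2: 0.17, 3: 0.07, 4: 0.03, 5: 0.02,
    6: 0.008, 7: 0.008, 8: 0.008, 9: 0.008, 10: 0.008,
}

#: default phrase-length distribution over 1..8 tokens, skewed short: most
#: app entries are a few words ("germs on hands", "did i lock the door").
DEFAULT_PHRASE_LEN = {1: 0.30, 2: 0.25, 3: 0.17, 4: 0.11,
                      5: 0.07, 6: 0.05, 7: 0.03, 8: 0.02}

_EPOCH = datetime(2018, 3, 22)
_SPAN_SECONDS = int(timedelta(days=840).total_seconds())

_PUNCT = ["!", "!!", "?", "...", ",", "-"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic corpus and its planted theme structure.

    ``separation`` is the pairwise Euclidean distance between theme centroids
    in the synthetic pretrained embedding space; ``noise_sd`` is the
    per-component standard deviation of word vectors around their theme
    centroid. ``core_mix`` is the probability that any token is drawn from
    the shared core lexicon instead of the user's theme lexicon.
    """

    n_users: int = 2000
    k_true: int = 3
    theme_lexicon_size: int = 30
    shared_core_size: int = 10
    core_mix: float = 0.2
    entries_per_user_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ENTRIES_PER_USER))
    outlier_rate: float = 0.0005
    outlier_size: int = 120
    phrase_len_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PHRASE_LEN))
    embed_dim: int = 50
    separation: float = 10.0
    noise_sd: float = 0.5
    dirty: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_users", "k_true", "theme_lexicon_size",
                     "shared_core_size", "embed_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if not 0.0 <= self.core_mix <= 1.0:
            raise ValueError("core_mix must lie in [0, 1]")
        if self.separation <= 0:
            raise ValueError("separation must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must lie in [0, 1]")
        if self.outlier_size < 1:
            raise ValueError("outlier_size must be a positive count")
        for dname in ("entries_per_user_dist", "phrase_len_dist"):
            dist = getattr(self, dname)
            if not dist or any(p < 0 for p in dist.values()):
                raise ValueError(f"{dname} must have nonnegative weights")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{dname} probabilities must sum to 1")

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class UserEntry:
    """One app submission: the obsession text plus optional companion texts."""

    user_id: str
    timestamp: datetime
    obsession: str
    trigger: str | None = None
    exposure: str | None = None
    compulsion: str | None = None
    true_theme: int | None = None  # planted-theme label, synthetic data only

    def __post_init__(self) -> None:
        if not self.obsession:
            raise ValueError("obsession text must be non-empty")


def theme_lexicons(spec: SyntheticSpec) -> list[list[str]]:
    """Deterministic per-theme word lists (``t<theme>w<idx>``)."""
    return [[f"t{t}w{i}" for i in range(spec.theme_lexicon_size)]
            for t in range(spec.k_true)]


def core_lexicon(spec: SyntheticSpec) -> list[str]:
    """Shared core word list (``corew<idx>``) drawn into every theme."""
    return [f"corew{i}" for i in range(spec.shared_core_size)]


def _draw_counts(rng: np.random.Generator, dist: dict[int, float],
                 size: int) -> np.ndarray:
    keys = np.array(sorted(dist))
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), size=size, p=probs)]


def _dirtify(token: str, rng: np.random.Generator) -> str:
    if rng.random() < 0.3:
        token = token.capitalize() if rng.random() < 0.5 else token.upper()
    if rng.random() < 0.3:
        token = token + _PUNCT[rng.integers(len(_PUNCT))]
    return token


def generate_corpus(spec: SyntheticSpec) -> list[UserEntry]:
    """Generate a full entry table with planted themes.

    Each user is assigned one latent theme uniformly at random; each of their
    entries is a short phrase whose tokens come from the shared core lexicon
    with probability ``core_mix`` and from the user's theme lexicon
    otherwise. Timestamps are uniform over a fixed ~28-month window so that
    chronological splitting is meaningful. Returned entries are sorted by
    timestamp.
    """
    rng = np.random.default_rng(spec.seed)
    themes = theme_lexicons(spec)
    core = core_lexicon(spec)

    user_themes = rng.integers(spec.k_true, size=spec.n_users)
    n_entries = _draw_counts(rng, spec.entries_per_user_dist, spec.n_users)
    outliers = rng.random(spec.n_users) < spec.outlier_rate
    n_entries = np.where(outliers, spec.outlier_size, n_entries)

    total = int(n_entries.sum())
    # distinct second offsets => total order on timestamps
    offsets = rng.choice(_SPAN_SECONDS, size=total, replace=False)
    lengths = _draw_counts(rng, spec.phrase_len_dist, total)

    entries: list[UserEntry] = []
    pos = 0
    for u in range(spec.n_users):
        theme = int(user_themes[u])
        lex = themes[theme]
        for _ in range(int(n_entries[u])):
            length = int(lengths[pos])
            tokens = []
            for _ in range(length):
                pool = core if (core and rng.random() < spec.core_mix) else lex
                tokens.append(pool[rng.integers(len(pool))])
            if spec.dirty:
                tokens = [_dirtify(tok, rng) for tok in tokens]
            entries.append(UserEntry(
                user_id=f"u{u:06d}",
                timestamp=_EPOCH + timedelta(seconds=int(offsets[pos])),
                obsession=" ".join(tokens),
                true_theme=theme,
            ))
            pos += 1
    entries.sort(key=lambda e: e.timestamp)
    return entries


def generate_pretrained_embeddings(spec: SyntheticSpec):
    """Synthetic "pretrained" vectors carrying the planted theme geometry.

    Theme centroids are placed at scaled standard-basis directions
    ``(separation/sqrt(2)) * e_t``, which makes every pair of centroids
    exactly ``separation`` apart. Each theme word's vector is its centroid
    plus isotropic Gaussian noise with standard deviation ``noise_sd``.

    Shared core words model the central area of convergence seen in real
    obsession vocabularies: words like "harm" are used across every theme,
    sitting between the theme clusters rather than forming a subtype of
    their own. Each core word is therefore placed at a random convex
    combination of the theme centroids (symmetric Dirichlet weights), plus
    the same Gaussian noise — a diffuse central bridge, not a fourth blob.
    """
    from .embedding import EmbeddingTable

    if spec.embed_dim < spec.k_true:
        raise ValueError("embed_dim must be >= k_true to place centroids")
    rng = np.random.default_rng(spec.seed + 1)  # independent of corpus stream
    d = spec.embed_dim
    centroids = np.zeros((spec.k_true, d))
    for t in range(spec.k_true):
        centroids[t, t] = spec.separation / np.sqrt(2.0)
    words: list[str] = []
    vecs: list[np.ndarray] = []
    for t, lex in enumerate(theme_lexicons(spec)):
        for w in lex:
            words.append(w)
            vecs.append(centroids[t] + rng.normal(0.0, spec.noise_sd, size=d))
    for w in core_lexicon(spec):
        mix = rng.dirichlet(np.ones(spec.k_true))
        words.append(w)
        vecs.append(mix @ centroids + rng.normal(0.0, spec.noise_sd, size=d))
    return EmbeddingTable(words=words,
                          vectors={w: v for w, v in zip(words, vecs)},
                          dim=d)


# ---------------------------------------------------------------------------
# entry-table IO

_COLUMNS = ["user_id", "timestamp", "obsession", "trigger", "exposure",
            "compulsion", "true_theme"]


def _entries_frame(entries: Sequence[UserEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "user_id": e.user_id,
        "timestamp": e.timestamp.isoformat(),
        "obsession": e.obsession,
        "trigger": e.trigger,
        "exposure": e.exposure,
        "compulsion": e.compulsion,
        "true_theme": e.true_theme,
    } for e in entries], columns=_COLUMNS)


def _entries_from_frame(df: pd.DataFrame) -> list[UserEntry]:
    def opt(v):
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

    out = []
    for row in df.itertuples(index=False):
        theme = opt(getattr(row, "true_theme", None))
        out.append(UserEntry(
            user_id=str(row.user_id),
            timestamp=datetime.fromisoformat(str(row.timestamp)),
            obsession=str(row.obsession),
            trigger=opt(getattr(row, "trigger", None)),
            exposure=opt(getattr(row, "exposure", None)),
            compulsion=opt(getattr(row, "compulsion", None)),
            true_theme=None if theme is None else int(theme),
        ))
    return out


def write_entries_csv(entries: Sequence[UserEntry], path: str | Path) -> None:
    _entries_frame(entries).to_csv(path, index=False)


def read_entries_csv(path: str | Path) -> list[UserEntry]:
    return _entries_from_frame(pd.read_csv(path))


def write_entries_jsonl(entries: Sequence[UserEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in _entries_frame(entries).to_dict(orient="records"):
            fh.write(json.dumps(rec) + "\n")


def read_entries_jsonl(path: str | Path) -> list[UserEntry]:
    with open(path, encoding="utf-8") as fh:
        rows = [json.loads(line) for line in fh if line.strip()]
    return _entries_from_frame(pd.DataFrame(rows, columns=_COLUMNS))
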