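"""Split-half reliability of the word map.

The corpus is split into two equal halves — chronologically, or by users so
that no individual contributes to both halves — the whole pipeline is rerun
independently on each half, and agreement is quantified per word: the
Pearson correlation between the word's vector of Euclidean distances to all
other shared words in one half's 2D map and the same vector in the other
half's map. Distance profiles are invariant to the arbitrary rotation,
reflection and translation of each half's principal-component axes, and
Pearson r additionally ignores any global rescaling, so no Procrustes
alignment is needed.
"""

from __future__ import annotations

import json
import re
import warnings
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .cluster import ProjectedEmbedding
from .synthetic import UserEntry

__all__ = ["SplitResult", "StabilityReport", "split_sample",
           "distance_matrix", "rowwise_pearson", "stability_summary",
           "split_half_stability"]

_WORD_RE = re.compile(r"[a-zA-Z0-9]+")


def _entry_weight(entry: UserEntry, balance_on: str) -> int:
    if balance_on == "entries":
        return 1
    texts = [t for t in (entry.obsession, entry.trigger, entry.exposure,
                         entry.compulsion) if t]
    return len(_WORD_RE.findall(" ".join(texts)))


@dataclass(frozen=True)
class SplitResult:
    """Two disjoint halves of the entry table plus bookkeeping."""

    half_a: list[UserEntry]
    half_b: list[UserEntry]
    split_mode: str
    sizes: dict[str, dict[str, int]]  # {"a": {...}, "b": {...}}


@dataclass(frozen=True)
class StabilityReport:
    """Per-word split-half correlations and their summary.

    ``fraction_above`` is the share of shared words whose distance profiles
    correlate at or above ``threshold`` between halves; the map is flagged
    ``stable`` when that share exceeds one half. ``whole_matrix_r`` is the
    single Pearson correlation between the two vectorized distance matrices,
    reported alongside the per-word distribution.
    """

    shared_words: list[str]
    per_word_r: dict[str, float]
    threshold: float
    fraction_above: float
    median_r: float
    stable: bool
    whole_matrix_r: float

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({
                "threshold": self.threshold,
                "fraction_above": self.fraction_above,
                "median_r": self.median_r,
                "stable": self.stable,
                "whole_matrix_r": self.whole_matrix_r,
                "n_shared_words": len(self.shared_words),
            }, fh, indent=2)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("word\tr\n")
            for w in sorted(self.per_word_r):
                fh.write(f"{w}\t{self.per_word_r[w]:.6f}\n")


def split_sample(entries: Sequence[UserEntry], mode: str = "by_user",
                 balance_on: str = "words", seed: int = 0) -> SplitResult:
    """Split the corpus into two halves balanced on words or entries.

    ``chronological`` sorts by timestamp and cuts where the cumulative
    balancing quantity is closest to half the total. ``by_user`` shuffles
    users by seed and assigns each greedily (largest first) to the lighter
    half, so user sets are disjoint.
    """
    if len(entries) < 2:
        raise ValueError("need at least 2 entries to split")
    if balance_on not in ("words", "entries"):
        raise ValueError("balance_on must be 'words' or 'entries'")
    if mode == "chronological":
        ordered = sorted(entries, key=lambda e: e.timestamp)
        wts = [_entry_weight(e, balance_on) for e in ordered]
        cum = np.cumsum(wts)
        half = cum[-1] / 2.0
        cut = int(np.argmin(np.abs(cum - half))) + 1
        a, b = ordered[:cut], ordered[cut:]
    elif mode == "by_user":
        by_user: dict[str, list[UserEntry]] = defaultdict(list)
        for e in entries:
            by_user[e.user_id].append(e)
        if len(by_user) < 2:
            raise ValueError("by_user split requires at least 2 users")
        users = sorted(by_user)
        rng = np.random.default_rng(seed)
        rng.shuffle(users)
        weights = {u: sum(_entry_weight(e, balance_on) for e in by_user[u])
                   for u in users}
        users.sort(key=lambda u: -weights[u])  # stable: shuffle breaks ties
        a, b = [], []
        tot_a = tot_b = 0
        for u in users:
            if tot_a <= tot_b:
                a.extend(by_user[u])
                tot_a += weights[u]
            else:
                b.extend(by_user[u])
                tot_b += weights[u]
        a.sort(key=lambda e: e.timestamp)
        b.sort(key=lambda e: e.timestamp)
    else:
        raise ValueError(f"unknown split mode {mode!r}")

    def _sizes(half: list[UserEntry]) -> dict[str, int]:
        return {"entries": len(half),
                "users": len({e.user_id for e in half}),
                "words": sum(_entry_weight(e, "words") for e in half)}

    return SplitResult(half_a=a, half_b=b, split_mode=mode,
                       sizes={"a": _sizes(a), "b": _sizes(b)})


def distance_matrix(proj: ProjectedEmbedding,
                    words: Sequence[str]) -> np.ndarray:
    """Symmetric Euclidean word-to-word distances on the 2D map."""
    missing = [w for w in words if w not in proj.coords]
    if missing:
        raise KeyError(f"words missing from projection: {missing[:5]}")
    return squareform(pdist(proj.matrix(words), metric="euclidean"))


def rowwise_pearson(D_a: np.ndarray, D_b: np.ndarray,
                    words: Sequence[str]) -> dict[str, float]:
    """Per-word Pearson r between matching distance-matrix rows.

    The self-distance entry (a constant zero in both rows) is excluded
    before correlating. Rows with zero variance in either half have no
    defined correlation and are omitted with a warning.
    """
    n = len(words)
    if D_a.shape != (n, n) or D_b.shape != (n, n):
        raise ValueError("distance matrices must be square over the words")
    if n < 3:
        raise ValueError("need at least 3 shared words")
    out: dict[str, float] = {}
    for i, w in enumerate(words):
        mask = np.arange(n) != i
        ra, rb = D_a[i, mask], D_b[i, mask]
        if ra.std() == 0.0 or rb.std() == 0.0:
            warnings.warn(f"zero-variance distance row for {w!r}; "
                          "correlation undefined")
            continue
        out[w] = float(np.corrcoef(ra, rb)[0, 1])
    return out


def stability_summary(per_word_r: dict[str, float],
                      threshold: float = 0.90,
                      whole_matrix_r: float = np.nan) -> StabilityReport:
    """Summarize the per-word correlation distribution."""
    if not per_word_r:
        raise ValueError("empty correlation map")
    rs = np.array(list(per_word_r.values()))
    frac = float(np.mean(rs >= threshold))
    return StabilityReport(shared_words=sorted(per_word_r),
                           per_word_r=dict(per_word_r),
                           threshold=threshold,
                           fraction_above=frac,
                           median_r=float(np.median(rs)),
                           stable=frac > 0.5,
                           whole_matrix_r=whole_matrix_r)


def split_half_stability(entries: Sequence[UserEntry], pretrained,
                         config=None, mode: str = "by_user",
                         balance_on: str = "words", seed: int = 0,
                         threshold: float = 0.90) -> StabilityReport:
    """Split, rerun the full pipeline per half, and compare distance maps.

    Each half gets its own vocabulary selection, co-occurrence matrix,
    fine-tuned embedding and PCA projection; correlations are computed over
    the intersection of the two halves' analysis vocabularies.
    """
    from .pipeline import PipelineConfig, run_pipeline

    config = config or PipelineConfig()
    split = split_sample(entries, mode=mode, balance_on=balance_on, seed=seed)
    res_a = run_pipeline(split.half_a, pretrained, config)
    res_b = run_pipeline(split.half_b, pretrained, config)
    shared = sorted(set(res_a.analysis_words) & set(res_b.analysis_words))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared analysis words between halves")
    D_a = distance_matrix(res_a.projection, shared)
    D_b = distance_matrix(res_b.projection, shared)
    per_word = rowwise_pearson(D_a, D_b, shared)
    iu = np.triu_indices(len(shared), k=1)
    whole = float(np.corrcoef(D_a[iu], D_b[iu])[0, 1])
    return stability_summary(per_word, threshold=threshold,
                             whole_matrix_r=whole)
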