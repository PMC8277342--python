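"""Cluster frequency tables and chi-square comparisons.

Once words are clustered, two frequency measures are tabulated per cluster:
the number of unique words, and the total token count (sum of the words'
corpus frequencies). Clusters are compared with a chi-square goodness-of-fit
test against equal expected frequencies (df = c - 1, no continuity
correction), both omnibus and pairwise; pairwise p-values also get a
Bonferroni adjustment for the C(k, 2) family.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .preprocessing import Vocabulary

__all__ = ["ClusterFrequencyTable", "ChiSquareResult",
           "cluster_frequency_table", "chisq_gof", "pairwise_chisq"]


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    p_adjusted: float | None = None  # Bonferroni, pairwise family only

    def __post_init__(self) -> None:
        if self.statistic < 0 or self.df < 1:
            raise ValueError("invalid chi-square result")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


@dataclass(frozen=True)
class ClusterFrequencyTable:
    """Unique-word and total-token counts per cluster."""

    unique: dict[int, int]
    tokens: dict[int, int]

    @property
    def clusters(self) -> list[int]:
        return sorted(self.unique)

    @property
    def total_unique(self) -> int:
        return sum(self.unique.values())

    @property
    def total_tokens(self) -> int:
        return sum(self.tokens.values())

    def counts(self, measure: str) -> list[int]:
        if measure == "unique":
            return [self.unique[c] for c in self.clusters]
        if measure == "tokens":
            return [self.tokens[c] for c in self.clusters]
        raise ValueError("measure must be 'unique' or 'tokens'")

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"unique": {str(c): v for c, v in self.unique.items()},
                       "tokens": {str(c): v for c, v in self.tokens.items()}},
                      fh, indent=2)


def cluster_frequency_table(labels: Mapping[str, int],
                            vocab: Vocabulary) -> ClusterFrequencyTable:
    """Tally per-cluster unique words and their summed corpus frequencies."""
    missing = [w for w in labels if w not in vocab.frequency]
    if missing:
        raise KeyError(f"labeled words missing from vocabulary: {missing[:5]}")
    unique: dict[int, int] = {}
    tokens: dict[int, int] = {}
    for w, c in labels.items():
        unique[c] = unique.get(c, 0) + 1
        tokens[c] = tokens.get(c, 0) + vocab.frequency[w]
    return ClusterFrequencyTable(unique=unique, tokens=tokens)


def chisq_gof(counts: Sequence[float]) -> ChiSquareResult:
    """Chi-square goodness of fit against equal expected frequencies."""
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 categories")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    if counts.sum() == 0:
        raise ValueError("all-zero counts")
    stat, p = stats.chisquare(counts)
    return ChiSquareResult(statistic=float(stat), df=counts.size - 1,
                           p_value=float(p))


def pairwise_chisq(table: ClusterFrequencyTable,
                   measure: str = "unique",
                   ) -> dict[tuple[int, int], ChiSquareResult]:
    """Goodness-of-fit test on each pair of cluster counts.

    Each pair's p-value is Bonferroni-adjusted for the number of pairs.
    """
    clusters = table.clusters
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    counts = dict(zip(clusters, table.counts(measure)))
    pairs = [(a, b) for i, a in enumerate(clusters)
             for b in clusters[i + 1:]]
    out: dict[tuple[int, int], ChiSquareResult] = {}
    for a, b in pairs:
        res = chisq_gof([counts[a], counts[b]])
        out[(a, b)] = ChiSquareResult(
            statistic=res.statistic, df=res.df, p_value=res.p_value,
            p_adjusted=min(1.0, res.p_value * len(pairs)))
    return out
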