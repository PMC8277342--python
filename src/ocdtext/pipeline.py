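"""End-to-end orchestration: entries in, clustered 2D word map out.

Stages, in order: outlier-user removal, phrase assembly and cleaning,
lemmatization, vocabulary construction, top-fraction + POS + exclusion-list
filtering, phrase-level co-occurrence over the full vocabulary, Mittens
fine-tuning of (synthetic or real) pretrained vectors, PCA of the analysis
words' vectors to two components, and optional k-means model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

from .cluster import (ProjectedEmbedding, ValidityReport, pca_project,
                      select_k)
from .cooccurrence import CooccurrenceMatrix, build_cooccurrence
from .embedding import EmbedConfig, EmbeddingTable, fit_mittens
from .lexicon import (DEFAULT_EXCLUDED_TAGS, default_lemmatizer,
                      default_tagger)
from .preprocessing import (Phrase, Vocabulary, assemble_phrases,
                            build_vocabulary, apply_exclusion_list,
                            lemmatize, pos_filter, remove_outlier_users,
                            select_top_fraction)
from .synthetic import UserEntry

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "run_model_selection"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything tunable about a pipeline run.

    ``top_fraction`` keeps the most frequent share of the lemmatized
    vocabulary (0.07 mirrors real free-text corpora where most of the long
    vocabulary tail is noise; synthetic corpora built from a closed planted
    lexicon typically use 1.0). ``project_to_2d`` controls whether
    clustering operates on the 2-component PCA map (default) or on the full
    embedding space.
    """

    max_entries_per_user: int = 100
    corrections: Mapping[str, str] | None = None
    lemmatizer: Callable[[str], str] = default_lemmatizer
    tagger: Callable[[str], str] = default_tagger
    excluded_tags: frozenset[str] = DEFAULT_EXCLUDED_TAGS
    stoplist: Iterable[str] = ()
    top_fraction: float = 0.07
    embed: EmbedConfig = field(default_factory=EmbedConfig)
    project_to_2d: bool = True

    def for_dim(self, dim: int) -> "PipelineConfig":
        """Copy with the embedding dimension matched to a pretrained table."""
        return replace(self, embed=replace(self.embed, dim=dim))


@dataclass(frozen=True)
class PipelineResult:
    """All intermediate artifacts of one pipeline run."""

    entries: list[UserEntry]
    phrases: list[Phrase]
    vocab: Vocabulary
    analysis_words: list[str]
    cooccurrence: CooccurrenceMatrix
    embeddings: EmbeddingTable
    projection: ProjectedEmbedding


def run_pipeline(entries: Sequence[UserEntry],
                 pretrained: EmbeddingTable | None,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run preprocessing, embedding fine-tuning and 2D projection."""
    cfg = config or PipelineConfig()
    if pretrained is not None and pretrained.dim != cfg.embed.dim:
        cfg = cfg.for_dim(pretrained.dim)

    kept = remove_outlier_users(entries, cfg.max_entries_per_user)
    phrases = assemble_phrases(kept, cfg.corrections)
    phrases = lemmatize(phrases, cfg.lemmatizer)
    vocab = build_vocabulary(phrases)
    words = select_top_fraction(vocab, cfg.top_fraction)
    words = pos_filter(words, cfg.tagger, cfg.excluded_tags)
    words = apply_exclusion_list(words, cfg.stoplist)
    if len(words) < 3:
        raise ValueError("analysis vocabulary has fewer than 3 words")

    cooc = build_cooccurrence(phrases, vocab)
    embeddings = fit_mittens(cooc, pretrained, cfg.embed)
    analysis_table = EmbeddingTable(
        words=words,
        vectors={w: embeddings[w] for w in words},
        dim=embeddings.dim)
    projection = pca_project(analysis_table, n_components=2)
    return PipelineResult(entries=list(kept), phrases=phrases, vocab=vocab,
                          analysis_words=words, cooccurrence=cooc,
                          embeddings=embeddings, projection=projection)


def run_model_selection(result: PipelineResult, k_range=range(2, 9),
                        seed: int = 0,
                        use_projection: bool = True) -> ValidityReport:
    """Apply the four cluster-number heuristics to a pipeline result.

    ``use_projection=False`` clusters in the full embedding space instead of
    the 2D map, for sensitivity checks.
    """
    if use_projection:
        points = result.projection
    else:
        points = ProjectedEmbedding(
            words=list(result.analysis_words),
            coords={w: result.embeddings[w] for w in result.analysis_words},
            explained_variance_ratio=None)
    return select_k(points, k_range=k_range, seed=seed)
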