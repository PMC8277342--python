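"""Domain-adaptive word-embedding fine-tuning (GloVe objective + Mittens).

The model fits, for every pair of words with nonzero co-occurrence count
``X_ij``, the log-bilinear relation

    w_i . wc_j + b_i + bc_j  ~  log X_ij

under the capped power weighting ``f(x) = min((x/x_max)^alpha, 1)``, and adds
a retrofitting penalty ``mu * sum_{i in R} ||(w_i + wc_i) - r_i||^2`` pulling
each trained word toward its pretrained reference vector ``r_i`` (for the
subset R of words that have one). With ``mu = 0`` the objective reduces to
plain GloVe on the local corpus; large ``mu`` pins vectors to the pretrained
table. Optimization is deterministic full-batch AdaGrad — the analysis
vocabulary is at most a few thousand words, so there is no need for
stochastic minibatching. The final representation is ``w + wc``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cooccurrence import CooccurrenceMatrix

#: guards the AdaGrad division when a parameter's gradient is exactly zero
_ADAGRAD_EPS = 1e-8

__all__ = ["EmbeddingTable", "EmbedConfig", "TrainingState", "glove_weight",
           "mittens_loss", "fit_mittens", "train_mittens",
           "read_vectors", "write_vectors"]


@dataclass(frozen=True)
class EmbeddingTable:
    """word -> d-dimensional vector mapping."""

    words: list[str]
    vectors: dict[str, np.ndarray]
    dim: int

    def __post_init__(self) -> None:
        for w in self.words:
            v = self.vectors[w]
            if v.shape != (self.dim,):
                raise ValueError(f"vector for {w!r} has wrong dimension")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"vector for {w!r} has nonfinite components")

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __getitem__(self, word: str) -> np.ndarray:
        return self.vectors[word]

    def matrix(self, words: Sequence[str] | None = None) -> np.ndarray:
        """Stack vectors for ``words`` (default: all, in listed order)."""
        words = self.words if words is None else words
        return np.vstack([self.vectors[w] for w in words])


@dataclass(frozen=True)
class EmbedConfig:
    """Hyperparameters of the fine-tuning objective and optimizer.

    Defaults follow the original GloVe recipe (``x_max=100``, ``alpha=0.75``,
    learning rate 0.05) and the standard retrofitting weight ``mu=0.1``.
    ``penalize_sum`` applies the proximity penalty to the summed
    representation ``w + wc`` (the vector actually used downstream); set it
    to False to penalize ``w`` alone.
    """

    dim: int = 100
    x_max: float = 100.0
    alpha: float = 0.75
    mu: float = 0.1
    learning_rate: float = 0.05
    n_epochs: int = 1000
    penalize_sum: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.x_max <= 0:
            raise ValueError("x_max must be > 0")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.n_epochs < 0:
            raise ValueError("n_epochs must be >= 0")


@dataclass
class TrainingState:
    """All trainable parameters plus the AdaGrad accumulators.

    Rows follow vocabulary index order. ``ref`` holds pretrained reference
    vectors and ``has_ref`` marks the subset R of words that have one.
    """

    words: list[str]
    W: np.ndarray          # word vectors, (n, d)
    Wc: np.ndarray         # context vectors, (n, d)
    b: np.ndarray          # word biases, (n,)
    bc: np.ndarray         # context biases, (n,)
    ref: np.ndarray        # pretrained references, (n, d); zero outside R
    has_ref: np.ndarray    # boolean mask of R, (n,)
    acc_W: np.ndarray = field(default=None, repr=False)
    acc_Wc: np.ndarray = field(default=None, repr=False)
    acc_b: np.ndarray = field(default=None, repr=False)
    acc_bc: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.acc_W is None:
            self.acc_W = np.zeros_like(self.W)
            self.acc_Wc = np.zeros_like(self.Wc)
            self.acc_b = np.zeros_like(self.b)
            self.acc_bc = np.zeros_like(self.bc)


def glove_weight(x: float | np.ndarray, x_max: float = 100.0,
                 alpha: float = 0.75) -> float | np.ndarray:
    """Capped power weighting ``min((x/x_max)^alpha, 1)``."""
    x = np.asarray(x, dtype=float)
    out = np.where(x < x_max, np.power(x / x_max, alpha,
                                       where=x > 0, out=np.zeros_like(x)), 1.0)
    return float(out) if out.ndim == 0 else out


def _dense_targets(X: CooccurrenceMatrix, cfg: EmbedConfig):
    """Dense weight matrix f(X) (zero where X=0) and masked log X."""
    dense = np.asarray(X.matrix.todense(), dtype=float)
    mask = dense > 0
    weights = np.zeros_like(dense)
    weights[mask] = glove_weight(dense[mask], cfg.x_max, cfg.alpha)
    logx = np.zeros_like(dense)
    logx[mask] = np.log(dense[mask])
    return weights, logx


def mittens_loss(state: TrainingState, X: CooccurrenceMatrix,
                 cfg: EmbedConfig) -> float:
    """Weighted squared-error objective plus the retrofitting penalty.

    Sums over every ordered pair (i, j) with ``X_ij > 0`` (the matrix is
    symmetric, so each unordered pair contributes twice, matching the
    standard formulation over all nonzero entries).
    """
    if not (np.all(np.isfinite(state.W)) and np.all(np.isfinite(state.Wc))
            and np.all(np.isfinite(state.b)) and np.all(np.isfinite(state.bc))):
        raise FloatingPointError("nonfinite parameters in training state")
    weights, logx = _dense_targets(X, cfg)
    scores = state.W @ state.Wc.T + state.b[:, None] + state.bc[None, :]
    fit = float(np.sum(weights * (scores - logx) ** 2))
    if cfg.mu > 0 and state.has_ref.any():
        target = state.W + state.Wc if cfg.penalize_sum else state.W
        diff = (target - state.ref)[state.has_ref]
        fit += cfg.mu * float(np.sum(diff ** 2))
    return fit


def _init_state(X: CooccurrenceMatrix, pretrained: EmbeddingTable | None,
                cfg: EmbedConfig) -> TrainingState:
    words = X.vocab.words
    n, d = len(words), cfg.dim
    if pretrained is not None and pretrained.dim != d:
        raise ValueError(
            f"pretrained dimension {pretrained.dim} != configured dim {d}")
    rng = np.random.default_rng(cfg.seed)
    lim = 0.5 / d
    W = rng.uniform(-lim, lim, size=(n, d))
    Wc = rng.uniform(-lim, lim, size=(n, d))
    b = rng.uniform(-lim, lim, size=n)
    bc = rng.uniform(-lim, lim, size=n)
    ref = np.zeros((n, d))
    has_ref = np.zeros(n, dtype=bool)
    if pretrained is not None:
        for i, w in enumerate(words):
            if w in pretrained:
                ref[i] = pretrained[w]
                has_ref[i] = True
                W[i] = ref[i] / 2.0
                Wc[i] = ref[i] / 2.0
    return TrainingState(words=list(words), W=W, Wc=Wc, b=b, bc=bc,
                         ref=ref, has_ref=has_ref)


def train_mittens(X: CooccurrenceMatrix,
                  pretrained: EmbeddingTable | None,
                  cfg: EmbedConfig) -> tuple[TrainingState, list[float]]:
    """Run full-batch AdaGrad and return the state and per-epoch losses.

    The loss recorded for epoch t is the objective value *before* the t-th
    update, so ``history[0]`` is the loss at initialization.
    """
    state = _init_state(X, pretrained, cfg)
    weights, logx = _dense_targets(X, cfg)
    lr = cfg.learning_rate
    history: list[float] = []
    for _ in range(cfg.n_epochs):
        scores = state.W @ state.Wc.T + state.b[:, None] + state.bc[None, :]
        resid = weights * (scores - logx)
        history.append(float(np.sum(resid * (scores - logx))))
        g = 2.0 * resid
        grad_W = g @ state.Wc
        grad_Wc = g.T @ state.W
        grad_b = g.sum(axis=1)
        grad_bc = g.sum(axis=0)
        if cfg.mu > 0 and state.has_ref.any():
            target = state.W + state.Wc if cfg.penalize_sum else state.W
            pen = 2.0 * cfg.mu * (target - state.ref)
            pen[~state.has_ref] = 0.0
            grad_W += pen
            if cfg.penalize_sum:
                grad_Wc += pen
            history[-1] += cfg.mu * float(
                np.sum((target - state.ref)[state.has_ref] ** 2))
        # standard AdaGrad: accumulate, then step; each component's step is
        # bounded by lr, which keeps the full-batch update stable even when
        # the initial residuals are large
        for p, grad, acc in ((state.W, grad_W, state.acc_W),
                             (state.Wc, grad_Wc, state.acc_Wc),
                             (state.b, grad_b, state.acc_b),
                             (state.bc, grad_bc, state.acc_bc)):
            acc += grad ** 2
            p -= lr * grad / (np.sqrt(acc) + _ADAGRAD_EPS)
    return state, history


def fit_mittens(X: CooccurrenceMatrix,
                pretrained: EmbeddingTable | None,
                cfg: EmbedConfig,
                log_path: str | Path | None = None) -> EmbeddingTable:
    """Fine-tune and return the summed representation ``w + wc`` per word."""
    state, history = train_mittens(X, pretrained, cfg)
    if log_path is not None:
        with open(log_path, "w", encoding="utf-8") as fh:
            fh.write("epoch\tloss\n")
            for i, loss in enumerate(history):
                fh.write(f"{i}\t{loss:.10g}\n")
    final = state.W + state.Wc
    return EmbeddingTable(words=list(state.words),
                          vectors={w: final[i] for i, w in
                                   enumerate(state.words)},
                          dim=cfg.dim)


def write_vectors(table: EmbeddingTable, path: str | Path) -> None:
    """Standard word-vector text format: ``word v1 ... vd`` per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for w in table.words:
            vals = " ".join(f"{v:.8g}" for v in table.vectors[w])
            fh.write(f"{w} {vals}\n")


def read_vectors(path: str | Path,
                 restrict_to: Sequence[str] | None = None) -> EmbeddingTable:
    """Read a word-vector text file, optionally keeping only some words.

    The dimension is inferred from the first line; any line with a different
    field count raises a format error naming the offending line number.
    """
    keep = None if restrict_to is None else set(restrict_to)
    words: list[str] = []
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            if dim is None:
                dim = len(parts) - 1
                if dim < 1:
                    raise ValueError(f"line {lineno}: no vector components")
            if len(parts) - 1 != dim:
                raise ValueError(
                    f"line {lineno}: expected {dim} components, "
                    f"got {len(parts) - 1}")
            word = parts[0]
            if keep is not None and word not in keep:
                continue
            words.append(word)
            vectors[word] = np.array(parts[1:], dtype=float)
    if dim is None:
        raise ValueError("empty vector file")
    return EmbeddingTable(words=words, vectors=vectors, dim=dim)
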