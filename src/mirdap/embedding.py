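"""k-mer tokenization and skip-gram embedding of miRNA sequences.

A sequence of length l yields the l-k+1 overlapping k-mers read with a
sliding window of stride 1; with k=6 the token space has 4^6 = 4096
possible words. The skip-gram objective learns a vector per token by
predicting context tokens within a window around each centre token,
trained by stochastic gradient descent with either negative sampling
(default) or the full softmax (practical only for small vocabularies).
A miRNA's pooled representation is the arithmetic mean of the vectors of
its in-vocabulary tokens; a sequence with no in-vocabulary token maps to
the zero vector so downstream feature widths stay fixed.

Training is single-threaded and fully driven by one RNG, so identical
seeds reproduce identical vectors bit for bit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, TrainingError
from .io_formats import NamedMatrix, SequenceSet

logger = logging.getLogger(__name__)

RNA_LETTERS = "ACGU"


def tokenize(sequence: str, k: int) -> list[str]:
    """Overlapping k-mers of a sequence, in order; empty when l < k."""
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if len(sequence) < k:
        logger.warning("sequence of length %d is shorter than k=%d; no tokens",
                       len(sequence), k)
        return []
    return [sequence[i:i + k] for i in range(len(sequence) - k + 1)]


def all_kmers(k: int) -> list[str]:
    """Every possible RNA k-mer (4**k of them), lexicographic order."""
    return ["".join(p) for p in itertools.product(RNA_LETTERS, repeat=k)]


@dataclass
class KmerCorpus:
    """miRNA name -> ordered token list, for a fixed k."""

    k: int
    documents: dict[str, list[str]]


def build_corpus(sequences: SequenceSet, k: int = 6) -> KmerCorpus:
    return KmerCorpus(k=k, documents={name: tokenize(seq, k)
                                      for name, seq in sequences.records.items()})


@dataclass
class SkipgramConfig:
    """Skip-gram hyperparameters.

    min_count=5, window=5, size=64 and iterations=10 are the operating
    point of the prediction pipeline; negative, learning_rate and the
    objective follow common word2vec practice.
    """

    min_count: int = 5
    window: int = 5
    size: int = 64
    iterations: int = 10
    seed: int = 1
    negative: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    objective: str = "negative_sampling"  # or "softmax"

    def __post_init__(self) -> None:
        for name in ("min_count", "window", "size", "iterations"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if self.objective not in ("negative_sampling", "softmax"):
            raise ConfigurationError(f"unknown objective {self.objective!r}")


@dataclass
class KmerEmbedding:
    """Trained token -> vector table (the input vectors of the model)."""

    vectors: dict[str, np.ndarray]
    config: SkipgramConfig
    metadata: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return self.config.size

    def save_text(self, path) -> None:
        """word2vec-text-compatible dump: header line, then token + floats."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vectors)} {self.size}\n")
            for token in sorted(self.vectors):
                vec = " ".join(f"{x:.8g}" for x in self.vectors[token])
                fh.write(f"{token} {vec}\n")

    @classmethod
    def load_text(cls, path, config: SkipgramConfig | None = None) -> "KmerEmbedding":
        with open(path, encoding="utf-8") as fh:
            n, size = map(int, fh.readline().split())
            vectors = {}
            for line in fh:
                parts = line.split()
                vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
        if len(vectors) != n:
            raise TrainingError(f"embedding file {path} truncated")
        cfg = config or SkipgramConfig(size=size, min_count=1)
        return cls(vectors=vectors, config=cfg)


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def train_skipgram(corpus: KmerCorpus, config: SkipgramConfig | None = None) -> KmerEmbedding:
    """Fit skip-gram vectors on a k-mer corpus by seeded SGD.

    Tokens occurring fewer than min_count times are dropped from the
    vocabulary (and from the token streams before windowing, as usual for
    word2vec). The effective window per position is drawn uniformly from
    1..window. Negative samples follow the unigram^0.75 distribution.
    """
    config = config or SkipgramConfig()
    counts: dict[str, int] = {}
    for tokens in corpus.documents.values():
        for t in tokens:
            counts[t] = counts.get(t, 0) + 1
    vocab = sorted((t for t, c in counts.items() if c >= config.min_count),
                   key=lambda t: (-counts[t], t))
    if not vocab:
        raise TrainingError(
            "no token reaches min_count"
            f"={config.min_count}; lower min_count or supply a larger corpus"
        )
    index = {t: i for i, t in enumerate(vocab)}
    sentences = [[index[t] for t in tokens if t in index]
                 for tokens in corpus.documents.values()]
    sentences = [s for s in sentences if len(s) >= 2]
    if not sentences:
        raise TrainingError("no document retains >= 2 in-vocabulary tokens")

    rng = np.random.default_rng(config.seed)
    v = len(vocab)
    dim = config.size
    w_in = (rng.random((v, dim)) - 0.5) / dim
    w_out = np.zeros((v, dim))

    freq = np.array([counts[t] for t in vocab], dtype=float)
    noise = freq ** 0.75
    noise /= noise.sum()

    total = config.iterations * sum(len(s) for s in sentences)
    processed = 0
    lr0, lr_min = config.learning_rate, config.min_learning_rate
    for _ in range(config.iterations):
        for sent in sentences:
            n = len(sent)
            for pos, center in enumerate(sent):
                lr = max(lr_min, lr0 * (1.0 - processed / total))
                processed += 1
                span = int(rng.integers(1, config.window + 1))
                lo, hi = max(0, pos - span), min(n, pos + span + 1)
                vc = w_in[center]
                for ctx_pos in range(lo, hi):
                    if ctx_pos == pos:
                        continue
                    target = sent[ctx_pos]
                    if config.objective == "negative_sampling":
                        negs = rng.choice(v, size=config.negative, p=noise)
                        ids = np.concatenate(([target], negs))
                        labels = np.zeros(len(ids))
                        labels[0] = 1.0
                        outs = w_out[ids]
                        g = (labels - _sigmoid(outs @ vc)) * lr
                        grad_in = g @ outs
                        w_out[ids] += np.outer(g, vc)
                        vc += grad_in
                    else:  # full softmax over the vocabulary
                        scores = w_out @ vc
                        p = np.exp(scores - scores.max())
                        p /= p.sum()
                        p[target] -= 1.0
                        grad_in = -(p @ w_out) * lr
                        w_out -= lr * np.outer(p, vc)
                        vc += grad_in
    vectors = {t: w_in[i].copy() for t, i in index.items()}
    return KmerEmbedding(vectors=vectors, config=config,
                         metadata={"objective": config.objective,
                                   "vocabulary_size": v,
                                   "corpus_tokens": int(sum(len(s) for s in sentences))})


def embed_sequence(tokens: list[str], embedding: KmerEmbedding) -> np.ndarray:
    """Mean of in-vocabulary token vectors; zero vector if none are known."""
    vecs = [embedding.vectors[t] for t in tokens if t in embedding.vectors]
    if not vecs:
        logger.warning("sequence has no in-vocabulary token; zero vector used")
        return np.zeros(embedding.size)
    return np.mean(vecs, axis=0)


def build_rseq(sequences: SequenceSet, embedding: KmerEmbedding, k: int = 6) -> NamedMatrix:
    """Pooled embedding matrix, one row per miRNA in registry order."""
    names = sequences.names()
    rows = np.zeros((len(names), embedding.size))
    for i, name in enumerate(names):
        rows[i] = embed_sequence(tokenize(sequences.records[name], k), embedding)
    return NamedMatrix(names, [f"dim{j}" for j in range(embedding.size)], rows)
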