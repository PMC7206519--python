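"""Corpus word embeddings and the keyword-to-term-space mapping.

Embeddings are trained with word2vec's continuous-bag-of-words (CBOW)
architecture and negative sampling (window 5, 200 dimensions by default),
implemented directly in numpy so that training is bit-reproducible for a
fixed seed.  A document's projection into the term space sums, for each
term j, the cosine similarities between the term's embedding and each
keyword embedding that reaches the mapping threshold:

    T_j = sum over keywords kw of  cos(e(kw), e(term_j)) * [cos >= threshold]

with threshold in [0, 1] (default 0.5, inclusive comparison).  Keywords or
terms missing from the embedding vocabulary contribute 0.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus
from .keywords import KeywordSet
from .vectorspace import VectorSpace

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingTable:
    dim: int
    vectors: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.vectors:
            raise ValueError("embedding table must have a non-empty vocabulary")
        for s, v in self.vectors.items():
            if v.shape != (self.dim,):
                raise ValueError(f"vector for {s!r} has length {v.shape}, expected {self.dim}")

    def __contains__(self, surface: str) -> bool:
        return surface in self.vectors

    def __getitem__(self, surface: str) -> np.ndarray:
        return self.vectors[surface]

    def get(self, surface: str):
        return self.vectors.get(surface)

    def save_text(self, path) -> None:
        """Standard word2vec text format: header ``vocab_size dim`` then rows."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vectors)} {self.dim}\n")
            for s, v in self.vectors.items():
                fh.write(s + " " + " ".join(f"{x:.6g}" for x in v) + "\n")

    @classmethod
    def load_text(cls, path) -> "EmbeddingTable":
        with open(path, encoding="utf-8") as fh:
            n, dim = map(int, fh.readline().split())
            vectors = {}
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                vectors[parts[0]] = np.asarray(parts[1:], dtype=float)
        if len(vectors) != n:
            raise ValueError(f"header promised {n} vectors, file holds {len(vectors)}")
        return cls(dim, vectors)


@dataclass(frozen=True)
class MappingParams:
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("mapping threshold must lie in [0, 1]")


@dataclass
class TextVector:
    doc_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("text-vector entries must be nonnegative")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def train_embeddings(corpus: Corpus, dim: int = 200, window: int = 5,
                     seed: int = 0, epochs: int = 5, min_count: int = 1,
                     negative: int = 5, alpha: float = 0.025,
                     min_alpha: float = 1e-4, sample: float = 1e-3) -> EmbeddingTable:
    """Train CBOW negative-sampling embeddings over the corpus tokens.

    One document is one training sentence (title tokens then body tokens).
    Very frequent words are down-sampled with the standard keep probability
    ``sqrt(t/f) + t/f`` (t = ``sample``); context windows shrink uniformly
    at random as in the reference word2vec implementation; negatives are
    drawn from the unigram distribution raised to the 3/4 power; the
    learning rate decays linearly from ``alpha`` to ``min_alpha``.
    Training is single-threaded and deterministic for a fixed seed.
    """
    sentences = [d.surfaces() for d in corpus]
    counts = Counter(s for sent in sentences for s in sent)
    vocab = sorted(s for s, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValueError("empty vocabulary after min_count filtering")
    index = {s: i for i, s in enumerate(vocab)}
    rng = np.random.default_rng(seed)

    total_count = sum(counts[s] for s in vocab)
    keep = np.ones(len(vocab))
    if sample > 0:
        freq = np.array([counts[s] / total_count for s in vocab])
        keep = np.minimum(1.0, np.sqrt(sample / freq) + sample / freq)
    base = [np.array([index[s] for s in sent if s in index], dtype=np.int64)
            for sent in sentences]
    # frequent-word subsampling is redrawn every epoch; on corpora so small
    # that subsampling empties an epoch, train on the full stream instead
    full = [ids for ids in base if len(ids) > 1]
    epoch_streams = []
    for _ in range(max(epochs, 1)):
        stream = []
        for ids in base:
            ids = ids[rng.random(len(ids)) < keep[ids]]
            if len(ids) > 1:
                stream.append(ids)
        epoch_streams.append(stream or full)
    v = len(vocab)
    syn0 = (rng.random((v, dim)) - 0.5) / dim  # input (word) vectors
    syn1 = np.zeros((v, dim))                  # output (context) weights

    noise = np.array([counts[s] for s in vocab], dtype=float) ** 0.75
    noise /= noise.sum()
    noise_cdf = np.cumsum(noise)

    total = sum(len(e) for stream in epoch_streams for e in stream)
    if total == 0:
        # single-word sentences only: nothing to train on, return the
        # random initialization (still a valid table)
        return EmbeddingTable(dim, {s: syn0[i].copy() for s, i in index.items()},
                              metadata={"architecture": "cbow", "window": window,
                                        "seed": seed, "epochs": 0})
    processed = 0
    labels = np.zeros(negative + 1)
    labels[0] = 1.0
    for stream in epoch_streams[:epochs]:
        for sent in stream:
            n = len(sent)
            shrink = rng.integers(0, window, size=n)
            for pos in range(n):
                lr = max(min_alpha, alpha * (1.0 - processed / total))
                processed += 1
                w = window - shrink[pos]
                lo, hi = max(0, pos - w), min(n, pos + w + 1)
                context = np.concatenate([sent[lo:pos], sent[pos + 1:hi]])
                if len(context) == 0:
                    continue
                h = syn0[context].mean(axis=0)
                targets = np.empty(negative + 1, dtype=np.int64)
                targets[0] = sent[pos]
                targets[1:] = np.searchsorted(noise_cdf, rng.random(negative))
                out = syn1[targets]
                g = (labels - _sigmoid(out @ h)) * lr
                neu1e = g @ out
                np.add.at(syn1, targets, g[:, None] * h[None, :])
                syn0[context] += neu1e
    table = EmbeddingTable(dim, {s: syn0[i].copy() for s, i in index.items()},
                           metadata={"architecture": "cbow", "window": window,
                                     "seed": seed, "epochs": epochs,
                                     "negative": negative, "min_count": min_count})
    return table


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity; a zero vector yields 0 with a warning."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        warnings.warn("cosine of a zero vector is defined as 0", RuntimeWarning,
                      stacklevel=2)
        return 0.0
    return float(a @ b / (na * nb))


def resolve_term_embedding(term: str, table: EmbeddingTable,
                           space: VectorSpace):
    """Embedding for a term label: try the label, its compound form, aliases."""
    for surface in space.surfaces_for(term):
        vec = table.get(surface)
        if vec is not None:
            return vec
    return None


def build_text_vector(keywords: KeywordSet, table: EmbeddingTable,
                      space: VectorSpace,
                      params: MappingParams = MappingParams()) -> TextVector:
    """Project a document's keywords into the term space (thresholded cosine sum).

    Entry j sums cos(e(kw), e(term_j)) over keywords whose cosine to term j
    is >= the threshold.  Out-of-vocabulary keywords contribute nothing; a
    term with no embedding keeps entry 0 and is logged.
    """
    values = np.zeros(len(space))
    kw_vecs = [(s, table.get(s)) for s in keywords.surfaces]
    warned = table.metadata.setdefault("_warned_oov_terms", set())
    for j, term in enumerate(space.terms):
        tvec = resolve_term_embedding(term, table, space)
        if tvec is None:
            if term not in warned:  # warn once per table, not once per document
                logger.warning("term %r has no embedding; text-vector entry left 0", term)
                warned.add(term)
            continue
        for _, kvec in kw_vecs:
            if kvec is None:
                continue
            sim = cosine(kvec, tvec)
            if sim >= params.threshold:
                values[j] += sim
    return TextVector(keywords.doc_id, values)
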