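"""Top-k keyword extraction with TF-IDF and TextRank, plus three optional
improvement strategies: POS/title weight assignment, compound words (via
:mod:`edurec.corpus`), and character-composition synonym elimination.

Weight assignment multiplies a term's score by 3 when it occurs in the
title, by 1.2 when it is a noun, and by 0.8 when it is a verb (title and POS
factors combine multiplicatively).  Synonym elimination drops the shorter of
two candidates whose character-set one-hot vectors have cosine similarity at
or above a threshold.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, Document, Token

ALL_STRATEGIES = frozenset({"weights", "compounds", "synonyms"})


@dataclass(frozen=True)
class StrategyConfig:
    weight_title: float = 3.0
    weight_noun: float = 1.2
    weight_verb: float = 0.8
    synonym_threshold: float = 0.5
    strategies: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if min(self.weight_title, self.weight_noun, self.weight_verb) <= 0:
            raise ValueError("weights must be positive")
        if not 0.0 <= self.synonym_threshold <= 1.0:
            raise ValueError("synonym_threshold must lie in [0, 1]")
        unknown = set(self.strategies) - ALL_STRATEGIES
        if unknown:
            raise ValueError(f"unknown strategies: {sorted(unknown)}")

    def enabled(self, name: str) -> bool:
        return name in self.strategies


@dataclass
class KeywordSet:
    """Ranked keywords of one document: ``(surface, score)`` descending."""

    doc_id: str
    keywords: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        surfaces = [s for s, _ in self.keywords]
        if len(surfaces) != len(set(surfaces)):
            raise ValueError("keyword surfaces must be distinct")
        scores = [sc for _, sc in self.keywords]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("keyword scores must be non-increasing")

    @property
    def surfaces(self) -> list[str]:
        return [s for s, _ in self.keywords]

    def __len__(self) -> int:
        return len(self.keywords)


def candidate_filter(document: Document, stopwords: frozenset[str] = frozenset(),
                     min_chars: int = 2) -> list[Token]:
    """Keyword candidates: tokens minus stopwords and sub-``min_chars`` surfaces,
    order and multiplicity preserved."""
    return [t for t in document.tokens
            if t.surface not in stopwords and len(t.surface) >= min_chars]


def _weight_factors(document: Document, candidates: list[Token],
                    config: StrategyConfig) -> dict[str, float]:
    """Per-surface score multiplier for the weight-assignment strategy.

    POS factor uses the tag of the surface's first occurrence in the
    candidate stream (tags rarely differ across occurrences in practice).
    """
    title_surfaces = {t.surface for t in document.tokens if t.in_title}
    first_pos: dict[str, str] = {}
    for t in candidates:
        first_pos.setdefault(t.surface, t.pos)
    factors = {}
    for surface, pos in first_pos.items():
        w = config.weight_title if surface in title_surfaces else 1.0
        if pos == "noun":
            w *= config.weight_noun
        elif pos == "verb":
            w *= config.weight_verb
        factors[surface] = w
    return factors


def tfidf_scores(corpus: Corpus, document: Document,
                 config: StrategyConfig = StrategyConfig(),
                 stopwords: frozenset[str] = frozenset()) -> dict[str, float]:
    """score(t, d) = tf(t, d) * (ln((N+1)/(df(t)+1)) + 1) * w(t, d).

    tf is the raw in-document count and idf the smoothed logarithm above;
    w is the strategy weight (1 when the ``weights`` strategy is off).
    """
    if all(d.doc_id != document.doc_id for d in corpus):
        raise ValueError(f"document {document.doc_id!r} is not in the corpus")
    candidates = candidate_filter(document, stopwords)
    tf = Counter(t.surface for t in candidates)
    n = corpus.total_docs
    weights = (_weight_factors(document, candidates, config)
               if config.enabled("weights") else {})
    return {s: c * (math.log((n + 1) / (corpus.df(s) + 1)) + 1.0) * weights.get(s, 1.0)
            for s, c in tf.items()}


def textrank_scores(document: Document, window: int = 2, damping: float = 0.85,
                    tol: float = 1e-6, max_iter: int = 100,
                    config: StrategyConfig = StrategyConfig(),
                    stopwords: frozenset[str] = frozenset()) -> dict[str, float]:
    """Graph-based candidate ranking on an undirected co-occurrence graph.

    Distinct candidate surfaces are nodes; an edge's weight counts
    co-occurrences within a sliding window of ``window`` over the candidate
    sequence (window 2 = strict adjacency).  Scores iterate

        S(v) = (1 - damping) + damping * sum_u  w_uv / deg(u) * S(u)

    from S = 1 until the largest per-node change drops below ``tol``.  An
    isolated node converges to ``1 - damping``.  When the ``weights``
    strategy is enabled the converged score is multiplied by the same
    title/POS factor as in :func:`tfidf_scores`.
    """
    candidates = candidate_filter(document, stopwords)
    if not candidates:
        return {}
    surfaces = sorted({t.surface for t in candidates})
    index = {s: i for i, s in enumerate(surfaces)}
    m = len(surfaces)
    w = np.zeros((m, m))
    seq = [index[t.surface] for t in candidates]
    for i in range(len(seq)):
        for j in range(i + 1, min(i + window, len(seq))):
            a, b = seq[i], seq[j]
            if a != b:
                w[a, b] += 1.0
                w[b, a] += 1.0
    deg = w.sum(axis=1)
    trans = np.divide(w, deg[:, None], out=np.zeros_like(w), where=deg[:, None] > 0)
    s = np.ones(m)
    converged = False
    for _ in range(max_iter):
        s_new = (1.0 - damping) + damping * (trans.T @ s)
        if np.max(np.abs(s_new - s)) < tol:
            s = s_new
            converged = True
            break
        s = s_new
    if not converged:
        warnings.warn(f"TextRank did not converge within {max_iter} iterations",
                      RuntimeWarning, stacklevel=2)
    scores = dict(zip(surfaces, s.tolist()))
    if config.enabled("weights"):
        factors = _weight_factors(document, candidates, config)
        scores = {s_: sc * factors.get(s_, 1.0) for s_, sc in scores.items()}
    return scores


def character_cosine(a: str, b: str) -> float:
    """Cosine between binary character-composition vectors: |A∩B|/sqrt(|A||B|)."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        return 0.0
    return len(sa & sb) / math.sqrt(len(sa) * len(sb))


def eliminate_synonyms(ranked: list[tuple[str, float]],
                       threshold: float = 0.5) -> list[tuple[str, float]]:
    """Remove the shorter member of each high-character-overlap pair.

    ``ranked`` is scanned in score order; whenever two surviving surfaces
    have character-set cosine >= ``threshold`` the shorter one is dropped
    (length tie: the lower-scored; full tie: the lexicographically larger).
    The survivors keep their original order and are pairwise below threshold.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    out = list(ranked)
    changed = True
    while changed:
        changed = False
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                (sa, sca), (sb, scb) = out[i], out[j]
                if character_cosine(sa, sb) >= threshold:
                    if len(sa) != len(sb):
                        loser = i if len(sa) < len(sb) else j
                    elif sca != scb:
                        loser = j if sca > scb else i
                    else:
                        loser = i if sa > sb else j
                    del out[loser]
                    changed = True
                    break
            if changed:
                break
    return out


def extract_keywords(corpus: Corpus, document: Document, method: str = "tfidf",
                     k: int = 5, config: StrategyConfig = StrategyConfig(),
                     stopwords: frozenset[str] = frozenset(),
                     **method_kwargs) -> KeywordSet:
    """Return the top-``k`` keywords of ``document`` by the chosen method.

    When the ``synonyms`` strategy is enabled, elimination runs over the full
    ranked candidate list before truncation, so lower-ranked non-synonyms are
    promoted into the top ``k``.  Ties in score break by surface.  If the
    ``compounds`` strategy is intended, the corpus must already have been
    resegmented with the induced lexicon.
    """
    if method == "tfidf":
        scores = tfidf_scores(corpus, document, config, stopwords)
    elif method == "textrank":
        scores = textrank_scores(document, config=config, stopwords=stopwords,
                                 **method_kwargs)
    else:
        raise ValueError(f"unknown method {method!r}; expected 'tfidf' or 'textrank'")
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if config.enabled("synonyms"):
        ranked = eliminate_synonyms(ranked, config.synonym_threshold)
    return KeywordSet(document.doc_id, ranked[:k])
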