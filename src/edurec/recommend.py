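"""Patient-document scoring, ranking and the thresholded push queue.

A patient-document pair is scored by the inner product of the patient's
integer severity vector and the document's nonnegative text vector — a
non-normalized similarity that rewards agreement in both direction and
magnitude.  Documents whose score strictly exceeds the queue threshold
(v = 2 by default, chosen small because both vectors are sparse) enter a
per-patient recommendation queue from which batches are popped for
delivery; documents flagged non-reproducible are never delivered, and a
document is never delivered twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import TextVector
from .patients import PatientVector


@dataclass(frozen=True)
class ScoredPair:
    patient_id: str
    doc_id: str
    score: float


def inner_product(p: PatientVector, t: TextVector) -> float:
    if p.values.shape != t.values.shape:
        raise ValueError(f"vector length mismatch: patient has {p.values.shape[0]}, "
                         f"text has {t.values.shape[0]}")
    return float(p.values @ t.values)


def rank_documents(p: PatientVector, texts: list[TextVector]) -> list[ScoredPair]:
    """All documents scored and sorted: score descending, ties by doc_id."""
    pairs = [ScoredPair(p.patient_id, t.doc_id, inner_product(p, t)) for t in texts]
    return sorted(pairs, key=lambda s: (-s.score, s.doc_id))


@dataclass
class RecommendationQueue:
    patient_id: str
    threshold: float = 2.0
    entries: list[tuple[str, float]] = field(default_factory=list)  # (doc_id, score) desc
    delivered: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def doc_ids(self) -> list[str]:
        return [d for d, _ in self.entries]


def update_queue(queue: RecommendationQueue, ranking: list[ScoredPair],
                 reproducible_flags: dict[str, bool] | None = None) -> RecommendationQueue:
    """Rebuild the queue from a fresh ranking (stale scores replaced wholesale).

    Queued documents must score strictly above the threshold, be flagged
    reproducible (missing flag counts as reproducible) and not have been
    delivered already.
    """
    flags = reproducible_flags or {}
    entries = [(s.doc_id, s.score) for s in ranking
               if s.score > queue.threshold
               and s.doc_id not in queue.delivered
               and flags.get(s.doc_id, True)]
    entries.sort(key=lambda e: (-e[1], e[0]))
    return RecommendationQueue(queue.patient_id, queue.threshold, entries,
                               set(queue.delivered))


def pop_next(queue: RecommendationQueue, n: int) -> list[str]:
    """Remove and return up to ``n`` highest-scored queued documents,
    marking them delivered."""
    if n < 1:
        raise ValueError("n must be >= 1")
    batch = queue.entries[:n]
    queue.entries = queue.entries[n:]
    popped = [d for d, _ in batch]
    queue.delivered.update(popped)
    return popped
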