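"""Evaluation metrics: keyword-extraction precision and graded ranking
metrics (credited P@k, macro precision, mean average precision).

Relevance judgments are graded 0 / 1 / 2 (no need / partial need / most
need).  Credited precision at k counts a grade-2 document as 1 and a
grade-1 document as 0.5:

    P@k = (1/k) * sum over the top k of credit(grade)

Average precision treats any grade >= 1 as relevant for the indicator while
keeping the credited P@k inside the sum, and normalizes by the patient's
number of relevant documents R_i so a perfect binary ranking scores 1:

    AP_i = (1/R_i) * sum_k (P@k)_i * rel_i(k),     MAP = mean_i AP_i

Keyword precision is the fraction of automatically extracted keywords that
match the manual annotation (exact surface match after whitespace/case
normalization); when the automatic and manual counts per document are
equal, precision equals recall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

GRADE_CREDIT = {0: 0.0, 1: 0.5, 2: 1.0}


@dataclass(frozen=True)
class RelevanceJudgment:
    patient_id: str
    doc_id: str
    grade: int

    def __post_init__(self) -> None:
        if self.grade not in (0, 1, 2):
            raise ValueError(f"grade must be 0, 1 or 2, got {self.grade}")


def judgments_by_patient(judgments: list[RelevanceJudgment]) -> dict[str, dict[str, int]]:
    out: dict[str, dict[str, int]] = {}
    for j in judgments:
        out.setdefault(j.patient_id, {})[j.doc_id] = j.grade
    return out


@dataclass(frozen=True)
class KeywordPrecisionReport:
    n_auto: int
    n_manual: int
    n_correct: int

    @property
    def precision(self) -> float:
        return self.n_correct / self.n_manual if self.n_manual else 0.0


def _normalize(surface: str) -> str:
    return " ".join(surface.split()).casefold()


def keyword_precision(auto: dict[str, "object"],
                      manual: dict[str, set[str]]) -> KeywordPrecisionReport:
    """Corpus-level precision of automatic keyword extraction.

    ``auto`` maps doc_id to a KeywordSet or an iterable of surfaces;
    ``manual`` maps doc_id to the annotated keyword set.  Both maps must
    cover the same documents.
    """
    only_auto = set(auto) - set(manual)
    only_manual = set(manual) - set(auto)
    if only_auto or only_manual:
        missing = sorted(only_auto | only_manual)
        raise ValueError(f"doc coverage mismatch between auto and manual: {missing}")
    n_auto = n_manual = n_correct = 0
    for doc_id, kws in auto.items():
        surfaces = getattr(kws, "surfaces", kws)
        auto_set = {_normalize(s) for s in surfaces}
        manual_set = {_normalize(s) for s in manual[doc_id]}
        n_auto += len(auto_set)
        n_manual += len(manual_set)
        n_correct += len(auto_set & manual_set)
    return KeywordPrecisionReport(n_auto, n_manual, n_correct)


def precision_at_k(ranking: list[str], judgments: dict[str, int], k: int) -> float:
    """Credited precision at rank ``k``; unjudged documents earn credit 0."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ranking):
        warnings.warn(f"k={k} exceeds ranking length {len(ranking)}; "
                      "computed over the full ranking", RuntimeWarning, stacklevel=2)
        k = len(ranking)
    credit = sum(GRADE_CREDIT[judgments.get(d, 0)] for d in ranking[:k])
    return credit / k


def macro_precision_at_k(rankings: dict[str, list[str]],
                         judgments: dict[str, dict[str, int]], k: int) -> float:
    """Arithmetic mean of per-patient credited P@k."""
    if not rankings:
        raise ValueError("macro precision needs at least one patient")
    return float(np.mean([precision_at_k(r, judgments.get(pid, {}), k)
                          for pid, r in rankings.items()]))


def average_precision(ranking: list[str], judgments: dict[str, int]) -> float:
    """Credited AP for one patient; raises if the patient has no relevant doc."""
    if not ranking:
        raise ValueError("cannot compute average precision of an empty ranking")
    relevant = {d for d, g in judgments.items() if g >= 1}
    r_i = len(relevant)
    if r_i == 0:
        raise ValueError("patient has no relevant (grade >= 1) document")
    total = 0.0
    credit = 0.0
    for k, doc in enumerate(ranking, start=1):
        credit += GRADE_CREDIT[judgments.get(doc, 0)]
        if doc in relevant:
            total += credit / k
    return total / r_i


def mean_average_precision(rankings: dict[str, list[str]],
                           judgments: dict[str, dict[str, int]]) -> float:
    """MAP over patients; patients with no relevant document are excluded
    (their AP is undefined) with a warning."""
    aps = []
    skipped = []
    for pid, ranking in rankings.items():
        judg = judgments.get(pid, {})
        if not any(g >= 1 for g in judg.values()):
            skipped.append(pid)
            continue
        aps.append(average_precision(ranking, judg))
    if skipped:
        warnings.warn(f"excluded {len(skipped)} patient(s) with no relevant "
                      f"document from MAP: {sorted(skipped)}", RuntimeWarning,
                      stacklevel=2)
    if not aps:
        raise ValueError("no patient has a relevant document; MAP undefined")
    return float(np.mean(aps))


@dataclass
class MetricsReport:
    """Recommendation metrics over one patient population."""

    m_patients: int
    n_documents: int
    per_patient_p_at_k: dict[str, dict[int, float]]
    macro_p_at_k: dict[int, float]
    map_score: float


def evaluate_rankings(rankings: dict[str, list[str]],
                      judgments: dict[str, dict[str, int]],
                      at: tuple[int, ...] = (1, 2, 3, 4, 5, 10, 15, 20, 25, 30)) -> MetricsReport:
    n_docs = max((len(r) for r in rankings.values()), default=0)
    ks = tuple(k for k in at if k <= n_docs)
    per_patient = {pid: {k: precision_at_k(r, judgments.get(pid, {}), k) for k in ks}
                   for pid, r in rankings.items()}
    macro = {k: macro_precision_at_k(rankings, judgments, k) for k in ks}
    return MetricsReport(len(rankings), n_docs, per_patient, macro,
                         mean_average_precision(rankings, judgments))


def random_baseline(m: int, n: int, relevant_per_patient: int, k: int,
                    replicates: int = 1000, seed: int = 0) -> float:
    """Monte-Carlo macro P@k for uniformly random rankings.

    Each of ``m`` patients has exactly ``relevant_per_patient`` grade-2
    documents among ``n``; the expectation is relevant_per_patient / n.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if not 0 <= relevant_per_patient <= n:
        raise ValueError("relevant_per_patient must lie in 0..n")
    if not 1 <= k <= n:
        raise ValueError("k must lie in 1..n")
    rng = np.random.default_rng(seed)
    # ranking positions of each doc are a uniform permutation; docs
    # 0..relevant-1 are the relevant ones
    perms = rng.random((replicates * m, n)).argsort(axis=1)
    hits = (perms[:, :k] < relevant_per_patient).sum(axis=1) / k
    return float(hits.reshape(replicates, m).mean(axis=1).mean())
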