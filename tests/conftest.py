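"""Shared fixtures and independent oracle implementations.

The oracles are deliberately plain-Python / brute-force re-statements of
the published formulas, kept free of any package internals so they can
serve as independent references.
"""

from __future__ import annotations

import pytest

from edurec.corpus import build_corpus


@pytest.fixture
def tiny_corpus():
    """Two untitled documents over three two-character surfaces."""
    return build_corpus([
        ("D1", "", "xx xx yy", True),
        ("D2", "", "yy zz", True),
    ])


@pytest.fixture
def titled_corpus():
    """D1 has a noun title word; body tokens carry explicit POS tags."""
    return build_corpus([
        ("D1", "yy/n", "xx/v xx/v", True),
        ("D2", "", "yy/n zz/n", True),
    ])


def textrank_oracle(sequence: list[str], window: int = 2, damping: float = 0.85,
                    iters: int = 100000, tol: float = 1e-14) -> dict[str, float]:
    """Dense power iteration over the co-occurrence graph, plain Python."""
    nodes = sorted(set(sequence))
    w = {u: {v: 0.0 for v in nodes} for u in nodes}
    for i in range(len(sequence)):
        for j in range(i + 1, min(i + window, len(sequence))):
            a, b = sequence[i], sequence[j]
            if a != b:
                w[a][b] += 1.0
                w[b][a] += 1.0
    deg = {u: sum(w[u].values()) for u in nodes}
    s = {u: 1.0 for u in nodes}
    for _ in range(iters):
        s_new = {}
        for v in nodes:
            acc = 0.0
            for u in nodes:
                if w[u][v] > 0 and deg[u] > 0:
                    acc += w[u][v] / deg[u] * s[u]
            s_new[v] = (1.0 - damping) + damping * acc
        delta = max(abs(s_new[v] - s[v]) for v in nodes)
        s = s_new
        if delta < tol:
            break
    return s


CREDIT = {0: 0.0, 1: 0.5, 2: 1.0}


def p_at_k_oracle(ranking: list[str], grades: dict[str, int], k: int) -> float:
    return sum(CREDIT[grades.get(d, 0)] for d in ranking[:k]) / k


def ap_oracle(ranking: list[str], grades: dict[str, int]) -> float:
    relevant = sum(1 for g in grades.values() if g >= 1)
    total = 0.0
    for k in range(1, len(ranking) + 1):
        if grades.get(ranking[k - 1], 0) >= 1:
            total += p_at_k_oracle(ranking, grades, k)
    return total / relevant
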