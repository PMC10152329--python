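"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the library's own scan/fit code paths: matching is
done by enumerating every n-gram, products by explicit double loops, and
ranking by exhaustive per-resource scoring.
"""

from __future__ import annotations

import math

import numpy as np


def relevance_oracle(tf: int, dl: int, pivot: float, slope: float) -> float:
    """Closed-form pivoted-unique-normalized log-tf weight."""
    return (1.0 + math.log(tf)) / ((1.0 - slope) * pivot + slope * dl)


def ngram_match_oracle(tokens, patterns, max_len):
    """Enumerate every n-gram (n <= max_len); apply longest-match,
    left-to-right, non-overlap.  Returns [(start, end, entry), ...]."""
    candidates = {}
    n = len(tokens)
    for i in range(n):
        for L in range(1, min(max_len, n - i) + 1):
            gram = tuple(tokens[i : i + L])
            if gram in patterns:
                candidates.setdefault(i, []).append(L)
    out = []
    i = 0
    while i < n:
        if i in candidates:
            L = max(candidates[i])
            for entry in patterns[tuple(tokens[i : i + L])]:
                out.append((i, i + L, entry))
            i += L
        else:
            i += 1
    return out


def matmul_oracle(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise triple-loop matrix product."""
    n, k = a.shape
    k2, m = b.shape
    assert k == k2
    out = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            s = 0.0
            for t in range(k):
                s += a[i, t] * b[t, j]
            out[i, j] = s
    return out


def owa_oracle(weights, values) -> float:
    vals = sorted(values, reverse=True)
    return sum(w * v for w, v in zip(weights, vals))


def rank_oracle(resource_vectors: dict, weights) -> list:
    """Exhaustive scoring of every resource; sort by (-score, doc_id)."""
    scored = [
        (owa_oracle(weights, vec), doc_id) for doc_id, vec in resource_vectors.items()
    ]
    return sorted(scored, key=lambda r: (-r[0], r[1]))


def macro_f1_oracle(pred, truth, categories) -> float:
    """Confusion-matrix macro F1 computed per category from scratch."""
    per_cat = []
    for c in categories:
        tp = fp = fn = 0
        for p, t in zip(pred, truth):
            if c in p and c in t:
                tp += 1
            elif c in p:
                fp += 1
            elif c in t:
                fn += 1
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        per_cat.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return sum(per_cat) / len(per_cat)
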