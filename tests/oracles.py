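"""Independent brute-force oracles used by unit and acceptance tests.

Deliberately naive implementations (loops, enumeration) kept separate from
the package code paths they verify.
"""

from __future__ import annotations

import math
from collections import Counter


def tau_oracle(transformed_profile) -> float:
    """Direct evaluation of the specificity index on already-transformed
    per-tissue values."""
    y = list(transformed_profile)
    ymax = max(y)
    if ymax == 0:
        return float("nan")
    total = 0.0
    for v in y:
        total += 1.0 - v / ymax
    return total / (len(y) - 1)


def bh_oracle(pvalues) -> list[float]:
    """Step-up Benjamini-Hochberg by explicit loops."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    adj_sorted = [0.0] * m
    running = float("inf")
    for k in range(m - 1, -1, -1):
        value = pvalues[indexed[k]] * m / (k + 1)
        running = min(running, value)
        adj_sorted[k] = min(running, 1.0)
    out = [0.0] * m
    for k, i in enumerate(indexed):
        out[i] = adj_sorted[k]
    return out


def identity_oracle(seq_a: str, seq_b: str) -> float:
    shared = 0
    same = 0
    for ca, cb in zip(seq_a, seq_b):
        if ca != "-" and cb != "-":
            shared += 1
            if ca == cb:
                same += 1
    return float("nan") if shared == 0 else same / shared


def column_conservation_oracle(column) -> float:
    residues = [c for c in column if c != "-"]
    if not residues:
        return float("nan")
    counts = Counter(residues)
    return max(counts.values()) / len(residues)


def nw_score_oracle(seq_a: str, seq_b: str, sub, gap_open: float,
                    gap_extend: float) -> float:
    """Optimal global alignment score by exhaustive enumeration.

    A gap of length L costs gap_open + (L - 1) * gap_extend; a gap in one
    sequence immediately followed by a gap in the other opens a new gap.
    Only usable for tiny sequences.
    """
    best = [-math.inf]

    def recurse(i: int, j: int, prev: str, score: float) -> None:
        if i == len(seq_a) and j == len(seq_b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(seq_a) and j < len(seq_b):
            recurse(i + 1, j + 1, "M", score + float(sub[seq_a[i], seq_b[j]]))
        if i < len(seq_a):
            pen = gap_extend if prev == "U" else gap_open
            recurse(i + 1, j, "U", score - pen)
        if j < len(seq_b):
            pen = gap_extend if prev == "L" else gap_open
            recurse(i, j + 1, "L", score - pen)

    recurse(0, 0, "", 0.0)
    return best[0]


def spearman_oracle(x, y) -> float:
    """Rank (mid-ranks for ties) then Pearson, all by hand."""

    def ranks(values):
        order = sorted(range(len(values)), key=lambda i: values[i])
        out = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                j += 1
            mid = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                out[order[k]] = mid
            i = j + 1
        return out

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)
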