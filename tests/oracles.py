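"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit Python loops, exact
integer arithmetic) and shares no code with the package internals it
checks.
"""

import math
from fractions import Fraction

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def window_score(probs, window: str, bg4, pseudocount: float) -> float:
    """Log2-odds of one window under a PSSM, pseudocount then renormalize."""
    order = "ACGT"
    total = 0.0
    for i, base in enumerate(window):
        if base not in order:
            return float("nan")
        row = [p + pseudocount for p in probs[i]]
        s = sum(row)
        q = row[order.index(base)] / s
        total += math.log2(q / bg4[order.index(base)])
    return total


def brute_force_hits(probs, seq: str, bg4, threshold: float, pseudocount: float):
    """All (offset, strand, score) with score >= threshold, both strands."""
    n = len(probs)
    out = []
    for off in range(len(seq) - n + 1):
        w = seq[off : off + n]
        s = window_score(probs, w, bg4, pseudocount)
        if s == s and s >= threshold:
            out.append((off, "+", s))
        s = window_score(probs, revcomp(w), bg4, pseudocount)
        if s == s and s >= threshold:
            out.append((off, "-", s))
    out.sort(key=lambda h: (h[0], h[1]))
    return out


def concordance_auc(scores, labels) -> float:
    """AUC by explicit pairwise concordance counting (ties = 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_region_mean(probes, start: int, end: int):
    """Mean of probe values overlapping [start, end) by >= 1 bp; None if none."""
    vals = [v for (s, e, v) in probes if s < end and e > start]
    return None if not vals else sum(vals) / len(vals)


def fisher_greater_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """One-sided (enrichment) Fisher P by exact hypergeometric enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    num = sum(math.comb(r1, x) * math.comb(n - r1, c1 - x) for x in range(a, hi + 1))
    return Fraction(num, math.comb(n, c1))


def information_content_terms(probs, bg4) -> float:
    """IC by explicit term summation: sum p * log2(p / bg), 0 log 0 = 0."""
    total = 0.0
    for row in probs:
        for p, b in zip(row, bg4):
            if p > 0:
                total += p * math.log2(p / b)
    return total
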