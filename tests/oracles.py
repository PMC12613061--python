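"""Independent brute-force oracles used to check the package's statistics.

Everything here is deliberately naive: big-integer enumeration, pure-Python
running sums, exhaustive sequence scoring.  None of it shares code with the
implementation under test.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import product
from math import comb


def hypergeom_sf_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by exact enumeration."""
    total = comb(N, n)
    s = sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1))
    return Fraction(s, total)


def bh_stepup(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up, written from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvals[i] * m / rank)
        adjusted[i] = min(1.0, running_min)
    return adjusted


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    N = a + b + c + d
    K, n = a + b, a + c
    total = comb(N, n)
    obs = comb(K, a) * comb(N - K, n - a)
    s = 0
    for x in range(max(0, n - (N - K)), min(K, n) + 1):
        w = comb(K, x) * comb(N - K, n - x)
        if w <= obs:
            s += w
    return Fraction(s, total)


def brute_es(
    genes: list[str], metric: list[float], members: set[str], weight: float
) -> float:
    """Weighted KS enrichment score via an explicit Python loop."""
    n = len(genes)
    hit_weights = [abs(m) ** weight if g in members else 0.0 for g, m in zip(genes, metric)]
    denom = sum(hit_weights)
    n_hits = sum(1 for g in genes if g in members)
    if denom == 0:
        hit_weights = [1.0 if g in members else 0.0 for g in genes]
        denom = float(n_hits)
    miss = 1.0 / (n - n_hits)
    running, best, cur = [], 0.0, 0.0
    for g, hw in zip(genes, hit_weights):
        if g in members:
            cur += hw / denom
        else:
            cur -= miss
        running.append(cur)
    hi = max(running)
    lo = min(running)
    return hi if abs(hi) >= abs(lo) else lo


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_scan(seq: str, pwm_cols: list[dict[str, float]], threshold: float):
    """Per-offset, per-strand scoring with explicit loops; N never matches."""
    w = len(pwm_cols)
    rc = "".join(_COMP.get(b, "N") for b in reversed(seq))
    hits = []
    for strand, s in (("+", seq), ("-", rc)):
        for off in range(len(s) - w + 1):
            window = s[off : off + w]
            if "N" in window:
                continue
            score = sum(pwm_cols[j][window[j]] for j in range(w))
            if score >= threshold:
                fwd_off = off if strand == "+" else len(seq) - w - off
                hits.append((fwd_off, strand, score))
    return sorted(hits)


def enumerate_pwm_tail(pwm_cols: list[dict[str, float]], background: dict[str, float]):
    """Exhaustive (score, probability) pairs over all 4^w background sequences."""
    out = []
    for word in product("ACGT", repeat=len(pwm_cols)):
        score = sum(pwm_cols[j][b] for j, b in enumerate(word))
        prob = 1.0
        for b in word:
            prob *= background[b]
        out.append((score, prob))
    return out


def enumerate_threshold(
    pwm_cols: list[dict[str, float]], background: dict[str, float], p_cutoff: float
) -> float:
    """Smallest attainable score whose upper-tail probability is <= p_cutoff."""
    by_score: dict[float, float] = {}
    for score, prob in enumerate_pwm_tail(pwm_cols, background):
        by_score[round(score, 9)] = by_score.get(round(score, 9), 0.0) + prob
    tail = 0.0
    best = float("inf")
    for score in sorted(by_score, reverse=True):
        tail += by_score[score]
        if tail <= p_cutoff * (1 + 1e-9):
            best = score
        else:
            break
    return best
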