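"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (loops, enumeration, direct
formulas) and shares no code with the package paths it checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def bh_stepup(pvals):
    """Benjamini-Hochberg step-up by the direct definition."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, p[i] * m / rank)
        adj[i] = min(val, 1.0)
        prev = val
    return adj


def hypergeom_tail(a, b, c, d):
    """P(X >= a) for the 2x2 table margins, by explicit enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d
    total = 0.0
    for k in range(a, min(row1, col1) + 1):
        total += comb(col1, k) * comb(n - col1, row1 - k) / comb(n, row1)
    return total


def gsea_running_sum(genes_sorted, scores_sorted, members, weight):
    """Weighted KS running sum, step by step."""
    nh = sum(1 for g in genes_sorted if g in members)
    n = len(genes_sorted)
    hit_norm = sum(abs(s) ** weight for g, s in zip(genes_sorted, scores_sorted)
                   if g in members)
    running, extremum = 0.0, 0.0
    for g, s in zip(genes_sorted, scores_sorted):
        if g in members:
            running += (abs(s) ** weight / hit_norm) if hit_norm > 0 else 1.0 / nh
        else:
            running -= 1.0 / (n - nh)
        if abs(running) > abs(extremum):
            extremum = running
    return extremum


def pwm_score_tail(emissions, background, granularity):
    """Null distribution of integerised window scores by enumerating every
    word over the 5-letter alphabet."""
    width = emissions.shape[0]
    dist = {}
    for word in itertools.product(range(5), repeat=width):
        k, prob, ok = 0, 1.0, True
        for pos, letter in enumerate(word):
            e = emissions[pos, letter]
            if e == 0:
                ok = False
                break
            k += int(round(np.log2(e / background[letter]) / granularity))
            prob *= background[letter]
        if ok:
            dist[k] = dist.get(k, 0.0) + prob
    return dist


def window_scores_bruteforce(encoded, emissions, background):
    """Real-valued log2-odds score of every window (both naive loops)."""
    idx = {c: i for i, c in enumerate("ACGTM")}
    width = emissions.shape[0]
    out = []
    for start in range(len(encoded) - width + 1):
        s = 0.0
        for pos in range(width):
            e = emissions[pos, idx[encoded[start + pos]]]
            if e == 0:
                s = float("-inf")
                break
            s += np.log2(e / background[idx[encoded[start + pos]]])
        out.append(s)
    return out


def pooled_t(x, y):
    """Textbook two-sample pooled-variance t statistic."""
    nx, ny = len(x), len(y)
    sp2 = (sum((v - np.mean(x)) ** 2 for v in x)
           + sum((v - np.mean(y)) ** 2 for v in y)) / (nx + ny - 2)
    return (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / nx + 1 / ny))
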