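"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: the repeat oracle
enumerates every (start, end, motif-length) substring, the alignment oracle
is a plain quadratic Needleman-Wunsch with linear gaps, and the Fisher
oracle sums hypergeometric point probabilities directly.
"""

from __future__ import annotations

from math import comb


def repeat_oracle(seq: str, max_motif_len: int = 6, min_copies: int = 3, min_length: int = 6):
    """Best pure tandem run by exhaustive enumeration.

    Returns (length, motif_len, start) of the winning maximal pure run under
    the same objective (longest, then shortest motif, then leftmost), or
    None if no qualifying run exists.
    """
    n = len(seq)
    best = None
    for m in range(1, max_motif_len + 1):
        for start in range(n):
            # longest pure run of period m starting here
            end = start + m
            if end > n:
                break
            while end < n and seq[end] == seq[end - m]:
                end += 1
            length = end - start
            if length < 2 * m:
                continue
            # maximality: not extendable left
            if start > 0 and seq[start - 1] == seq[start - 1 + m]:
                continue
            if length / m < min_copies or length < min_length:
                continue
            cand = (-length, m, start)
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    return (-best[0], best[1], best[2])


def nw_linear_score(a: str, b: str, match: float, mismatch: float, gap: float) -> float:
    """Optimal global alignment score with linear gap penalty (plain DP)."""
    n, m = len(a), len(b)
    prev = [j * gap for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [i * gap] + [0.0] * m
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            cur[j] = max(prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return prev[m]


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by enumerating all tables with the observed
    margins and summing hypergeometric probabilities <= that of the table."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)

    def pmf(k: int) -> float:
        return comb(r1, k) * comb(r2, c1 - k) / denom

    p_obs = pmf(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = 0.0
    for k in range(lo, hi + 1):
        p = pmf(k)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)
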