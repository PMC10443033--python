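"""Independent brute-force oracles used only by the tests.

These are deliberately naive implementations, kept separate from the package
so the production code paths are checked against a different derivation.
"""

from __future__ import annotations

import itertools

NEG_INF = float("-inf")


def affine_global_score(a: str, b: str, match=1.0, mismatch=-4.0,
                        gap_open=-6.0, gap_extend=-1.0) -> float:
    """Gotoh global alignment score; a gap of length g costs open + g*extend."""
    first = gap_open + gap_extend
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Iy = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = first + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Iy[0][j] = first + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            Ix[i][j] = max(M[i - 1][j] + first, Ix[i - 1][j] + gap_extend)
            Iy[i][j] = max(M[i][j - 1] + first, Iy[i][j - 1] + gap_extend)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def glocal_score_bruteforce(reference: str, read: str, **scores) -> float:
    """Glocal optimum by enumerating every reference substring and running
    the global affine DP against it. Exponentially safe, quadratically slow."""
    best = NEG_INF
    n = len(reference)
    for j0 in range(n + 1):
        for j1 in range(j0, n + 1):
            best = max(best, affine_global_score(reference[j0:j1], read, **scores))
    return best


def glocal_score(reference: str, read: str, match=1.0, mismatch=-4.0,
                 gap_open=-6.0, gap_extend=-1.0) -> float:
    """Gotoh glocal score: read global, reference local (free reference
    flanks). Cross-checked against :func:`glocal_score_bruteforce`."""
    first = gap_open + gap_extend
    n, m = len(read), len(reference)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    D = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # internal ref-only gap
    I = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # read-only gap
    for j in range(m + 1):
        M[0][j] = 0.0  # free leading reference flank
    for i in range(1, n + 1):
        I[i][0] = first + gap_extend * (i - 1)
        for j in range(1, m + 1):
            s = match if read[i - 1] == reference[j - 1] else mismatch
            prev = max(M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1])
            if prev > NEG_INF:
                M[i][j] = s + prev
            D[i][j] = max(M[i][j - 1] + first, D[i][j - 1] + gap_extend)
            I[i][j] = max(M[i - 1][j] + first, I[i - 1][j] + gap_extend)
    return max(
        max(M[n][j] for j in range(m + 1)),
        max(I[n][j] for j in range(m + 1)),
    )


def levenshtein(a: str, b: str) -> int:
    """Textbook unit-cost edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def hamming(a: str, b: str):
    if len(a) != len(b):
        return None
    return sum(x != y for x, y in zip(a, b))


def brute_force_read_filters(reads: list[str], parental_reads: list[str],
                             reference_window: str, min_count: int = 5):
    """Direct enumeration of the read-level filter chain.

    Returns (surviving read -> count) after: indel removal (length change or
    edit < hamming), occurrence >= min_count, and removal of strings with
    occurrence >= min_count among the parental reads.
    """
    from collections import Counter

    counts = Counter(reads)
    parental = Counter(parental_reads)
    surviving = {}
    for seq, count in counts.items():
        h = hamming(seq, reference_window)
        e = levenshtein(seq, reference_window)
        if h is None or e < h:
            continue
        if count < min_count:
            continue
        if parental[seq] >= min_count:
            continue
        surviving[seq] = count
    return surviving


def enumerate_mutated(seq: str, positions: list[int], alts: list[str]) -> str:
    out = list(seq)
    for p, a in zip(positions, alts):
        out[p] = a
    return "".join(out)
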