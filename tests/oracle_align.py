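"""Independent brute-force oracles used by the test suite.

``sw_oracle`` is a plain-Python full-matrix affine-gap Smith-Waterman with
the same published tie policy as the production engine (best cell = highest
score then smallest query/target index; traceback prefers diagonal, then
target gap, then query gap; gap closure preferred over extension), so the
two must produce the identical alignment, not merely the same score.
"""

from __future__ import annotations

from itertools import permutations

NEG = -(10**9)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def sw_oracle(q: str, t: str, match=2, mismatch=-3, gap_open=-5, gap_extend=-2):
    """Full-matrix local alignment; returns None if the best score is 0,
    else a dict with score, spans and column tallies."""
    m, n = len(q), len(t)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if q[i - 1] == t[j - 1] else mismatch
            h = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return None
    i, j = bi, bj
    state = "H"
    aligned = matches = ts = tv = gaps = 0
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            s = match if q[i - 1] == t[j - 1] else mismatch
            if H[i][j] == H[i - 1][j - 1] + s:
                aligned += 1
                if q[i - 1] == t[j - 1]:
                    matches += 1
                elif (q[i - 1], t[j - 1]) in _TRANSITIONS:
                    ts += 1
                else:
                    tv += 1
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            gaps += 1
            if E[i][j] == H[i][j - 1] + gap_open:
                state = "H"
            j -= 1
        else:
            gaps += 1
            if F[i][j] == H[i - 1][j] + gap_open:
                state = "H"
            i -= 1
    return {
        "score": best,
        "query_start": i,
        "query_end": bi,
        "target_start": j,
        "target_end": bj,
        "aligned_columns": aligned,
        "matches": matches,
        "transitions": ts,
        "transversions": tv,
        "gap_columns": gaps,
    }


def spearman_perm_oracle(x, y):
    """Exhaustive-permutation two-sided Spearman test, written from the
    definition: mid-ranks, Pearson correlation of ranks, p = fraction of
    permutations of y-ranks with |rho| >= |observed|."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    def corr(a, b):
        n = len(a)
        ma = sum(a) / n
        mb = sum(b) / n
        num = sum((ai - ma) * (bi - mb) for ai, bi in zip(a, b))
        da = sum((ai - ma) ** 2 for ai in a) ** 0.5
        db = sum((bi - mb) ** 2 for bi in b) ** 0.5
        return num / (da * db)

    rx, ry = midranks(list(x)), midranks(list(y))
    rho = corr(rx, ry)
    hits = total = 0
    for perm in permutations(ry):
        if abs(corr(rx, list(perm))) >= abs(rho) - 1e-12:
            hits += 1
        total += 1
    return rho, hits / total
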