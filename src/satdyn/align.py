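"""Affine-gap Smith-Waterman local alignment with Kimura-2-parameter divergence.

The engine runs a linear-memory forward pass to locate the optimal end cell,
a reverse pass to bound the start, and a full traceback DP on the resulting
rectangle only.  Tie handling is fully deterministic so that an independent
full-matrix DP reproduces the identical alignment:

* best cell: highest score, then smallest query index, then smallest target
  index (forward sweep order);
* traceback: diagonal preferred over a target gap (E) over a query gap (F);
  inside a gap state, closing the gap is preferred over extending it.

A gap of length L costs ``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from ._seq import encode

NEG = -(10**9)


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring and hit-filter parameters.

    Defaults follow common repeat-masking practice: a mildly mismatch-averse
    matrix, a minimum score that demands ~20 bp of perfect match, and a
    divergence ceiling just above the most diverged satellite copies that
    remain recognisable (~45%).
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    min_score: int = 40
    min_hit_length: int = 30
    max_divergence: float = 45.0

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if self.min_hit_length < 1:
            raise ValueError("min_hit_length must be >= 1")


@dataclass
class Alignment:
    """One local alignment: query/target spans and per-column tallies."""

    score: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    aligned_columns: int  # ungapped columns
    matches: int
    transitions: int
    transversions: int
    gap_columns: int

    @property
    def mismatches(self) -> int:
        return self.transitions + self.transversions

    @property
    def raw_divergence(self) -> float:
        """Mismatch proportion over ungapped columns, in percent."""
        return 100.0 * self.mismatches / self.aligned_columns


class SaturationError(ValueError):
    """Raised when divergence is too high for the Kimura correction."""


def kimura_divergence(transitions: int, transversions: int, aligned_columns: int) -> float:
    """Kimura 2-parameter distance in percent.

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q)) * 100, with P and Q the
    transition and transversion proportions over ungapped columns.
    """
    if aligned_columns < 1:
        raise ValueError("alignment has no ungapped columns")
    p = transitions / aligned_columns
    q = transversions / aligned_columns
    a = 1.0 - 2.0 * p - q
    b = 1.0 - 2.0 * q
    if a <= 0.0 or b <= 0.0:
        raise SaturationError(
            f"Kimura distance undefined at P={p:.3f}, Q={q:.3f} (saturated)"
        )
    return -0.5 * math.log(a * math.sqrt(b)) * 100.0


@njit(cache=False)
def _sw_forward(q, t, match, mismatch, gap_open, gap_extend):
    """Linear-memory forward pass: optimal score and its first-best end cell."""
    n = t.shape[0]
    h_prev = np.zeros(n + 1, dtype=np.int64)
    h_cur = np.zeros(n + 1, dtype=np.int64)
    f = np.full(n + 1, NEG, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, q.shape[0] + 1):
        e = NEG
        h_cur[0] = 0
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = max(h_cur[j - 1] + gap_open, e + gap_extend)
            f[j] = max(h_prev[j] + gap_open, f[j] + gap_extend)
            s = match if qi == t[j - 1] else mismatch
            h = h_prev[j - 1] + s
            if e > h:
                h = e
            if f[j] > h:
                h = f[j]
            if h < 0:
                h = 0
            h_cur[j] = h
            if h > best:
                best = h
                bi = i
                bj = j
        h_prev, h_cur = h_cur, h_prev
    return best, bi, bj


@njit(cache=False)
def _sw_reverse_bounds(q, t, match, mismatch, gap_open, gap_extend):
    """Forward pass on reversed inputs; returns the score and, over all cells
    achieving it, the largest query/target indices (=> minimal start bounds)."""
    n = t.shape[0]
    h_prev = np.zeros(n + 1, dtype=np.int64)
    h_cur = np.zeros(n + 1, dtype=np.int64)
    f = np.full(n + 1, NEG, dtype=np.int64)
    best = 0
    max_i = 0
    max_j = 0
    for i in range(1, q.shape[0] + 1):
        e = NEG
        h_cur[0] = 0
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = max(h_cur[j - 1] + gap_open, e + gap_extend)
            f[j] = max(h_prev[j] + gap_open, f[j] + gap_extend)
            s = match if qi == t[j - 1] else mismatch
            h = h_prev[j - 1] + s
            if e > h:
                h = e
            if f[j] > h:
                h = f[j]
            if h < 0:
                h = 0
            h_cur[j] = h
            if h > best:
                best = h
                max_i = i
                max_j = j
            elif h == best and h > 0:
                if i > max_i:
                    max_i = i
                if j > max_j:
                    max_j = j
        h_prev, h_cur = h_cur, h_prev
    return best, max_i, max_j


@njit(cache=False)
def _sw_traceback(q, t, match, mismatch, gap_open, gap_extend, end_i, end_j):
    """Full DP on a (small) rectangle, then traceback from (end_i, end_j).

    Returns (qs, qe, ts, te, aligned_cols, matches, transitions,
    transversions, gap_cols) in rectangle-local coordinates.
    """
    m = q.shape[0]
    n = t.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            s = match if qi == t[j - 1] else mismatch
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h

    i = end_i
    j = end_j
    aligned = 0
    matches = 0
    ts_count = 0
    tv_count = 0
    gap_cols = 0
    state = 0  # 0 = H, 1 = E (gap in query, consumes target), 2 = F
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            s = match if q[i - 1] == t[j - 1] else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                aligned += 1
                if q[i - 1] == t[j - 1]:
                    matches += 1
                elif (q[i - 1] ^ t[j - 1]) == 2:
                    ts_count += 1
                else:
                    tv_count += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            gap_cols += 1
            if E[i, j] == H[i, j - 1] + gap_open:
                state = 0
            j -= 1
        else:
            gap_cols += 1
            if F[i, j] == H[i - 1, j] + gap_open:
                state = 0
            i -= 1
    return i, end_i, j, end_j, aligned, matches, ts_count, tv_count, gap_cols


def local_align(query, target, scoring: ScoringScheme = ScoringScheme()) -> Alignment | None:
    """Best local alignment of ``query`` against ``target``.

    Accepts strings or pre-encoded uint8 arrays.  Returns ``None`` when the
    optimal score is 0 (no positive-scoring alignment).
    """
    q = encode(query) if isinstance(query, str) else query
    t = encode(target) if isinstance(target, str) else target
    if q.size == 0 or t.size == 0:
        raise ValueError("empty sequence")
    return _align_arrays(q, t, scoring)


def _align_arrays(q: np.ndarray, t: np.ndarray, sc: ScoringScheme) -> Alignment | None:
    best, qe, te = _sw_forward(q, t, sc.match, sc.mismatch, sc.gap_open, sc.gap_extend)
    if best <= 0:
        return None
    _, ri, rj = _sw_reverse_bounds(
        q[:qe][::-1].copy(), t[:te][::-1].copy(),
        sc.match, sc.mismatch, sc.gap_open, sc.gap_extend,
    )
    qs_lo = qe - ri
    ts_lo = te - rj
    sub_q = q[qs_lo:qe]
    sub_t = t[ts_lo:te]
    qs, qe_l, ts, te_l, aligned, matches, k_ts, k_tv, gaps = _sw_traceback(
        sub_q, sub_t, sc.match, sc.mismatch, sc.gap_open, sc.gap_extend,
        sub_q.shape[0], sub_t.shape[0],
    )
    return Alignment(
        score=int(best),
        query_start=qs_lo + qs,
        query_end=qs_lo + qe_l,
        target_start=ts_lo + ts,
        target_end=ts_lo + te_l,
        aligned_columns=aligned,
        matches=matches,
        transitions=k_ts,
        transversions=k_tv,
        gap_columns=gaps,
    )
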