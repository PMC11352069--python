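"""Descriptive statistics and Spearman rank correlation.

Cross-species satellitome comparisons involve very few observations (8-9
species), where the t-approximation to the Spearman null is unreliable; the
two-sided p-value is therefore computed by full permutation enumeration for
n <= 9 and by the t-approximation above that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats as sps

__all__ = ["CorrelationResult", "spearman", "pearson", "describe"]

EXACT_N_MAX = 9


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str  # {exact_permutation, t_approximation}


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of (mid-)ranks."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    if denom == 0:
        raise ValueError("constant vector: correlation undefined")
    return float((rx * ry).sum() / denom)


def spearman(x, y) -> CorrelationResult:
    """Spearman correlation with ties mid-ranked; two-sided p-value by
    exhaustive permutation for n <= 9, t-approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rank_corr(rx, ry)
    if n <= EXACT_N_MAX:
        obs = abs(rho)
        count = 0
        total = 0
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float((rxc**2).sum() * (ryc**2).sum()))
        for perm in permutations(range(n)):
            r = float((rxc * ryc[list(perm)]).sum()) / denom
            if abs(r) >= obs - 1e-12:
                count += 1
            total += 1
        p = count / total
        method = "exact_permutation"
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = 2.0 * sps.t.sf(abs(t), df=n - 2)
        p = min(1.0, p)
        method = "t_approximation"
    return CorrelationResult(rho=rho, p_value=p, n=n, method=method)


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation (two-sided t test p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(rho=float(r), p_value=float(p), n=x.size, method="pearson_t")


def describe(values) -> dict:
    """{n, min, max, mean, median}; median is the midpoint average for even n."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    return {
        "n": int(arr.size),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
    }
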