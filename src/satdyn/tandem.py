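"""Tandem-structure confirmation from a self dot plot.

A contig of a tandem array produces off-diagonal k-mer self-matches whose
offsets concentrate on multiples of the monomer length — the computational
analogue of the ring-shaped dot plots used to confirm tandemness by eye.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

__all__ = ["DotplotResult", "TandemCall", "self_kmer_matches", "estimate_period", "is_tandem"]

# A real tandem contig produces many periodic self-matches; a handful of
# chance k-mer collisions must not trigger a call.
MIN_MATCHES = 10


@dataclass
class DotplotResult:
    """Forward-strand exact k-mer self-matches of one sequence (i < j only)."""

    k: int
    matches: list[tuple[int, int]]

    @property
    def offsets(self) -> Counter:
        return Counter(j - i for i, j in self.matches)


@dataclass
class TandemCall:
    is_tandem: bool
    period: int | None
    support: float


def self_kmer_matches(seq: str, k: int = 12) -> DotplotResult:
    """All pairs (i, j), i < j, of positions with identical forward-strand
    k-mers; the main diagonal is excluded by construction."""
    if len(seq) < 2 * k:
        raise ValueError(f"sequence shorter than 2k ({2 * k})")
    positions: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        positions[seq[i : i + k]].append(i)
    matches = [
        (pos[a], pos[b])
        for pos in positions.values()
        if len(pos) > 1
        for a in range(len(pos))
        for b in range(a + 1, len(pos))
    ]
    return DotplotResult(k=k, matches=matches)


def estimate_period(
    dotplot: DotplotResult, support_threshold: float = 0.5
) -> tuple[int | None, float]:
    """Smallest offset p whose multiples hold >= support_threshold of all
    off-diagonal matches; (None, support-of-best) if no offset qualifies or
    there are fewer than MIN_MATCHES matches."""
    offsets = dotplot.offsets
    total = sum(offsets.values())
    if total < MIN_MATCHES:
        return None, 0.0
    best_support = 0.0
    for p in sorted(offsets):
        at_multiples = sum(c for off, c in offsets.items() if off % p == 0)
        support = at_multiples / total
        if support >= support_threshold:
            return p, support
        best_support = max(best_support, support)
    return None, best_support


def is_tandem(contig: str, k: int = 12, support_threshold: float = 0.5) -> TandemCall:
    """Tandem call for a contig: dot plot, then periodicity detection."""
    dotplot = self_kmer_matches(contig, k=k)
    period, support = estimate_period(dotplot, support_threshold=support_threshold)
    return TandemCall(is_tandem=period is not None, period=period, support=support)
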