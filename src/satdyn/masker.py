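"""Tandem-aware masking of reads or assembly windows against a satellite
library, with per-hit Kimura divergence and a divsum-style summary.

Each query is aligned against a tandemized copy of every family consensus on
both strands (monomers are circular, so a doubled-plus run of the consensus
lets any window of an array align contiguously).  Within one query/family/
strand, hits are recovered by iterative best-hit removal: find the optimal
local alignment, record it, and recurse into the unmasked flanks — long
arrays are therefore tiled by consecutive hits.  Hits from all families are
then reconciled greedily by score, discarding any hit that overlaps an
already accepted one by more than 10% of its own length, and filtered by
minimum score, minimum length and a divergence ceiling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._seq import encode, revcomp
from .align import Alignment, SaturationError, ScoringScheme, _align_arrays, kimura_divergence
from .library import SatFamily

__all__ = [
    "MaskHit",
    "DivsumTable",
    "tandemize",
    "mask_sequences",
    "summarize_divsum",
    "write_hits_bed",
    "write_hits_tsv",
]

log = logging.getLogger(__name__)

MAX_DIV_BIN = 70
OVERLAP_TOLERANCE = 0.10
# Tandemized targets are capped so that masking long windows stays linear in
# window length; arrays longer than the cap are tiled by consecutive hits and
# merged downstream.
MAX_TARGET_LENGTH = 1200


@dataclass
class MaskHit:
    """One accepted alignment of a query segment to a satellite family."""

    query_id: str
    family_name: str
    query_start: int
    query_end: int
    strand: str
    score: int
    aligned_columns: int
    mismatches: int
    transitions: int
    transversions: int
    kimura_divergence: float

    @property
    def length(self) -> int:
        return self.query_end - self.query_start


def tandemize(consensus: str, target_length: int) -> str:
    """Repeat a monomer ceil(target_length / monomer_length) + 1 times so any
    target_length-window of a circular array aligns contiguously."""
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    n = math.ceil(target_length / len(consensus)) + 1
    return consensus * n


def _hits_for_target(
    q: np.ndarray, t: np.ndarray, scoring: ScoringScheme
) -> list[Alignment]:
    """All disjoint local alignments of q vs t by iterative best-hit removal."""
    hits: list[Alignment] = []
    stack = [(0, q.shape[0])]
    while stack:
        a, b = stack.pop()
        if b - a < scoring.min_hit_length:
            continue
        aln = _align_arrays(q[a:b], t, scoring)
        if aln is None or aln.score < scoring.min_score:
            continue
        aln.query_start += a
        aln.query_end += a
        hits.append(aln)
        stack.append((a, aln.query_start))
        stack.append((aln.query_end, b))
    return hits


def _resolve_greedy(hits: list[MaskHit]) -> list[MaskHit]:
    """Accept hits in decreasing score order; drop any hit overlapping an
    accepted hit on the query by more than 10% of its own length."""
    accepted: list[MaskHit] = []
    for hit in sorted(hits, key=lambda h: (-h.score, h.query_start, h.family_name)):
        overlap = 0
        for acc in accepted:
            lo = max(hit.query_start, acc.query_start)
            hi = min(hit.query_end, acc.query_end)
            if hi > lo:
                overlap += hi - lo
        if overlap <= OVERLAP_TOLERANCE * hit.length:
            accepted.append(hit)
    accepted.sort(key=lambda h: h.query_start)
    return accepted


def mask_sequences(
    queries: dict[str, str] | list[tuple[str, str]],
    library: list[SatFamily],
    scoring: ScoringScheme = ScoringScheme(),
) -> list[MaskHit]:
    """Mask queries (reads or contigs) against every family on both strands.

    Returns accepted hits after greedy overlap resolution and filtering by
    min_score, min_hit_length and max_divergence.  Hits whose divergence is
    Kimura-saturated are discarded with a logged warning.
    """
    if not library:
        raise ValueError("empty satellite library")
    items = queries.items() if isinstance(queries, dict) else queries

    # Pre-tandemized targets, rebuilt lazily per required length.
    target_cache: dict[tuple[str, str, int], np.ndarray] = {}

    def target_for(fam: SatFamily, strand: str, qlen: int) -> np.ndarray:
        tlen = min(qlen, MAX_TARGET_LENGTH)
        key = (fam.name, strand, tlen)
        if key not in target_cache:
            cons = fam.consensus if strand == "+" else revcomp(fam.consensus)
            target_cache[key] = encode(tandemize(cons, tlen))
        return target_cache[key]

    all_hits: list[MaskHit] = []
    n_saturated = 0
    for qid, seq in items:
        q = encode(seq)
        if q.size < scoring.min_hit_length:
            continue
        candidates: list[MaskHit] = []
        for fam in library:
            for strand in "+-":
                t = target_for(fam, strand, q.size)
                for aln in _hits_for_target(q, t, scoring):
                    if aln.query_end - aln.query_start < scoring.min_hit_length:
                        continue
                    try:
                        div = kimura_divergence(
                            aln.transitions, aln.transversions, aln.aligned_columns
                        )
                    except SaturationError:
                        n_saturated += 1
                        continue
                    if div > scoring.max_divergence:
                        continue
                    candidates.append(
                        MaskHit(
                            query_id=qid,
                            family_name=fam.name,
                            query_start=aln.query_start,
                            query_end=aln.query_end,
                            strand=strand,
                            score=aln.score,
                            aligned_columns=aln.aligned_columns,
                            mismatches=aln.mismatches,
                            transitions=aln.transitions,
                            transversions=aln.transversions,
                            kimura_divergence=div,
                        )
                    )
        all_hits.extend(_resolve_greedy(candidates))
    if n_saturated:
        log.warning("discarded %d hits with Kimura-saturated divergence", n_saturated)
    return all_hits


@dataclass
class DivsumTable:
    """Aligned bp per (family, integer divergence bin); the quantitative core
    of repeat landscapes and of per-family abundance/divergence statistics."""

    cells: dict[tuple[str, int], int]
    total_query_bp: int

    def family_bp(self, family: str) -> int:
        return sum(bp for (fam, _), bp in self.cells.items() if fam == family)

    def families(self) -> list[str]:
        return sorted({fam for fam, _ in self.cells})

    def abundance(self, family: str) -> float:
        """Family abundance as a fraction of total query bp."""
        return self.family_bp(family) / self.total_query_bp

    def mean_divergence(self, family: str) -> float:
        """bp-weighted mean of bin midpoints, in percent."""
        num = den = 0.0
        for (fam, b), bp in self.cells.items():
            if fam == family:
                num += (b + 0.5) * bp
                den += bp
        return num / den if den else 0.0

    def to_frame(self):
        import pandas as pd

        rows = [
            {"family": fam, "bin": b, "aligned_bp": bp}
            for (fam, b), bp in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows, columns=["family", "bin", "aligned_bp"])

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.to_csv(path, sep="\t", index=False)


def summarize_divsum(hits: list[MaskHit], total_query_bp: int) -> DivsumTable:
    """Aggregate hits into per-(family, 1% divergence bin) aligned bp.

    Each hit contributes its query span to bin floor(kimura_divergence);
    divergences at or above 70% are clamped into the top bin with a warning.
    """
    if total_query_bp <= 0:
        raise ValueError("total_query_bp must be positive")
    cells: dict[tuple[str, int], int] = {}
    n_clamped = 0
    for hit in hits:
        b = int(math.floor(hit.kimura_divergence))
        if b >= MAX_DIV_BIN:
            b = MAX_DIV_BIN - 1
            n_clamped += 1
        key = (hit.family_name, b)
        cells[key] = cells.get(key, 0) + hit.length
    if n_clamped:
        log.warning("clamped %d hits into the top divergence bin", n_clamped)
    return DivsumTable(cells=cells, total_query_bp=total_query_bp)


def write_hits_bed(hits: list[MaskHit], path: str | Path) -> None:
    """BED6 + divergence column (chrom/read, start, end, family, score, strand,
    kimura_divergence)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.query_start}\t{h.query_end}\t{h.family_name}\t"
                f"{h.score}\t{h.strand}\t{h.kimura_divergence:.2f}\n"
            )


def write_hits_tsv(hits: list[MaskHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "query_id\tfamily\tquery_start\tquery_end\tstrand\tscore\t"
            "aligned_columns\tmismatches\ttransitions\ttransversions\t"
            "kimura_divergence\traw_divergence\n"
        )
        for h in hits:
            raw = 100.0 * h.mismatches / h.aligned_columns
            fh.write(
                f"{h.query_id}\t{h.family_name}\t{h.query_start}\t{h.query_end}\t"
                f"{h.strand}\t{h.score}\t{h.aligned_columns}\t{h.mismatches}\t"
                f"{h.transitions}\t{h.transversions}\t{h.kimura_divergence:.3f}\t{raw:.3f}\n"
            )
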