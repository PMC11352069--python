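"""Chromosome-level satellite distribution on an assembly.

Chromosomes are masked in overlapping windows (memory-bounded), hits are
mapped back to chromosome coordinates, duplicates from window overlaps are
removed, and abutting or overlapping same-family hits are merged.  From the
merged hits the module reports per-chromosome satellite percentages,
per-family-per-chromosome shares, chromosome-specific families, and
per-chromosome landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .align import ScoringScheme
from .landscape import DEFAULT_MIN_ABUNDANCE, LandscapeTable, build_landscape
from .library import SatFamily
from .masker import DivsumTable, MaskHit, mask_sequences, summarize_divsum

__all__ = [
    "ChromProfile",
    "read_assembly",
    "mask_assembly_windows",
    "chromosome_abundance",
    "chromosome_landscape",
]

DEFAULT_WINDOW = 100_000
CHROM_SPECIFIC_FRACTION = 0.90


@dataclass
class ChromProfile:
    chromosome: str
    length: int
    satellite_bp: int
    satellite_percent: float
    per_family: dict[str, dict] = field(default_factory=dict)  # {bp, percent_of_chromosome}
    specific_families: list[str] = field(default_factory=list)


def read_assembly(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _merge_hits(hits: list[MaskHit]) -> list[MaskHit]:
    """Merge abutting/overlapping same-family, same-chromosome hits; merged
    divergence is the bp-weighted mean of the parts."""
    merged: list[MaskHit] = []
    by_key: dict[tuple[str, str], list[MaskHit]] = {}
    for h in hits:
        by_key.setdefault((h.query_id, h.family_name), []).append(h)
    for (_, _), group in sorted(by_key.items()):
        group.sort(key=lambda h: (h.query_start, h.query_end))
        cur = None
        for h in group:
            if cur is None or h.query_start > cur.query_end:
                if cur is not None:
                    merged.append(cur)
                cur = MaskHit(**{k: getattr(h, k) for k in h.__dataclass_fields__})
            else:
                new_end = max(cur.query_end, h.query_end)
                w_cur, w_new = cur.length, max(0, h.query_end - cur.query_end)
                if w_cur + w_new > 0:
                    cur.kimura_divergence = (
                        cur.kimura_divergence * w_cur + h.kimura_divergence * w_new
                    ) / (w_cur + w_new)
                cur.query_end = new_end
                cur.score = max(cur.score, h.score)
                cur.aligned_columns += h.aligned_columns
                cur.mismatches += h.mismatches
                cur.transitions += h.transitions
                cur.transversions += h.transversions
        if cur is not None:
            merged.append(cur)
    merged.sort(key=lambda h: (h.query_id, h.query_start))
    return merged


def mask_assembly_windows(
    assembly: dict[str, str],
    library: list[SatFamily],
    scoring: ScoringScheme = ScoringScheme(),
    window: int = DEFAULT_WINDOW,
    overlap: int | None = None,
) -> list[MaskHit]:
    """Mask an assembly window by window; returns merged chromosome-coordinate
    hits.  ``overlap`` must be at least twice the longest monomer so that no
    array window is split without a full-length context on either side."""
    if not library:
        raise ValueError("empty satellite library")
    max_monomer = max(f.monomer_length for f in library)
    if overlap is None:
        overlap = max(2 * max_monomer, 2 * scoring.min_hit_length)
    if overlap < 2 * max_monomer:
        raise ValueError(f"overlap must be >= 2 x max monomer length ({2 * max_monomer})")
    if window <= overlap:
        raise ValueError("window must exceed overlap")

    seen: set[tuple[str, str, int, int, str]] = set()
    hits: list[MaskHit] = []
    for chrom, seq in assembly.items():
        start = 0
        while start < len(seq):
            end = min(start + window, len(seq))
            sub = seq[start:end]
            for h in mask_sequences([(chrom, sub)], library, scoring):
                key = (chrom, h.family_name, start + h.query_start, start + h.query_end, h.strand)
                if key in seen:
                    continue
                seen.add(key)
                h.query_start += start
                h.query_end += start
                hits.append(h)
            if end == len(seq):
                break
            start = end - overlap
    return _merge_hits(hits)


def chromosome_abundance(
    hits: list[MaskHit], chrom_lengths: dict[str, int]
) -> list[ChromProfile]:
    """Per-chromosome satellite percentage and per-family shares; families
    with >= 90% of their assembly-wide bp on one chromosome are flagged
    chromosome-specific there."""
    fam_chrom_bp: dict[tuple[str, str], int] = {}
    for h in hits:
        if h.query_id not in chrom_lengths:
            raise ValueError(f"hit on unknown chromosome {h.query_id!r}")
        if h.query_end > chrom_lengths[h.query_id]:
            raise ValueError(f"hit beyond end of {h.query_id!r}")
        key = (h.family_name, h.query_id)
        fam_chrom_bp[key] = fam_chrom_bp.get(key, 0) + h.length

    fam_total: dict[str, int] = {}
    for (fam, _), bp in fam_chrom_bp.items():
        fam_total[fam] = fam_total.get(fam, 0) + bp

    profiles = []
    for chrom, length in chrom_lengths.items():
        per_family = {}
        sat_bp = 0
        specific = []
        for (fam, c), bp in fam_chrom_bp.items():
            if c != chrom:
                continue
            per_family[fam] = {"bp": bp, "percent_of_chromosome": 100.0 * bp / length}
            sat_bp += bp
            if bp >= CHROM_SPECIFIC_FRACTION * fam_total[fam]:
                specific.append(fam)
        profiles.append(
            ChromProfile(
                chromosome=chrom,
                length=length,
                satellite_bp=sat_bp,
                satellite_percent=100.0 * sat_bp / length,
                per_family=per_family,
                specific_families=sorted(specific),
            )
        )
    return profiles


def chromosome_landscape(
    hits: list[MaskHit],
    chromosome: str,
    chrom_lengths: dict[str, int],
    min_abundance: float = DEFAULT_MIN_ABUNDANCE,
) -> LandscapeTable:
    """Landscape of one chromosome, with chromosome bp as the denominator."""
    if chromosome not in chrom_lengths:
        raise ValueError(f"unknown chromosome {chromosome!r}")
    chrom_hits = [h for h in hits if h.query_id == chromosome]
    if not chrom_hits:
        divsum = DivsumTable(cells={}, total_query_bp=chrom_lengths[chromosome])
    else:
        divsum = summarize_divsum(chrom_hits, chrom_lengths[chromosome])
    return build_landscape(divsum, min_abundance=min_abundance)


def write_profiles_tsv(profiles: list[ChromProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tlength\tsatellite_bp\tsatellite_percent\tspecific_families\n")
        for p in profiles:
            fh.write(
                f"{p.chromosome}\t{p.length}\t{p.satellite_bp}\t"
                f"{p.satellite_percent:.2f}\t{','.join(p.specific_families)}\n"
            )


def write_family_chrom_tsv(profiles: list[ChromProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tfamily\tbp\tpercent_of_chromosome\n")
        for p in profiles:
            for fam, d in sorted(p.per_family.items()):
                fh.write(f"{p.chromosome}\t{fam}\t{d['bp']}\t{d['percent_of_chromosome']:.3f}\n")
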