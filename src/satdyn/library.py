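"""Satellite-family library: nomenclature, FASTA I/O, superfamily grouping.

Families are named <Spc>SatNN by decreasing genomic abundance (three digits
from 100 onward), following the satellite-DNA nomenclature in common use.
Superfamilies are connected components of the homology graph built from
all-to-all consensus comparisons that account for both strands and for the
circularity of monomers (the shorter consensus is doubled so every rotation
can align contiguously).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import encode, revcomp

__all__ = [
    "SatFamily",
    "SuperfamilyPartition",
    "assign_names",
    "read_library",
    "write_library",
    "group_superfamilies",
]

NAME_RE = re.compile(r"^[A-Z][a-z]{2}Sat\d{2,3}$")


@dataclass
class SatFamily:
    """One satellite family: a named circular monomer consensus."""

    name: str
    consensus: str
    confidence: str = "high"  # {high, low}

    def __post_init__(self) -> None:
        encode(self.consensus)  # rejects non-ACGT
        self.consensus = self.consensus.upper()
        if self.confidence not in ("high", "low"):
            raise ValueError("confidence must be 'high' or 'low'")

    @property
    def monomer_length(self) -> int:
        return len(self.consensus)

    @property
    def species_code(self) -> str:
        return self.name[:3]


def assign_names(
    families: list[tuple[str, float]], species_code: str, confidences: dict | None = None
) -> list[SatFamily]:
    """Name families <Spc>Sat01.. by decreasing abundance.

    ``families`` is a list of (consensus, abundance).  Ties go to the longer
    monomer, then to input order.  Numbers use two digits up to 99 and three
    digits from 100.
    """
    if not re.fullmatch(r"[A-Za-z]{3}", species_code):
        raise ValueError("species_code must be exactly 3 letters")
    code = species_code[0].upper() + species_code[1:3].lower()
    if any(a < 0 for _, a in families):
        raise ValueError("abundances must be >= 0")
    order = sorted(
        range(len(families)),
        key=lambda i: (-families[i][1], -len(families[i][0]), i),
    )
    out = []
    for rank, i in enumerate(order, start=1):
        name = f"{code}Sat{rank:02d}" if rank < 100 else f"{code}Sat{rank:03d}"
        conf = (confidences or {}).get(i, "high")
        out.append(SatFamily(name=name, consensus=families[i][0], confidence=conf))
    return out


def read_library(path: str | Path) -> list[SatFamily]:
    """Read a library FASTA (headers ``>NAME [confidence=low]``)."""
    fams: list[SatFamily] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in seen:
            raise ValueError(f"duplicate family name {name!r} in library")
        seen.add(name)
        conf = "low" if "confidence=low" in rec.description else "high"
        seq = str(rec.seq).upper()
        try:
            encode(seq)
        except ValueError as exc:
            raise ValueError(f"record {name!r}: {exc}") from exc
        fams.append(SatFamily(name=name, consensus=seq, confidence=conf))
    return fams


def write_library(families: list[SatFamily], path: str | Path) -> None:
    seen: set[str] = set()
    records = []
    for fam in families:
        if fam.name in seen:
            raise ValueError(f"duplicate family name {fam.name!r}")
        seen.add(fam.name)
        desc = "confidence=low" if fam.confidence == "low" else ""
        records.append(SeqRecord(Seq(fam.consensus), id=fam.name, description=desc))
    SeqIO.write(records, str(path), "fasta")


@dataclass
class SuperfamilyPartition:
    """family name -> 1-based contiguous superfamily id, plus per-pair
    evidence for edges that passed the homology thresholds."""

    assignment: dict[str, int]
    evidence: dict[tuple[str, str], dict] = field(default_factory=dict)

    @property
    def n_superfamilies(self) -> int:
        return max(self.assignment.values(), default=0)

    def members(self, sf_id: int) -> list[str]:
        return sorted(n for n, s in self.assignment.items() if s == sf_id)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("family\tsuperfamily_id\tbest_identity\tbest_coverage\n")
            best: dict[str, tuple[float, float]] = {}
            for (a, b), ev in self.evidence.items():
                for name in (a, b):
                    cur = best.get(name, (0.0, 0.0))
                    if ev["identity"] > cur[0]:
                        best[name] = (ev["identity"], ev["coverage"])
            for name in sorted(self.assignment, key=lambda n: self.assignment[n]):
                ident, cov = best.get(name, (float("nan"), float("nan")))
                fh.write(f"{name}\t{self.assignment[name]}\t{ident:.3f}\t{cov:.3f}\n")


def _pair_homology(a: SatFamily, b: SatFamily, scoring) -> dict | None:
    """Best identity/coverage between two consensuses over both strands and
    all rotations of the shorter (via doubling)."""
    from .align import ScoringScheme, local_align

    scoring = scoring or ScoringScheme()
    short, long_ = (a, b) if a.monomer_length <= b.monomer_length else (b, a)
    target = short.consensus * 2
    best = None
    best_score = -1
    for strand, query in (("+", long_.consensus), ("-", revcomp(long_.consensus))):
        aln = local_align(query, target, scoring)
        if aln is None or aln.aligned_columns == 0:
            continue
        identity = aln.matches / (aln.aligned_columns + aln.gap_columns)
        coverage = min(1.0, (aln.target_end - aln.target_start) / short.monomer_length)
        # the higher-scoring strand carries the homology signal: score scales
        # with both aligned length and identity, so a short spurious
        # high-identity fragment never outranks a genuine full-length match
        if aln.score > best_score:
            best_score = aln.score
            best = {"identity": identity, "coverage": coverage, "strand": strand}
    return best


def group_superfamilies(
    library: list[SatFamily],
    min_identity: float = 0.70,
    min_coverage: float = 0.50,
    scoring=None,
) -> SuperfamilyPartition:
    """Group families into superfamilies = connected components of the
    pairwise-homology graph (identity >= min_identity over >= min_coverage of
    the shorter monomer, best over strands and rotations)."""
    if not library:
        raise ValueError("empty library")
    names = [f.name for f in library]
    parent = list(range(len(names)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    evidence: dict[tuple[str, str], dict] = {}
    for i in range(len(library)):
        for j in range(i + 1, len(library)):
            ev = _pair_homology(library[i], library[j], scoring)
            if ev and ev["identity"] >= min_identity and ev["coverage"] >= min_coverage:
                evidence[(names[i], names[j])] = ev
                parent[find(i)] = find(j)

    # contiguous ids 1..K, ordered by first library appearance of each root
    roots: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for idx, name in enumerate(names):
        r = find(idx)
        if r not in roots:
            roots[r] = len(roots) + 1
        assignment[name] = roots[r]
    return SuperfamilyPartition(assignment=assignment, evidence=evidence)
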