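"""Synthetic tandem-repeat genomes and low-coverage paired-end reads.

The generator plants head-to-tail satellite arrays with known occupancy and
divergence-from-consensus into a random background, then samples 150 bp
paired-end reads at sub-1x coverage — the regime in which satellitomes are
profiled from unassembled genomes.  Every planted quantity is recorded in a
truth table so downstream estimates can be scored exactly.

Monomer copies are mutated independently from the consensus (a star
phylogeny): the realized divergence of an array is then directly controlled
by the per-family substitution rate, which is what divergence-from-consensus
landscapes measure.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import decode, revcomp
from .align import kimura_divergence

__all__ = [
    "FamilySpec",
    "SimConfig",
    "TruthTable",
    "make_consensus",
    "mutate_copy",
    "build_genome",
    "simulate_reads",
    "write_reads_fastq",
    "write_genome_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class FamilySpec:
    """Simulation parameters for one satellite family."""

    monomer_length: int
    target_occupancy: float  # fraction of genome
    divergence_rate: float  # expected substitutions/site vs consensus
    indel_rate: float = 0.0  # expected indel events/site
    ts_tv_ratio: float = 2.0  # transition odds vs each transversion class
    name: str | None = None

    def validate(self) -> None:
        if self.monomer_length < 10:
            raise ValueError("monomer_length must be >= 10")
        for r in (self.target_occupancy, self.divergence_rate, self.indel_rate):
            if not (0.0 <= r < 1.0):
                raise ValueError("rates must lie in [0, 1)")
        if self.ts_tv_ratio < 0:
            raise ValueError("ts_tv_ratio must be >= 0")


@dataclass
class SimConfig:
    genome_length: int = 1_000_000
    families: list[FamilySpec] = field(default_factory=list)
    background_gc: float = 0.5
    coverage: float = 0.1
    read_length: int = 150
    insert_size: int = 350
    seq_error_rate: float = 0.0
    n_chromosomes: int = 1
    seed: int = 0

    def validate(self) -> None:
        for fam in self.families:
            fam.validate()
        if sum(f.target_occupancy for f in self.families) >= 1.0:
            raise ValueError("sum of target occupancies must be < 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.read_length > self.insert_size:
            raise ValueError("read_length must be <= insert_size")
        if not (0.0 <= self.seq_error_rate < 1.0):
            raise ValueError("seq_error_rate must lie in [0, 1)")
        if self.genome_length < 1 or self.n_chromosomes < 1:
            raise ValueError("genome_length and n_chromosomes must be positive")


@dataclass
class FamilyTruth:
    name: str
    consensus: str
    planted_bp: int
    realized_occupancy: float
    mean_realized_divergence: float  # bp-weighted Kimura %, vs consensus
    planted_sub_rate: float = 0.0  # the substitution rate the copies were drawn at


@dataclass
class TruthTable:
    """Ground truth of a simulated genome: per-family totals and array intervals
    (0-based half-open, per chromosome)."""

    families: dict[str, FamilyTruth]
    arrays: list[tuple[str, str, int, int]]  # (family, chrom, start, end)
    genome_length: int

    def occupancy(self, family: str) -> float:
        return self.families[family].realized_occupancy

    def write_tsv(self, arrays_path: str | Path, summary_path: str | Path) -> None:
        with open(arrays_path, "w") as fh:
            fh.write("family\tchrom\tstart\tend\n")
            for fam, chrom, s, e in self.arrays:
                fh.write(f"{fam}\t{chrom}\t{s}\t{e}\n")
        with open(summary_path, "w") as fh:
            fh.write(
                "family\tmonomer_length\tplanted_bp\trealized_occupancy\t"
                "mean_realized_divergence\n"
            )
            for ft in self.families.values():
                fh.write(
                    f"{ft.name}\t{len(ft.consensus)}\t{ft.planted_bp}\t"
                    f"{ft.realized_occupancy:.6f}\t{ft.mean_realized_divergence:.4f}\n"
                )


def make_consensus(length: int, gc: float, seed: int) -> str:
    """Random monomer consensus with the given GC fraction; deterministic."""
    if length < 10:
        raise ValueError("consensus length must be >= 10")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return decode(_random_bases(rng, length, gc))


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _mutate_encoded(
    cons: np.ndarray,
    sub_rate: float,
    indel_rate: float,
    ts_tv_ratio: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int, int]:
    """Mutated copy of an encoded monomer plus its (transition, transversion)
    substitution counts."""
    n = cons.size
    seq = cons.copy()
    ts_n = tv_n = 0
    if sub_rate > 0:
        sites = np.nonzero(rng.random(n) < sub_rate)[0]
        if sites.size:
            k = ts_tv_ratio
            # odds transition : each transversion class = k : 1 : 1
            kind = rng.choice(3, size=sites.size, p=[k / (k + 2), 1 / (k + 2), 1 / (k + 2)])
            for pos, kd in zip(sites, kind):
                b = int(seq[pos])
                if kd == 0:
                    seq[pos] = b ^ 2  # A<->G, C<->T
                    ts_n += 1
                else:
                    # the two transversion partners of base b
                    tv = [x for x in range(4) if x != b and (x ^ b) != 2]
                    seq[pos] = tv[kd - 1]
                    tv_n += 1
    if indel_rate > 0:
        events = np.nonzero(rng.random(n) < indel_rate)[0]
        if events.size:
            parts: list[np.ndarray] = []
            prev = 0
            for pos in events:
                parts.append(seq[prev:pos])
                length = int(rng.integers(1, 6))
                if rng.random() < 0.5:  # insertion before pos
                    parts.append(_random_bases(rng, length, 0.5))
                    parts.append(seq[pos : pos + 1])
                    prev = pos + 1
                else:  # deletion of up to `length` bases starting at pos
                    prev = min(pos + length, n)
            parts.append(seq[prev:])
            seq = np.concatenate(parts) if parts else seq
    return seq, ts_n, tv_n


def mutate_copy(
    consensus: str, sub_rate: float, indel_rate: float, ts_tv_ratio: float, seed: int
) -> str:
    """One mutated monomer copy: per-site substitutions (transition odds
    ts_tv_ratio : 1 per transversion class) and uniform 1-5 bp indels."""
    for r in (sub_rate, indel_rate):
        if not (0.0 <= r < 1.0):
            raise ValueError("rates must lie in [0, 1)")
    from ._seq import encode

    rng = np.random.default_rng(seed)
    seq, _, _ = _mutate_encoded(encode(consensus), sub_rate, indel_rate, ts_tv_ratio, rng)
    return decode(seq)


def build_genome(config: SimConfig) -> tuple[dict[str, str], TruthTable]:
    """Assemble chromosomes of background sequence with tandem arrays planted
    at random non-overlapping loci; returns (genome, truth table).

    Each family's bp budget (target_occupancy x genome_length) is split over
    1-10 arrays of independently mutated head-to-tail monomer copies; array
    orientation is uniform.
    """
    from ._seq import encode

    config.validate()
    rng = np.random.default_rng(config.seed)

    # Per-family arrays of mutated copies.
    fam_arrays: list[tuple[str, np.ndarray]] = []  # (family, encoded array)
    truths: dict[str, FamilyTruth] = {}
    consensuses: dict[str, str] = {}
    total_planted = 0
    for idx, fam in enumerate(config.families):
        name = fam.name or f"fam{idx + 1:02d}"
        if name in truths:
            raise ValueError(f"duplicate family name {name!r}")
        cons = _random_bases(rng, fam.monomer_length, config.background_gc)
        consensuses[name] = decode(cons)
        budget = int(round(fam.target_occupancy * config.genome_length))
        n_arrays = int(rng.integers(1, 11))
        # at least one monomer per array
        n_arrays = max(1, min(n_arrays, budget // fam.monomer_length or 1))
        shares = np.full(n_arrays, budget // n_arrays)
        shares[: budget % n_arrays] += 1
        planted = 0
        div_num = 0.0  # bp-weighted Kimura divergence accumulator
        for share in shares:
            copies: list[np.ndarray] = []
            length = 0
            while length < share:
                copy, ts_n, tv_n = _mutate_encoded(
                    cons, fam.divergence_rate, fam.indel_rate, fam.ts_tv_ratio, rng
                )
                copies.append(copy)
                length += copy.size
                if ts_n + tv_n > 0:
                    div = kimura_divergence(ts_n, tv_n, fam.monomer_length)
                else:
                    div = 0.0
                div_num += div * copy.size
            arr = np.concatenate(copies)
            if rng.random() < 0.5:
                arr = 3 - arr[::-1]  # reverse complement under 0123=ACGT
            fam_arrays.append((name, arr))
            planted += arr.size
        total_planted += planted
        truths[name] = FamilyTruth(
            name=name,
            consensus=consensuses[name],
            planted_bp=planted,
            realized_occupancy=planted / config.genome_length,
            mean_realized_divergence=div_num / planted if planted else 0.0,
            planted_sub_rate=fam.divergence_rate,
        )

    background_bp = config.genome_length - total_planted
    if background_bp < config.n_chromosomes:
        raise ValueError("occupancy budgets leave no room for background sequence")

    # Background split across chromosomes, arrays assigned and inserted at
    # random cut points.
    chrom_bg = np.full(config.n_chromosomes, background_bp // config.n_chromosomes)
    chrom_bg[: background_bp % config.n_chromosomes] += 1
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    assignment: dict[str, list[tuple[str, np.ndarray]]] = {c: [] for c in chrom_names}
    order = rng.permutation(len(fam_arrays))
    for k in order:
        chrom = chrom_names[int(rng.integers(config.n_chromosomes))]
        assignment[chrom].append(fam_arrays[k])

    genome: dict[str, str] = {}
    intervals: list[tuple[str, str, int, int]] = []
    for chrom, bg_len in zip(chrom_names, chrom_bg):
        bg = _random_bases(rng, int(bg_len), config.background_gc)
        arrays = assignment[chrom]
        cuts = np.sort(rng.integers(0, int(bg_len) + 1, size=len(arrays)))
        parts: list[np.ndarray] = []
        pos = 0
        prev_cut = 0
        for cut, (fam_name, arr) in zip(cuts, arrays):
            parts.append(bg[prev_cut:cut])
            pos += cut - prev_cut
            intervals.append((fam_name, chrom, pos, pos + arr.size))
            parts.append(arr)
            pos += arr.size
            prev_cut = cut
        parts.append(bg[prev_cut:])
        genome[chrom] = decode(np.concatenate(parts) if parts else bg)

    truth = TruthTable(families=truths, arrays=intervals, genome_length=config.genome_length)
    return genome, truth


@dataclass
class ReadPair:
    name: str
    seq1: str
    seq2: str
    qual: str


def simulate_reads(
    genome: dict[str, str],
    coverage: float,
    read_length: int = 150,
    insert_size: int = 350,
    seq_error_rate: float = 0.0,
    seed: int = 0,
) -> list[ReadPair]:
    """Uniform paired-end reads: n_pairs = floor(coverage * total_bp /
    (2 * read_length)); read 2 is the reverse complement of the fragment
    3' end; constant 'I' qualities."""
    if insert_size < read_length:
        raise ValueError("insert_size must be >= read_length")
    chroms = [c for c in genome if len(genome[c]) >= insert_size]
    if not chroms:
        raise ValueError("genome shorter than insert_size")
    rng = np.random.default_rng(seed)
    total_bp = sum(len(s) for s in genome.values())
    n_pairs = int(math.floor(coverage * total_bp / (2 * read_length)))
    lengths = np.array([len(genome[c]) - insert_size + 1 for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    qual = "I" * read_length
    pairs: list[ReadPair] = []
    chrom_idx = rng.choice(len(chroms), size=n_pairs, p=probs)
    for i in range(n_pairs):
        chrom = chroms[int(chrom_idx[i])]
        start = int(rng.integers(0, len(genome[chrom]) - insert_size + 1))
        frag = genome[chrom][start : start + insert_size]
        r1 = frag[:read_length]
        r2 = revcomp(frag[-read_length:])
        if seq_error_rate > 0:
            r1 = _add_errors(r1, seq_error_rate, rng)
            r2 = _add_errors(r2, seq_error_rate, rng)
        pairs.append(ReadPair(f"sim_{i}", r1, r2, qual))
    return pairs


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    from ._seq import encode

    arr = encode(seq)
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for pos in hits:
        arr[pos] = (arr[pos] + int(rng.integers(1, 4))) % 4
    return decode(arr)


def write_reads_fastq(pairs: list[ReadPair], r1_path: str | Path, r2_path: str | Path) -> None:
    """Write a read-pair list as two gzip FASTQ files."""
    with gzip.open(r1_path, "wt") as f1, gzip.open(r2_path, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{p.qual}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{p.qual}\n")


def write_genome_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
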