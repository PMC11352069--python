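"""End-to-end orchestration: subsample -> mask -> landscape -> gain/loss
(-> chromosome distribution), with a run manifest and one summary table.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._seq import read_fastq_pairs
from .align import ScoringScheme
from .chromdist import (
    chromosome_abundance,
    mask_assembly_windows,
    read_assembly,
    write_family_chrom_tsv,
    write_profiles_tsv,
)
from .dynamics import compute_zscores, family_stats_from_divsum, write_zscores_tsv
from .landscape import build_landscape, peak_ages
from .library import read_library
from .masker import mask_sequences, summarize_divsum, write_hits_tsv

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "subsample_reads", "run_pipeline"]


@dataclass
class PipelineConfig:
    library: str
    reads1: str | None = None
    reads2: str | None = None
    assembly: str | None = None
    outdir: str = "satdyn_out"
    subsample_n: int = 3_000_000
    seed: int = 0
    min_abundance: float = 0.2
    recent_bin: int = 5
    window: int = 100_000
    scoring: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "library" not in data:
            raise ValueError("config error: 'library' path is required")
        return cls(**data)

    def validate(self) -> None:
        if self.subsample_n < 1:
            raise ValueError("subsample_n must be >= 1")
        for key in ("library", "reads1", "reads2", "assembly"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"config error: {key} path {val!r} does not exist")

    def scoring_scheme(self) -> ScoringScheme:
        return ScoringScheme(**self.scoring)


def subsample_reads(
    r1_in: str | Path,
    r2_in: str | Path,
    r1_out: str | Path,
    r2_out: str | Path,
    n_pairs: int,
    seed: int = 0,
) -> int:
    """Uniform sample of read pairs without replacement (reservoir), mates
    kept together and input order preserved.  Passthrough when n_pairs covers
    the whole file.  Returns the number of pairs written."""
    rng = np.random.default_rng(seed)
    reservoir: list[tuple[int, tuple, tuple]] = []
    total = 0
    for rec1, rec2 in read_fastq_pairs(r1_in, r2_in):
        if total < n_pairs:
            reservoir.append((total, rec1, rec2))
        else:
            k = int(rng.integers(0, total + 1))
            if k < n_pairs:
                reservoir[k] = (total, rec1, rec2)
        total += 1
    reservoir.sort(key=lambda t: t[0])
    with gzip.open(r1_out, "wt") as f1, gzip.open(r2_out, "wt") as f2:
        for _, rec1, rec2 in reservoir:
            f1.write(f"@{rec1[0]}\n{rec1[1]}\n+\n{rec1[2]}\n")
            f2.write(f"@{rec2[0]}\n{rec2[1]}\n+\n{rec2[2]}\n")
    return len(reservoir)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; every stage writes its table under
    ``outdir`` and the run ends with summary.tsv and manifest.json."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scoring = config.scoring_scheme()
    library = read_library(config.library)
    report: dict = {"stages": [], "species": {}}
    checksums = {"library": _sha256(config.library)}

    if config.reads1:
        try:
            sub1 = outdir / "subsampled_1.fastq.gz"
            sub2 = outdir / "subsampled_2.fastq.gz"
            n_sampled = subsample_reads(
                config.reads1, config.reads2, sub1, sub2, config.subsample_n, config.seed
            )
            report["stages"].append({"stage": "subsample", "n_pairs": n_sampled})
            checksums["reads1"] = _sha256(config.reads1)
            checksums["reads2"] = _sha256(config.reads2)
        except Exception as exc:
            raise RuntimeError(f"stage 'subsample' failed: {exc}") from exc

        try:
            queries = []
            total_bp = 0
            for i, (rec1, rec2) in enumerate(read_fastq_pairs(sub1, sub2)):
                queries.append((f"p{i}/1", rec1[1]))
                queries.append((f"p{i}/2", rec2[1]))
                total_bp += len(rec1[1]) + len(rec2[1])
            hits = mask_sequences(queries, library, scoring)
            write_hits_tsv(hits, outdir / "read_hits.tsv")
            divsum = summarize_divsum(hits, total_bp)
            divsum.write_tsv(outdir / "divsum.tsv")
            report["stages"].append(
                {"stage": "mask", "n_reads": len(queries), "n_hits": len(hits)}
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'mask' failed: {exc}") from exc

        try:
            land = build_landscape(divsum, min_abundance=config.min_abundance)
            land.write_csv(outdir / "landscape.csv")
            if not land.rows.empty:
                peak_ages(land, recent_bin=config.recent_bin).to_csv(
                    outdir / "peak_ages.tsv", sep="\t", index=False
                )
            report["stages"].append(
                {"stage": "landscape", "n_families_retained": len(land.families())}
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'landscape' failed: {exc}") from exc

        try:
            stats = family_stats_from_divsum(divsum)
            zrecords = compute_zscores(stats) if len(stats) >= 2 else []
            if zrecords:
                write_zscores_tsv(zrecords, outdir / "zscores.tsv")
            zmap = {r.family: r for r in zrecords}
            with open(outdir / "summary.tsv", "w") as fh:
                fh.write(
                    "family\tabundance_percent\tmean_divergence\tz_abundance\t"
                    "z_divergence\tclass\thighly_abundant_homogenized\n"
                )
                for s in sorted(stats, key=lambda s: -s.abundance):
                    z = zmap.get(s.family)
                    fh.write(
                        f"{s.family}\t{100 * s.abundance:.4f}\t{s.mean_divergence:.3f}\t"
                        + (
                            f"{z.z_abundance:.4f}\t{z.z_divergence:.4f}\t{z.klass}\t"
                            f"{int(z.highly_abundant_homogenized)}\n"
                            if z
                            else "nan\tnan\tNA\t0\n"
                        )
                    )
            n_gain = sum(r.klass == "gain" for r in zrecords)
            report["stages"].append(
                {"stage": "gainloss", "n_gain": n_gain, "n_loss": len(zrecords) - n_gain}
            )
            report["species"]["n_families_detected"] = len(stats)
        except Exception as exc:
            raise RuntimeError(f"stage 'gainloss' failed: {exc}") from exc

    if config.assembly:
        try:
            assembly = read_assembly(config.assembly)
            checksums["assembly"] = _sha256(config.assembly)
            hits = mask_assembly_windows(assembly, library, scoring, window=config.window)
            lengths = {c: len(s) for c, s in assembly.items()}
            profiles = chromosome_abundance(hits, lengths)
            write_profiles_tsv(profiles, outdir / "chromosomes.tsv")
            write_family_chrom_tsv(profiles, outdir / "family_by_chromosome.tsv")
            report["stages"].append(
                {"stage": "chromdist", "n_chromosomes": len(profiles), "n_hits": len(hits)}
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'chromdist' failed: {exc}") from exc

    manifest = {
        "parameters": asdict(config),
        "checksums": checksums,
        "stages": report["stages"],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    report["manifest"] = manifest
    return report
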