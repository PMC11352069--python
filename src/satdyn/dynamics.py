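"""Z-score gain/loss/homogenization classification of satellite families.

Within one species, per-family abundance and mean divergence are
standardized across families (sample standard deviation).  A family with
positive standardized abundance is classified as a gain regardless of the
divergence sign; negative standardized abundance is a loss.  A standardized
abundance above 1 combined with negative standardized divergence marks a
highly abundant, homogenized family — the signature of recent concerted
amplification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "FamilyStat",
    "ZScoreRecord",
    "compute_zscores",
    "classify",
    "gainloss_summary",
    "family_stats_from_divsum",
]


@dataclass
class FamilyStat:
    """Per-family genome abundance (fraction) and bp-weighted mean Kimura
    divergence (percent)."""

    family: str
    abundance: float
    mean_divergence: float

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")
        if not (0.0 <= self.mean_divergence < 70.0):
            raise ValueError("mean_divergence must lie in [0, 70)")


@dataclass
class ZScoreRecord:
    family: str
    z_abundance: float
    z_divergence: float
    klass: str  # {gain, loss}
    highly_abundant_homogenized: bool


def classify(z_abundance: float, z_divergence: float) -> tuple[str, bool]:
    """Gain iff z_abundance > 0 (any divergence sign); loss otherwise
    (including the measure-zero z_abundance == 0 boundary).  The
    homogenization flag requires z_abundance > 1 and z_divergence < 0."""
    if math.isnan(z_abundance) or math.isnan(z_divergence):
        raise ValueError("z-scores must be finite")
    klass = "gain" if z_abundance > 0 else "loss"
    flagged = z_abundance > 1 and z_divergence < 0
    return klass, flagged


def compute_zscores(stats: list[FamilyStat]) -> list[ZScoreRecord]:
    """Standardize abundance and divergence independently across the species'
    families (z = (x - mean)/sd, sample sd with n-1) and classify each."""
    if len(stats) < 2:
        raise ValueError("need at least 2 families to standardize")
    records = []
    means = {}
    sds = {}
    for var in ("abundance", "mean_divergence"):
        xs = [getattr(s, var) for s in stats]
        mean = sum(xs) / len(xs)
        sd = math.sqrt(sum((x - mean) ** 2 for x in xs) / (len(xs) - 1))
        if sd == 0:
            raise ValueError(f"zero variance in {var}; z-scores undefined")
        means[var], sds[var] = mean, sd
    for s in stats:
        za = (s.abundance - means["abundance"]) / sds["abundance"]
        zd = (s.mean_divergence - means["mean_divergence"]) / sds["mean_divergence"]
        klass, flagged = classify(za, zd)
        records.append(
            ZScoreRecord(
                family=s.family,
                z_abundance=za,
                z_divergence=zd,
                klass=klass,
                highly_abundant_homogenized=flagged,
            )
        )
    return records


def gainloss_summary(per_species: dict[str, list[ZScoreRecord]]) -> pd.DataFrame:
    """Counts of gains, losses and flagged families per species."""
    rows = []
    for species, records in per_species.items():
        n_gain = sum(r.klass == "gain" for r in records)
        rows.append(
            {
                "species": species,
                "n_families": len(records),
                "n_gain": n_gain,
                "n_loss": len(records) - n_gain,
                "n_flagged": sum(r.highly_abundant_homogenized for r in records),
            }
        )
    return pd.DataFrame(rows, columns=["species", "n_families", "n_gain", "n_loss", "n_flagged"])


def family_stats_from_divsum(divsum) -> list[FamilyStat]:
    """FamilyStat list (abundance fraction, bp-weighted mean divergence) from
    a divsum table."""
    return [
        FamilyStat(
            family=f,
            abundance=divsum.abundance(f),
            mean_divergence=divsum.mean_divergence(f),
        )
        for f in divsum.families()
    ]


def write_zscores_tsv(records: list[ZScoreRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tz_abundance\tz_divergence\tclass\thighly_abundant_homogenized\n")
        for r in records:
            fh.write(
                f"{r.family}\t{r.z_abundance:.4f}\t{r.z_divergence:.4f}\t{r.klass}\t"
                f"{int(r.highly_abundant_homogenized)}\n"
            )
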