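"""Satellitome landscapes: genome fraction per 1% divergence bin.

A landscape is the divsum table rescaled to percent of the sequenced (or
assembled) bp, keeping only families above a minimum-abundance filter.  A
low-divergence mode marks a recent amplification burst; a high-divergence
mode marks old, decaying copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .masker import DivsumTable

__all__ = ["LandscapeTable", "build_landscape", "peak_ages", "plot_landscape"]

DEFAULT_MIN_ABUNDANCE = 0.2  # percent of genome
DEFAULT_RECENT_BIN = 5  # mode at <= 5% divergence counts as a recent burst


@dataclass
class LandscapeTable:
    """Rows (family, divergence bin, percent of genome)."""

    rows: pd.DataFrame  # columns: family, bin, percent
    total_bp: int
    min_abundance_filter: float

    def families(self) -> list[str]:
        return sorted(self.rows["family"].unique())

    def family_abundance(self, family: str) -> float:
        """Total abundance of a retained family, in percent of genome."""
        return float(self.rows.loc[self.rows["family"] == family, "percent"].sum())

    def write_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)


def build_landscape(
    divsum: DivsumTable, min_abundance: float = DEFAULT_MIN_ABUNDANCE
) -> LandscapeTable:
    """Per-family, per-bin percent of genome; families whose total abundance
    does not exceed ``min_abundance`` (percent) are dropped."""
    if divsum.total_query_bp <= 0:
        raise ValueError("divsum total_query_bp must be positive")
    records = []
    for family in divsum.families():
        total_pct = 100.0 * divsum.family_bp(family) / divsum.total_query_bp
        if total_pct <= min_abundance:
            continue
        for (fam, b), bp in sorted(divsum.cells.items()):
            if fam == family:
                records.append(
                    {"family": family, "bin": b, "percent": 100.0 * bp / divsum.total_query_bp}
                )
    rows = pd.DataFrame(records, columns=["family", "bin", "percent"])
    return LandscapeTable(
        rows=rows, total_bp=divsum.total_query_bp, min_abundance_filter=min_abundance
    )


def peak_ages(
    landscape: LandscapeTable, recent_bin: int = DEFAULT_RECENT_BIN
) -> pd.DataFrame:
    """Mode divergence bin per family (ties -> lowest bin) and whether the
    family's amplification peak is recent (mode <= recent_bin)."""
    if landscape.rows.empty:
        raise ValueError("empty landscape")
    records = []
    for family, grp in landscape.rows.groupby("family"):
        top = grp["percent"].max()
        mode_bin = int(grp.loc[grp["percent"] == top, "bin"].min())
        records.append(
            {"family": family, "mode_bin": mode_bin, "is_recent": mode_bin <= recent_bin}
        )
    return pd.DataFrame(records, columns=["family", "mode_bin", "is_recent"])


def plot_landscape(landscape: LandscapeTable, path: str | Path) -> None:
    """Stacked-bar landscape figure (optional; requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = landscape.rows.pivot_table(
        index="bin", columns="family", values="percent", fill_value=0.0
    )
    fig, ax = plt.subplots(figsize=(8, 4))
    pivot.plot.bar(stacked=True, ax=ax, width=1.0)
    ax.set_xlabel("Kimura divergence from consensus (%)")
    ax.set_ylabel("percent of genome")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
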