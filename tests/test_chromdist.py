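"""Chromosome-level distribution: windowed masking, abundance, landscapes."""

import pytest

from satdyn.chromdist import (
    chromosome_abundance,
    chromosome_landscape,
    mask_assembly_windows,
)
from satdyn.library import SatFamily
from satdyn.masker import mask_sequences
from satdyn.simulate import FamilySpec, SimConfig, build_genome, make_consensus


def _per_family_bp(hits):
    out = {}
    for h in hits:
        out[h.family_name] = out.get(h.family_name, 0) + h.length
    return out


@pytest.fixture(scope="module")
def toy_assembly():
    """Three ~50 kb chromosomes; fam01 everywhere, fam02 planted on chr2 only."""
    cfg = SimConfig(
        genome_length=150_000,
        families=[FamilySpec(170, 0.06, 0.03, name="fam01")],
        n_chromosomes=3,
        seed=17,
    )
    genome, truth = build_genome(cfg)
    cons2 = make_consensus(210, 0.5, seed=18)
    from satdyn.simulate import mutate_copy

    array2 = "".join(mutate_copy(cons2, 0.02, 0.0, 2.0, seed=300 + i) for i in range(40))
    pos = 20_000
    genome["chr2"] = genome["chr2"][:pos] + array2 + genome["chr2"][pos:]
    lib = [
        SatFamily("SimSat01", truth.families["fam01"].consensus),
        SatFamily("SimSat02", cons2),
    ]
    return genome, truth, lib, len(array2)


class TestMaskAssemblyWindows:
    def test_windowed_equals_unwindowed_on_toy(self, toy_assembly):
        genome, _, lib, _ = toy_assembly
        hits_w = mask_assembly_windows(genome, lib, window=20_000, overlap=1000)
        hits_u = mask_assembly_windows(
            genome, lib, window=10**9 // 1000, overlap=1000
        )
        bp_w = _per_family_bp(hits_w)
        bp_u = _per_family_bp(hits_u)
        assert set(bp_w) == set(bp_u)
        for fam in bp_w:
            assert bp_w[fam] == pytest.approx(bp_u[fam], rel=0.01)

    def test_window_larger_than_chromosome_single_window(self, toy_assembly):
        genome, _, lib, _ = toy_assembly
        sub = {"chr1": genome["chr1"]}
        hits_big = mask_assembly_windows(sub, lib, window=10**7, overlap=1000)
        direct = mask_sequences([("chr1", genome["chr1"])], lib)
        from satdyn.chromdist import _merge_hits

        assert _per_family_bp(hits_big) == _per_family_bp(_merge_hits(direct))

    def test_empty_assembly_empty_hits(self, toy_assembly):
        _, _, lib, _ = toy_assembly
        assert mask_assembly_windows({}, lib, window=10_000, overlap=1000) == []

    def test_too_small_overlap_rejected(self, toy_assembly):
        genome, _, lib, _ = toy_assembly
        with pytest.raises(ValueError, match="overlap"):
            mask_assembly_windows(genome, lib, window=10_000, overlap=100)

    def test_merged_hits_disjoint_per_family(self, toy_assembly):
        genome, _, lib, _ = toy_assembly
        hits = mask_assembly_windows(genome, lib, window=20_000, overlap=1000)
        by_fam = {}
        for h in hits:
            by_fam.setdefault((h.query_id, h.family_name), []).append(h)
        for group in by_fam.values():
            group.sort(key=lambda h: h.query_start)
            for a, b in zip(group, group[1:]):
                assert a.query_end < b.query_start


class TestChromosomeAbundance:
    def test_planted_fraction_recovered(self, toy_assembly):
        genome, truth, lib, array2_len = toy_assembly
        hits = mask_assembly_windows(genome, lib, window=20_000, overlap=1000)
        lengths = {c: len(s) for c, s in genome.items()}
        profiles = {p.chromosome: p for p in chromosome_abundance(hits, lengths)}
        planted2_pct = 100 * array2_len / lengths["chr2"]
        est2 = profiles["chr2"].per_family.get("SimSat02", {"percent_of_chromosome": 0})
        assert est2["percent_of_chromosome"] == pytest.approx(planted2_pct, abs=1.0)

    def test_chromosome_specific_family_flagged(self, toy_assembly):
        genome, _, lib, _ = toy_assembly
        hits = mask_assembly_windows(genome, lib, window=20_000, overlap=1000)
        lengths = {c: len(s) for c, s in genome.items()}
        profiles = {p.chromosome: p for p in chromosome_abundance(hits, lengths)}
        assert "SimSat02" in profiles["chr2"].specific_families
        for chrom in ("chr1", "chr3"):
            assert "SimSat02" not in profiles[chrom].specific_families

    def test_satellite_bp_conservation_across_chromosomes(self, toy_assembly):
        genome, _, lib, _ = toy_assembly
        hits = mask_assembly_windows(genome, lib, window=20_000, overlap=1000)
        lengths = {c: len(s) for c, s in genome.items()}
        profiles = chromosome_abundance(hits, lengths)
        assert sum(p.satellite_bp for p in profiles) == sum(h.length for h in hits)
        for p in profiles:
            assert p.satellite_bp == sum(d["bp"] for d in p.per_family.values())
            assert p.satellite_percent == pytest.approx(100 * p.satellite_bp / p.length)

    def test_hit_beyond_chromosome_rejected(self, toy_assembly):
        genome, _, lib, _ = toy_assembly
        hits = mask_assembly_windows(genome, lib, window=20_000, overlap=1000)
        short = {c: 10 for c in genome}
        with pytest.raises(ValueError):
            chromosome_abundance(hits, short)


class TestChromosomeLandscape:
    def test_low_divergence_family_has_recent_mode(self, toy_assembly):
        genome, _, lib, _ = toy_assembly
        hits = mask_assembly_windows(genome, lib, window=20_000, overlap=1000)
        lengths = {c: len(s) for c, s in genome.items()}
        land = chromosome_landscape(hits, "chr2", lengths, min_abundance=0.2)
        from satdyn.landscape import peak_ages

        ages = peak_ages(land).set_index("family")
        assert int(ages.loc["SimSat02", "mode_bin"]) <= 3

    def test_unknown_chromosome_rejected(self, toy_assembly):
        genome, _, lib, _ = toy_assembly
        with pytest.raises(ValueError):
            chromosome_landscape([], "chrZ", {c: len(s) for c, s in genome.items()})

    def test_empty_chromosome_empty_table(self, toy_assembly):
        genome, _, _, _ = toy_assembly
        land = chromosome_landscape([], "chr1", {c: len(s) for c, s in genome.items()})
        assert land.rows.empty
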