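"""Synthetic genome generator: determinism, planted rates, conservation."""

import numpy as np
import pytest

from satdyn._seq import revcomp
from satdyn.simulate import (
    FamilySpec,
    SimConfig,
    build_genome,
    make_consensus,
    mutate_copy,
    simulate_reads,
)

from oracle_align import sw_oracle


class TestMakeConsensus:
    def test_gc_zero_uses_only_at(self):
        assert set(make_consensus(60, 0.0, seed=1)) <= {"A", "T"}

    def test_seed_determinism(self):
        assert make_consensus(300, 0.5, seed=42) == make_consensus(300, 0.5, seed=42)

    def test_gc_count_within_binomial_bounds(self):
        seq = make_consensus(1000, 0.5, seed=7)
        gc = seq.count("G") + seq.count("C")
        sd = (1000 * 0.25) ** 0.5
        assert abs(gc - 500) <= 4 * sd

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            make_consensus(9, 0.5, seed=0)


class TestMutateCopy:
    def test_zero_rates_identity(self):
        cons = make_consensus(200, 0.5, seed=5)
        assert mutate_copy(cons, 0.0, 0.0, 2.0, seed=9) == cons

    def test_pooled_substitution_rate_matches_binomial(self):
        cons = make_consensus(100, 0.5, seed=2)
        mism = total = 0
        for i in range(1000):
            copy = mutate_copy(cons, 0.10, 0.0, 2.0, seed=i)
            assert len(copy) == 100
            mism += sum(a != b for a, b in zip(copy, cons))
            total += 100
        # central 99.9% binomial interval around p=0.10
        from scipy.stats import binom

        lo, hi = binom.ppf([0.0005, 0.9995], total, 0.10)
        assert lo <= mism <= hi

    def test_indel_only_copies_show_no_mismatches(self):
        cons = make_consensus(150, 0.5, seed=3)
        for i in range(5):
            copy = mutate_copy(cons, 0.0, 0.02, 2.0, seed=50 + i)
            # with mismatches priced out, the optimal alignment is gaps-only
            # and still covers essentially the whole copy
            aln = sw_oracle(copy, cons, mismatch=-10**6)
            assert aln["transitions"] + aln["transversions"] == 0
            assert aln["matches"] >= 0.9 * min(len(copy), len(cons))

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            mutate_copy("ACGT" * 10, 1.0, 0.0, 2.0, seed=0)


class TestBuildGenome:
    def test_no_families_gives_pure_background(self):
        genome, truth = build_genome(SimConfig(genome_length=50_000, seed=3))
        assert sum(len(s) for s in genome.values()) == 50_000
        assert truth.families == {} and truth.arrays == []

    def test_realized_occupancy_near_target(self):
        cfg = SimConfig(
            genome_length=1_000_000,
            families=[FamilySpec(170, 0.05, 0.02)],
            seed=5,
        )
        _, truth = build_genome(cfg)
        assert truth.families["fam01"].realized_occupancy == pytest.approx(0.05, abs=0.005)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_array_intervals_disjoint_and_conserved(self, seed):
        cfg = SimConfig(
            genome_length=300_000,
            families=[FamilySpec(170, 0.04, 0.05), FamilySpec(210, 0.02, 0.1)],
            n_chromosomes=3,
            seed=seed,
        )
        genome, truth = build_genome(cfg)
        by_chrom = {}
        for fam, chrom, s, e in truth.arrays:
            assert 0 <= s < e <= len(genome[chrom])
            by_chrom.setdefault(chrom, []).append((s, e))
        for ivals in by_chrom.values():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                assert e1 <= s2
        planted = sum(e - s for _, _, s, e in truth.arrays)
        assert planted == sum(f.planted_bp for f in truth.families.values())
        assert sum(len(s) for s in genome.values()) == cfg.genome_length

    def test_arrays_contain_monomer_copies(self, small_sim):
        """Planted array sequence aligns to its consensus with ~the planted
        divergence."""
        _, genome, truth = small_sim
        fam, chrom, s, e = truth.arrays[0]
        cons = truth.families[fam].consensus
        window = genome[chrom][s : s + min(e - s, len(cons))]
        alns = [sw_oracle(window, cons * 2), sw_oracle(revcomp(window), cons * 2)]
        best = max((a for a in alns if a), key=lambda a: a["score"])
        assert best["matches"] > 0.7 * len(window)

    def test_overfull_occupancy_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(
                genome_length=10_000,
                families=[FamilySpec(170, 0.6, 0.0), FamilySpec(170, 0.5, 0.0)],
            ).validate()


class TestSimulateReads:
    def test_pair_count_formula(self):
        genome = {"chr1": make_consensus(1_000_000, 0.5, seed=1)}
        pairs = simulate_reads(genome, 0.1, 150, 350, 0.0, seed=2)
        assert len(pairs) == 333  # floor(0.1 * 1e6 / 300)

    def test_error_free_reads_are_genome_substrings(self):
        genome = {"chr1": make_consensus(20_000, 0.5, seed=4)}
        rc = revcomp(genome["chr1"])
        for p in simulate_reads(genome, 0.05, 150, 350, 0.0, seed=5):
            assert p.seq1 in genome["chr1"] or p.seq1 in rc
            assert p.seq2 in genome["chr1"] or p.seq2 in rc

    def test_mate_is_fragment_end_revcomp(self):
        genome = {"chr1": make_consensus(5_000, 0.5, seed=6)}
        p = simulate_reads(genome, 0.05, 100, 300, 0.0, seed=7)[0]
        i = genome["chr1"].find(p.seq1)
        frag = genome["chr1"][i : i + 300]
        assert revcomp(frag[-100:]) == p.seq2

    def test_seed_determinism(self):
        genome = {"chr1": make_consensus(30_000, 0.5, seed=8)}
        a = simulate_reads(genome, 0.1, 150, 350, 0.01, seed=9)
        b = simulate_reads(genome, 0.1, 150, 350, 0.01, seed=9)
        assert [(p.seq1, p.seq2) for p in a] == [(p.seq1, p.seq2) for p in b]

    def test_short_genome_rejected(self):
        with pytest.raises(ValueError):
            simulate_reads({"chr1": "ACGT" * 20}, 0.1, 150, 350, 0.0, seed=0)
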