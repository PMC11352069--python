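"""Library nomenclature, FASTA round-trips and superfamily grouping."""

import pytest

from satdyn._seq import revcomp
from satdyn.library import (
    NAME_RE,
    SatFamily,
    assign_names,
    group_superfamilies,
    read_library,
    write_library,
)
from satdyn.simulate import make_consensus, mutate_copy


class TestAssignNames:
    def test_rank_by_decreasing_abundance(self):
        fa = make_consensus(200, 0.5, 1)
        fb = make_consensus(200, 0.5, 2)
        named = assign_names([(fa, 0.03), (fb, 0.05)], "Mth")
        assert named[0].name == "MthSat01" and named[0].consensus == fb
        assert named[1].name == "MthSat02" and named[1].consensus == fa

    def test_empty_list(self):
        assert assign_names([], "Mth") == []

    def test_tie_broken_by_longer_monomer(self):
        long_m = make_consensus(300, 0.5, 3)
        short_m = make_consensus(150, 0.5, 4)
        named = assign_names([(short_m, 0.01), (long_m, 0.01)], "Psu")
        assert named[0].consensus == long_m

    def test_three_digit_names_from_rank_100(self):
        fams = [(make_consensus(50, 0.5, i), 1.0 / (i + 1)) for i in range(105)]
        named = assign_names(fams, "Mth")
        assert named[98].name == "MthSat99"
        assert named[99].name == "MthSat100"
        assert all(NAME_RE.match(f.name) for f in named)

    def test_bad_species_code_rejected(self):
        with pytest.raises(ValueError):
            assign_names([(make_consensus(50, 0.5, 0), 1.0)], "Myth")


class TestLibraryIO:
    def test_round_trip(self, tmp_path):
        fams = [
            SatFamily(f"MthSat{i:02d}", make_consensus(100 + 10 * i, 0.5, i), conf)
            for i, conf in zip(range(1, 6), ["high", "low", "high", "high", "low"])
        ]
        path = tmp_path / "lib.fasta"
        write_library(fams, path)
        back = read_library(path)
        assert [(f.name, f.consensus, f.confidence) for f in back] == [
            (f.name, f.consensus, f.confidence) for f in fams
        ]

    def test_duplicate_names_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        seq = make_consensus(80, 0.5, 9)
        path.write_text(f">MthSat01\n{seq}\n>MthSat01\n{seq}\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_library(path)

    def test_non_acgt_names_offending_record(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">MthSat01\nACGTNNACGTAC\n")
        with pytest.raises(ValueError, match="MthSat01"):
            read_library(path)

    def test_multispecies_concatenation_preserves_order(self, tmp_path):
        libs = []
        for s, (code, n) in enumerate([("Aaa", 10), ("Bbb", 20), ("Ccc", 5)]):
            libs.append(
                [
                    SatFamily(f"{code}Sat{i + 1:02d}", make_consensus(60, 0.5, 100 * s + i))
                    for i in range(n)
                ]
            )
        merged = [f for lib in libs for f in lib]
        path = tmp_path / "merged.fasta"
        write_library(merged, path)
        back = read_library(path)
        assert len(back) == 35
        assert [f.name for f in back] == [f.name for f in merged]


class TestSuperfamilies:
    def test_identical_consensuses_grouped(self):
        cons = make_consensus(200, 0.5, 7)
        part = group_superfamilies(
            [SatFamily("AaaSat01", cons), SatFamily("BbbSat01", cons)]
        )
        assert part.assignment["AaaSat01"] == part.assignment["BbbSat01"]
        assert part.n_superfamilies == 1

    def test_revcomp_rotation_grouped(self):
        cons = make_consensus(200, 0.5, 8)
        rotated_rc = revcomp(cons[37:] + cons[:37])
        part = group_superfamilies(
            [SatFamily("AaaSat01", cons), SatFamily("BbbSat01", rotated_rc)]
        )
        assert part.n_superfamilies == 1
        (ev,) = part.evidence.values()
        assert ev["identity"] >= 0.99 and ev["coverage"] >= 0.99

    def test_diverged_relative_grouped_random_not(self):
        cons = make_consensus(180, 0.5, 12)
        relative = mutate_copy(cons, 0.15, 0.01, 2.0, seed=13)
        stranger = make_consensus(180, 0.5, 14)
        part = group_superfamilies(
            [
                SatFamily("AaaSat01", cons),
                SatFamily("BbbSat01", relative),
                SatFamily("CccSat01", stranger),
            ]
        )
        assert part.assignment["AaaSat01"] == part.assignment["BbbSat01"]
        assert part.assignment["CccSat01"] != part.assignment["AaaSat01"]

    def test_random_families_stay_singletons(self):
        lib = [
            SatFamily(f"Aaa" + f"Sat{i + 1:02d}", make_consensus(200, 0.5, 1000 + i))
            for i in range(20)
        ]
        part = group_superfamilies(lib)
        assert part.n_superfamilies == 20

    def test_partition_invariant_to_input_order(self):
        cons = make_consensus(150, 0.5, 21)
        fams = [
            SatFamily("AaaSat01", cons),
            SatFamily("BbbSat01", mutate_copy(cons, 0.1, 0.0, 2.0, seed=22)),
            SatFamily("CccSat01", make_consensus(150, 0.5, 23)),
            SatFamily("DddSat01", make_consensus(220, 0.5, 24)),
        ]
        def groups(partition):
            by_id = {}
            for name, sid in partition.assignment.items():
                by_id.setdefault(sid, set()).add(name)
            return {frozenset(v) for v in by_id.values()}

        p1 = group_superfamilies(fams)
        p2 = group_superfamilies(fams[::-1])
        assert groups(p1) == groups(p2)
        assert sorted(set(p1.assignment.values())) == list(
            range(1, p1.n_superfamilies + 1)
        )
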