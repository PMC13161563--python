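"""Hairpin-processing profiler: arm assignment, isomiR grouping, bias, abundance."""

import math

import numpy as np
import pytest

from cagmir.guides import RepeatTarget
from cagmir.simulate import make_reads, study_hairpin, study_mixture
from cagmir.smallrna import (
    GUIDE,
    PASSENGER,
    EmptyLibraryError,
    HairpinAnnotation,
    assign_read,
    assign_reads,
    annotate_registers,
    group_variants,
    length_distribution,
    profile_reads,
    read_small_rna,
    strand_bias,
    top_n_fraction,
)


@pytest.fixture(scope="module")
def hairpin():
    return study_hairpin()


def guide_seq(hairpin):
    s, e = hairpin.guide_arm
    return hairpin.sequence[s:e]


class TestAssignRead:
    def test_perfect_guide_excision(self, hairpin):
        a = assign_read(guide_seq(hairpin), hairpin)
        assert (a.arm, a.start_offset) == (GUIDE, hairpin.guide_arm[0])
        assert a.templated_length == len(guide_seq(hairpin))

    def test_plus_one_shifted_isomir(self, hairpin):
        s = hairpin.guide_arm[0]
        read = hairpin.sequence[s - 1 : hairpin.guide_arm[1]]
        a = assign_read(read, hairpin)
        assert (a.arm, a.start_offset) == (GUIDE, s - 1)

    def test_nontemplated_tail_lands_in_same_group(self, hairpin):
        base = assign_read(guide_seq(hairpin), hairpin)
        # a tail the hairpin cannot template (loop starts with T here)
        tailed = assign_read(guide_seq(hairpin) + "GA", hairpin)
        assert (tailed.arm, tailed.start_offset) == (base.arm, base.start_offset)

    def test_passenger_read(self, hairpin):
        s, e = hairpin.passenger_arm
        a = assign_read(hairpin.sequence[s:e], hairpin)
        assert (a.arm, a.start_offset) == (PASSENGER, s)

    def test_foreign_read_unassigned_not_dropped(self, hairpin):
        a = assign_read("ATATATATATATATATATA", hairpin)
        assert not a.assigned
        assert a.count == 1

    def test_length_bounds(self, hairpin):
        assert not assign_read("ACGTACGTACGT", hairpin).assigned  # 12 nt < 15
        assert not assign_read(hairpin.sequence[:31], hairpin).assigned  # > 30


class TestGrouping:
    def test_all_identical_reads_single_group(self, hairpin):
        groups = group_variants(assign_reads([guide_seq(hairpin)] * 10, hairpin))
        assert len(groups) == 1
        assert groups[0].fraction_of_assigned == 100.0

    def test_equal_counts_ordered_by_start_offset(self, hairpin):
        s = hairpin.guide_arm[0]
        reads = [guide_seq(hairpin)] * 5 + [
            hairpin.sequence[s - 1 : hairpin.guide_arm[1]]
        ] * 5
        groups = group_variants(assign_reads(reads, hairpin))
        assert [g.start_offset for g in groups] == [s - 1, s]
        assert all(g.fraction_of_assigned == 50.0 for g in groups)

    def test_rare_starts_pooled_into_other(self, hairpin):
        s = hairpin.guide_arm[0]
        reads = [guide_seq(hairpin)] * 990 + [
            hairpin.sequence[s + 2 : s + 2 + 19]
        ] * 2  # 0.2% < default 0.5%
        groups = group_variants(assign_reads(reads, hairpin))
        other = [g for g in groups if g.start_offset is None]
        assert len(other) == 1
        assert other[0].read_count == 2

    def test_zero_assigned_reads_is_an_error(self, hairpin):
        with pytest.raises(EmptyLibraryError):
            group_variants(assign_reads(["ATATATATATATATATATA"], hairpin))

    def test_conservation_of_read_counts(self, hairpin):
        rng = np.random.default_rng(2)
        reads, _, _ = make_reads(hairpin, study_mixture(hairpin, depth=5000), seed=2)
        junk = ["".join("ACGT"[b] for b in rng.integers(0, 4, 20)) for _ in range(50)]
        assignments = assign_reads(reads + junk, hairpin)
        n_total = sum(a.count for a in assignments)
        n_assigned = sum(a.count for a in assignments if a.assigned)
        assert n_total == len(reads) + len(junk)
        groups = group_variants(assignments)
        assert sum(g.read_count for g in groups) == n_assigned
        assert math.isclose(sum(g.fraction_of_assigned for g in groups), 100.0)


class TestStrandBiasAndLengths:
    def test_all_guide(self, hairpin):
        groups = group_variants(assign_reads([guide_seq(hairpin)] * 4, hairpin))
        assert strand_bias(groups) == (100.0, 0.0)

    def test_equal_split(self, hairpin):
        s, e = hairpin.passenger_arm
        reads = [guide_seq(hairpin)] * 6 + [hairpin.sequence[s:e]] * 6
        assert strand_bias(group_variants(assign_reads(reads, hairpin))) == (50.0, 50.0)

    def test_length_histogram_support(self, hairpin):
        s = hairpin.guide_arm[0]
        reads = [hairpin.sequence[s : s + L] for L in range(19, 24)]
        hist = length_distribution(group_variants(assign_reads(reads, hairpin)))
        assert sorted(hist) == [19, 20, 21, 22, 23]
        assert all(v == 1 for v in hist.values())


class TestTopNFraction:
    def test_reference_arithmetic(self):
        endo = {f"m{i}": 200 for i in range(50)}  # top-50 sum = 10000
        assert top_n_fraction(71, endo, 50) == pytest.approx(0.71)

    def test_zero_amirna(self):
        assert top_n_fraction(0, {"m": 10}, 1) == 0.0

    def test_scale_invariance(self):
        endo = {f"m{i}": c for i, c in enumerate(range(1, 101))}
        a = top_n_fraction(37, endo, 50)
        b = top_n_fraction(370, {k: v * 10 for k, v in endo.items()}, 50)
        assert a == pytest.approx(b)

    def test_fewer_species_than_n_warns(self):
        with pytest.warns(UserWarning, match="only 2"):
            top_n_fraction(5, {"a": 10, "b": 10}, 50)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            top_n_fraction(5, {"a": 0}, 1)


class TestRegisterAnnotation:
    def test_canonical_and_shifted_registers(self, hairpin):
        s, e = hairpin.guide_arm
        reads = [hairpin.sequence[s:e]] * 5 + [hairpin.sequence[s - 1 : e]] * 5
        groups = annotate_registers(
            group_variants(assign_reads(reads, hairpin)), RepeatTarget("CAG", 28)
        )
        by_start = {g.start_offset: g.register_mismatches for g in groups}
        assert by_start[s] == (8, 13)
        assert by_start[s - 1] == (9, 14)

    def test_pure_repeat_control_guide_has_empty_register(self):
        pure = "CTG" * 6 + "C"
        hp = HairpinAnnotation(
            "pure", "ACGGTATCTG" + pure + "TGTGACCGAATTCATGC" + "GCA" * 7,
            guide_arm=(10, 29), passenger_arm=(46, 67),
        )
        groups = annotate_registers(
            group_variants(assign_reads([pure] * 3, hp)), RepeatTarget("CAG", 28)
        )
        assert groups[0].register_mismatches == ()

    def test_register_shift_consistency(self, hairpin):
        """A +1 start shift displaces every register mismatch by +1."""
        s, e = hairpin.guide_arm
        reads = [hairpin.sequence[s:e]] * 5 + [hairpin.sequence[s - 1 : e - 1]] * 5
        groups = annotate_registers(
            group_variants(assign_reads(reads, hairpin)), RepeatTarget("CAG", 28)
        )
        by_start = {g.start_offset: g.register_mismatches for g in groups}
        assert by_start[s - 1] == tuple(p + 1 for p in by_start[s])


class TestMixtureRecovery:
    def test_proportions_within_three_sigma(self, hairpin):
        mixture = study_mixture(hairpin)
        reads, endo, truth = make_reads(hairpin, mixture, seed=17)
        report = profile_reads(reads, hairpin, endogenous=endo)
        n = report.n_assigned
        truth_groups = truth.records[1]["groups"]
        observed = {
            (g.arm, g.start_offset): g.read_count / n
            for g in report.variant_table
        }
        for tg in truth_groups:
            p = tg["proportion"]
            sigma = math.sqrt(p * (1 - p) / n)
            assert abs(observed[(tg["arm"], tg["start_offset"])] - p) <= 3 * sigma
        guide_p = truth.params["guide_proportion"]
        sigma = math.sqrt(guide_p * (1 - guide_p) / n)
        assert abs(report.strand_bias_guide_percent / 100 - guide_p) <= 3 * sigma

    def test_report_is_deterministic(self, hairpin):
        reads, endo, _ = make_reads(hairpin, study_mixture(hairpin, depth=20000), seed=8)
        r1 = profile_reads(reads, hairpin, repeat_target=RepeatTarget("CAG", 28),
                           endogenous=endo)
        r2 = profile_reads(reads, hairpin, repeat_target=RepeatTarget("CAG", 28),
                           endogenous=endo)
        assert r1.to_json() == r2.to_json()


def test_read_small_rna_formats(tmp_path, hairpin):
    g = guide_seq(hairpin)
    (tmp_path / "r.fastq").write_text(f"@r1\n{g}\n+\n{'I' * len(g)}\n@r2\n{g}\n+\n{'I' * len(g)}\n")
    (tmp_path / "r.fasta").write_text(f">r1\n{g}\n")
    (tmp_path / "r.tsv").write_text(f"{g}\t7\n")
    assert read_small_rna(tmp_path / "r.fastq") == {g: 2}
    assert read_small_rna(tmp_path / "r.fasta") == {g: 1}
    assert read_small_rna(tmp_path / "r.tsv") == {g: 7}
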