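"""Off-target scanning: seeded scan vs naive oracle, loci, annotation, ranking."""

import warnings

import numpy as np
import pytest

from cagmir.guides import A2, GuideStrand
from cagmir.offtarget import (
    OffTargetHit,
    OffTargetSummary,
    RegionAnnotation,
    annotate_loci,
    make_target_site,
    merge_loci,
    naive_scan,
    rank_guides,
    scan,
    summarize,
)
from cagmir.guides import revcomp_dna
from oracles import merge_intervals, revcomp_dna_oracle, sliding_hamming_hits


def random_dna(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


class TestTargetSite:
    def test_a2_site(self):
        assert make_target_site(A2).site_sequence == "GCAGCAGCAGCTGCAGCAG"
        assert make_target_site(A2).site_sequence == revcomp_dna_oracle(A2.dna)

    def test_pure_repeat_guide_site(self):
        pure = GuideStrand("pure", "CUG" * 6 + "C")
        assert make_target_site(pure).site_sequence == "GCAGCAGCAGCAGCAGCAG"

    def test_13a_site(self, variants):
        site = make_target_site(variants["13A"])
        assert site.site_sequence == "GCAGCATCAGCTGCAGCAG"
        assert site.site_sequence == revcomp_dna_oracle(variants["13A"].dna)

    def test_double_reverse_complement_recovers_guide(self, variants):
        for v in variants.values():
            site = make_target_site(v).site_sequence
            assert revcomp_dna(site) == v.dna


class TestScan:
    def test_planted_site_exact_hit(self):
        rng = np.random.default_rng(0)
        site = make_target_site(A2)
        seq = random_dna(rng, 200)
        seq = seq[:50] + site.site_sequence + seq[69:]
        hits = scan([("s", seq)], site, 0, "sense").hits
        planted = [h for h in hits if h.start == 50]
        assert len(planted) == 1
        assert (planted[0].start, planted[0].end, planted[0].mismatch_count) == (50, 69, 0)

    def test_cag_tract_in_frame_one_mismatch_hits(self):
        site = make_target_site(A2)
        tract = "CAG" * 30
        result = scan([("t", tract)], site, 1, "sense")
        expected = sliding_hamming_hits(tract, site.site_sequence, 1)
        assert [(h.start, h.mismatch_count) for h in result.hits] == expected
        assert all(h.mismatch_count == 1 for h in result.hits)
        assert len({h.start % 3 for h in result.hits}) == 1  # all in one frame

    def test_cag_tract_has_no_perfect_windows(self):
        site = make_target_site(A2)
        assert scan([("t", "CAG" * 30)], site, 0, "sense").hits == []

    @pytest.mark.parametrize("budget", [0, 1, 2, 3])
    @pytest.mark.parametrize("strands", ["sense", "both"])
    def test_seeded_scan_equals_naive_oracle(self, budget, strands):
        rng = np.random.default_rng(42)
        site = make_target_site(A2)
        for _ in range(8):
            seq = random_dna(rng, int(rng.integers(500, 2000)))
            a = scan([("s", seq)], site, budget, strands)
            b = naive_scan([("s", seq)], site, budget, strands)
            assert a.hits == b.hits
            assert a.n_windows_skipped == b.n_windows_skipped

    def test_windows_with_n_skipped_and_tallied(self):
        rng = np.random.default_rng(1)
        site = make_target_site(A2)
        seq = random_dna(rng, 100)
        seq = seq[:30] + site.site_sequence + seq[49:]
        seq = seq[:40] + "N" + seq[41:]  # N inside the planted window
        result = scan([("s", seq)], site, 0, "sense")
        assert result.hits == []
        # independent N-window count
        L = len(site.site_sequence)
        n_skipped = sum(
            1
            for start in range(len(seq) - L + 1)
            if "N" in seq[start : start + L]
        )
        assert result.n_windows_skipped == n_skipped > 0

    def test_strand_symmetry(self):
        rng = np.random.default_rng(3)
        site = make_target_site(A2)
        seq = random_dna(rng, 1500)
        fwd = scan([("s", seq)], site, 3, "both")
        rev = scan([("s", revcomp_dna(seq))], site, 3, "both")
        n = len(seq)
        L = len(site.site_sequence)
        reflected = sorted(
            (n - h.end, "-" if h.strand == "+" else "+", h.mismatch_count)
            for h in rev.hits
        )
        assert sorted((h.start, h.strand, h.mismatch_count) for h in fwd.hits) == reflected

    def test_mismatch_positions_verify_against_observed_site(self):
        rng = np.random.default_rng(9)
        site = make_target_site(A2)
        seq = random_dna(rng, 3000)
        seq = seq[:100] + site.site_sequence + seq[119:]
        for h in scan([("s", seq)], site, 3, "both").hits:
            L = len(site.site_sequence)
            diff = {
                L - i
                for i, (a, b) in enumerate(zip(h.site_observed, site.site_sequence))
                if a != b
            }
            assert set(h.mismatch_positions) == diff
            assert h.mismatch_count == len(diff) <= 3

    def test_cumulative_monotonicity(self):
        rng = np.random.default_rng(5)
        site = make_target_site(A2)
        seq = random_dna(rng, 4000)
        totals = [len(scan([("s", seq)], site, k, "both").hits) for k in range(4)]
        assert totals == sorted(totals)

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            scan([], make_target_site(A2), 0)

    def test_budget_out_of_range(self):
        with pytest.raises(ValueError, match="budget"):
            scan([("s", "ACGT" * 20)], make_target_site(A2), 4)


class TestMergeLoci:
    def test_overlapping_tract_windows_form_one_locus(self):
        site = make_target_site(A2)
        hits = scan([("t", "CAG" * 30)], site, 1, "sense").hits
        loci = merge_loci(hits)
        assert len(loci) == 1
        assert loci[0].n_windows == len(hits)
        assert loci[0].min_mismatch_count == 1
        (span,) = merge_intervals([(h.start, h.end) for h in hits])
        assert (loci[0].start, loci[0].end) == span

    def test_distant_sites_stay_separate(self):
        rng = np.random.default_rng(11)
        site = make_target_site(A2)
        seq = random_dna(rng, 400)
        for off in (50, 150, 300):
            seq = seq[:off] + site.site_sequence + seq[off + 19 :]
        hits = [h for h in scan([("s", seq)], site, 0, "sense").hits]
        assert len(merge_loci(hits)) == 3

    def test_empty_input(self):
        assert merge_loci([]) == []

    def test_random_intervals_match_union_oracle(self):
        rng = np.random.default_rng(13)
        hits = []
        for _ in range(60):
            start = int(rng.integers(0, 500))
            hits.append(
                OffTargetHit("s", "+", start, start + 19, 1, (8,), "x" * 19)
            )
        loci = merge_loci(hits)
        assert [(l.start, l.end) for l in loci] == merge_intervals(
            [(h.start, h.end) for h in hits]
        )
        assert sum(l.n_windows for l in loci) == len(hits)


class TestAnnotateLoci:
    def _loci(self, *spans):
        return [
            merge_loci([OffTargetHit("chr1", "+", s, e, 0, (), "")])[0]
            for s, e in spans
        ]

    def test_cds_label_and_boundary_span(self, tmp_path):
        bed = tmp_path / "regions.bed"
        bed.write_text(
            "chr1\t90\t200\tCDS\t0\t+\n"
            "chr1\t200\t300\t3UTR\t0\t+\n"
        )
        ann = RegionAnnotation.from_bed(bed)
        inside, straddle, outside = annotate_loci(
            self._loci((100, 119), (190, 210), (400, 419)), ann
        )
        assert inside.region_labels == {"CDS"}
        assert straddle.region_labels == {"CDS", "3UTR"}
        assert outside.region_labels == {"intergenic"}

    def test_gff3_region_types(self, tmp_path):
        gff = tmp_path / "ann.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tCDS\t91\t200\t.\t+\t0\tID=c1\n"
            "chr1\tsrc\tfive_prime_UTR\t1\t90\t.\t+\t.\tID=u1\n"
            "chr1\tsrc\tgene\t1\t300\t.\t+\t.\tID=g1\n"
        )
        ann = RegionAnnotation.from_gff3(gff)
        (locus,) = annotate_loci(self._loci((85, 104)), ann)
        assert locus.region_labels == {"CDS", "5UTR"}

    def test_unknown_sequence_warns_and_leaves_unlabelled(self, tmp_path):
        bed = tmp_path / "regions.bed"
        bed.write_text("chr2\t0\t100\tCDS\t0\t+\n")
        ann = RegionAnnotation.from_bed(bed)
        with pytest.warns(UserWarning, match="no annotation"):
            (locus,) = annotate_loci(self._loci((10, 29)), ann)
        assert locus.region_labels == frozenset()


class TestSummarizeAndRank:
    def test_planted_transcriptome_counts(self):
        from cagmir.simulate import make_genome

        site = make_target_site(A2)
        records, truth = make_genome(
            n_sequences=15,
            length=2000,
            planted=[
                (site.site_sequence, 0, 3),
                (site.site_sequence, 1, 5),
                (site.site_sequence, 2, 7),
            ],
            scan_budget=2,
            seed=21,
        )
        (summary,) = summarize([A2], records, budget=2, level="transcript")
        counts = dict(summary.counts_by_exact_mismatch)
        # 15 transcripts, one planted site each -> per-transcript minima
        assert counts == {0: 3, 1: 5, 2: 7}

    def test_window_and_locus_levels_on_tract(self):
        tract = [("t", "CAG" * 30)]
        (win,) = summarize([A2], tract, budget=1, level="window", strands="sense")
        (loc,) = summarize([A2], tract, budget=1, level="locus", strands="sense")
        assert win.counts_by_exact_mismatch[1] > 1
        assert loc.counts_by_exact_mismatch[1] == 1

    def test_variant_without_planted_sites_ranks_first(self, variants):
        from cagmir.simulate import make_genome

        others = ["9A", "10A", "11A", "13G", "13G16U"]
        planted = [(make_target_site(A2).site_sequence, 0, 2)]
        planted += [
            (make_target_site(variants[n]).site_sequence, 0, 1) for n in others
        ]
        records, _ = make_genome(
            n_sequences=7, length=1500, planted=planted, scan_budget=0, seed=33
        )
        guides = [A2] + [variants[n] for n in others + ["13A"]]
        ranked = rank_guides(summarize(guides, records, budget=0, level="transcript"))
        assert ranked[0].guide_name == "13A"

    def test_rank_is_lexicographic_then_alphabetical(self):
        mk = lambda name, c: OffTargetSummary(name, "transcript", dict(enumerate(c)))
        ranked = rank_guides([mk("A", (0, 2, 9)), mk("B", (0, 1, 30)), mk("C", (1, 0, 0))])
        assert [s.guide_name for s in ranked] == ["B", "A", "C"]
        ranked = rank_guides([mk("zeta", (1, 1)), mk("alpha", (1, 1))])
        assert [s.guide_name for s in ranked] == ["alpha", "zeta"]
        assert [s.guide_name for s in rank_guides([mk("only", (5,))])] == ["only"]

    def test_mixed_levels_rejected(self):
        a = OffTargetSummary("a", "window", {0: 1})
        b = OffTargetSummary("b", "locus", {0: 1})
        with pytest.raises(ValueError, match="mixed levels"):
            rank_guides([a, b])
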