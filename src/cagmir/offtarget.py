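"""Mismatch-budget enumeration of guide-strand binding sites in sequence databases.

A guide binds any genomic or transcript window whose sequence is the
reverse complement of the guide up to a small Hamming budget (0–3
mismatches, no indels, no wobble).  This module enumerates every such
window exhaustively, merges overlapping windows into loci, annotates loci
against CDS/UTR/intron intervals, summarizes exact-mismatch counts per
guide, and ranks design variants by their off-target load.

The production scanner (:func:`scan`) uses pigeonhole seeding: a site
scanned at budget k is split into k+1 near-equal segments, at least one of
which must match exactly in any hit window; exact segment matches anchor
candidate windows that are then fully verified.  The contract is the hit
set, not the algorithm — :func:`naive_scan` is the plain sliding-window
Hamming reference that the seeded scanner must agree with exactly.

Genome scans run in both-strand mode; transcriptome scans run sense-only
(the guide binds mRNA).  Coordinates are 0-based half-open on the forward
strand, BED-style.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .guides import GuideStrand, normalize_dna, revcomp_dna

__all__ = [
    "TargetSite",
    "OffTargetHit",
    "OffTargetLocus",
    "OffTargetSummary",
    "ScanResult",
    "make_target_site",
    "scan",
    "naive_scan",
    "merge_loci",
    "annotate_loci",
    "summarize",
    "rank_guides",
    "RegionAnnotation",
    "read_fasta",
    "write_hits_bed",
    "write_locus_table",
    "write_summary_table",
]

MAX_BUDGET = 3
REGION_TYPES = ("CDS", "5UTR", "3UTR", "intron", "intergenic")


@dataclass(frozen=True)
class TargetSite:
    """The DNA sequence a fully complementary target segment would carry."""

    guide_name: str
    site_sequence: str

    def __len__(self) -> int:
        return len(self.site_sequence)


def make_target_site(guide: GuideStrand) -> TargetSite:
    """Reverse complement of the guide, in DNA space (U→T)."""
    return TargetSite(guide.name, revcomp_dna(guide.dna))


@dataclass(frozen=True)
class OffTargetHit:
    """One matched window, in forward-strand 0-based half-open coordinates.

    ``mismatch_positions`` are 1-based positions on the *guide* (from its
    5' end), so they line up with design-mismatch nomenclature regardless
    of strand.
    """

    sequence_id: str
    strand: str
    start: int
    end: int
    mismatch_count: int
    mismatch_positions: tuple[int, ...]
    site_observed: str


@dataclass(frozen=True)
class OffTargetLocus:
    """A maximal run of transitively overlapping windows on one strand."""

    sequence_id: str
    strand: str
    start: int
    end: int
    n_windows: int
    min_mismatch_count: int
    region_labels: frozenset[str] = frozenset()


@dataclass(frozen=True)
class OffTargetSummary:
    guide_name: str
    level: str  # window | locus | transcript
    counts_by_exact_mismatch: Mapping[int, int]

    def count_tuple(self, budget: int = MAX_BUDGET) -> tuple[int, ...]:
        return tuple(
            self.counts_by_exact_mismatch.get(k, 0) for k in range(budget + 1)
        )


@dataclass
class ScanResult:
    site: TargetSite
    budget: int
    strands: str
    hits: list[OffTargetHit]
    n_windows_skipped: int

    def __iter__(self):
        return iter(self.hits)

    def __len__(self) -> int:
        return len(self.hits)


def _as_pairs(sequences) -> list[tuple[str, str]]:
    pairs = []
    for item in sequences:
        if isinstance(item, tuple):
            name, seq = item
        else:  # SeqRecord-like
            name, seq = item.id, str(item.seq)
        pairs.append((name, normalize_dna(seq, allow_n=True)))
    if not pairs:
        raise ValueError("empty sequence database")
    return pairs


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return _as_pairs(SeqIO.parse(str(path), "fasta"))


def _skipped_window_count(seq: str, L: int) -> int:
    """How many length-L windows contain at least one N."""
    if "N" not in seq:
        return 0
    n_windows = len(seq) - L + 1
    if n_windows <= 0:
        return 0
    covered = 0
    prev_end = -1
    pos = seq.find("N")
    while pos != -1:
        lo = max(0, pos - L + 1)
        hi = min(pos, n_windows - 1)
        lo = max(lo, prev_end + 1)
        if hi >= lo:
            covered += hi - lo + 1
            prev_end = hi
        pos = seq.find("N", pos + 1)
    return covered


def _mismatch_indices(window: str, pattern: str, budget: int) -> Optional[list[int]]:
    """Indices where window differs from pattern, or None if over budget."""
    mism = []
    for i, (a, b) in enumerate(zip(window, pattern)):
        if a != b:
            mism.append(i)
            if len(mism) > budget:
                return None
    return mism


def _segments(pattern: str, k: int) -> list[tuple[int, str]]:
    """Split a pattern into k+1 near-equal segments (pigeonhole seeds)."""
    L = len(pattern)
    n = k + 1
    bounds = [round(i * L / n) for i in range(n + 1)]
    return [(bounds[i], pattern[bounds[i] : bounds[i + 1]]) for i in range(n)]


def _hit_from_window(
    seq_id: str, seq: str, start: int, L: int, pattern: str, strand: str, budget: int
) -> Optional[OffTargetHit]:
    window = seq[start : start + L]
    if "N" in window:
        return None
    mism = _mismatch_indices(window, pattern, budget)
    if mism is None:
        return None
    if strand == "+":
        # pattern == site; site index i faces guide position L - i
        guide_pos = tuple(sorted(L - i for i in mism))
        observed = window
    else:
        # pattern == revcomp(site) == guide as DNA; index j is guide position j+1
        guide_pos = tuple(j + 1 for j in mism)
        observed = revcomp_dna(window)
    return OffTargetHit(
        seq_id, strand, start, start + L, len(mism), guide_pos, observed
    )


def _scan_one_seeded(
    seq_id: str, seq: str, site: TargetSite, budget: int, strands: str
) -> list[OffTargetHit]:
    L = len(site)
    n_windows = len(seq) - L + 1
    hits: list[OffTargetHit] = []
    if n_windows <= 0:
        return hits
    patterns = [("+", site.site_sequence)]
    if strands == "both":
        patterns.append(("-", revcomp_dna(site.site_sequence)))
    for strand, pattern in patterns:
        candidates: set[int] = set()
        for seg_off, seg in _segments(pattern, budget):
            pos = seq.find(seg)
            while pos != -1:
                start = pos - seg_off
                if 0 <= start <= n_windows - 1:
                    candidates.add(start)
                pos = seq.find(seg, pos + 1)
        for start in sorted(candidates):
            hit = _hit_from_window(seq_id, seq, start, L, pattern, strand, budget)
            if hit is not None:
                hits.append(hit)
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan(
    sequences,
    site: TargetSite,
    budget: int,
    strands: str = "both",
) -> ScanResult:
    """Find every window within ``budget`` Hamming mismatches of ``site``.

    ``strands='both'`` also reports windows whose reverse complement
    matches the site (minus-strand binding), in forward coordinates.
    Windows containing N are skipped and counted in
    ``ScanResult.n_windows_skipped``.
    """
    if not 0 <= budget <= MAX_BUDGET:
        raise ValueError(f"budget must be in [0, {MAX_BUDGET}]")
    if strands not in ("both", "sense"):
        raise ValueError("strands must be 'both' or 'sense'")
    pairs = _as_pairs(sequences)
    L = len(site)
    hits: list[OffTargetHit] = []
    skipped = 0
    for seq_id, seq in pairs:
        skipped += _skipped_window_count(seq, L)
        hits.extend(_scan_one_seeded(seq_id, seq, site, budget, strands))
    return ScanResult(site, budget, strands, hits, skipped)


def naive_scan(
    sequences,
    site: TargetSite,
    budget: int,
    strands: str = "both",
) -> ScanResult:
    """Plain sliding-window Hamming scan; the reference the seeded scan must match."""
    if not 0 <= budget <= MAX_BUDGET:
        raise ValueError(f"budget must be in [0, {MAX_BUDGET}]")
    if strands not in ("both", "sense"):
        raise ValueError("strands must be 'both' or 'sense'")
    pairs = _as_pairs(sequences)
    L = len(site)
    patterns = [("+", site.site_sequence)]
    if strands == "both":
        patterns.append(("-", revcomp_dna(site.site_sequence)))
    hits: list[OffTargetHit] = []
    skipped = 0
    for seq_id, seq in pairs:
        skipped += _skipped_window_count(seq, L)
        for start in range(len(seq) - L + 1):
            per_start = []
            for strand, pattern in patterns:
                hit = _hit_from_window(seq_id, seq, start, L, pattern, strand, budget)
                if hit is not None:
                    per_start.append(hit)
            per_start.sort(key=lambda h: h.strand)
            hits.extend(per_start)
    return ScanResult(site, budget, strands, hits, skipped)


def merge_loci(hits: Iterable[OffTargetHit]) -> list[OffTargetLocus]:
    """Transitively merge windows overlapping by >=1 bp on one strand."""
    by_key: dict[tuple[str, str], list[OffTargetHit]] = {}
    for h in hits:
        by_key.setdefault((h.sequence_id, h.strand), []).append(h)
    loci: list[OffTargetLocus] = []
    for (seq_id, strand), group in sorted(by_key.items()):
        group.sort(key=lambda h: h.start)
        cur_start, cur_end = group[0].start, group[0].end
        members = [group[0]]
        for h in group[1:]:
            if h.start < cur_end:  # >=1 bp overlap
                cur_end = max(cur_end, h.end)
                members.append(h)
            else:
                loci.append(
                    OffTargetLocus(
                        seq_id,
                        strand,
                        cur_start,
                        cur_end,
                        len(members),
                        min(m.mismatch_count for m in members),
                    )
                )
                cur_start, cur_end, members = h.start, h.end, [h]
        loci.append(
            OffTargetLocus(
                seq_id,
                strand,
                cur_start,
                cur_end,
                len(members),
                min(m.mismatch_count for m in members),
            )
        )
    loci.sort(key=lambda l: (l.sequence_id, l.strand, l.start))
    return loci


class RegionAnnotation:
    """CDS/UTR/intron intervals per sequence, for locus labelling.

    Built from BED6+ (the name column holds the region label) or from
    GFF3 (feature types CDS, five_prime_UTR, three_prime_UTR, intron).
    """

    _GFF_TYPES = {
        "CDS": "CDS",
        "five_prime_UTR": "5UTR",
        "three_prime_UTR": "3UTR",
        "intron": "intron",
    }

    def __init__(self, intervals: Iterable[tuple[str, int, int, str]]):
        self._trees: dict[str, IntervalTree] = {}
        for seq_id, start, end, label in intervals:
            if label not in REGION_TYPES or label == "intergenic":
                raise ValueError(f"unknown region label {label!r}")
            if end <= start:
                continue
            self._trees.setdefault(seq_id, IntervalTree()).addi(start, end, label)

    @classmethod
    def from_bed(cls, path: str | Path) -> "RegionAnnotation":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "name"],
        )
        return cls(df.itertuples(index=False, name=None))

    @classmethod
    def from_gff3(cls, path: str | Path) -> "RegionAnnotation":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=[
                "seqid", "source", "type", "start", "end",
                "score", "strand", "phase", "attributes",
            ],
        )
        rows = []
        for rec in df.itertuples(index=False):
            label = cls._GFF_TYPES.get(rec.type)
            if label is not None:
                # GFF3 is 1-based inclusive
                rows.append((rec.seqid, int(rec.start) - 1, int(rec.end), label))
        return cls(rows)

    @property
    def sequence_ids(self) -> set[str]:
        return set(self._trees)

    def labels_overlapping(self, seq_id: str, start: int, end: int) -> frozenset[str]:
        tree = self._trees.get(seq_id)
        if tree is None:
            return frozenset()
        return frozenset(iv.data for iv in tree.overlap(start, end))


def annotate_loci(
    loci: Sequence[OffTargetLocus], annotation: RegionAnnotation
) -> list[OffTargetLocus]:
    """Label each locus with every region type it overlaps by >=1 bp.

    Loci on sequences the annotation does not cover are left unlabelled
    with a warning; loci overlapping no annotated interval are labelled
    intergenic.
    """
    out = []
    warned: set[str] = set()
    for locus in loci:
        if locus.sequence_id not in annotation.sequence_ids:
            if locus.sequence_id not in warned:
                warnings.warn(
                    f"no annotation for sequence {locus.sequence_id!r}; "
                    "locus left unlabelled"
                )
                warned.add(locus.sequence_id)
            out.append(locus)
            continue
        labels = annotation.labels_overlapping(
            locus.sequence_id, locus.start, locus.end
        )
        if not labels:
            labels = frozenset({"intergenic"})
        out.append(replace(locus, region_labels=labels))
    return out


def summarize(
    guides: Sequence[GuideStrand],
    database,
    budget: int,
    level: str = "transcript",
    strands: Optional[str] = None,
) -> list[OffTargetSummary]:
    """Per-guide exact-mismatch count summaries over a sequence database.

    ``level='window'`` bins every hit window by its exact mismatch count;
    ``'locus'`` bins merged loci by their minimum; ``'transcript'`` bins
    each sequence record once by the minimum over its hits (a transcript
    with best distance 1 contributes to k=1 only).  Strand mode defaults
    to sense-only at transcript level (guides bind mRNA) and both-strand
    otherwise (genome scans).
    """
    if level not in ("window", "locus", "transcript"):
        raise ValueError(f"unknown level {level!r}")
    if strands is None:
        strands = "sense" if level == "transcript" else "both"
    pairs = _as_pairs(database)
    summaries = []
    for guide in guides:
        site = make_target_site(guide)
        result = scan(pairs, site, budget, strands)
        counts: dict[int, int] = {k: 0 for k in range(budget + 1)}
        if level == "window":
            for h in result.hits:
                counts[h.mismatch_count] += 1
        elif level == "locus":
            for locus in merge_loci(result.hits):
                counts[locus.min_mismatch_count] += 1
        else:
            best: dict[str, int] = {}
            for h in result.hits:
                prev = best.get(h.sequence_id)
                if prev is None or h.mismatch_count < prev:
                    best[h.sequence_id] = h.mismatch_count
            for k in best.values():
                counts[k] += 1
        summaries.append(OffTargetSummary(guide.name, level, counts))
    return summaries


def rank_guides(summaries: Sequence[OffTargetSummary]) -> list[OffTargetSummary]:
    """Ascending lexicographic order on (k=0, k=1, k=2, k=3) counts, then name.

    The first guide is the design with the lightest off-target load.
    """
    levels = {s.level for s in summaries}
    if len(levels) > 1:
        raise ValueError(f"cannot rank summaries at mixed levels {sorted(levels)}")
    return sorted(summaries, key=lambda s: (s.count_tuple(), s.guide_name))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_hits_bed(
    result: ScanResult, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    """BED6: name = guide:mismatch_count, score = mismatch_count."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for h in result.hits:
            fh.write(
                f"{h.sequence_id}\t{h.start}\t{h.end}\t"
                f"{result.site.guide_name}:{h.mismatch_count}\t"
                f"{h.mismatch_count}\t{h.strand}\n"
            )


def write_locus_table(
    loci: Sequence[OffTargetLocus], path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            [
                "sequence_id", "strand", "start", "end",
                "n_windows", "min_mismatch_count", "region_labels",
            ]
        )
        for l in loci:
            writer.writerow(
                [
                    l.sequence_id, l.strand, l.start, l.end,
                    l.n_windows, l.min_mismatch_count,
                    ",".join(sorted(l.region_labels)),
                ]
            )


def write_summary_table(
    summaries: Sequence[OffTargetSummary],
    path: str | Path,
    budget: int = MAX_BUDGET,
    header_lines: Sequence[str] = (),
) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["guide", "level"] + [f"mm{k}" for k in range(budget + 1)])
        for s in summaries:
            writer.writerow([s.guide_name, s.level, *s.count_tuple(budget)])
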