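"""Classification of small-RNA reads against an amiRNA hairpin.

Drosha/Dicer processing of a pri-miRNA scaffold is heterogeneous: the
excised products vary in their 5' start site (which, for a repeat-directed
guide, shifts every target-register mismatch position by the same amount)
and in 3' length.  Given adapter-trimmed reads and an annotated hairpin,
this module assigns each read to the guide or passenger arm by its 5'
start, groups reads into 5'-start-site variants, and reports strand bias,
the variant table, the templated-length distribution, and the abundance of
the amiRNA relative to the top-N endogenous miRNAs.

Read-to-hairpin matching is exact (deep coverage of a short hairpin makes
error-tolerant mapping unnecessary), with up to ``max_nontemplated_3p``
unmatched 3' nucleotides tolerated.  Because the CAG-rich insert can make
a read match several hairpin offsets, ties are broken by the leftmost
occurrence within an annotated arm, then leftmost overall; the ambiguity
tally is reported.  Counts, not normalized units, are the internal
currency.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .guides import (
    GuideStrand,
    RepeatTarget,
    best_frame_profile,
    normalize_dna,
)

__all__ = [
    "HairpinAnnotation",
    "ReadAssignment",
    "ReadGroup",
    "ProcessingReport",
    "assign_read",
    "assign_reads",
    "group_variants",
    "strand_bias",
    "length_distribution",
    "top_n_fraction",
    "annotate_registers",
    "profile_reads",
    "read_small_rna",
    "read_count_table",
    "EmptyLibraryError",
]

GUIDE = "guide"
PASSENGER = "passenger"


class EmptyLibraryError(ValueError):
    """No reads could be assigned to the hairpin."""


@dataclass(frozen=True)
class HairpinAnnotation:
    """An amiRNA hairpin with annotated arm intervals (0-based half-open)."""

    name: str
    sequence: str
    guide_arm: tuple[int, int]
    passenger_arm: tuple[int, int]
    start_slack: int = 5
    max_nontemplated_3p: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_dna(self.sequence))
        for label, (s, e) in (("guide", self.guide_arm), ("passenger", self.passenger_arm)):
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError(f"{label} arm {s, e} outside hairpin")
        g, p = self.guide_arm, self.passenger_arm
        if max(g[0], p[0]) < min(g[1], p[1]):
            raise ValueError("guide and passenger arms overlap")

    @property
    def guide_arm_label(self) -> str:
        """'5p' if the guide arm precedes the passenger arm, else '3p'."""
        return "5p" if self.guide_arm[0] < self.passenger_arm[0] else "3p"

    def arm_of(self, start_offset: int) -> Optional[str]:
        """Arm whose slack-expanded interval contains a 5' start, or None."""
        containing = []
        for arm, (s, e) in ((GUIDE, self.guide_arm), (PASSENGER, self.passenger_arm)):
            if s - self.start_slack <= start_offset < e + self.start_slack:
                containing.append((abs(start_offset - s), arm == PASSENGER, arm))
        if not containing:
            return None
        return min(containing)[2]

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "name": self.name,
            "sequence": self.sequence,
            "guide_arm": list(self.guide_arm),
            "passenger_arm": list(self.passenger_arm),
            "start_slack": self.start_slack,
            "max_nontemplated_3p": self.max_nontemplated_3p,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HairpinAnnotation":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            name=data["name"],
            sequence=data["sequence"],
            guide_arm=tuple(data["guide_arm"]),
            passenger_arm=tuple(data["passenger_arm"]),
            start_slack=int(data.get("start_slack", 5)),
            max_nontemplated_3p=int(data.get("max_nontemplated_3p", 2)),
        )


@dataclass(frozen=True)
class ReadAssignment:
    sequence: str
    arm: Optional[str]  # guide | passenger | None (unassigned)
    start_offset: Optional[int]
    templated_length: Optional[int]
    ambiguous: bool = False
    count: int = 1

    @property
    def assigned(self) -> bool:
        return self.arm is not None


def _occurrences(haystack: str, needle: str) -> list[int]:
    occs = []
    pos = haystack.find(needle)
    while pos != -1:
        occs.append(pos)
        pos = haystack.find(needle, pos + 1)
    return occs


def assign_read(
    read: str,
    hairpin: HairpinAnnotation,
    min_len: int = 15,
    max_len: int = 30,
    count: int = 1,
) -> ReadAssignment:
    """Locate a read's templated 5' portion on the hairpin and assign an arm.

    The longest read prefix occurring exactly in the hairpin wins, with up
    to ``hairpin.max_nontemplated_3p`` trailing non-templated nucleotides
    tolerated.  The match's 5' position is the start offset; the arm is
    whichever annotated arm's slack-expanded interval contains it.  Reads
    that cannot be placed are returned as unassigned, never dropped.
    """
    seq = normalize_dna(read, allow_n=True)
    if not min_len <= len(seq) <= max_len:
        return ReadAssignment(seq, None, None, None, count=count)
    for tail in range(hairpin.max_nontemplated_3p + 1):
        core = seq[: len(seq) - tail]
        if len(core) < min_len:
            break
        occs = _occurrences(hairpin.sequence, core)
        if not occs:
            continue
        in_arm = [o for o in occs if hairpin.arm_of(o) is not None]
        start = in_arm[0] if in_arm else occs[0]
        arm = hairpin.arm_of(start)
        if arm is None:
            return ReadAssignment(
                seq, None, start, len(core), ambiguous=len(occs) > 1, count=count
            )
        return ReadAssignment(
            seq, arm, start, len(core), ambiguous=len(occs) > 1, count=count
        )
    return ReadAssignment(seq, None, None, None, count=count)


def assign_reads(
    reads: Iterable[str] | Mapping[str, int],
    hairpin: HairpinAnnotation,
    min_len: int = 15,
    max_len: int = 30,
) -> list[ReadAssignment]:
    """Assign a read collection, collapsing duplicate sequences first."""
    if isinstance(reads, Mapping):
        counts = reads
    else:
        counts = Counter(reads)
    return [
        assign_read(seq, hairpin, min_len=min_len, max_len=max_len, count=n)
        for seq, n in sorted(counts.items())
    ]


@dataclass(frozen=True)
class ReadGroup:
    """All reads sharing one (arm, 5' start site); the isomiR unit of report."""

    arm: str
    start_offset: Optional[int]  # None for the pooled sub-threshold group
    representative_sequence: str
    read_count: int
    fraction_of_assigned: float  # percent
    lengths: Mapping[int, int]  # templated length -> read count
    register_mismatches: Optional[tuple[int, ...]] = None


def _representative(core_counter: Counter) -> str:
    return min(core_counter.items(), key=lambda kv: (-kv[1], len(kv[0]), kv[0]))[0]


def group_variants(
    assignments: Sequence[ReadAssignment], min_fraction: float = 0.5
) -> list[ReadGroup]:
    """Group assigned reads by (arm, 5' start); pool rare starts per arm.

    Fractions are percentages of assigned reads.  Groups below
    ``min_fraction`` percent are pooled into one "other" group per arm
    (``start_offset=None``).  Raises :class:`EmptyLibraryError` when
    nothing was assigned.
    """
    assigned = [a for a in assignments if a.assigned]
    total = sum(a.count for a in assigned)
    if total == 0:
        raise EmptyLibraryError("no reads assigned to the hairpin")
    buckets: dict[tuple[str, int], dict] = {}
    for a in assigned:
        key = (a.arm, a.start_offset)
        b = buckets.setdefault(key, {"count": 0, "cores": Counter(), "lengths": Counter()})
        b["count"] += a.count
        core = a.sequence[: a.templated_length]
        b["cores"][core] += a.count
        b["lengths"][a.templated_length] += a.count
    groups: list[ReadGroup] = []
    pooled: dict[str, dict] = {}
    for (arm, start), b in buckets.items():
        fraction = 100.0 * b["count"] / total
        if fraction < min_fraction:
            p = pooled.setdefault(arm, {"count": 0, "cores": Counter(), "lengths": Counter()})
            p["count"] += b["count"]
            p["cores"] += b["cores"]
            p["lengths"] += b["lengths"]
            continue
        groups.append(
            ReadGroup(
                arm=arm,
                start_offset=start,
                representative_sequence=_representative(b["cores"]),
                read_count=b["count"],
                fraction_of_assigned=fraction,
                lengths=dict(sorted(b["lengths"].items())),
            )
        )
    for arm, p in pooled.items():
        groups.append(
            ReadGroup(
                arm=arm,
                start_offset=None,
                representative_sequence=_representative(p["cores"]),
                read_count=p["count"],
                fraction_of_assigned=100.0 * p["count"] / total,
                lengths=dict(sorted(p["lengths"].items())),
            )
        )
    groups.sort(
        key=lambda g: (
            g.arm != GUIDE,
            g.start_offset is None,
            g.start_offset if g.start_offset is not None else 0,
        )
    )
    return groups


def strand_bias(groups: Sequence[ReadGroup]) -> tuple[float, float]:
    """(guide %, passenger %) over assigned reads; the pair sums to 100."""
    guide = sum(g.read_count for g in groups if g.arm == GUIDE)
    passenger = sum(g.read_count for g in groups if g.arm == PASSENGER)
    total = guide + passenger
    if total == 0:
        raise EmptyLibraryError("no assigned reads")
    return 100.0 * guide / total, 100.0 * passenger / total


def length_distribution(groups: Sequence[ReadGroup]) -> dict[int, int]:
    """Templated-length histogram over all assigned reads."""
    hist: Counter = Counter()
    for g in groups:
        hist.update(g.lengths)
    return dict(sorted(hist.items()))


def top_n_fraction(
    amirna_total: int, endogenous: Mapping[str, int], n: int = 50
) -> float:
    """amiRNA reads as a percent of the summed top-N endogenous miRNA counts.

    With fewer than ``n`` species the sum runs over all of them, with a
    warning.  All-zero endogenous counts are an error.
    """
    if not endogenous:
        raise ValueError("empty endogenous miRNA table")
    counts = sorted(endogenous.values(), reverse=True)
    if len(counts) < n:
        warnings.warn(
            f"only {len(counts)} endogenous miRNAs available; using all of them"
        )
    denom = sum(counts[:n])
    if denom == 0:
        raise ValueError("endogenous miRNA counts are all zero")
    return 100.0 * amirna_total / denom


def annotate_registers(
    groups: Sequence[ReadGroup], target: RepeatTarget
) -> list[ReadGroup]:
    """Attach target-register mismatch positions to guide-arm groups.

    Each guide variant's representative sequence is aligned to the repeat
    in its best register, so a +1 5'-shifted variant reports every design
    mismatch shifted by +1 (e.g. {8,13} → {9,14}).
    """
    out = []
    for g in groups:
        if g.arm != GUIDE:
            out.append(g)
            continue
        rep = g.representative_sequence
        guide = GuideStrand(f"{g.arm}@{g.start_offset}", rep)
        profile = best_frame_profile(guide, target)
        out.append(replace(g, register_mismatches=profile.positions))
    return out


@dataclass
class ProcessingReport:
    """Full hairpin-processing summary for one small-RNA library."""

    hairpin_name: str
    n_reads_total: int
    n_assigned: int
    n_unassigned: int
    n_ambiguous: int
    strand_bias_guide_percent: float
    strand_bias_passenger_percent: float
    variant_table: list[ReadGroup]
    length_histogram: dict[int, int]
    top_n_fraction_percent: Optional[float] = None
    total_pool_fraction_percent: Optional[float] = None
    top_n_used: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "hairpin_name": self.hairpin_name,
            "n_reads_total": self.n_reads_total,
            "n_assigned": self.n_assigned,
            "n_unassigned": self.n_unassigned,
            "n_ambiguous": self.n_ambiguous,
            "strand_bias_guide_percent": round(self.strand_bias_guide_percent, 6),
            "strand_bias_passenger_percent": round(self.strand_bias_passenger_percent, 6),
            "variant_table": [
                {
                    "arm": g.arm,
                    "start_offset": g.start_offset,
                    "representative_sequence": g.representative_sequence,
                    "read_count": g.read_count,
                    "fraction_of_assigned": round(g.fraction_of_assigned, 6),
                    "lengths": {str(k): v for k, v in g.lengths.items()},
                    "register_mismatches": list(g.register_mismatches)
                    if g.register_mismatches is not None
                    else None,
                }
                for g in self.variant_table
            ],
            "length_histogram": {str(k): v for k, v in self.length_histogram.items()},
            "top_n_fraction_percent": None
            if self.top_n_fraction_percent is None
            else round(self.top_n_fraction_percent, 6),
            "total_pool_fraction_percent": None
            if self.total_pool_fraction_percent is None
            else round(self.total_pool_fraction_percent, 6),
            "top_n_used": self.top_n_used,
        }

    def to_json(self, path: Optional[str | Path] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def write_variant_table(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(
                "arm\tstart_offset\trepresentative_sequence\tread_count\t"
                "fraction_of_assigned\tregister_mismatches\n"
            )
            for g in self.variant_table:
                mism = (
                    ",".join(map(str, g.register_mismatches))
                    if g.register_mismatches is not None
                    else ""
                )
                start = "other" if g.start_offset is None else g.start_offset
                fh.write(
                    f"{g.arm}\t{start}\t{g.representative_sequence}\t"
                    f"{g.read_count}\t{g.fraction_of_assigned:.4f}\t{mism}\n"
                )


def profile_reads(
    reads: Iterable[str] | Mapping[str, int],
    hairpin: HairpinAnnotation,
    repeat_target: Optional[RepeatTarget] = None,
    min_fraction: float = 0.5,
    endogenous: Optional[Mapping[str, int]] = None,
    top_n: int = 50,
    min_len: int = 15,
    max_len: int = 30,
) -> ProcessingReport:
    """Run the whole read-classification pipeline and build the report."""
    assignments = assign_reads(reads, hairpin, min_len=min_len, max_len=max_len)
    n_total = sum(a.count for a in assignments)
    n_assigned = sum(a.count for a in assignments if a.assigned)
    n_ambiguous = sum(a.count for a in assignments if a.assigned and a.ambiguous)
    groups = group_variants(assignments, min_fraction=min_fraction)
    if repeat_target is not None:
        groups = annotate_registers(groups, repeat_target)
    guide_pct, passenger_pct = strand_bias(groups)
    report = ProcessingReport(
        hairpin_name=hairpin.name,
        n_reads_total=n_total,
        n_assigned=n_assigned,
        n_unassigned=n_total - n_assigned,
        n_ambiguous=n_ambiguous,
        strand_bias_guide_percent=guide_pct,
        strand_bias_passenger_percent=passenger_pct,
        variant_table=groups,
        length_histogram=length_distribution(groups),
    )
    if endogenous is not None:
        report.top_n_used = top_n
        report.top_n_fraction_percent = top_n_fraction(n_assigned, endogenous, top_n)
        total = sum(endogenous.values())
        report.total_pool_fraction_percent = (
            100.0 * n_assigned / total if total else None
        )
    return report


# ---------------------------------------------------------------------------
# Input formats
# ---------------------------------------------------------------------------


def read_small_rna(path: str | Path) -> Counter:
    """Read a small-RNA library into sequence counts.

    FASTQ (.fastq/.fq), FASTA (.fasta/.fa), or a collapsed two-column
    "sequence<TAB>count" table are accepted.
    """
    from Bio import SeqIO

    path = Path(path)
    suffix = path.suffix.lower()
    counts: Counter = Counter()
    if suffix in (".fastq", ".fq"):
        for rec in SeqIO.parse(str(path), "fastq"):
            counts[str(rec.seq).upper()] += 1
    elif suffix in (".fasta", ".fa"):
        for rec in SeqIO.parse(str(path), "fasta"):
            counts[str(rec.seq).upper()] += 1
    else:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                seq, n = line.split("\t")
                counts[seq.upper()] += int(n)
    return counts


def read_count_table(path: str | Path) -> dict[str, int]:
    """Two-column "name<TAB>count" table (endogenous mature miRNA counts)."""
    counts: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("mirna\t"):
                continue
            name, n = line.split("\t")
            counts[name] = int(n)
    return counts
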