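"""Guide strands and repeat targets for CAG-directed allele-selective silencing.

A CAG-repeat-targeting guide strand is a 19–23 nt CUG-repeat-like RNA that
base-pairs, in RISC, with the expanded CAG tract of a polyglutamine-disease
transcript.  Allele preference is engineered by interrupting the pure CUG
sequence: the parent guide ``A2`` (5'-CUGCUGCAGCUGCUGCUGC-3') carries an
A at position 8 that forms an A:A mismatch with every CAG unit it faces,
switching the silencing mode from cleavage to translation inhibition.
Further single substitutions (9A, 10A, 11A, 13G, 13A, ...) add a second
mismatch that thins out near-complementary off-target sites elsewhere in
the genome.

This module models guides, repeat targets and their pairing geometry:

* :class:`GuideStrand` — a named guide with its substitution history
  relative to the A2 parent;
* :class:`RepeatTarget` — a trinucleotide repeat tract (optionally with
  interrupted units);
* :func:`mismatch_profile` — which guide positions fail strict
  Watson–Crick pairing against the tract in a given binding register;
* :func:`substitution_scan` — the exhaustive one-substitution design scan;
* :func:`inframe_register_count` — how many in-phase binding registers a
  tract of a given length offers (the basis of cooperative RISC binding
  on expanded alleles).

Conventions: guide positions are 1-based from the 5' end; pairing is
strict Watson–Crick (A–U, G–C; G:U wobble counts as a mismatch, matching
DNA-space alignment of short sites); guides are held as RNA, genomic
sites as DNA, and U/T are interchangeable on input.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GuideStrand",
    "RepeatTarget",
    "MismatchProfile",
    "Substitution",
    "A2",
    "design_variants",
    "apply_substitution",
    "mismatch_profile",
    "best_frame_profile",
    "substitution_scan",
    "inframe_register_count",
    "normalize_rna",
    "normalize_dna",
    "revcomp_rna",
    "revcomp_dna",
    "read_guides",
    "write_guides",
    "write_substitution_scan",
]

RNA_BASES = "ACGU"
_RNA_COMP = str.maketrans("ACGU", "UGCA")
_DNA_COMP = str.maketrans("ACGTN", "TGCAN")

#: length bounds for canonical designs and released processing products
MIN_GUIDE_LEN = 19
MAX_GUIDE_LEN = 23


def normalize_rna(seq: str) -> str:
    """Uppercase, T→U; reject anything outside {A,C,G,U}."""
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - set(RNA_BASES)
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    return s


def normalize_dna(seq: str, allow_n: bool = False) -> str:
    """Uppercase, U→T; reject anything outside {A,C,G,T} (plus N if allowed)."""
    s = seq.strip().upper().replace("U", "T")
    allowed = set("ACGTN" if allow_n else "ACGT")
    bad = set(s) - allowed
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return s


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


@dataclass(frozen=True)
class Substitution:
    """A single designed base change, 1-based from the guide 5' end."""

    position: int
    from_base: str
    to_base: str

    def __str__(self) -> str:  # e.g. "13C>A"
        return f"{self.position}{self.from_base}>{self.to_base}"


@dataclass(frozen=True)
class GuideStrand:
    """A guide-strand design with its substitution record relative to A2.

    ``substitutions`` lists the designed changes that produced ``sequence``
    from the A2 parent (empty for A2 itself).  Replaying them onto the
    parent must reproduce ``sequence`` exactly; :func:`apply_substitution`
    maintains this invariant.
    """

    name: str
    sequence: str
    substitutions: tuple[Substitution, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        n = len(self.sequence)
        if not MIN_GUIDE_LEN <= n <= MAX_GUIDE_LEN:
            raise ValueError(
                f"guide {self.name!r} has length {n}; expected "
                f"{MIN_GUIDE_LEN}-{MAX_GUIDE_LEN} nt"
            )
        for sub in self.substitutions:
            if not 1 <= sub.position <= n:
                raise ValueError(f"substitution {sub} outside guide of length {n}")
            if self.sequence[sub.position - 1] != sub.to_base:
                raise ValueError(
                    f"substitution record {sub} inconsistent with sequence "
                    f"base {self.sequence[sub.position - 1]!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def dna(self) -> str:
        """The guide sequence in DNA alphabet (as cloned into a hairpin)."""
        return self.sequence.replace("U", "T")


#: The parent guide: pure CUG repeat interrupted by A at position 8.
A2 = GuideStrand("A2", "CUGCUGCAGCUGCUGCUGC")


def apply_substitution(
    parent: GuideStrand, position: int, new_base: str, name: Optional[str] = None
) -> GuideStrand:
    """Return a new guide differing from ``parent`` by one base.

    Raises ``ValueError`` for an out-of-range position or when ``new_base``
    equals the current base (a no-op substitution is a design error, not a
    variant).
    """
    new_base = normalize_rna(new_base)
    if len(new_base) != 1:
        raise ValueError("new_base must be a single RNA base")
    if not 1 <= position <= len(parent):
        raise ValueError(
            f"position {position} outside guide of length {len(parent)}"
        )
    old = parent.sequence[position - 1]
    if new_base == old:
        raise ValueError(
            f"no-op substitution: {parent.name} already has {old} at "
            f"position {position}"
        )
    seq = parent.sequence[: position - 1] + new_base + parent.sequence[position:]
    sub = Substitution(position, old, new_base)
    if name is None:
        name = f"{parent.name}_{position}{new_base}"
    return GuideStrand(name, seq, parent.substitutions + (sub,))


def design_variants(parent: GuideStrand = A2) -> dict[str, GuideStrand]:
    """The released second-mismatch designs derived from A2.

    9A (G>A), 10A (C>A), 11A (U>A), 13G (C>G), 13A (C>A), and the
    serendipitous triple-interruption variant 13G16U (13 C>G then 16 C>U).
    """
    variants = {
        "9A": apply_substitution(parent, 9, "A", name="9A"),
        "10A": apply_substitution(parent, 10, "A", name="10A"),
        "11A": apply_substitution(parent, 11, "A", name="11A"),
        "13G": apply_substitution(parent, 13, "G", name="13G"),
        "13A": apply_substitution(parent, 13, "A", name="13A"),
    }
    variants["13G16U"] = apply_substitution(variants["13G"], 16, "U", name="13G16U")
    return variants


@dataclass(frozen=True)
class RepeatTarget:
    """A trinucleotide repeat tract in transcript sense (5'→3').

    ``interruptions`` replaces whole units: ``(unit_index, replacement)``
    with 0-based ``unit_index`` — e.g. the CAA interruptions of some
    repeat alleles.
    """

    unit: str = "CAG"
    n_units: int = 28
    interruptions: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit", normalize_rna(self.unit))
        if len(self.unit) != 3:
            raise ValueError("repeat unit must be a trinucleotide")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        for idx, repl in self.interruptions:
            if not 0 <= idx < self.n_units:
                raise ValueError(f"interruption index {idx} out of range")
            if len(normalize_rna(repl)) != 3:
                raise ValueError("interruption replacement must be a trinucleotide")

    def transcript_sequence(self) -> str:
        units = [self.unit] * self.n_units
        for idx, repl in self.interruptions:
            units[idx] = normalize_rna(repl)
        return "".join(units)

    def guide_reference(self) -> str:
        """Reverse complement of the tract: what a bound guide reads 5'→3'.

        For a pure CAG tract this is the (CUG)n repeat; phase 0 of the
        reference starts at C.
        """
        return revcomp_rna(self.transcript_sequence())

    def __len__(self) -> int:
        return 3 * self.n_units


@dataclass(frozen=True)
class MismatchProfile:
    """Guide positions failing Watson–Crick pairing in one binding register."""

    guide_name: str
    frame_offset: int
    positions: tuple[int, ...]

    @property
    def count(self) -> int:
        return len(self.positions)


def mismatch_profile(
    guide: GuideStrand, target: RepeatTarget, frame_offset: int = 0
) -> MismatchProfile:
    """Mismatch positions of ``guide`` bound to ``target`` at a given phase.

    The guide is compared base-by-base against the phase-shifted repeat
    complement (:meth:`RepeatTarget.guide_reference`): position ``p`` is a
    mismatch iff ``guide[p] != reference[frame_offset + p]``.  Strict
    Watson–Crick pairing only — G:U wobble is a mismatch.

    Raises ``ValueError`` when the tract is too short to offer the
    requested register (zero available registers).
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    ref = target.guide_reference()
    L = len(guide)
    if frame_offset + L > len(ref):
        raise ValueError(
            f"target of {len(ref)} nt too short for a {L}-nt guide at "
            f"frame {frame_offset}"
        )
    positions = tuple(
        p
        for p in range(1, L + 1)
        if guide.sequence[p - 1] != ref[frame_offset + p - 1]
    )
    return MismatchProfile(guide.name, frame_offset, positions)


def best_frame_profile(guide: GuideStrand, target: RepeatTarget) -> MismatchProfile:
    """The register minimizing the mismatch count; ties go to the lowest frame."""
    profiles = []
    for frame in (0, 1, 2):
        try:
            profiles.append(mismatch_profile(guide, target, frame))
        except ValueError:
            continue
    if not profiles:
        raise ValueError("target too short for any register")
    return min(profiles, key=lambda pr: (pr.count, pr.frame_offset))


@dataclass(frozen=True)
class ScanRow:
    position: int
    alt_base: str
    profile: MismatchProfile


def substitution_scan(
    parent: GuideStrand, target: RepeatTarget, frame_offset: int = 0
) -> list[ScanRow]:
    """Exhaustive one-substitution design scan of ``parent``.

    One row per (position, alternative base); 3·L rows for a 4-letter
    alphabet.  Each row carries the mismatch profile of the substituted
    guide against ``target`` at the given phase — the desk version of
    asking how an extra mismatch at each position reshapes the
    off-target landscape.
    """
    rows = []
    for position in range(1, len(parent) + 1):
        current = parent.sequence[position - 1]
        for base in RNA_BASES:
            if base == current:
                continue
            variant = apply_substitution(parent, position, base)
            rows.append(
                ScanRow(position, base, mismatch_profile(variant, target, frame_offset))
            )
    return rows


def inframe_register_count(
    target: RepeatTarget,
    guide_length: int,
    max_mismatches: int = 2,
    guide: Optional[GuideStrand] = None,
) -> int:
    """Number of in-phase binding registers a repeat tract offers.

    Alignment windows on the tract are enumerated at unit-length (3 nt)
    steps, in the phase the guide binds; a register qualifies when the
    guide pairs with at most ``max_mismatches`` mismatches.  Longer tracts
    offer proportionally more registers — one extra per added unit — which
    is the geometric basis for cooperative RISC binding on expanded
    alleles.

    With ``guide=None`` every in-phase window is assumed to qualify (for a
    repeat-like guide within budget all in-frame windows share one
    profile), giving the purely combinatorial count
    ``floor((3n - L)/3) + 1`` (0 when the tract is shorter than the
    guide).
    """
    if guide_length < 1:
        raise ValueError("guide_length must be >= 1")
    tract = target.transcript_sequence()
    L = guide_length
    if len(tract) < L:
        return 0
    if guide is None:
        return (len(tract) - L) // 3 + 1
    if len(guide) != L:
        raise ValueError("guide_length disagrees with guide")
    best = 0
    for residue in (0, 1, 2):
        qualifying = 0
        for o in range(residue, len(tract) - L + 1, 3):
            window_ref = revcomp_rna(tract[o : o + L])
            mismatches = sum(
                1 for a, b in zip(guide.sequence, window_ref) if a != b
            )
            if mismatches <= max_mismatches:
                qualifying += 1
        best = max(best, qualifying)
    return best


# ---------------------------------------------------------------------------
# IO: guide sets as FASTA (+ TSV substitution sidecar)
# ---------------------------------------------------------------------------

_SIDE_FIELDS = ["guide", "position", "from_base", "to_base"]


def write_guides(
    guides: Iterable[GuideStrand], fasta_path: str | Path, sidecar_path: str | Path
) -> None:
    guides = list(guides)
    records = [
        SeqRecord(Seq(g.sequence), id=g.name, description="") for g in guides
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(sidecar_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_SIDE_FIELDS)
        for g in guides:
            for sub in g.substitutions:
                writer.writerow([g.name, sub.position, sub.from_base, sub.to_base])


def read_guides(
    fasta_path: str | Path, sidecar_path: Optional[str | Path] = None
) -> list[GuideStrand]:
    """Read a guide set from FASTA (U or T accepted) plus optional sidecar."""
    subs: dict[str, list[Substitution]] = {}
    if sidecar_path is not None:
        with open(sidecar_path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                subs.setdefault(row["guide"], []).append(
                    Substitution(
                        int(row["position"]),
                        normalize_rna(row["from_base"]),
                        normalize_rna(row["to_base"]),
                    )
                )
    guides = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        guides.append(
            GuideStrand(rec.id, str(rec.seq), tuple(subs.get(rec.id, ())))
        )
    return guides


def write_substitution_scan(
    rows: Sequence[ScanRow], path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["position", "alt_base", "mismatch_positions", "mismatch_count"])
        for row in rows:
            writer.writerow(
                [
                    row.position,
                    row.alt_base,
                    ",".join(map(str, row.profile.positions)),
                    row.profile.count,
                ]
            )
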