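"""Independent reference implementations used only to check the package.

Everything here is deliberately written the dumb way (character loops,
Biopython complements, exhaustive enumeration) and never calls the code
path it validates.
"""

from Bio.Seq import Seq

RNA_PAIR = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def revcomp_dna_oracle(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def repeat_mismatches(guide_rna: str, frame: int, unit_complement: str = "CUG") -> tuple:
    """Positions where a guide fails to match the phase-shifted repeat complement."""
    ref = (unit_complement * ((len(guide_rna) + frame) // 3 + 2))[frame:]
    return tuple(
        p for p in range(1, len(guide_rna) + 1) if guide_rna[p - 1] != ref[p - 1]
    )


def pairing_mismatches(guide_rna: str, target_rna: str) -> tuple:
    """Antiparallel Watson-Crick check of a guide against an equal-length target.

    target_rna is transcript sense 5'->3'; guide position p faces target
    base L - p (0-based from the target 5' end).
    """
    L = len(guide_rna)
    assert len(target_rna) == L
    return tuple(
        p
        for p in range(1, L + 1)
        if (guide_rna[p - 1], target_rna[L - p]) not in RNA_PAIR
    )


def sliding_hamming_hits(seq: str, pattern: str, budget: int) -> list:
    """All (start, mismatch_count) of windows within budget; N-windows skipped."""
    L = len(pattern)
    out = []
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        if "N" in window:
            continue
        d = sum(1 for a, b in zip(window, pattern) if a != b)
        if d <= budget:
            out.append((start, d))
    return out


def merge_intervals(intervals: list) -> list:
    """Transitive >=1 bp overlap union of (start, end) pairs."""
    merged = []
    for s, e in sorted(intervals):
        if merged and s < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged
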