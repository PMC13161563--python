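# Methods

## Pairing model

Guides are 19–23 nt RNAs compared against repeat targets under strict
Watson–Crick pairing (A–U, G–C).  G:U wobble is counted as a mismatch:
off-target enumeration happens in DNA space (as with short-read aligners
and BLAST on genomic/transcript sequence), which has no wobble, and using
one rule everywhere keeps design profiles and scan results commensurable.
Guide coordinates are 1-based from the 5' end; the repeat reference is the
reverse complement of the transcript-sense tract, with phase 0 starting at
C for a CAG target (so the reference reads CUGCUG...).  "Best frame" is
the phase minimizing the mismatch count, ties to the lowest frame index.
U and T are interchangeable on input; guides are held as RNA, genomic
sites and hairpins as DNA.

In-frame register counting enumerates alignment windows at 3-nt steps in
the residue class the guide actually binds (for a CUG-phase-0 guide this
is the class anchored at the tract's 3'-terminal window).  A register
qualifies when the guide pairs within the mismatch allowance (default 2).
With no guide supplied the count is the combinatorial
floor((3n − L)/3) + 1, which is exact for repeat-like guides within the
allowance since all in-phase windows then share one profile.

## Off-target scanning

Distance is pure Hamming over equal-length windows — no gaps, matching
the v-mode behaviour of short-site alignment for a 19-nt query.  The
production scanner seeds by pigeonhole: at budget k the site is split into
k+1 near-equal segments, of which at least one must occur exactly in any
window within budget; exact segment occurrences (string search) anchor
candidate windows that are fully verified with early abort.  The contract
is the hit set, not the algorithm: `naive_scan` implements the plain
O(N·L) sliding-window comparison and the test suite asserts hit-set
identity across budgets 0–3 and both strand modes on seeded random
sequences.  Windows containing N are excluded (not treated as wildcards)
and tallied.  Genome scans default to both strands, transcriptome scans
to sense-only (the guide binds mRNA).  Coordinates are 0-based half-open
internally and in BED output; mismatch positions are reported in guide
coordinates on both strands so they line up with design nomenclature.

Overlapping windows (≥1 bp, same sequence and strand) merge transitively
into loci; summaries bin windows, loci, or transcripts at their *exact*
(for transcripts/loci: minimum) mismatch count, with cumulative counts
derivable downstream.  Both window- and locus-level summaries are
emitted because a repeat tract yields many overlapping windows but one
locus.  Variant ranking is ascending lexicographic on the (k=0..3) count
vector, ties broken alphabetically.

## Hairpin-processing profiling

Reads are matched to the hairpin exactly: the longest read prefix
occurring in the hairpin fixes the 5' start, with up to 2 non-templated 3'
nt tolerated (default; configurable).  Error-tolerant mapping is
deliberately omitted — coverage of a ~75-nt hairpin is deep, and exact
matching keeps 5'-start groups unambiguous; reads carrying internal
sequencing errors fall into the unassigned tally rather than blurring
groups.  Repeat-rich inserts can make a read match several offsets; ties
go to the leftmost occurrence within an annotated arm, then leftmost
overall, and the ambiguity count is reported.  A read's arm is the
annotated arm whose interval, expanded by the 5' slack (default 5 nt),
contains its start; arm intervals come from a configuration file rather
than being inferred.  Groups are keyed by (arm, start); groups below 0.5%
of assigned reads (default) pool into one "other" group per arm.  All
fractions are percentages of assigned reads; raw counts are the internal
currency and normalization happens only at report time.  Guide-arm groups
are annotated with their target-register mismatch positions via the
best-frame pairing model, so a +1 5' shift visibly displaces the designed
mismatches by +1.

The amiRNA's abundance is reported two ways, since "fraction of the
miRNA pool" is ambiguous: relative to the summed counts of the top-N
(default 50) endogenous mature miRNAs, and relative to all endogenous
counts.

## Restoration statistic

Genes significant (default: adjusted p < alpha = 0.05) in both the
treated-vs-reference and untreated-vs-reference tables form the shared
set; Pearson's r is computed over their paired log2 fold changes and
reversal is a per-gene sign flip.  The adjusted p-value is the default
criterion because volcano-style DE outputs are thresholded on adjusted p;
the raw p-value is available behind a flag.  Genes with a fold change of
exactly 0 are neither concordant nor reversed and are counted separately;
NA effects or p-values drop a gene with a tally.  r is flagged undefined
below 3 shared genes or for zero-variance effect vectors.  No fold-change
magnitude filter is applied by default.

## Synthetic data

The generators replace the study-scale raw data (multi-gigabase genome,
10–30 M-read libraries, 100 M-read mRNA-seq) at desk scale while keeping
the *measured composition* of the real system as defaults:

* **Genomes** (default 0.5–5 Mb, uniform composition): planted sites are
  the guide's complementary site with exactly k mutated positions
  (mutations always change the base, so the planted distance is exact);
  placements are padded so no scan window straddles two features.  After
  assembly, an independent vectorized window-distance routine certifies
  that no accidental window within the scan budget exists outside planted
  features and repeat tracts, redrawing offending background positions
  (bounded retries, then an error for repeat-like compositions).  Truth
  counts are therefore exact, and planted-site recovery is a strict
  100%-sensitivity/precision check.
* **Read libraries** (default depth 1e5): a multinomial draw over
  hairpin-templated variants whose default proportions mirror the
  measured processing profile — guide/passenger 85.5/14.5, the +1-shifted
  guide start at 35.9% and the canonical start at 32.4%, the remaining
  guide share on minor 5' starts, templated lengths 19–23 nt — plus
  non-templated 3' tails (1–2 random nt at rate 0.15) and a log-normal
  endogenous miRNA count table (300 species).  The hairpin is a synthetic
  stand-in: the 13A guide on the 5p arm, its reverse complement as the
  passenger arm, arbitrary flanks/loop with a G immediately 5' of the
  guide so the +1 product still pairs the repeat.  Real scaffold flanks
  are a configuration input, not a model output.  Quality scores are
  constant — the profiler consumes read identity only.
* **DE tables** (default 2000 genes): 111 co-significant genes draw
  paired effects from a bivariate normal with population correlation
  −0.81 (the measured restoration correlation) and sub-alpha adjusted
  p-values in both tables; null genes carry small effects and are never
  significant in both tables at once, so the shared-set count is exact by
  construction.  |target_r| = 1 is handled analytically (zero noise).

Every generator is a pure function of (seed, parameters) with independent
random streams per sequence/read block, and serializes a truth table
sufficient to score the corresponding pipeline stage without re-derivation.

What passing the synthetic checks does *not* show: recovery of the real
libraries' numbers depends on upstream choices the generators do not model
(adapter trimming, read-collapsing and count thresholds, scaffold flank
identity, non-uniform genomic composition and N-content, DE model
calibration).  The generators validate the measurement machinery, not
those upstream choices.

## Tolerances and sizes

Mixture recovery is checked against 3 binomial/multinomial standard
deviations at the generated depth, repeated over 20 fixed seeds with at
most one excursion allowed (the expected excursion count at 3 sigma over
~140 checks is ≈0.4).  Correlation recovery is checked inside the 99%
Fisher-z band at n = 111.  Scanner equivalence uses 100 seeded random
sequences of 1–5 kb across budgets 0–3 and both strand modes, and
planted-site recovery runs on a 5-Mb genome (5 × 1 Mb) with 25 planted
sites at k = 0–3 — sizes chosen so the whole suite runs in seconds on one
CPU while still exercising every code path at realistic densities.

## Known limitations

No thermodynamic duplex modelling, RISC-loading prediction, or
quantitative allele-selectivity model (selectivity is established
experimentally); no splice-aware or indel-tolerant scanning; no adapter
trimming or quality filtering; DE model fitting is consumed, not
performed.  The scanner is exhaustive by design and makes no attempt to
reproduce heuristic aligner reporting caps.
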