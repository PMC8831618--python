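# Methods

## The structure being screened for

`hsrscan` detects a particular architecture of tandem gene amplification:
an array of near-identical DNA *units* (50 bp – 30 kb) whose junctions are
tandem runs of one *short repeated sequence* (SRS, a 2–200 bp motif), with
the number of SRS copies varying from junction to junction:

    SRS×c1 — unit — SRS×c2 — unit — … — unit — SRS×c(k+1),   not all cᵢ equal

The copy-number variability is the diagnostic: it is the expected footprint
of repeated unequal sister-chromatid exchange (USCE) seeded by
microhomology at the SRS, and it separates these arrays from uniform
tandem repeats and from rolling-circle-style amplification products, whose
junction repeats (if any) have constant copy number. The screen therefore
*excludes* arrays whose junction copy numbers are all equal.

## Screening conditions

Candidate loci are assembled from a tandem-repeat annotation matrix
(either a Tandem Repeats Finder `.dat` file or the built-in detector) and
must pass, with all thresholds configurable in `ScanConfig`:

1. **SRS length** within [`srs_min_len`, `srs_max_len`] = [2, 200] bp.
   Loci are classed *short* (motif ≤ 3 bp) or *long* (4–200 bp).
2. **SRS match** — per-record percent matches strictly above
   `srs_min_match` = 70, and the observed motifs of chained blocks must
   agree at ≥ `srs_cross_match` = 70 % identity (maximised over motif
   rotations, and over the reverse complement when strand merging is on,
   so that rotated spellings of one family are not rejected).
3. **Unit length** — every inter-block gap within
   [`unit_min_len`, `unit_max_len`] = [50, 30000] bp; a gap outside the
   range ends the chain.
4. **Unit identity** — adjacent units globally align at
   ≥ `unit_min_identity` = 90 % (identity = matching columns / alignment
   columns of the edit-distance-optimal global alignment). An
   `all_pairs_identity` switch additionally checks non-adjacent pairs.
   Amplification is sequential, so adjacency is the default reading.
5. **Copy-number variability** — integer-rounded SRS copy counts across
   the chain's blocks must take at least two distinct values
   (`require_variable_copies`). Rounding absorbs the fractional copy
   numbers detectors report under boundary jitter.

A minimum of `min_units` = 3 units is required: one or two duplications do
not evidence processive tandem amplification. Chains are *split*, not
rejected, where condition 4 fails: a low-identity adjacency means the
sequence beyond it is not the same amplified unit, so it marks a locus
boundary. The two fragments share the junction block. This matters in
practice — a stray same-family repeat within chaining distance (30 kb) of
a genuine locus would otherwise poison the whole chain.

Same-family blocks within `merge_max_gap` = 8 bp are fused first (copy
count recomputed from the fused span): detectors fragment one junction
run at isolated mismatches. The window is deliberately a few base pairs;
absorbing a same-family run tens of bp away would corrupt the junction's
copy count — in testing, a 50 bp window turned a uniform-copy array's
[4,4,4,4] into [4,4,4,6] by swallowing a nearby background repeat,
creating a false positive.

Overlapping candidates (families at nested periods) are resolved greedily:
more units, then longer span, then smaller start — fully deterministic.

## The built-in tandem-repeat detector

So the pipeline is testable without external binaries, `hsrscan` includes
a detector in the Tandem Repeats Finder tradition. Candidate periods come
from exact character recurrence (`seq[i] == seq[i+d]`); each maximal run
of length ≥ d (≥ 2 motif copies) is scored by **wraparound dynamic
programming**: a global alignment of the region against unbounded tandem
copies of the motif, the motif column index wrapping modulo the motif
length, under integer weights (match +2, mismatch −3, indel −5 by
default — the weight set the screen's thresholds were designed around).
In-row wrap dependencies are resolved with the standard two-pass row
update. Records whose period is an integer multiple of a same-span
record's period are pruned (so (ACGT)×3 is not also reported as
(ACGTACGT)×1.5).

The detector is *not* a byte-exact TRF clone; its fidelity contract is
exact agreement with brute-force enumeration of maximal perfect tandem
repeats (property-tested on random sequences, and re-verified by the
acceptance script on 200 sequences per run). It detects perfect and
near-perfect runs; bridging of interrupted runs (`merge_gap`) exists but
is off by default, because under the simulator's noise model junction
runs are never mutated and the oracle property is exact only for perfect
runs.

Two score floors exist deliberately. `find_tandem_repeats` defaults to
`min_score` = 20, a common working floor for general repeat annotation.
The *screen* (`ScanConfig.finder_min_score`) uses 16 = two copies of a
4 bp motif at match reward 2: junction blocks with N = 2 of a short motif
are real amplification junctions and must be visible to the scan. Blocks
below the floor (e.g. two copies of a dinucleotide, 8 bp) are invisible
to any score-thresholded detector; the simulator's randomized study
conditions only plant blocks of ≥ 10 bp for this reason.

Motif families are keyed by the lexicographically minimal rotation,
minimised also over the reverse complement's rotations when
`merge_strands` is on (the default) — TG, GT, CA and AC are then one
family, "AC".

## Head/tail ratio

Each accepted locus gets a head and a tail statistic in [0, 1]: the
fraction of one amplified unit present immediately *outside* the
outermost SRS block. 0 means the array ends on SRS (amplification ran to
completion at that end); 1 means a full un-flanked unit copy lies beyond
the outer junction; intermediate values mean a partial unit.

The consensus unit is the medoid (maximum mean identity to the other
units). Against the flank (window = `unit_max_len`), a base-wise scan
from the outer block outward scores +1 per match and −3 per mismatch; the
arg-max of the cumulative score estimates the breakpoint. The +1/−3
weights make the expected slope +0.8/bp over true unit sequence even at
5 % divergence, and −2/bp over unrelated background (≈ 25 % identity), so
chance overshoot beyond the true breakpoint is a bp or two. A nonzero
ratio additionally requires ≥ `head_tail_min_anchor` = 20 bp of matched
flank at ≥ `unit_min_identity`; this makes the "ends exactly on SRS →
exactly 0" contract hold against chance micro-matches in random flanks.
The scan is substitution-only (the no-indel special case of a semi-global
alignment), matching the simulator's default noise model; flanks with
indels would fragment the match run and bias the ratio downward — a known
limitation.

Head and tail ratios are pooled (two observations per locus) in the
summary histogram: an exact-0 bin, ten equal bins over (0, 1), and an
exact-1 bin.

## Summary statistics

Per genome, the report carries locus counts per SRS class, genome length,
Mb-per-locus density, median SRS length / unit count / unit length, GC of
the genome versus GC of the SRS blocks, presence counts of the
recombination-associated dinucleotide families (AC/CA/TG/GT, strand-merged
to "AC"; loci counted once per family, with an occurrences mode off by
default), and the pooled ratio histogram.

`compare_across_genomes` matches loci across assemblies when they share
an SRS family and their medoid units align at ≥ 90 % identity (the same
knob as condition 4), then tabulates per-genome unit counts, copy-number
vectors and spans — the structural "dynamics" view of one locus across
species, ecotypes or strains. Matching is by connected components, so a
group may chain through intermediate genomes.

## The synthetic-genome generator

`SimSpec` describes one genome: i.i.d. background of configurable GC
(default 0.41, a typical vertebrate value), planted loci, confounders and
a mandatory seed. Everything is a pure function of the spec at byte
level; `simulate_genome` writes FASTA plus a truth GFF3 mirroring the
scanner's output schema.

Each planted locus lays down `SRS×c1 + unit + … + SRS×c(k+1)` from one
master unit sequence; every unit copy is independently mutated at
`substitution_rate` (modelling post-amplification divergence; the default
noise model has no indels so truth intervals stay exact). Optional
partial head/tail units — a suffix/prefix of the master of the stated
fraction — are appended outside the outer blocks. Confounders are either
uniform-copy junction arrays (the screen's exclusion case) or SRS-free
tandem arrays (plain long-period repeats). A hard mode plants random
background microsatellites to stress precision.

Three construction rules keep ground truth exact and unambiguous, at the
cost of realism (see limitations):

* master units are *cleaned* of incidental internal tandem runs at the
  detector floor — such a run would recur in every unit copy and plant a
  junction-like array of an undeclared kind;
* a master unit's first/last base is redrawn when it would continue the
  flanking SRS motif's periodicity, and likewise the single background
  base flanking each planted array — otherwise detector boundaries
  systematically extend past the planted junctions (identical units
  extend identically, which once turned a uniform [4,4,4,4] confounder
  into a detected [5,5,5,4]); chance same-family background runs close
  enough to a planted edge to be merge-fused into its outer block —
  including runs crossing the boundary, where a background suffix plus
  the block's first bases form a perfect phase-shifted run — are broken
  by redrawing background bases only;
* the randomized study conditions (`random_spec`: 100 kb genome, 1–3 loci,
  motifs of 2–12 bp with distinct families, 3–5 units of 100–500 bp,
  junction blocks ≥ 10 bp, one uniform-copy and one SRS-free confounder)
  draw distinct SRS families per genome, since two same-family structures
  within chaining distance merge into one candidate by construction.

`evaluate_detection` matches detections to truth at ≥ 50 % reciprocal
span overlap with agreeing strand-merged families (best-overlap first,
one-to-one) and reports precision, recall, mean absolute boundary error,
and the fraction of matched loci with exact unit counts. Confounders are
never matchable, so calling one is a false positive.

## What passing tests do and do not show

The simulator emulates the *architecture* the screen targets, not real
genomic sequence. Background is i.i.d. (no repeat landscape, no GC
isochores), units carry no internal repeats or transposon insertions, and
noise is substitution-only. Perfect precision/recall on these conditions
demonstrates the algorithm implements its own definition correctly —
exact junction arithmetic, correct condition logic, deterministic
tie-breaking — not that real-genome performance is perfect. On real
assemblies, collapsed repeats, indel polymorphism and unit-internal
microsatellites will all degrade boundaries and identities in ways these
tests deliberately hold fixed. The noise sweep (recall 1.0 through 2 %
unit divergence, degrading near 5 % where expected pairwise identity
crosses the 90 % threshold) probes the one failure mode the model does
include.

Problem sizes in the shipped tests and acceptance script — 100 kb
genomes, 20 seeds per condition, 200 finder-oracle sequences — were
chosen as the smallest sets that exercise every code path with stable
statistics; all scale linearly if larger studies are wanted.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; TRF and GFF3 (1-based
  inclusive) are converted only at file boundaries, BED passes through.
* Copy counts round half away from zero from detectors' fractional
  values.
* `wraparound_align` requires a non-empty region and motif; empty
  sequences raise. A defensive step bound guards the wrap traceback.
* Identity checks fail fast via a bounded-distance alignment
  (distance > (1 − t)·(|a|+|b|) proves identity < t) before any full
  traceback.
* `resolve_overlaps` and all writers are byte-deterministic; ties are
  fully ordered (units desc, span desc, start asc, seq asc).
* Genomes shorter than their inserts plus 300 bp spacing margins are
  rejected before any output; zero-locus reports carry explicit
  undefined (`NA`) densities and medians rather than zeros.

## Known limitations

* Junction runs below the detector score floor (e.g. 2 copies of a
  dinucleotide) are invisible; loci whose every junction is that small
  cannot be found, and a locus is truncated where such a junction
  interrupts it.
* The head/tail scan assumes breakpoint-preserving flanks (no indels).
* Strand handling is interval-based: families merge across strands, but
  no reverse-complement scan of the sequence is performed (tandem arrays
  are strand-symmetric as intervals).
* `compare_across_genomes` is structural only; it does not classify unit
  coding content or estimate divergence times.
* The detector does not reproduce TRF's composition/entropy statistics
  (pass-through fields) and does not detect inverted repeats.
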