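# Methods

## Mechanism and model

SMART (template-switching) library preparation T-tails the 3′ ends of
DNA templates and primes reverse transcription with a poly(dA) primer.
The primer also anneals to genomic poly(T) runs, either inside genuine
immunoprecipitated fragments or in non-target fragments, and the
resulting molecules are PCR-amplified like any other. Because the
primer anneals only to the strand carrying the Ts, the artifact reads
are strand-specific: they accumulate on the "+" strand upstream of a
poly(T) tract and on the "-" strand downstream of a poly(A) tract (the
tract's *affected strand* and *affected side*). In paired-end
sequencing, Read2 begins at the primer, so the Read2 5′ terminus of
every falsely primed fragment coincides with the tract's
primer-proximal boundary (the *anchor*: left edge of a poly(T) tract,
right edge of a poly(A) tract), and amplification of a single priming
event produces many pairs sharing one terminus coordinate.

All coordinates are 0-based half-open (BED convention) internally;
1-based coordinates appear only inside SAM records, handled by pysam.

## Site scanner

A poly(T/A) site is a maximal chain of same-base runs in which
consecutive runs are separated by gaps of 1..`max_gap_len` A/C/G/T
bases, with at most `max_interruptions` gaps per chain and at least
`min_matches` matching bases in total. Matching is case-insensitive;
bases outside A/C/G/T (N, ambiguity codes) neither match nor may be
bridged. Defaults: `min_matches = 12` (the tract length at which false
priming becomes significant — shorter tracts attract no more Read2
termini than expected by chance), `max_interruptions = 2`,
`max_gap_len = 1` (a single inserted mismatch base reduces but does not
abolish priming, whereas two or more consecutive mismatch bases do, so
an interruption is one base; up to two such interruptions are allowed
per tract). All three are CLI-exposed.

Requiring non-overlapping maximal tracts forces a deterministic
tie-break when interrupted chains could be assembled in more than one
way. Chains are extended greedily *away from the anchor*: left-to-right
for poly(T), right-to-left for poly(A). Since an A tract is a T tract
read on the minus strand, this orientation-aware rule keeps the scanner
exactly symmetric under reverse complement (verified as a property
test), which a single fixed scan direction would not be. The scanner is
validated against two independent brute-force oracles: a character-level
O(n²) interval enumeration on tiny sequences, and a run-level chain
enumeration on kilobase-scale sequences, both applying the same
anchor-oriented non-overlap selection.

Every sequence in the FASTA is scanned; users subset the FASTA to
restrict assemblies. The BED6 output encodes base:match_len:gaps in the
name column and the affected strand in the strand column, and
round-trips losslessly through the companion reader.

## Paired-end cleaning

For a poly(T) site the primer window is `[start − max_gap, end]` for
"-"-strand Read2 termini (the exclusive right coordinate); for a
poly(A) site, `[start, end + max_gap]` for "+"-strand termini (the
leftmost coordinate). The window spans the whole tract, not just the
anchor, because primer-derived bases can be aligned into the tract by
the aligner; `max_gap` (default 10 bp) absorbs 3′ quality/primer
trimming of Read2, which shifts the observed terminus away from the
tract edge. When windows of same-base sites overlap, the leftmost site
in genome order claims the terminus.

Stacks are keyed per (site, terminus coordinate), not per site: two
singleton stacks at different coordinates of one site are both kept. A
stack moves to the noise file when its size is strictly greater than
`threshold` (default 1) — independent genuine fragments essentially
never share an exact Read2 terminus inside these windows, so a stack of
two or more at one coordinate marks amplification of a single priming
event. Both mates of a noise pair travel together; unmapped, secondary
and supplementary records always pass to the clean file, so the two
outputs exactly partition the input. The cleaner streams the
coordinate-sorted input twice (collect stacks, then partition), keeping
memory proportional to the candidate set rather than the file.
Duplicate-flagged reads are evaluated like any other — deduplication is
an upstream concern — but a duplicate fraction above 20 % triggers a
warning. Mean template lengths of the clean and noise outputs are
reported (artifact fragments tend to run shorter, since the primer
annealed inside the fragment rather than at its tailed end) but never
asserted.

## Single-end cleaning

Single-end data lacks Read2, so artifacts are detected as a
strand imbalance. Reads are located by their 5′ end throughout: the
leftmost coordinate for "+" reads, the rightmost aligned base for "-"
reads.

**Distance profile.** For each poly(T) site, reads in the upstream
flank (default 2 kb) contribute the distance `anchor − five_prime`
(counted when 0 < d < flank): "+"-strand reads to the affected counts,
"-"-strand reads to the opposite counts. Poly(A) sites are mirrored
(`five_prime − anchor`, downstream, strands swapped), so both tract
types pool into one oriented profile. Under artifact-free data the two
series agree at every offset up to sampling noise; false priming shows
as an affected-side excess at offsets up to the artifact fragment
length.

**Window estimation.** Both series are smoothed with a running mean
(width `smooth`, default 25 offsets) and the per-offset affected/
opposite ratio computed (0/0 counts as 1, x/0 as infinity). Offsets
with ratio ≥ `ratio_floor` (default 1.2) are flagged; flagged runs
separated by fewer than `min_run` (default 50) clean offsets merge into
blocks; blocks whose raw count excess is within 3 σ of Poisson noise
are discarded; the window `w` is the end of the surviving block with
the largest excess — the edge of the contaminated zone. A first-clean-
run rule was rejected because artifact fragments have a minimum length,
leaving the shortest offsets uncontaminated and the rule answering
`w ≈ 0`; taking the far edge of the dominant excess block recovers the
maximum artifact extent, which is what the resampling regions must
cover. No flagged block means `w = 0` (nothing to clean); an all-zero
opposite series, or a block reaching within `min_run` of the flank
edge, falls back to `w = flank` since the contamination may extend
beyond what was measured. The estimate is deterministic, and `--window`
overrides it.

**Resampling.** One region per site — `[anchor − w, anchor)` with
affected strand "+" for poly(T), `[anchor, anchor + w)` with "-" for
poly(A) — truncated at chromosome edges. Regions are processed in
genome order; reads already sent to noise by an earlier region are
invisible to later ones. Per region, with `Na` affected-strand and `No`
opposite-strand 5′ ends inside, if `Na > ratio × No` (default ratio 2)
a uniform random subset of exactly `No` affected reads is kept — the
opposite strand is the best local estimate of the genuine signal — and
the remaining `Na − No` go to noise; otherwise the region is left
alone. One generator seeded once drives all draws in region order, so a
given seed reproduces the partition exactly; candidate reads are sorted
by (position, name) before drawing so the result is independent of
fetch order. Balancing is per-region, not per-position: per-position
counts are too sparse to estimate at realistic depth. Resampling to
exactly `No` (not `ratio × No`) makes a second pass a no-op, so
cleaning is idempotent.

## Simulator

The generator emulates an input-DNA (control) SMART library at desk
scale. Defaults: two 500 kb chromosomes of i.i.d. uniform ACGT bases;
40 planted tracts of 12–30 matching bases (half T, half A; 20 % carry a
single 1-bp interruption), flanked by 2 bp of C/G so each planted tract
is maximal and cannot chain with a chance-adjacent run at the default
gap length; 10,000 background fragments uniform in position and strand;
500 artifact fragments whose primer-side terminus sits exactly on a
site anchor (optional jitter exercises the gap-tolerance path), in
stacks of 2–4 identical termini; fragment lengths normal (mean 200 bp,
sd 25) truncated to [50, 500], with optional harder truncation and mean
shift for artifact fragments; 50 bp reads, pure-match CIGAR, constant
base quality, written directly as coordinate-sorted, indexed BAM with a
truth table mapping every read name to background/artifact/peak.

The window-estimation checks use a deeper configuration — 200 tracts,
200,000 background reads, 20,000 artifacts truncated at 300 bp — since
a per-offset strand comparison needs profiling depth; this mirrors the
regime the estimator targets (tens of millions of reads over hundreds
of thousands of sites in a mammalian genome) at about a thousandth of
the volume.

The simulator does **not** model sequencing errors, adapters, PCR
duplicates of background reads, mappability, GC bias, or chance-placed
artifact termini away from anchors. Passing tests therefore demonstrate
the cleaning logic — classification windows, stack thresholds, strand
accounting, resampling arithmetic, determinism — not robustness to
alignment noise, and real-data removal percentages need not match the
simulation's.

## Numerical and design choices

- PE stacks key on the Read2 5′ (primer-side) terminus; after 3′
  trimming the 5′ end is the coordinate the aligner still reports
  faithfully.
- The SE 5′ end of a "-" read is its rightmost aligned base
  (`reference_end − 1`); the PE "-" terminus is the exclusive end
  (`reference_end`), matching the abutting-fragment geometry where the
  fragment end equals the tract start.
- Ratio arithmetic treats 0/0 as 1 (no evidence of contamination) and
  x/0 as infinity (pure one-strand pileup).
- Region-order validation requires grouping by chromosome with
  non-decreasing starts; the cleaner itself never re-sorts.
- `evaluate_cleaning` scores fragment names, so a PE pair counts once;
  precision of an empty noise set is reported as NaN with n = 0.

## Limitations

- SE mode is inherently less specific than PE mode: it removes a
  (seeded) random subset in imbalanced regions, so some genuine
  affected-strand reads are sacrificed and some artifacts survive; at
  the default simulation depth recall is ≈ 85–90 % with ≲ 0.5 %
  collateral removal, whereas PE mode is exact on stacks ≥ 2.
- The automatic window rule is a heuristic change-point detector; at
  very low coverage its blocks lose significance and `w` collapses to 0
  or inflates to the flank — the CLI override exists for exactly that
  case.
- Tract counts at full mammalian-genome scale are not validated by the
  test suite, which runs entirely on simulated megabase genomes.
- Peak-aware cleaning is out of scope: a genuine peak overlapping a
  resampling region on the affected strand will be thinned toward the
  opposite-strand count like any other imbalance.
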