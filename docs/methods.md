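# Methods

This note records the models, conventions and design choices behind
`svfootprint`, in the order the pipeline applies them.

## Coordinates and sequence conventions

All internal coordinates are 0-based half-open; VCF positions are
converted on read and write, BED is consumed natively.  Sequences are
uppercase over A/C/G/T/N.  N is treated conservatively throughout: it
never matches any base (including another N) in grids, microhomology
runs, homology prefixes or template searches, and random placements
whose windows touch an N run are rejected and redrawn.

## Breakend geometry

A fusion ("translocation" here: any inter- or intra-chromosomal
junction) arrives as two mated VCF BND records.  The ALT bracket shape
fixes how the two loci join: `t[p[` fuses the 3′ sense strand to the 5′
sense strand (type 1); `t]p]` fuses 3′ sense to 5′ anti-sense
(type 2); `]p]t` is the type-1 fusion annotated from its other end and
is merged into type 1; `[p[t` fuses 3′ anti-sense to 5′ sense
(type 4).  For the strand-symmetric types 2 and 4 the two mate records
describe the same molecule from opposite strands; the canonical form
is the view whose left partner is the lexicographically smaller locus,
so results never depend on record order.  Records lacking MATEID are
paired by reciprocal coordinates within the merged confidence
intervals; unpaired singletons are dropped with a warning.

Flanks of half-window w (default 4; 8 for deletion grids) are labeled
so that 0 is the junction-adjacent base included in the fusion
product, +1…+(w−1) the further included bases, and −1…−w the bases
beyond the break.  The figure axis for such grids could equally be
drawn mirrored; mirroring only relabels rows and columns and changes
no statistic, so the label direction here is fixed once: included
bases count upward away from the junction.  A single label→(position,
strand) mapping drives both flank extraction and the simulator's
planting edits, which is what makes the closed-loop tests exact.

## Filtering cascade

Stage order is fixed: caller-PASS → parental overlap → repeat regions
→ deduplication; the order is observable only in the per-stage removal
counts of the filter report.  A FILTER value of "." (no filter
applied) is treated as non-PASS, keeping only calls that affirmatively
passed.  Parental overlap removes an offspring indel/duplication when
its interval shares ≥ 1 bp with *any* parental SV interval, and an
offspring fusion when a parental fusion has both break sites within
the merged confidence windows in either partner order; two break sites
match when their distance is at most the largest absolute
confidence-interval bound of either record.  The repeat filter removes
indels intersecting any repeat interval, but fusions only when both
break points lie in intervals of the *same* repeat class — fusions
between different repeat families are informative and retained.
Deduplication keeps the lexicographically smallest representative of
each within-CI cluster.  No genotype-based filtering is applied.

## Insertion footprint

The inserted junction sequence is searched as an exact substring of
the 51 bp window centred on each breakend base, in four literal string
transforms: normal, reverse, complement, reverse complement.  Reverse
and complement alone are not biological strands, but the four-transform
search is the stated procedure for this footprint and is kept as such.
Insertions ≥ 3 bp with at least one hit are *templated*; any other
non-empty insertion is *miscellaneous*.  All hits are recorded, and
the search is over the full windows (hits inside the insert's own
reference context are not excluded).  The search is exhaustive — unit
tests pin it to a brute-force offset × orientation × site enumeration.

## Match grids and permutation null

Each junction's 2w-flanks are compared all-against-all; the aggregated
grid is the mean of the per-junction binary grids.  Microhomology of
length m appears on the grid's main diagonal in storage order: label
pairs (0, −1), (+1, −2), … for one junction-shift direction and
(−1, 0), (−2, +1), … for the other.  The junction microhomology
*length* is the longer of the two directional runs, saturating at w.

Per-bin significance uses a permutation null: each permutation places
the same number of junctions, with the same type mix, uniformly at
random on the genome (contigs weighted by length, positions ≥ w from
contig ends, N-free windows), extracts flanks with the type-specific
orientations, and averages the bins.  Break-site pairs are placed
independently; the observed inter/intra-chromosomal pairing is not
preserved, because the flank statistics depend only on local sequence.
The one-sided upper-tail p-value is (r+1)/(n_perm+1) — the standard
finite-sample estimator, never exactly zero — compared on integer
match counts so no floating-point ties arise.  Benjamini–Hochberg
adjustment runs over all bins (statsmodels `fdr_bh`).  The reference
profile uses 100,000 permutations for the grid and 25,000 for the base
composition; the test profile uses 9,999 and 2,500.  Given a seed,
permutation results are bit-identical across runs.

The base composition of junctions with microhomology length 1 tallies
per-position percentages over both oriented flanks and compares them to
the mean over resampled draws of equally many uniform random genomic
positions.

## Deletion footprints

Deletions are size-filtered to 8–200 bp inclusive.  Homology is the
longest common prefix of the deleted sequence and the retained
sequence immediately following it, computed after left-alignment
(shifting the interval left while the base before it equals its last
deleted base), so equivalent representations of the same allele get
the same length.  A single-direction prefix convention is used because
the 75% chance expectation for zero homology corresponds to one
first-base comparison (3/4), not a two-sided one (9/16).

Categories: *C. elegans* scheme — 0 non, 1 micro, ≥ 2 macro; human
scheme — ≤ 1 non, 2–6 micro, ≥ 7 macro.  The chance probabilities are
stored as the published constants (75 / 16.66 / 8.33%; human
91.66 / 8.325 / 1:12288%) rather than re-derived: under the geometric
single-comparison model with match probability 1/4 the non-homology
chance is exactly 75%, but the published micro/macro splits do not
follow from that model (geometric would give 18.75 / 6.25%), so the
constants are used verbatim and the discrepancy is noted here.  The
over-representation test is a one-sided (greater) exact binomial test
on the micro count.  Trio de novo filtering removes child deletions
overlapping either parent; gamete-of-origin labels split the set into
father/mother strata tested separately.  Repeat filtering for
deletions removes only those whose two break sites lie in the same
repeat class, and is applied where the workflow calls for it.  The
16 × 16 deletion grid routes each deletion through the identical grid
code path as a type-1 fusion whose left partner ends at the last
retained base before the deletion.

## Synthetic data

The generator emulates the statistical structure the analyses assume:
i.i.d. random genomes at configurable base frequencies (uniform by
default), fusions of the three canonical types with a configurable
microhomology-length distribution, templated inserts copied from the
±25 bp flank windows in one of the four orientations, miscellaneous
inserts, deletions with a configurable junction-homology distribution
and uniform sizes in 8–200 bp, inherited background SVs shared with a
parent, a 5% caller-failure (non-PASS) rate, and non-overlapping
repeat tracks.

Microhomology and deletion homology are planted by editing the genome
before the FASTA is finalized, writing through the same label→position
mapping used by flank extraction and forcing the bases that would
extend a run to mismatch; truth labels are therefore exact rather than
sampled, and arbitrary homology lengths cost no rejection time.  Break
sites of different events are kept ≥ 80 bp apart so edit zones and
template windows never interact, and repeat intervals avoid event
neighbourhoods so planted de novo events are never swallowed by the
repeat filter.  Miscellaneous inserts default to 1–2 bp; longer
miscellaneous inserts are rejection-sampled against the template
search, since in random sequence a 3-mer is almost always present
somewhere in two 51 bp windows.  A single RNG stream is seeded from
the configuration; all outputs are byte-identical under a fixed seed.

What the generator does **not** emulate: real genome composition
(repeat families, GC structure, chromatin context), caller-specific
error modes beyond a flat non-PASS rate, imprecise breakpoints beyond
a fixed CI width, clustered rearrangements, and read-level artefacts.
Passing closed-loop tests therefore demonstrates correctness of the
*computations* under the stated junction model, not robustness to
every property of real sequencing data.

## Problem sizes and test calibration

The closed-loop check runs 1,000 events per seed over 10 seeds, with
call sets round-tripped through VCF.  Grid calibration uses a 200 kb
uniform genome, 100 random junctions and 9,999 permutations; with
n = 100 junctions each bin frequency should sit within 3 binomial SE
(±0.13) of the 0.25 chance level and the 64 p-values should be
uniform.  Planted-signal detection uses 50 junctions with 2-bp
microhomology.  The binomial type-I check runs 200 null seeds at
n = 500 deletions with the generator's homology distribution equal to
the chance constants; because the exact test's true level at n = 500
is 4.6% and 200 seeds carry Monte-Carlo noise, the test asserts the
rejection rate stays below the 99.5% binomial envelope of a 5% rate
(9%).  The power check doubles the micro probability and expects
p < 10⁻⁶.

## Known limitations

* The grid's permutation null ignores inter/intra-chromosomal pairing
  (see above); on genomes with strong regional composition differences
  this could mildly misstate per-bin significance.
* Symbolic `<INS>` records carry no insert sequence, so insertions read
  from such records cannot enter the template search.
* The writer emits explicit deletions with an N padding base when the
  genome is not supplied; consumers use only the deleted bases.
* Homology lengths saturate at the flank half-window (w) in grid-based
  measurements; deletion homology is measured directly on the genome
  and does not saturate until the deletion length.
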