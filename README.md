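# svfootprint

Junction signatures of error-prone DNA double-strand-break repair in
structural-variant call sets.

Polymerase theta-mediated end joining (TMEJ) leaves a characteristic
footprint at repair junctions: short stretches of **microhomology**
shared by the two joined ends, and **templated insertions** copied from
DNA within a few dozen base pairs of the breakpoints.  `svfootprint`
detects and quantifies these signatures in SV calls — de novo
translocations in parent/offspring designs (e.g. single-worm WGS of
*C. elegans* pedigrees) and small deletions in population call sets
(natural isolates, trio truthsets, gamete-of-origin tables) — so that
the repair pathway that produced a set of rearrangements can be read
off the sequence context of their junctions.

## What it computes

**De novo filtering.** Offspring SV calls (VCF with breakend/BND mate
pairs plus DEL/INS/DUP records) are reduced to de novo events: caller
PASS only; removal of anything overlapping a parental SV; removal of
indels in repeat regions and of translocations whose two break points
lie in the *same* repeat class; deduplication of fusions annotated twice
within their confidence intervals.  Every stage's removals are reported.

**Fusion types and flanks.** Each breakend mate pair is classified by
its ALT bracket shape — `t[p[` (type 1), `t]p]` (type 2), `]p]t`
(type 3, the type-1 fusion seen from its other end, merged into
type 1), `[p[t` (type 4) — and the 2w bases flanking each break site
are extracted in the strand orientation the type dictates.  Position 0
is the last base included in the fusion product; −1…−w are the bases
beyond the break.

**Match grids.** For each junction, an all-against-all 2w × 2w grid
scores base identity between the two flanks (N never matches); grids
are averaged into a match-frequency heat map.  Microhomology of length
*m* appears as *m* enriched junction-spanning bins.  Each bin is tested
against a permutation null — the same number of junctions, with the
same type mix, placed uniformly at random on the genome — with
one-sided p = (r+1)/(n_perm+1) and Benjamini–Hochberg adjustment over
the 64 (or 256) bins.

**Insertion footprint.** The inserted sequence between the breakpoints
is searched exactly within ±25 bp of both break sites in four
orientations (normal, reverse, complement, reverse complement).
Insertions ≥ 3 bp with a hit are *templated*; all other non-empty
insertions are *miscellaneous*.

**Deletion footprints.** Deletions of 8–200 bp are categorized by the
homology between the deleted sequence and the retained sequence that
follows it (after left-alignment): the *C. elegans* scheme calls
exactly 1 bp "micro", the human scheme calls 2–6 bp "micro".
Over-representation of the micro class against the chance expectation
(75% non / 16.66% micro / 8.33% macro; human: 91.66% / 8.325% /
1:12288) is tested with a one-sided exact binomial test; trio de novo
filtering and gamete-of-origin stratification are supported.  The same
grid machinery produces the 16 × 16 deletion heat map.

**Synthetic data.** A generator emits multi-contig genomes, repeat
tracks, and parent/offspring VCF call sets with *exact* truth labels:
junction microhomology of any configured length is planted by editing
the genome before the FASTA is finalized, templated inserts are copied
from the ±25 bp flanks, and inherited background SVs are shared with
the parents.  Every analysis stage can therefore be validated closed
loop at desk scale.

## Worked example

```python
from svfootprint import (
    SimulationConfig, simulate, RunConfig,
    run_translocation_analysis, run_deletion_footprint,
)

cfg = SimulationConfig(seed=7, contig_lengths={"chrI": 150_000, "chrII": 100_000},
                       n_translocations=60, n_deletions=60,
                       n_inherited_background_svs=10)
simulate(cfg).write("demo")

run = RunConfig(genome_fasta="demo/genome.fa",
                offspring_vcfs=["demo/F1.vcf"],
                parent_vcfs=["demo/P0_a.vcf", "demo/P0_b.vcf"],
                repeats_bed="demo/repeats.bed",
                seed=0).with_profile("test")
rep = run_translocation_analysis(run)
print("n translocations:", len(rep.translocations))
print("type counts:", rep.type_counts)
print("insertion distribution:",
      {k: round(v, 3) for k, v in rep.insertion_summary.items()})
print("deletion footprint:",
      run_deletion_footprint(run).footprint.to_dict())
```

prints

```
n translocations: 58
type counts: {1: 31, 2: 10, 4: 17}
insertion distribution: {'no_insertion': 0.81, 'miscellaneous': 0.155, 'templated': 0.034, 'n': 58}
deletion footprint: {'scheme': 'celegans_1bp', 'counts': {'non': 42, 'micro': 13, 'macro': 5},
                     'n': 60, 'null_probs': {'non': 0.75, 'micro': 0.1666, 'macro': 0.0833},
                     'binom_p': 0.1899438020446211}
```

58 of the 60 planted de novo fusions survive the cascade (two were
drawn non-PASS by the simulator's 5% caller-failure rate), the type mix
reflects the configured equal thirds, and — with the generator's
deletion homology drawn from the chance expectation itself — the
binomial test is, correctly, not significant.  The junction-spanning
grid bin (0, −1) sits at frequency 0.66 against the 0.25 chance level
with q = 0.0064, reflecting the planted microhomology distribution.

The same workflows are available from a shell:

```bash
svfootprint simulate --seed 7 --out demo
svfootprint run-all --genome demo/genome.fa --offspring-vcf demo/F1.vcf \
    --parent-vcf demo/P0_a.vcf --parent-vcf demo/P0_b.vcf \
    --repeats demo/repeats.bed --profile test --seed 0 --out demo_results
svfootprint delfoot --genome demo/genome.fa --offspring-vcf demo/F1.vcf \
    --parent-vcf demo/P0_a.vcf --parent-vcf demo/P0_b.vcf --scheme celegans_1bp
```

`--profile paper` switches to the reference permutation counts
(100,000 for the grid, 25,000 for the base composition); `--profile
test` is the desk-scale profile (9,999 / 2,500).  The two profiles
differ in nothing else.

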