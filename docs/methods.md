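# Methods

This note records the models, parameter choices and numerical conventions
behind `linkfrag`, and what the synthetic validation does and does not
establish about real data.

## Coordinates, strands and alignment primitives

All internal coordinates are 0-based half-open; 1-based positions appear
only in human-facing report columns. Guide and linker intervals are stored
on the forward reference strand; reverse-strand features carry strand `-`.

Two in-package alignment primitives back the desk-scale workflows (ingested
SAM/PAF from a production aligner remains the expected input at genome
scale):

* `semiglobal_align` — full-read-vs-window alignment with free end gaps on
  the reference, engine = edlib (bit-parallel edit distance) for the
  distance and leftmost optimal location, followed by a unit-cost
  Needleman–Wunsch traceback that fixes the operation order deterministically
  (match > mismatch > deletion > insertion). `N` never matches anything,
  including another `N` (cost 1): the two sides' `N`s are mapped to distinct
  sentinel characters before scoring.
* `overlap_align` — score-maximizing dovetail/containment alignment
  (+1/−1/−1) with free end gaps on *both* sequences and soft-clipped
  overhangs. This is the right model for de novo consensus building, where
  read parts cover ragged extents around a linker: forcing a full-query
  semiglobal alignment there crams non-overlapping overhangs into the
  center sequence and manufactures spurious disagreement columns.

`levenshtein_within_k` is edlib's k-banded edit distance with a `None`
sentinel above the band; the length-difference bound short-circuits.

## Panel design

A region of length `L` is tiled with `ceil(L/F) + 2` sub-regions of fixed
length `F` (default 15 000 bp, the target read length): the first ends at
the region start, the last starts at the region end, interior ones tile the
region at even stride. The linker-search area defaults to the whole
sub-region. Inside each LSA, every 20-mer followed by NGG (both strands) is
a guide candidate; the nick sits 3 bp 5′ of the PAM (between protospacer
positions 17/18, the canonical blunt-cut offset of SpCas9). Filters, in
order:

1. **Uniqueness** — the 23-mer protospacer+PAM occurs exactly once in the
   genome counting both strands (an odd-length k-mer can never equal its own
   reverse complement, so forward counts of the k-mer and its reverse
   complement add cleanly).
2. **GC** — candidates with protospacer GC *below* 0.40 or *above* 0.60 are
   removed; the boundaries are kept.
3. **Off-target score** — `w1·h1 + w2·h2` with `w1 = 256/257`,
   `w2 = 1/257`; `h1` counts other genomic 20-mer+NGG sites sharing the
   PAM-proximal 12-mer, `h2` those sharing the PAM-proximal 8-mer but not
   the 12-mer (the 8-mer seed is a suffix of the 12-mer seed, so the counts
   nest). The candidate's own locus is excluded — otherwise every unique
   guide would score at least `w1`. Scores above 20 are removed. Seeds are
   taken PAM-proximal, the seed region that dominates Cas9 specificity.
4. **Variant avoidance** — candidates whose 23-bp footprint intersects a
   known variant's reference span are removed.

Opposite-strand candidate pairs whose linker interval (3 bp outside the
upstream protospacer start to 3 bp outside the downstream PAM end) has an
in-window length (default 300–500 bp; 50–250 bp in the model-genome
preset), is unique in the genome, and — when required — contains at least
one known heterozygous variant, become linker candidates. Linker
uniqueness is decided by unique-23-mer containment (a segment containing a
genome-unique 23-mer is itself unique), with a direct substring count as
fallback.

Linkers form a DAG with an edge X→Y whenever `start(Y) − end(X)` lies in
the inclusive gap window (default 10–20 kbp; "10–20" is read as a closed
interval). Per region, dynamic programming over the DAG minimizes
`Σ |fragment − F|` over the interior fragments (fragment length =
`end(Y) − start(X)`, linkers included, matching how fragment lengths are
tabulated); ties resolve to the lexicographically smallest sequence of
linker starts. Regions are processed longest first and each guide already
selected earns a discount of 0.5·F per reuse, which is the package's
concrete reading of the qualitative "reuse guides across regions"
objective. Terminal fragments extend one sub-region length beyond the
region boundary, clipped to the contig. To keep dense genomes tractable the
graph keeps at most `max_linkers_per_lsa` (default 50) linkers per LSA,
preferring the lowest combined guide off-target score, then the leftmost
start; linker *enumeration* itself is exhaustive.

## Fragmentation efficiency

At each designed linker, an alignment counts as **with-linker** if one read
end lies within ±tolerance of the matching linker boundary and the read
covers at least `linker length − tolerance` of the linker; it counts as
**spanning** if it contiguously covers the linker plus tolerance on both
sides. The tolerance default is 50 bp, sized for nanopore end trimming and
adapter remnants. Each read counts at most once per linker. The formation
ratio is `r = with/(with + spanning)`; terminal fragments take `100·r` of
their single flanking linker and interior fragments `100·r_left·r_right`
("linker generation on both ends"). This composition reproduces the
published six-linker phage benchmark table exactly at printed rounding,
which is the formula's acceptance oracle in the test suite.

Depth for enrichment profiles is computed from alignment reference
intervals (deletions covered, insertions ignored). Each region body and
each flank (default 20 kbp) is scaled to 100 bins; bin edges are rounded to
whole bases, so regions shorter than 100 bp degrade to fractional-width
bins sharing bases. Fold enrichment = mean per-base depth over region
bodies / genome-wide mean depth.

## Reference-based phasing

Pileup columns count alleles from bases with quality ≥ 10; a quality-failing
base still counts toward the column total `n`, so the coverage condition
below doubles as a quality guard (the upstream description is silent on
this; counting failures in `n` is the conservative reading). Insertions are
keyed at their anchor base together with the inserted sequence — two
distinct inserted strings are distinct alleles; deletions are a distinct
allele at every deleted position.

A site with top-two allele counts `n1 ≥ n2` is heterozygous iff

1. `n1 + n2 ≥ 10`,
2. `n1 + n2 ≥ n/2` (real division), and
3. `n1 ≤ 2·n2` and `n2 ≤ 2·n1`.

Variants inside runs of ≥ 5 consecutive copies of a 1-bp or 2-bp unit
(homopolymers ≥ 5 bp, dinucleotide repeats ≥ 10 bp) are removed before
phasing; a doubled base is treated as a 1-bp unit, not a 2-bp one.

Reads vote allele co-occurrence edges; pairs with total weight ≥ 10 get a
two-sided Fisher's exact test (scipy). Significant pairs (p < 0.05) are cis
when `w11 > w12` and trans when `w11 < w12`; an exact tie yields no
orientation. Per site, its pair p-values are Bonferroni-corrected within
the site's own family (multiplied by the number of tests involving that
site, capped at 1) and the site is dropped iff fewer than one-third are
significant — exactly one-third retains. Surviving cis/trans constraints
are 2-colored with a parity union-find, applied in decreasing total-weight
order so a conflicting weaker constraint loses (conflicts are counted and
reported); each connected component becomes a phase block, canonicalized so
its leftmost site carries allele 1 on haplotype 1. Output is therefore
unique up to a global swap per block, and the comparison metrics
(`compare_haplotypes`) score matches under the best global swap and count
switch errors as adjacent shared-site pairs whose relative orientation
flips.

## De novo phasing

Designed guides (protospacer+PAM, 23-mers) are searched in the first and
last 500 bp of each read (whole read if shorter; overlapping windows report
a match once) in both orientations at edit distance ≤ 4, as infix matches
with free end gaps on the read side. Reads matching either guide of a
linker join that linker's group; the extracted part spans the match ±
(linker length + 200 bp), oriented to the genome-forward strand using the
matched orientation and the guide's design strand. The 200-bp margin is a
configuration choice — large enough to carry flanking context for anchoring,
small enough to keep the consensus local to the linker.

Consensus: parts are overlap-aligned to the longest part (center-star) and
each center column is voted by majority (ties break lexicographically,
A < C < G < T, gap and insertion last); columns whose two most frequent
alleles total < 30 supporting reads are masked; gap-majority columns drop
out and majority insertions are spliced in after their anchor. Reads from
both haplotypes enter one consensus, so at a true het site the consensus
carries whichever allele wins the vote — the disagreement re-appears as a
called het when the parts are realigned, which is exactly what the phasing
stage consumes. Realigned parts are piled up, het-called, repeat-filtered
and graph-phased with the same thresholds as the reference-based engine,
on (linker id, consensus position) coordinates; parts of one source read
share its read id, so a read touching two linkers phases them together.
Consensuses with fewer than 50 unmasked columns are skipped with a warning.

## Simulator

`make_diploid_genome` plants heterozygous SNVs (default 1e-3/bp) and
1–5-bp indels (default 1e-4/bp) on a uniform-composition random reference,
each alt allele assigned to haplotype 1 or 2 by fair coin; variants closer
than 12 bp are thinned so alleles never overlap. Piecewise offset maps
convert reference to haplotype coordinates.

`simulate_linked_fragments` draws molecules covering the panel span plus a
2-kbp overhang beyond the outermost linkers (so molecule ends never sit
within classification tolerance of a linker boundary), one full molecule
per unit of configured depth, haplotype by fair coin. Each selected linker
fires independently; a fired linker cuts the molecule with the *full*
linker sequence duplicated onto both flanking fragments, a non-fired linker
leaves it contiguous. One read per fragment is emitted, in a random
orientation, with Gaussian end jitter (default off; 10 bp in the validation
studies).

The firing parameter is deliberately the **observable read-space formation
ratio** `e`, not the molecular nicking probability: a fired linker yields
two linker-terminated reads while an unfired one yields a single spanning
read, so molecule-level firing at probability `p` produces an expected
formation ratio `2p/(1+p)`. The generator therefore fires at
`p = e/(2−e)`, making the efficiency module's estimator converge to the
configured `e` and keeping the parameter directly comparable to the
published efficiency tables. Per-guide nick efficiencies are not separately
identifiable from read data (reads observe only linker formation), so a
single Bernoulli event per linker is modeled.

Background reads model residual off-target molecules that escape the
5′-dephosphorylation / 3′-blocking suppression: a Poisson count at
`background_rate` reads per kbp of off-target genome, log-normal lengths
(median 8 kbp, σ = 0.5, a typical nanopore library shape), clipped to
their off-target interval. Errors are iid per-base substitutions,
insertions and deletions; error bases get Phred 5 against a baseline of 30,
so the phasing quality filter (≥ 10) can suppress them — this models the
fact that basecallers flag most errors with low confidence, and it is the
reason error rates well above the simulated 0.5% would degrade phasing
less than linearly. Everything is deterministic given the seed; identical
seeds produce byte-identical FASTQ.

`expected_enrichment_fold` computes the fold the study conditions imply:
body depth equals the molecule count; the baseline adds on-target bases
(including one extra linker copy per expected firing) and expected
background bases using the exact expectation of the boundary-clipped
log-normal length (trapezoid integration of the survival function; the
only neglected effect is sub-percent).

## Validation studies and their scope

`lambda_style_design` designs on a 48.5-kbp random linear molecule with the
model-genome preset (linkers 50–250 bp) at a 9.3-kbp fragment target and a
gap window of 8.2–10.6 kbp; with ~46.5 kbp between the first and last
sub-region, only five interior hops fit the window, so the panel has
exactly six linkers and seven fragments — the geometry of the published
phage model system — without depending on the seed.

`roundtrip_study` runs the full loop on a 200-kbp diploid locus: a 110-kbp
target designed at default (15-kbp) scale giving ~10 linkers, 50 molecules
(50× body depth), formation ratio 0.9, 0.5% read errors (half
substitutions, quarter insertions, quarter deletions), 10-bp end jitter and
one background read per kbp off-target. It checks that per-linker
formation-ratio estimates fall within the 3σ binomial band of the planted
value, that reference-based and de novo phasing recover the planted
haplotypes with zero switch errors, and that the measured enrichment fold
is within 10% of the planted expectation. These sizes keep the whole study
around a minute on one CPU while leaving ~90 informative reads per linker
and ~170 phased sites, enough for the bands to be meaningful.

What passing these studies does **not** show: performance on real nanopore
error profiles (errors here are iid and quality-labelled; real errors are
context-dependent and miscalibrated), on repetitive or structurally variant
genomes (the random reference makes uniqueness filters nearly vacuous), on
chimeric or adapter-contaminated reads, or at the whole-genome design scale
where off-target seed counts are large and the candidate cap matters.

## Known limitations

* PAF input carries no bases/qualities, so it serves interval analyses
  (efficiency, enrichment) but is rejected for phasing with a capability
  error; SAM with SEQ/QUAL is required there.
* The de novo consensus is quality-blind majority voting; quality-aware
  weighting would improve it at low support.
* Coordinate maps near planted indels are approximate within the indel's
  own span (a few bp), which only perturbs jittered fragment ends.
* The deterministic operation-order tie-break of `semiglobal_align` is
  guaranteed for desk-scale problems (≤ ~4·10⁶ DP cells); larger alignments
  take the engine's deterministic path, which may order ops differently at
  equal cost.
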