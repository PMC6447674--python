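# Methods

This note documents the models and procedures behind `chromostruct`, the
assumptions they make, the parameters that matter, and the design choices
taken where the problem admitted more than one reasonable answer.

## Coordinates and formats

All internal coordinates are 0-based half-open. The two 1-based-inclusive
dialects the pipeline consumes — AGP v2.1 rows and the nucmer
`show-coords -T -H -l` tab layout — are converted at the I/O boundary only.
Alignment strand is carried on the query interval (the reference is always
forward, matching show-coords semantics); reverse-strand records store the
query interval forward with a strand flag. Marker tables have no standard
format, so the reader takes a column-mapping dialect (`MarkerDialect`) as part
of the public interface; published linkage maps vary too much for a fixed
layout.

N50 is the length of the smallest contig in the minimal set of longest contigs
whose sum reaches half the assembly; L50 is that set's size; NG50/LG50 use
half of an estimated genome size instead. Ties resolve by taking the minimal
count, the standard convention.

## Misassembly detection

A contig is a chimera candidate when its markers split across two or more
linkage groups, each supported by at least `min_markers_per_lg` markers
(default 1 — single-marker signals are kept visible and dealt with by the
repeat filter rather than discarded upfront). Partitions are ordered by median
marker position; the junction search interval runs from the last marker of one
partition to the first of the next.

Breakpoint refinement is deterministic where manual inspection would have
been used on real data: the breakpoint is the argmin of read depth inside the
search interval, accepted when that depth is ≤ `dip_fraction` (0.5) of the
contig-median depth; otherwise a zero run of mate-pair clone coverage of
≥ `min_clone_gap` (1 kbp) overlapping the interval places the break at the
run midpoint. Depth wins over clone coverage when both fire because it is the
sharper signal. If neither fires the candidate stays unresolved, gets the
interval midpoint as a flagged fallback, and is not broken by default.
These thresholds are exposed as configuration, not constants: they stand in
for a judgment call that real analyses make with more evidence types.

The repeat filter downgrades a candidate to `repeat_false_signal` only when
*every* marker of every minority partition lies in an annotated repeat or has
a non-unique placement flag; mixed evidence keeps the candidate (conservative
in the direction of inspecting too many rather than breaking too few).

Alignment-based detection (for intra-chromosomal joins linkage maps cannot
see) flags consecutive blocks that switch reference chromosome, jump more
than `max_jump` (2 Mbp) on the reference, or violate within-strand
monotonicity. A clean strand flip with locally consistent coordinates is a
species-level inversion, not a misassembly, and is deliberately not flagged.

## Anchoring

Assignment is a majority vote of unique-placement markers per contig; exact
ties leave the contig unanchored rather than guessing. The order key is the
median (not mean) cM of the winning group's markers — robust to a single
stray marker. Orientation is the sign of Kendall's τ between marker bp offset
and cM; a single occupied cM bin (markers co-segregating) gives '?', placed
as '+' but counted as unoriented. Within a cM bin, contig order ties break
lexicographically by contig id so runs are reproducible; F2 maps have many
co-segregating markers, so this tie-break is exercised constantly.

Gap length between anchored contigs is 100 bp. Unanchored contigs are
emitted as standalone AGP objects.

Multi-map integration copies each linkage group's component list from one
selected map. Selection is either explicit (the real analyses chose maps per
chromosome on a mixture of collinearity, size, and map-order evidence — a
composite judgment we expose as the manual override) or automatic by
collinearity score: the fraction of aligned bp in the maximum-weight strictly
increasing chain of synteny-block reference midpoints, orientation-agnostic
by default. A contig claimed by two selected groups stays where it has more
markers; the loss is logged. A sequential-chaining integration (concatenating
every map's anchoring) is known to anchor more bp less accurately and is
intentionally not implemented.

## Rearrangement calling and karyotypes

Alignment records below 10% identity or 5 kbp are dropped (mirroring the
filter settings used to produce such coordinate files); overlapping records
resolve one-to-one keeping the larger; same-pair same-strand records merge
when both coordinate gaps are ≤100 kbp and the diagonal is consistent.
Chaining never increases aligned bp and is idempotent.

Per query chromosome the primary reference is the one with the most aligned
bp. Another reference reaching `fusion_min_secondary_bp` (5 Mbp) is a fusion
partner when its blocks sit terminally on the query and a translocation when
they interleave inside the primary's span. No formal fusion/translocation
boundary exists in the source material; terminality is the testable surrogate
and is flagged as such in reports. Inversions are maximal runs of
minority-strand blocks on the primary reference spanning ≥ `inversion_min_bp`
(2 Mbp; a 6-Mbp preset matches the summary-figure convention). Using the
minority strand rather than '-' makes the call invariant to the arbitrary
polarity of the query chromosome — with the corollary that inversions
covering more than half a chromosome's alignment are reported relative to the
flipped polarity.

Centromeres are the largest cluster of named satellite families (ONSATA and
TZSAT by default; consensus sequences are not embedded — annotation is
input), merging hits closer than 500 kbp. A call is ambiguous when two
clusters each hold ≥25% of the chromosome's satellite bp and lie >5 Mbp
apart. The centromere point is the cluster midpoint (a bp-weighted centroid
is available by configuration; the two differ negligibly for compact
clusters). Karyotype classes follow the Levan arm-ratio convention with a
1-bp short-arm floor so terminal centromeres classify as acrocentric, and the
classification is mirror-invariant. Repositioning is reported when homologous
chromosomes fall in different class *groups* (meta/submetacentric vs
subtelo/acrocentric); finer within-group changes are below the resolution
this evidence supports.

## Recombination

The Marey-map smoother is locally weighted quadratic regression: at each grid
point the `ceil(span·n)` nearest markers are fit with a degree-2 polynomial
under tri-cube weights, and the fitted value is read at the point. Degree 2
(the convention of the plotting routine such curves usually come from) makes
the smoother exact on quadratic Marey maps, which the tests exploit; an
independent cross-check against R's `loess` (degree 2, direct surface) agrees
to <0.05 cM on a 60-cM chromosome. Defaults: span 0.17, grid interval
0.1 Mbp. The rate is the central finite difference of the fitted curve in
cM/Mbp, clipped at zero for reporting (cM is physically nondecreasing;
negative fitted slopes are smoothing artifacts) with the raw derivative
retained.

Suppression regions — candidate inversions heterozygous in some crosses —
are grid runs of ≥ `min_length` (5 Mbp) where at least one cross's rate is
≤0.1 cM/Mbp while another's is ≥1.0. Suppression shared by every cross is
indistinguishable from the common landscape and is not called. Because the
smoothed rate crosses the 0.1 threshold well inside a true zero-recombination
interval (the smoother bleeds the neighboring slope inward over roughly half
its window), run boundaries are refined to the extent of the suppressed
crosses' flat cM plateau (fitted cM within 1 cM of the run median,
intersected across suppressed crosses). On simulated 15-Mbp intervals this
raises boundary recovery from ~70% to ~95% reciprocal overlap. Runs within
`min_length/2` of a chromosome end are annotated `terminal`: low
recombination at chromosome ends is the genome-wide norm in these fish, so
terminal runs are not inversion candidates.

LD is the squared Pearson correlation of allele dosages over individuals
non-missing at both loci, with monomorphic loci skipped and r² > 0.97
flagged (the reporting threshold used for such plots). No phasing or pedigree
correction is applied; how the original pedigree-based computation handled
founders is not recoverable, and dosage r² is the reproducible baseline.

## TE landscape and context

Landscape fractions are per (repeat class, 1% divergence bin), as a
percentage of total assembly size including gaps. Overlapping same-class
annotations are merged before summation (first-covering annotation claims the
bp; processing order is (start, divergence), deterministic), so the landscape
total times genome size equals the merged repeat bp. Divergence is taken from
the annotation input, never recomputed — divergence calculation belongs to
the repeat-masking step upstream.

Genic context assigns each insertion to exactly one of promoter, exon,
intron, intergenic, in that precedence, by any-overlap (≥1 bp); whether the
original counts used midpoints or any-overlap is not stated anywhere, so the
choice is recorded in the output metadata. Promoters are strand-aware windows
(1 kbp or 15 kbp) upstream of the transcription start, exclusive of the gene
body. Counts are of annotations, not bp.

## Synthetic data: what it emulates and what it does not

The generator produces, deterministically per (config, seed): chromosomes
with one satellite array at a configured centromere fraction (default 0.1 —
a mostly subtelo-acrocentric karyotype, as in these fish) and TE copies with
configurable divergence distributions; fragmentation into contigs (uniform
fragment lengths in [0.5, 1.5]×target N50) with planted cross-chromosome
chimeras; F2 intercross maps; diverged genome pairs whose alignment records
are synthesized directly from the planted event coordinates (no aligner run —
this keeps the test surface deterministic and download-free; the coordinate
reader is exercised separately on real-format fixtures); and evidence tracks
(Poisson read depth with a ≥50% dip of ≤2 kbp at each chimera junction;
clone coverage zero over a 40-kbp window there, the span of a long-insert
jumping library).

Cross simulation samples recombinant counts between adjacent markers from
Binomial(2·n_F2, r) — two informative meioses per F2 — and inverts the
mapping function on the observed fraction. Kosambi is the default mapping
function (the common default in fish linkage mapping; Haldane is available).
The along-chromosome crossover density is uniform or sigmoidal (low within
5 Mbp of each end, the typical pattern in these genomes); suppressed
intervals have their density zeroed without redistribution, as in an
inversion heterozygote, so markers inside co-segregate exactly. Sex-specific
maps scale the density by a configured female:male ratio around the
sex-averaged landscape.

What the generator does *not* model: sequence-level mutation (alignment
identities are drawn, not computed), read-level noise (no FASTQ), map errors
other than sampling noise (no genotyping error or marker misplacement),
repeat-driven mis-mapping, and demographic realism. Passing the truth-recovery
tests therefore demonstrates the algorithms' correctness under clean,
well-powered conditions — marker densities of one per ~100 kbp and crosses of
hundreds of F2 — not robustness to the messier failure modes of real maps
(those are what the repeat filter, unresolved statuses, and conservative
tie-breaks are for, and they are tested on constructed edge cases instead).

## Problem sizes used in the packaged checks

The packaged acceptance checks run the chimera pipeline on five replicate
200-Mbp, 10-chromosome genomes with 20 planted chimeras each; the anchoring
round trip on a 75-Mbp three-chromosome genome at 400 markers per chromosome;
rearrangement recovery on a 213-Mbp seven-chromosome genome with two fusions
and three 7–9-Mbp inversions; and suppression recovery on a 32-Mbp chromosome
(roughly the size of the chromosome carrying the motivating 15-Mbp inversion)
across ten planted and ten control replicates. These sizes keep the full
suite to well under a minute of simulation while leaving every rate estimate
based on ≥100 planted events or ≥10 replicates.

## Known limitations

- Multi-junction chimeras are detected as one candidate with several
  junctions, but evidence-track refinement treats junctions independently;
  closely spaced junctions (< the clone span) can shadow each other.
- The fusion/translocation terminality rule misclassifies a fusion whose
  partner later inverted across the fusion point.
- The collinearity score is O(n²) in block count; for whole-genome block
  lists beyond ~10⁴ blocks a patience-sorting implementation would be needed.
- `integrate_maps` trusts each input anchoring's internal order; it does not
  re-order across maps within a linkage group.
- LD r² on an F2 pedigree reflects cross structure, not population LD; it is
  intended for the within-cross comparisons the pipeline makes.
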