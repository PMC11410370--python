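# Methods

## Coordinate and naming conventions

All internal coordinates are 0-based half-open; GTF input (1-based
inclusive) is converted at the I/O boundary and restored on write.  The TSS
of a minus-strand transcript is `end − 1` (the biological 5' base) and the
transcription end is `start`.  Chromosome names are matched as exact
strings — no "chr"-prefix aliasing, so namespace mismatches surface as
empty results or errors rather than silent misjoins.  bedGraph is the
coverage interchange format throughout (binary bigWig is out of scope);
records are resampled onto fixed bins by coverage-weighted averaging with
uncovered base pairs contributing zero.

## Interval statistics

**Jaccard.**  Computed on merged interval sets (overlapping *and*
bookended intervals merge — base-pair set semantics), as intersection bp /
union bp.  Symmetric in its arguments; the pair count
(`n_overlapping_pairs`) is reported for the first argument against the
merged second.

**Relative distance.**  Queries are reduced to midpoints
`floor((start+end)/2)`; reference points are the TSS for promoters, the CDS
midpoint for ORFs, and the 3' end for termination sites.  Queries outside
the outermost references on their chromosome are dropped (there is no
defined flanking span) and counted.  The histogram uses bins of width 0.02
by default.  Under spatial independence the statistic is uniform on
[0, 0.5]; at 10⁴ queries the inherent multinomial noise of 25 bins gives an
expected max−min bin-frequency range of ≈0.007, so the "flat null" check
is a ~0.01-scale bound, not an exact identity.  Integer coordinates also
quantize the statistic: with reference spacing *s* only multiples of 1/*s*
are attainable, so the suite uses spacing 1000 to keep bins uniformly
populated.

**Peak classification.**  A peak is `TSS` when it contains any
transcript's TSS coordinate, else `gene_body` when it overlaps any
transcript span, else `intergenic`; each peak is also assigned its
closest-TSS gene (ties break to the lexicographically smaller gene id).
Percentages are reported with round-half-away-from-zero.

**Fisher's exact test.**  The headline statistic is the sample odds ratio
`n₁₁n₂₂/(n₁₂n₂₁)`, reported as +∞ when the denominator is zero with a
positive numerator (matching the "Infinite" convention used when a
contingency cell is empty) and NaN with p = 1 for degenerate (zero-margin)
tables.  Two-sided p-values are the standard sum of hypergeometric point
probabilities not exceeding the observed table's, computed via
scipy.stats; the conditional-MLE odds ratio is exposed separately.  An
exhaustive enumeration oracle in the test suite confirms agreement for
every 2×2 table with total ≤ 30.

**Genome-wide overlap enrichment.**  The 2×2 table counts merged intervals
of each set that do or do not overlap the other; the no/no cell is
estimated as `genome_size / mean_interval_width` minus the other three
cells.  *This slot construction is a descriptive heuristic and is biased
under the null*: slots are one interval wide while co-overlap of two
intervals requires ~two widths, so independent sparse sets yield sample
ORs concentrated near 2 rather than 1.  Treat these ORs as rankings of
association strength, not calibrated effect sizes; permutation nulls are
deliberately out of scope.

## Motif scanning

The shipped catalog holds the six published OVO-binding consensus motifs
(`TAACGGTAAA`, `RWMTAACGGV`, `TAACTGTTTT`, `TTACSGTAA`, `AGTAACNGT`,
`TGTAACNGT`), all sharing the `TAACNGT` core.  Default scanning is exact
IUPAC class matching (the motifs are published as consensus strings, not
matrices); `N` in a *sequence* matches nothing.  Minus-strand hits are
found by scanning the reverse-complemented motif and reported in forward
coordinates; overlapping hits are all kept, since downstream use is
presence/absence per peak or promoter.

PWM mode scores windows by log₂ likelihood ratio against a zero-order
background (uniform by default, configurable).  The null score
distribution is computed exactly by position-wise convolution on a
discretized grid (1/1000 of the finite score range; words containing a
zero-probability base carry −∞ and drop out of the live mass).  The
threshold for significance level α is the smallest grid score whose tail
probability is ≤ α; when α is below the single best word's probability the
best-word score is used with a warning — this is why a 4-bp exact-match
word (p = 4⁻⁴ ≈ 0.0039) cannot pass α = 0.003 while a 5-bp word
(4⁻⁵ ≈ 0.001) can.  Window scores use the same discretized grid as the
threshold, so the comparison is self-consistent; the discretization error
is bounded by the grid step times motif length.

The mask-and-rescan procedure reports, for each catalog motif in priority
order, the fraction of still-unexplained peaks containing it, then removes
those peaks — reproducing the iterative remove-and-resubmit motif
follow-up on the presence matrix alone (de novo discovery itself is out of
scope; the catalog is an input).

## CAGE TSS calling

Tags are aggregated per (chromosome, position, strand) and normalized as
simple tags-per-million.  CTSS below the 1-TPM floor are discarded before
clustering.  Two clustering modes:

- **distclu** (default): same-strand CTSS within ≤ 20 bp merge
  transitively.  The 20 bp gap is the stated distance parameter of the
  original toolchain call; that call names the paraclu method while
  passing a distance-clustering parameter, so both are implemented and the
  distance mode with the printed parameter is the default.
- **paraclu**: recursive maximal-density segmentation.  For a segment,
  `max_density` = total weight / span (span = last − first + 1); the break
  point is the proper prefix or suffix of minimal density, where a prefix
  `[i..k]`'s density is its weight divided by the distance to the next
  retained site (`pos[k+1] − pos[i]`); that minimal density is the
  segment's `min_density` and the segment is reported only when its
  maximality interval is non-empty (its break density exceeds the
  enclosing segment's).  A single position is reported with
  `max_density` = its weight and `min_density` = 0 (sentinel).  Reported
  clusters are post-filtered to ≤ 500 bp and non-overlapping (highest
  max_density wins).  A brute-force enumeration over all density
  thresholds confirms the recursion for ≤ 10 positions.

Singleton clusters are removed unless their **raw tag count** (not TPM) is
at least the keep-singletons floor (default 5), following the tag-count
semantics of the original parameter.  The dominant TSS is the member
position of maximal TPM, ties breaking to the 5'-most position relative to
the strand.  Promoter windows are `[pos−flank, pos+flank+1)` with the
sequence oriented 5'→3' so index `flank` is the TSS base; the source
analyses state 200 nt in their protocol text and 150 nt in one results
passage — flank is a parameter with default 200.

## Core-promoter architecture

The element catalog is configuration with defaults transcribed from the
fly core-promoter literature: TATA `STATAWAWR`, initiator `TCAKTY`, MTE
`CSARCSSAACGS`, DPE `KCGGTTSK`, M1BP/Ohler-1 `GGTCACACTG` — all scanned
sense-strand only, plus the OVO motifs on both strands.  The exact
matrices and backgrounds behind the original scans are not published, so
these consensus defaults are swappable and the per-element enrichment
machinery is generic over any two promoter classes (bound vs unbound,
tissue vs tissue).  Positional histograms report the percent of promoters
with ≥ 1 hit per offset bin relative to the dominant TSS; per-element
enrichment is Fisher's exact test on presence counts, with optional
Bonferroni correction (off by default, matching per-element reporting).

## Coverage metaprofiles

BPM normalization scales bins to sum to 10⁶; subtraction is per-bin
chip − input with negatives kept (no clipping, no pseudocount).  Replicate
pooling, when needed, is a documented pre-step (sum raw tracks, then BPM).
Reference-point matrices average per-bp signal into 25 bp columns over
±2 kb; minus-strand rows are reversed so columns always run 5'→3' along
the feature, and off-contig bins are zero.  Scale-regions mode linearly
rescales each region (whole span, or exon-concatenated "metagene"
coordinates, the default) onto 4000/25 columns via interpolation of the
cumulative signal — regions the size of the body reproduce their binned
signal exactly.  Heatmap row order is descending by row max (ties by row
id); profiles are column means.  Matrix construction is verified against
a naive per-position oracle.

## ChIP × RNA integration

The expressed-gene universe is the rows of the DE table (genes with zero
detectable expression are excluded upstream).  Thresholds are strict:
`up` ⇔ log2FC > 0.5 and p-adj < 0.05; missing p-adj is never significant.
A gene is `bound_at_tss` when any consensus peak contains any of its
transcripts' TSS coordinates and `bound_any` when a peak overlaps any
transcript span (interpreting "overlapped a peak" as any-span overlap —
flagged as an interpretation).  All enrichments are Fisher tables over the
universe; the target report lists bound-at-TSS ∧ up genes sorted by
log2FC.  The published marginal counts (10,804 expressed; 2,298 bound;
1,994 up; 2,924 down; 666 and 564 bound∧regulated; 1,409/625/3,448
embryo-listed) are recorded as inputs in `study_tables` so the printed
odds ratios (2.21, 0.85, 2.8, 0.17) are recomputed, not transcribed.  Note
the published classification counts 1394+1339+366 total 3,099 against the
stated 3,094 consensus peaks; the percentage arithmetic (45/43/12) is
unaffected.

## Synthetic data: what it emulates and what it does not

Defaults are the study conditions wherever one is stated: replicate
bp-Jaccard 0.64, ~45% of peaks centered on TSSs, 72% of consensus peaks
carrying a planted motif, bound × up OR 2.21 (secondary: bound × down
0.85, up × embryo-list 2.8, and the up/down/embryo marginal fractions of
the 10,804-gene universe).  Where no value is stated, desk-scale choices
are made once: a 1.2 Mb two-chromosome genome at GC 0.43 (fly-like), 300
non-overlapping genes of 0.8–3 kb with 1–4 exons and ≥ 500 bp spacing, 250
peaks of mean width 300 bp with ±50 bp TSS jitter, 50 CAGE tags/gene at
±5 bp spread, ChIP enrichment 5× over |N(1, 0.25)| input noise, DE effect
|log2FC| = 1.  These sizes keep a full bundle under ~6 s while leaving
every statistic estimable.

Replicate 2 retains whole replicate-1 intervals with fraction
`f = 2J/(1+J)` of the base pairs and adds independent peaks of equal bp so
the realized Jaccard lands on the target (±0.05, else an error); realized
values, planted motif placements, and the realized post-threshold
contingency tables are recorded in `truth.yaml`, and downstream estimates
are tested against the *realized* values.  Up/down/list status is drawn
per gene with Bernoulli rates solved (bisection) so the expected sample OR
equals the planted OR at the given marginals; any OR > 0 is feasible for
marginals strictly inside (0, 1), so the infeasibility error concerns
boundary marginals.  With effect 0 the regulated genes' log2FC is
N(0, 0.2), leaving ~1.2% tail mass beyond the 0.5 cutoff — "no DE calls"
holds only approximately.  Sub-seeds derive from the master seed by stable
stage-name hashing, making each stage independently reproducible and the
whole bundle byte-identical for a fixed config.

Deliberately not modeled: read-level data (FASTQ/alignment), fragment-size
effects, chromatin-state structure, correlated peak widths/heights,
realistic p-adj distributions (p-adj is simulated around the threshold,
not derived from counts — the integration stage only consumes thresholds),
and genome-build differences.  Passing tests therefore demonstrate the
*statistical machinery* recovers planted structure, not that the generator
reproduces real sequencing noise.

## Problem sizes in tests and acceptance

The suite validates oracles exhaustively where cheap (all 2×2 tables with
total ≤ 30; all 4^L words for L ≤ 8; all paraclu segments for ≤ 10 sites)
and statistically elsewhere (100-replicate OR recovery at 3,000 genes;
10⁴-query relative-distance null; one shared default bundle).  The
acceptance script runs the published-count statistics, two fresh bundles,
a 10-replicate OR recovery at the full 10,804-gene marginals, and the
closed-form threshold probabilities — a few seconds end to end.
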