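# Methods

This note records the models, conventions and numerical choices behind
dipeval, and what its synthetic-data tests do and do not demonstrate.
Coordinates are 0-based half-open everywhere; sequences are uppercase
ACGTN.

## The synthetic trio model (`synthio`)

The generator produces a parent–parent–child trio from a single ancestral
sequence drawn i.i.d. uniform over ACGT. GC skew, repeat families and
mutation-rate heterogeneity are deliberately not modeled: the consumers of
these sequences are k-mer, interval and alignment algorithms whose
correctness does not depend on base composition, and uniform sequence
maximizes k-mer uniqueness, which makes truth bookkeeping exact.

Each of the four parental haplotypes mutates the ancestor independently at
**half** the configured per-class rate. Two haplotypes from different
parents then differ at approximately the configured rate, so `snv_rate`
reads directly as the expected SNV heterozygosity between the child's
haplotypes (0.001 → 0.1%). Realized counts are binomial; tests accept
±3 SD. Variant classes:

* SNVs: uniform among the three non-reference bases.
* Small indels: geometric lengths with mean 3 bp, capped at 49 bp,
  insertion/deletion with equal probability.
* SVs: uniform 50–5,000 bp, types insertion/deletion/inversion. The
  50-bp boundary is the small/large threshold used by every downstream
  catalog, so the generator exercises both sides of it.

Overlapping or adjacent events on one haplotype are dropped, not merged,
and events keep clear of chromosome ends by k plus the maximum event span
so that k-mer windows and VCF anchoring are always well-defined. Each
child haplotype is a recombinant of one parent's two haplotypes with a
configurable number of crossovers (default 1, positions uniform); a
variant truncated by a crossover is dropped from the child's truth list.

Truth is stored as per-haplotype variant lists in ancestor coordinates.
`child_truth_vcf` merges the two child lists into phased records
(paternal allele first) after passing every allele through the same
left-normalization used by the caller, which is what makes the round-trip
comparison exact rather than approximately equal.

Long reads model the HiFi regime: lengths normal with SD 10% of the mean
(default 15 kb), starts uniform, half the reads reverse-complemented,
errors 90% substitutions / 10% single-base indels at the configured rate.
`coverage` is depth over the supplied sequence set, so passing both child
haplotypes at coverage 30 yields a 30× diploid read set. Read origins are
embedded in the read name after the reserved token `dipeval_truth`, so a
FASTQ written to disk still carries its truth. Short parental reads reuse
the same machinery with fixed length and no length variance.

Optical molecules sample intervals ≥ 150 kb (exponential tail, mean near
the 293-kb N50 of real DLE1 molecule sets), take the true digestion sites
of the interval, and then corrupt them: Gaussian sizing noise with SD =
`sizing_cv` × interval length applied to inter-label intervals, labels
dropped independently at `fn_rate`, spurious labels added binomially at
`fp_rate` per true label. Reverse-strand molecules mirror label positions
by molecule coordinates, which offsets site starts by up to the motif
length; the aligner searches both orientations, so this convention is
internal only.

Coverage tracks are Normal(mean_depth, noise_sd) per bin (default 1 kb),
multiplied by copy number inside implanted collapse intervals, clipped at
zero.

## k-mer machinery (`kmerset`)

k-mers are packed 2 bits/base into `uint64` (k ≤ 31). With A<C<G<T the
numeric minimum of the forward and reverse-complement codes is exactly
the lexicographically smaller string, so canonicalization is a vectorized
`minimum`. Counting is exact — no sketches — because the test strategy
depends on set identities; large inputs are processed in ~32-Mb chunks
and merged by sort + segmented reduction. k-mers containing N are
skipped, consistent with treating N runs as gaps. k defaults to 21 and
must be odd (a k-mer can then never equal its own reverse complement).

Hapmer extraction requires count ≥ `reliable_min` (default 2) in both the
specific parent and the child, which removes singleton sequencing-error
k-mers. When parental k-mers come from error-free genome sequences rather
than reads, `reliable_min=1` is appropriate and used by the simulation
tests. The QV report keeps `k_err = 0` distinct from a numeric QV via an
`infinite` flag plus a sentinel value (999), never a silently huge float.

False duplication compares each distinct assembly k-mer's copy number
with `round(read_count / haploid_peak)` floored at 1 (so consensus-error
k-mers with zero read support are not miscounted as duplications); each
excess instance stands in for one duplicated base. The accounting is
instance-based — whether the upstream convention counts instances or
distinct k-mers is not documented, so this choice is stated here. The
haploid peak may be given directly; the estimator takes the
lowest-multiplicity local maximum of the spectrum above `reliable_min`,
because in a diploid read set the global mode is the 2-copy (homozygous)
peak whenever heterozygosity is low.

## Read and pair binning (`triobin`)

A read goes to the parent with strictly more hapmer hits, provided that
count reaches `min_hits` (default 2 — a single marker hit is within reach
of one sequencing error). Exact ties are never broken arbitrarily: they
stay UNKNOWN and `split_unknowns` divides them into two equal seeded
halves, preserving auditability. Hit counts are not normalized by hapmer
set size; with parental marker sets of similar cardinality (the synthetic
and the typical real situation) normalization would not change decisions,
and the unnormalized counts are reported per read. Reads under 1 kb are
excluded and listed. Linked-pair filtering drops a pair when either mate
contains ≥ 1 other-haplotype marker — deliberately asymmetric (it only
ever removes contamination of one haplotype's pair set).

## Phase blocks (`phaseval`)

Markers are hapmer occurrences on the contig. Blocks are maximal
same-label runs; an opposite-label run of ≤ 100 markers spanning ≤ 20 kb
is a short-range switch counted inside the block, anything longer starts
a new block. These two tolerances are exposed because no printed value
fixes them; the defaults follow the established k-mer evaluator's
convention, and figures produced with other tolerances will differ. Block
extents cover marker positions only — unmarked terminal sequence
contributes nothing to block length, so the sum of block lengths is
bounded by assembly length. The switch rate is switches / adjacent marker
pairs over the whole track; with fewer than two markers it is reported as
0 with a `defined=False` flag rather than NaN. NG50 uses the standard
definition against a supplied G (3 Gb for human); when blocks cover less
than G/2 it is 0, not undefined.

## Continuity, telomeres, patching (`asmstats`)

Any run of ≥ 1 N splits a contig and counts fully toward `total_N`.
Telomere calls test the terminal 1-kb window of each end for coverage by
the repeat motif (forward at the 3'/q end, reverse complement at the
5'/p end) at a closed threshold of 0.4; window and threshold are
configurable since no authoritative values are printed.

Gap patching is conservative by construction: a gap is filled only when
exactly one donor candidate anchors both flanks (up to 10 kb each, edit
budget 1% per flank, found by edlib infix alignment in both donor
orientations) in consistent order. Two candidate placements — even from
the same donor — are a conflict and the gap is left alone, with the
conflict logged. The patch log records donor interval and orientation per
gap, and total-bp bookkeeping (donor insert minus N-run length per patch)
is asserted in tests.

## Collapse detection (`collapse`)

Depth statistics exclude zero-depth (gap) bins and trim the top and
bottom 1% before computing mean and SD, so the collapses being sought do
not inflate the threshold they are compared against. The threshold is
mean + 3 SD; runs may bridge a single sub-threshold bin (sizing noise
regularly produces isolated dips inside genuine collapses — whether the
original analysis merged such runs is unstated, so the choice is made
explicit here); surviving runs must reach 15 kb. The bin size defaults to
1 kb, also an undocumented-upstream choice. Repeat filtering drops
regions whose annotated-repeat overlap exceeds 75%, computed by exact
interval intersection against an input BED — repeat annotation itself is
an input, not something this package computes. Expandable sequence is
Σ length × depth / average coverage, the bp the collapse would occupy at
full copy number.

## Optical maps (`mapbin`)

Digestion places one label per motif occurrence on either strand,
collapsed to the forward-strand site start. Molecule-to-map alignment is
a dynamic program over label intervals: consecutive intervals match when
they agree within `sizing_tol` (default 10%) of the map interval; a step
may skip up to 4 labels on either side at 0.5 penalty per skipped label;
alignment is global in the molecule (leading/trailing skipped labels are
penalized) and local in the map. Score = matched labels − penalties;
confidence = score / molecule label count clamped to [0, 1]. The real
pipeline's "alignment confidence" is an undocumented internal of the
vendor aligner; this normalized score is a documented monotone stand-in,
and the binning tie window (10⁻²) applies to it. Molecules with < 9
labels are unalignable (the standard molecule filter), and alignments
below confidence 0.5 are rejected, which in practice excludes unrelated
molecules. Binning assigns each molecule to the higher-confidence parent;
ties and unaligned molecules are split into equal halves in seeded random
order.

The cross-check scans fixed windows (default 50 kb) where all four
parental haplotype maps are present. A window's allele is its label
pattern; two patterns are the same allele when label counts match and
every label sits within `sizing_tol` × window of its counterpart. At
windows where exactly one parent is heterozygous (A/B) and the other is
homozygous for the shared allele A, the child haplotype inherited from
the heterozygous parent is expected to carry B; if it carries A the
window is reported as a break and the child map is cut at the window
midpoint (break coordinates are not specified anywhere authoritative;
the midpoint is this package's choice). Limitation: a child that
legitimately inherited A from the heterozygous parent is indistinguishable
from a mis-binned one without child molecule evidence, and is broken too;
the synthetic acceptance fixtures construct the child so that expected-B
windows are genuinely B except at the implanted mis-binned loci.

## Variant benchmarking (`varbench`)

Haplotype-to-reference alignment is anchor-based: 31-mers unique in both
sequences are chained (longest colinear chain; anchors that overlap a
kept predecessor on a different diagonal are discarded), and edlib fills
inter-anchor gaps and sequence ends with global alignment. This assumes
desk-scale contigs that span their chromosome — the synthetic regime —
and is not a general-purpose aligner; contigs without anchors are
reported unaligned.

Calling follows the two-haplotype convention: per-haplotype edits
(per-base SNVs, anchored indels) are left-aligned and made parsimonious;
genotype position 1 is haplotype 1 (paternal by this package's
convention, configurable by argument order). Sites covered by both
haplotype alignments get phased genotypes and PASS; sites covered by
exactly one haplotype get filter GAP2 and the half-call is promoted to
homozygous (`1|.` → `1|1`). Confident regions are the intersection of the
two haplotypes' aligned intervals. No minimum contig length is imposed at
desk scale (real-data pipelines often ignore contigs < 10 kb).

Comparison is exact matching on normalized (chrom, pos, ref, alt) keys
within confident regions: TP requires genotype identity, an allele match
with genotype mismatch counts as FP.gt (and stays in query FP), truth
records without an allele match are FN. Haplotype-graph matching of
complex overlapping representations and the lenient FP.al category are
out of scope; exact normalized matching is sufficient for synthetic
acceptance because truth and calls share one normalizer. Metrics follow
the printed formulas: `Recall_ignoreGT = (TP + FP.gt)/TOTAL`,
`Recall = TP/TOTAL`, `QV_dip = −10·log10((SNP.FP + INDEL.FP)/(2·conf_bp))`,
with an explicit infinite-QV flag at zero FP, and optional strata
(e.g. segmental duplications) evaluated on region intersections and
complements.

## Haplotype diversity (`hetview`)

Hap1-vs-hap2 cataloging reuses the anchored aligner with hap2 as the
reference. Non-match ops separated by ≤ 20 bp of chance matches are
grouped; a group whose alt allele reverse-complement-matches its
reference span (≥ 50 bp both sides, ≤ 10% edit divergence, ≤ 20% size
difference) is one inversion record — chance matches at an inversion's
edges may trim its reported span by a few bases — and any other group
falls back to its constituent edits. Features more than half N are
excluded. Classification uses the 50-bp boundary: SNVs, small indels
(< 50 bp), SVs (≥ 50 bp). Swapping the haplotypes inverts
insertion/deletion polarity and preserves totals.

The heterozygosity percentage counts 1 bp per SNV, the length change per
indel/SV, and the span per inversion, over a caller-supplied genome size;
with an exclusion BED (e.g. centromeres) both numerator records and
denominator bp inside excluded regions are removed. Because the
denominator convention (assembly bp vs aligned bp) is ambiguous in
published summaries, `genome_bp` is an explicit argument rather than
something inferred.

Coding classification translates each gene's concatenated CDS before and
after the SNV (strand-aware, standard codon table); genes whose CDS
length is not a multiple of 3 are skipped and reported. Percentages are
reported to one decimal; the synonymous and non-synonymous percentages
may sum to 99.9–100.1 by rounding. The per-gene rollup flags genes whose
coding SNVs are exclusively non-synonymous; enrichment statistics are out
of scope.

Heteroplasmy screens per-site base counts (optionally stranded) for minor
alleles with frequency strictly above `min_frac` (default 1%, the
long-read error floor). Frequencies use the total of all counted bases at
the site; reported percentages are integer-rounded. Note that published
major/minor percentages for such sites need not sum to 100 when further
low-count bases are present in the denominator.

## Problem sizes and what the tests show

The test suite and acceptance script run entirely on synthetic data at
desk scale: trio round-trips on 80-kb chromosomes, optical-map fixtures
of a few Mb, and one full trio-binning simulation (one 5-Mb chromosome,
0.1% SNV heterozygosity, 30× of 15-kb reads at 0.1% error — ~300 Mb of
sequence, a few minutes on one CPU). These sizes were chosen so exact,
truth-aware assertions are feasible; the algorithms are vectorized and
scale linearly in sequence, but whole-genome human inputs are outside
what the tests demonstrate. Passing tests show the machinery is correct
under the simulator's assumptions — uniform base composition, independent
errors, clean digestion statistics. Real genomes add repeat structure
(which weakens unique-k-mer anchoring and makes k-mer markers sparser in
satellite arrays), error-profile structure, and reference-representation
ambiguity that exact variant matching does not resolve; conclusions about
real-data behavior should be drawn from the formulas and conventions,
which match the published ones, not from the synthetic accuracy numbers.
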