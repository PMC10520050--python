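# Methods

This note records the models, conventions, and design choices behind
`granulekit`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinates and annotations

All internal coordinates are 0-based half-open `[start, end)`. GFF3 is
1-based inclusive at the file boundary (converted on read/write); BED passes
through unchanged. One transcript model per gene is assumed. The
"5′UTR start" (`utr5_start`) marks the transcription-start side of a gene:
for a plus-strand gene the 0-based position of the 5′-most base, for a
minus-strand gene the exclusive end coordinate — with this convention the
1 kb promoter is `[s-1000, s)` on the plus strand and `[s, s+1000)` on the
minus strand, clipped at contig bounds. Genes lacking an annotated 5′UTR
fall back to the gene's 5′-most coordinate rather than being dropped.
Promoter derivation covers protein-coding genes, lincRNAs, and pseudogenes
by default; every operon member inherits the promoter of the operon's first
gene (the 5′-most member on the operon strand).

## Read processing

Reads are collapsed to unique sequences with occurrence counts
(N-containing reads dropped and tallied; other non-ACGT characters are an
error). Alignment is exact-match enumeration of every occurrence on both
strands via a seed-and-verify k-mer index (k = 12, linear-scan fallback for
shorter queries); a naive scan of every position is the test oracle on
desk-scale genomes. Reads with more than `max_hits` (default 1000)
locations are dropped entirely and tallied. `--best --strata`-style tie
handling is moot at zero mismatches and is not emulated.

Structural filtering is applied after genomic alignment using the genome's
own structural-RNA annotations (snRNA, snoRNA, tRNA, ncRNA; either strand):
a read with *any* structural-overlapping alignment moves, with all of its
alignments, to the structural partition. When structural loci are annotated
on the genome this single-pass design partitions reads identically to
pre-aligning against a separate structural reference, while keeping one
aligner and one coordinate system. The structural pre-filter is exact-match
(0 mismatches) like the genomic pass; this is configurable in principle but
not exposed, since the simulator draws structural reads from the genome
itself.

## Class calling

Rules are data (`ClassRule`), applied in the order piRNA → 22G → 26G; the
first match wins. The piRNA rule's uniqueness + sense + 5′T requirements
make genuine overlap with the G classes essentially impossible, so the
order is benign. The piRNA 5′-offset (0, 1, or 2) is measured on the
locus's annotated strand, offset 0 being the annotated 5′ end. The 26G
class is not pinned down as sharply in the literature as the other two; the
default here (25–27 nt, 5′ G, antisense to protein-coding exons, perfect
match) follows the class's name and typical usage, and every field of the
rule is overridable.

Weighting: a read of count *c* with *n* genomic locations carries *c*/*n*
per location, split equally among the eligible features there; where an
rRNA overlaps another feature at a location, the rRNA takes the entire
location weight (precedence applies among the features that are eligible
for the class, i.e. antisense for 22G). Locations overlapping no eligible
feature contribute nothing, so the per-read weight total equals *c* exactly
when every location lands on an eligible feature — true by construction for
unambiguously simulated reads, and asserted to 1e-9 relative in the
acceptance suite. Sequencing depth for RPM is the number of *reads* (raw
occurrences, not weights) with at least one genomic alignment after
structural filtering.

## Differential analysis

Per gene, a two-sample two-tailed t-test on replicate RPMs; fold change
from condition means with a pseudocount (default 0.5 RPM) to absorb zeros;
calls at |log₂FC| ≥ log₂(4) and p < 0.05 by default. Genes absent from a
replicate count as zero. Replicate-level testing is the default; pooling
replicates first (`aggregate`-style workflows) can be emulated by passing
single summed tables, but then no test is possible.

The default statistic is the pooled-variance (Student) t. At two replicates
per condition the Welch/Satterthwaite approximation is severely
conservative — measured type-I error ≈ 0.024 at nominal 0.05 on normal
null data — whereas the pooled test is exact under the equal-variance null
that the calibration simulation instantiates. Welch remains available
(`equal_var=False`) for settings with more replicates or clearly unequal
variances. Genes whose replicates are all identical produce a degenerate
t; their p is reported as 1 (no evidence) rather than NaN. No
multiple-testing correction is applied by default (calls are at raw p, as
is common for small-RNA four-fold screens); BH adjustment can be layered on
the returned p column if desired.

Gene-set enrichment is log₂ of (fraction of the DE list in the set) over
(fraction of the universe in the set), with a two-sided Fisher's exact p
(`scipy.stats.fisher_exact`; verified against brute-force hypergeometric
summation to ≲1e-15). The universe is the caller's choice — in the
pipeline, all genes appearing in the differential table. Empty DE lists or
sets give NaN enrichment with p = 1 rather than an error.

## Synthetic data: what it emulates, what it does not

The generator instantiates the study design the pipeline targets: two
conditions ("wildtype", "mutant") × two replicates; a 200 kb two-contig
genome with ~120 genes (some in operons, one with an embedded antisense
rRNA), 60 piRNA loci, structural RNAs, and transposons; a class mix of 30%
piRNA / 45% 22G / 10% 26G / 5% structural / 10% background; a 20-gene
depletion set whose 22G expectation is divided by 4 in the mutant; and
oxidation survival probabilities 0.95 (2′-O-methylated) / 0.05
(unmethylated), chosen to make oxidation enrichment unambiguous at 10⁴
reads.

Abundance model: per-gene log-normal baselines (σ = 0.5) shared across
conditions and replicates; per-library multinomial sampling; the mutant
depletion is applied by binomial thinning of the depleted genes' reads, so
the expected mutant/wild-type raw-count ratio is exactly 1/fold. The
type-I calibration uses a separate null generator with Gaussian replicate
noise around the log-normal baselines, under which the pooled t-test's
p-values are exactly uniform — so the calibration measures the test
implementation, not distributional slack. Real libraries add features none
of this models: sequencing error, adapter/ligation bias, UMI structure,
overdispersion beyond Poisson/multinomial, and annotation error. Passing
tests therefore demonstrate the correctness of the rules and statistics as
specified, not robustness to those artifacts.

"Unambiguous" read generation additionally verifies each drawn read against
its class template (piRNA reads must map uniquely; no occurrence of a
22G/26G read may touch a structural RNA; background reads start with C and
avoid all features) and redraws offenders, so classifier truth recovery of
100% is a meaningful consistency check of the generator and classifier
against the same written rules, via independent code paths (the generator
samples from annotation intervals; the classifier works from alignments).

### A note on depletion recovery

With the true depletion fold equal to the four-fold call threshold, the
log₂FC estimator is centered *at* the decision boundary — in fact slightly
above it after depth renormalization (the mutant library is smaller, so
RPM ratios are ≈ 0.27, log₂ ≈ −1.9) — so down-call recall is capped near
35–50% at any depth. Precision is 1.0 and the depleted set dominates the
down list (log₂ enrichment ≈ 3.3, Fisher p ≪ 10⁻⁶). Detecting a four-fold
effect *at* a four-fold threshold is a boundary experiment by construction;
real effects cross thresholds only when they exceed them.

## ChIP target calling

Peaks are inputs (peak calling is out of scope); the score column of BED
input is interpreted as −log₁₀ q by MACS2 convention. The q threshold is
strict (q < 0.1). Overlap is ≥ 1 bp against half-open intervals; a peak
overlapping two promoters supports both genes; a gene is a target only with
support in both replicates. The peak simulator confines each planted peak
to the part of the target's promoter not shared with non-target promoters;
genes whose promoter is entirely shared (operon members after the first)
are not individually resolvable, and `resolvable_target_genes` lists the
ones that are.

## Volumetry

The workflow mirrors confocal granule sizing: subtract the mean of a
background ROI (clipping at 0); compute a Li minimum-cross-entropy
threshold on the z maximum-intensity projection of each wild-type nucleus
stack; apply the *median* across wild-type nuclei to every stack (so mutant
segmentation is not biased by its own intensity range, and rachis ROIs use
the same consensus value); label 26-connected 3D components (6-connectivity
available); discard components under 2 voxels (shot-noise singletons);
report voxel-count × voxel-volume in µm³ with a default 0.2 µm z step and
0.1 µm pixels.

The Li threshold is found by exhaustive scan over observed intensity
levels, maximizing S₀·log μ₀ + S₁·log μ₁ (equivalent to minimizing the
cross-entropy between the image and its two-class mean reconstruction);
the returned value is the midpoint of the optimal split, so it lies
strictly between the classes and `>= threshold` reproduces the optimal
partition. Iterative implementations (ImageJ, scikit-image) can land one
intensity level away on plateaued histograms; the test suite checks
partition agreement with scikit-image's iterative Li on well-separated
images and tolerates plateau ambiguity elsewhere.

Digitized spheres measured by voxel counting fluctuate by roughly ±5% in
volume at radii of 5–7 voxels (lattice effects), settling below 2% by 8
voxels; volumetric accuracy checks therefore use spheres of 8–10 voxel
radius. Rendered stacks apply Gaussian blur and Poisson noise before a
constant background offset, in that order.

## Problem sizes

The default test and acceptance workloads — 200 kb genome, 10⁵-read
libraries, 2000-gene count tables, 100-run calibrations, 80³-voxel stacks —
were chosen as the smallest sizes at which every statistical check has
comfortable power; the whole suite runs in well under a minute beyond the
classifier run itself.
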