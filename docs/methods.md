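# Methods

## The analysis in brief

`aluclip` quantifies competition between two RNA-binding proteins from
iCLIP-style crosslink data. The pipeline runs in six stages: (1) raw
reads or alignments become deduplicated per-nucleotide crosslink-event
tracks; (2) binding sites are called per gene by a randomization FDR on
windowed event counts; (3) site occupancies are normalized within genes,
corrected across libraries by size factors, and compared between
knockdown and control; (4) de novo exon predictions are filtered,
assigned to genes, classified as Alu exons and tested for differential
usage; (5) positional summaries (RNA maps, heatmaps, pentamer
enrichment, co-binding profiles) relate binding to splice sites; (6) Alu
elements are mapped onto the family consensus and the lengths of their
transcribed U-tracts compared between exonized and matched nonexonized
elements.

## Crosslink events

The cDNA-truncation convention defines the crosslink nucleotide as the
position immediately 5′ of the read start in transcript orientation
(plus strand: start − 1; minus strand: the alignment end). Reads carry a
composite barcode — by default layout `NNNXXXXNN`, a 4-nt experimental
barcode nested in a 5-nt random barcode; the order within the read is an
assumption and is configurable. PCR duplicates are alignments identical
in (contig, strand, crosslink position, random barcode); the key uses
the crosslink position rather than the alignment span so that 3′
trimming differences do not split duplicates. Barcode matching is exact.

Genomic annotation of crosslink positions uses the priority
ncRNA > 3′UTR > 5′UTR > exon > intron > antisense > intergenic, with
intronic positions subdivided at 200 nt from the nearest exon boundary
(near-3′ss / near-5′ss / deep-intronic; proximity beats deep when genes
overlap, and 3′ss proximity is preferred on the rare position near both
boundaries).

## Peak calling

Heights are windowed event sums (±flank, clipped to the gene). The null
model places the gene's *n* events uniformly at random, with
replacement, across the gene for R iterations (default 100).
FDR(h) is the mean randomized count of crosslinked *positions* with
height ≥ h divided by the observed count, capped at 1 and made monotone
non-increasing in h. The ratio uses the plain mean over iterations (not
mean + SD) — the simplest unbiased estimator; the choice is visible in
the code and shared by the brute-force reference used in testing. Note
that a perfectly uniform observed track (one event per position) yields
FDR ≈ 0.4 at the maximal height, not 1: with-replacement placement
occupies fewer distinct positions than the observation.

Significant positions within ≤ flank nt merge into one site spanning
their outermost positions; the summit is the member position with most
events, ties broken toward the transcript 5′ end. Events are assigned to
the gene on the matching strand; same-strand overlaps resolve to the
longest gene. Randomization is reproducible: each gene draws its
placement matrix in a single call from a stream keyed by the global seed
and the gene's index in the sorted gene list, so an independent
implementation sharing that stream reproduces site calls exactly.

Defaults follow the two binding modes: flank 10 nt for the broad U-tract
binder, flank 5 nt for the focused PPT binder, FDR < 5% for both.

## Occupancy and differential binding

Occupancy is site events / (gene total × gene length), where the gene
total sums events over the gene's binding sites (a flag switches to all
gene positions). Sites overlapping more than one annotated gene are
excluded. For the broad binder the numerator is restricted to an 11-nt
window centred on the summit. Decile ranks (rank 10 = strongest 10%) use
a stable ascending sort with any remainder spread over the lowest bins.

Size factors are median-of-ratios: for sites positive in every sample,
counts are divided by the site's geometric mean across samples and the
per-sample factor is the median ratio. Note the factors are defined only
up to the geometric-mean convention: scaling one library by c scales its
factor *relative to the others* by c.

The differential statistic is log₂((occ_KD/f_KD + ε)/(occ_Ctrl/f_Ctrl + ε))
with ε defaulting to half the smallest positive corrected occupancy
(the data decide the scale of the regularization; zero-count conditions
stay finite). Categories: up at log₂FC ≥ 2, down at ≤ −2 (both
inclusive, reading "at least four-fold" literally), unchanged at
|log₂FC| < 0.1, otherwise other.

## Exon pipeline

Predicted exons survive when they (a) belong to multi-exon transcripts,
(b) have ≥ 1 junction-spanning read at a splice site, and (c) are
25 bp–10 kb long. Overlapping exons whose starts and ends are each
< 25 bp apart merge to outer boundaries (single linkage, iterated to a
fixpoint so the operation is idempotent and order-independent). Gene
assignment: direct single-gene overlap wins; multi-gene overlaps are
discarded; intergenic exons inherit through their predicted transcript
model when it overlaps exactly one gene.

An Alu exon has ≥ 1 junction-supported splice site inside an antisense
Alu element; the splice-site coordinate is the intronic boundary
nucleotide adjacent to the exon (the position the spliceosome's
dinucleotide signal occupies), a convention chosen because either edge
is defensible and this one is strand-symmetric.

Disruption prediction: frameshift ⇔ exon length mod 3 ≠ 0; stop codons
are scanned in the three exon-internal frames (the upstream CDS frame is
not available for cryptic exons). The default combination — disrupted ⇔
frameshift OR stops in all three frames — is logged whenever it is used
implicitly, and an any-frame variant is selectable.

The usage test is an explicit stand-in for a count-model fit: a 2×2
contingency test of exon inclusion vs. remaining gene counts between one
knockdown and control (chi-square with continuity correction, Fisher
when any expected cell < 5), with fold change as the ratio of normalized
inclusion. Its p-values feed the combiner (p < 0.01 in one knockdown,
p < 0.05 in the other, concordant direction). Externally computed
p-values can be substituted column-for-column.

## Positional summaries

RNA maps anchor offset 0 at the first (3′ss) or last (5′ss) exonic
nucleotide in transcript orientation; percentage mode reports the
fraction of exons with ≥ 1 event per offset, total mode sums events with
optional size-factor correction. Heatmap matrices keep per-exon rows,
filter rows by ≥ 5 events of a designated track within the window
(default −50..+10 around the 3′ss), and share row order across tracks.

Pentamer enrichment counts every 5-mer (transcript strand) covering any
position within ±10 nt of a crosslink nucleotide, weighted by event
count; the expectation repeats the count with per-gene event totals
placed uniformly at random (the same null model as the peak caller),
averaged over iterations and floored at one occurrence.

Co-binding profiles report, per offset in ±100 nt around binding-site
summits, the fraction of summits covered by another protein's site,
normalized to the mean over the background windows −99..−90 and
+90..+99 (one reading of "two 10-nt windows 90 nt up- and downstream");
a zero background flags the profile undefined.

## Alu consensus mapping and the selection statistic

Elements within ±15% of the consensus length are aligned to the
consensus by global pairwise alignment with affine gaps (match +1,
mismatch −1, open −5, extend −1). Pairwise alignment was chosen over
grouped multiple alignment: it is deterministic, dependency-free and
sufficient for coordinate mapping on a single consensus. The mapping
sends each element position to a consensus coordinate or a gap;
splice-site histograms bin acceptors/donors by consensus coordinate
(gaps to an "unmapped" bin) with arms split at the linker boundary.

U-tract lengths are read from consensus-coordinate regions (supplied by
the generator's config for the synthetic consensus, since no universal
coordinates exist): the longest poly(A)/poly(U) run overlapping the
element span aligned into the region, falling back to the span between
flanking mapped coordinates when the region aligns to a gap.

The selection statistic compares, per length L (inclusive ≥ L, matching
the "at least …" reading), cumulative U-tract frequencies between
exonized elements and nonexonized antisense elements of the same genes,
with Pearson's chi-square (Fisher when any cell < 5). Calibration uses
within-gene label permutations on *null* sets in which both labels draw
from the same tract-length distribution: permuting sets that genuinely
differ makes the paired randomization variance exceed what the unpaired
chi-square assumes and inflates the apparent rate, which is a property
of the design, not a miscalibration of the test. Because the conditional
permutation distribution is discrete, the rate is averaged over
L ∈ {7..10} rather than read at a single cutoff.

## Synthetic data

The generator emulates the content of an iCLIP + RNA-seq study of two
competing proteins: per-nucleotide crosslink tracks for both proteins
under control and two knockdown conditions, junction count tables with
two replicates per condition, over a toy genome of non-overlapping
two-exon genes (alternating strands) whose introns host antisense
Alu-like elements.

The synthetic ~290-nt consensus follows the canonical Alu anatomy — two
arms, a poly(A) linker, a poly(A) tail — plus a mixed C/U polypyrimidine
block before the tail so that, antisense, the transcript reads upstream
U-tract → PPT → exon body → linker U-tract. It is generated, not a
database sequence: the anatomy is what matters. Planted tract lengths
are rounded normals clipped to [3, 14]: control mean 8 sd 2, "exonized"
mean 10 sd 2 (a two-nucleotide preservation signal). Substitutions at
the mutation rate (default 0.05/nt) hit the arms only, and
tract-flanking bases are kept non-U, so planted lengths are exact ground
truth.

Crosslink counts are Poisson — the simplest count model with
variance scaling. Per transcript position: the U-tract binder's rate is
a background (0.01/nt) plus α·max(0, L−3)/L spread over each tract
(α = 2 events per U beyond the minimal 3-U tract); the PPT binder's rate
is background + β·pyr(p)·(1 − s·occupied(p)) with β = 2, where pyr(p)
rescales the 11-nt-window pyrimidine fraction so random sequence scores
0 and pure pyrimidine 1, occupied(p) marks tracts of ≥ 4 U (where
α·(L−3) > 0), and s (default 0.8) is the suppression strength. The
knockdown drops the suppression term; the U-tract binder's knockdown
track is background-only.

Exon inclusion follows a logistic link: ψ = logistic(γ·(λ_U − θ)) with
slope γ = 8 and threshold θ = 1.2 between the suppressed (0.4) and
released (2.0) per-nucleotide PPT-binder rates, giving near-complete
suppression in control and near-complete inclusion after knockdown at
occupied tracts — the qualitative regime of cryptic exons. Junction
totals are Poisson(depth = 500 per exon and replicate) and inclusion
counts Binomial(total, ψ), so per-gene counts are conserved by
construction. Explicit ψ values can be planted by editing the truth
table before drawing counts, which is how calibration experiments set
ψ = 0.3/0.6.

One global seed is split into per-stage streams (genome, tracks,
counts), making every file byte-reproducible.

What the generator does **not** emulate: read-level errors and quality
strings, fragment-length and crosslink-sequence biases, overlapping
genes and alternative isoforms, transcript-abundance variation between
conditions, replicate overdispersion beyond Poisson/Binomial, and indel
evolution of repeats. Passing tests therefore demonstrate that the
implementations recover the structures they are designed for under
idealized noise; they do not certify performance on real libraries,
where mapping artifacts and dispersion dominate.

## Validation problem sizes

The validation experiments use: 120 genes (≤ 200 nt, ≤ 20 events) for
the peak-caller reference comparison; 300 genes with s = 0.8 and s = 0
(about 22,000 called sites, roughly 1,200 at occupied tracts) for the
competition and null analyses; 60 genes for motif recovery; 500 genes ×
2 elements (500 per set) for the selection statistic with 500
permutations for its calibration; 1,000 exons at depth 500 for usage
calibration and sensitivity. These sizes put Monte-Carlo error well
below every margin tested while keeping the full run to a couple of
minutes on one CPU.

## Known limitations

* The FDR is per gene and unadjusted across genes; site lists pooled
  over genes inherit gene-level, not global, error control.
* The uniform within-gene null ignores crosslinkability sequence bias;
  on real data a matched-background null would be preferable.
* The usage stand-in assumes Binomial counts; real RNA-seq
  overdispersion would inflate its false-positive rate, which is why the
  surrounding machinery accepts external p-values.
* Pairwise consensus alignment can misplace coordinates in highly
  degraded elements where a grouped multiple alignment would rescue
  them; the ±15% length filter limits, but does not remove, this.
* The co-binding profile treats sites as intervals without weights;
  occupancy-weighted profiles are not implemented.
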