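# Methods

This note documents the models and procedures implemented in `decoyscan`,
the parameter choices that matter, what the synthetic generators do and do
not emulate, and the numerical conventions used throughout.

## Sequences and motifs

Sequences are stored DNA-style over `{A, C, G, T, N}`; RNA input is mapped
U→T on ingest and the presentation is remembered for faithful round-trips.
Motifs are degenerate IUPAC consensi compiled to per-position allowed-base
sets. Two PRE forms are bundled: `UGURUAUA` (R = A/G), used for
motif-density statistics on a transcript, and `UGUANAUA` (N = any), used
for genome-wide 3′-UTR target calling.

Coordinates are 0-based half-open (BED-compatible). Non-overlapping
counting is greedy left-to-right: after a hit at *i* the scan restarts at
*i + m*. Greedy resolution is deterministic and, for motifs that cannot
self-overlap tightly, coincides with maximal packing; the brute-force
scan-with-restart oracle in the test suite checks the equivalence
exhaustively on small alphabets. `N` in the *subject* sequence matches
nothing — masked sequence can only lose hits, never gain them. Only the
sense strand is scanned by default (PREs act on the transcript's own
strand); reverse-complement scanning is an explicit flag.

## Dinucleotide-preserving shuffle null

The null model for motif density preserves all 16 adjacent-pair counts of
the observed sequence (hence also its first/last characters and
mononucleotide composition). A shuffled sequence is a uniform random
Eulerian trail on the dinucleotide multigraph, sampled by the classic
last-edge construction: a uniform random last-exit-edge assignment is
rejection-sampled until it forms an arborescence into the terminal vertex,
then every vertex's remaining out-edges are ordered uniformly at random.
Uniformity over valid permutations is verified in the tests by exhaustive
enumeration on small two-letter sequences (chi-square, α = 0.01).

The enrichment statistic reports the observed non-overlapping count, the
mean over shuffles (the "expected by chance" value), and an add-one
empirical p-value `(1 + #{shuffle ≥ obs}) / (1 + N)`, which can never be
0 — with the default N = 1,000 the smallest reportable p is ~0.001.
Shuffled sequences are counted in the same mode as the observed sequence
so the two are commensurable. A closed-form occurrence expectation
`E = (L − m + 1)·Π_i Σ_{b∈set_i} p(b)` under an i.i.d. mononucleotide
model is provided as a fast alternative; it is an *occurrence* (not
non-overlap) expectation, a distinction that is negligible for motifs as
sparse as the PRE.

## 3′-UTR target calling

Per gene, the observed count is the greedy non-overlapping `UGUANAUA`
count in its 3′-UTR; the expected count is either the mean over per-UTR
dinucleotide shuffles (default, n = 200, consistent with the transcript
statistic) or the closed form with mononucleotide frequencies pooled from
the whole supplied UTR set. Classes: **target** if observed − expected ≥ 2,
**control** if observed ≤ expected, **intermediate** otherwise;
intermediates belong to neither analysis group. Genes with absent/empty
UTRs are excluded and reported. One UTR per gene is taken as given;
isoform-aware site pooling is out of scope.

Length-matched control sampling cuts all genes (targets and pool together)
into 10 UTR-length decile bins and samples, per bin and without
replacement, as many controls as there are targets; a bin with too few
controls is an error naming the bin. An alternative CLIP-based target
definition (genes whose UTR interval overlaps a binding-site cluster) is
provided as an interval-overlap predicate.

## Expression response

Counts are normalised to reads per million aligned reads per sample;
genes with mean RPM < 50 across the supplied samples are dropped (the
filter averages over all samples in the design — per-contrast averaging
changes little and the choice is recorded here). Replicates are averaged
per condition before fold changes `log2((RPM_t + 0.1)/(RPM_c + 0.1))`;
the 0.1 pseudocount caps the leverage of barely-expressed genes. Intronic
counts are whole-locus minus exon-mapping reads, clipped at zero (multi-
mapping can invert the subtraction) with the clip count reported.

Target-vs-control comparisons use the two-sided Wilcoxon rank-sum test:
exact enumeration of all labelings for total n ≤ 10 (two-sided p defined
symmetrically around the tie-invariant mean rank sum), tie- and
continuity-corrected normal approximation above. Perturbation pairs are
compared by Spearman correlation on the intersection of filtered genes.
Translation efficiency is `(footprint RPM + 0.1)/(mRNA RPM + 0.1)`; its
log2 change isolates translational regulation from mRNA-level effects up
to a small pseudocount residual. "Consistent" regulation across several
contrasts means same-sign fold change beyond a fractional threshold
(e.g. 20–30%) in all of them.

One consequence of RPM normalisation worth knowing: planting a shift on a
sizeable target fraction moves the library total, so control genes show a
small opposite shift. Effect recovery is therefore measured as the
*difference* of group medians, which cancels the compositional term.

## Repeat architecture

Self-comparison uses an exact k-word dotplot (default k = 8) rather than
local alignment: deterministic, dependency-free, and sufficient for
period detection. Per-offset match density divides match counts at offset
d by the L − d − k + 1 comparable pairs. The period is the smallest
offset ≥ `min_period` (default 30) whose density is a local maximum above
`min_density`; the repeat span is the union of coordinates matching at
near-multiples of the period, cut into units at period intervals.

The default `min_density` of 0.2 is calibrated for well-conserved arrays:
between two copies each diverged 10% from their ancestor, the expected
exact 8-mer match density is 0.81⁸ ≈ 0.19, so analyses of diverged
tandems should pass `min_density=0.1` explicitly (the examples and
acceptance runs do). Point substitutions do not shift offsets, so the
estimated period is exact even at moderate divergence.

Hairpins are contiguous Watson–Crick stems (G·U off by default — wobble
is a flag) of s ∈ [stem_min, stem_max] pairs enclosing a loop of 3–30 nt,
reported once at maximal extension; no thermodynamics is attempted.
U-rich elements are maximal T-runs with length in [2, 5] inclusive —
longer runs fall outside the reported class. A repeat-unit annotation
composes the PRE scan, both hairpin modes (4 bp and 8–9 bp) and the
U-rich search.

## smFISH quantification

Stacks are (z, y, x) with default voxel sizes 0.13 µm in-plane and 0.3 µm
z-spacing. Filtering uses an explicit 15³ negated Laplacian-of-Gaussian
kernel (σ = 1.5 px, isotropic in voxel units despite z-anisotropy; an
anisotropic σ_z would be a straightforward extension but the standard
recipe uses a single σ), shifted to zero sum so constant stacks give zero
response, applied with reflective edge handling.

Threshold selection records 26-connectivity component counts over a
100-point uniform threshold grid spanning the response range (range-
relative, so detection is invariant to uniform intensity scaling). The
selected threshold is the centre of the longest *credible* plateau of the
count curve — a maximal constant-count run holding ≥ 2 components and
spanning ≥ 5% of the grid — with ties broken toward the lowest threshold.
Plateaus of 0–1 components are treated as degenerate because, for any
image whose brightest spot dominates the range, the single-component
plateau below its peak persists for most of the grid regardless of how
many real spots exist; they are used only as a fallback (e.g. noise-only
stacks, which then correctly yield ≤ 2 components). A perfectly flat
response is a "no signal" outcome, not an error.

Spots are the components at the selected threshold, with intensity-
weighted centroids and voxel counts. Background removal drops spots
outside a voxel-count range (default 2–100) and spots whose centroid lies
within 2 px of a centroid in *another* channel (probe-independent
artifacts). The nuclear mask is the Otsu threshold of the max-z DAPI
projection with holes filled; a spot is nuclear iff its (y, x) centroid
falls inside. Counts are per stack; per-cell statistics require caller-
supplied cell masks (single-cell segmentation is out of scope).

## Stoichiometry

Decoy capacity is purely multiplicative — transcript copies per cell ×
sites per copy — with optional rounding for headline figures (default:
full precision, rounded figure alongside). No dissociation constants or
occupancy model are implied. Protein copy numbers invert a linear
least-squares standard curve; negative inversions (signal below
intercept) report 0 with a warning.

## Synthetic data

Generators are deterministic functions of their seed and return truth
tables. Backgrounds are first-order Markov chains with specified
dinucleotide frequencies. Motif planting writes concrete instantiations
of a degenerate pattern at non-overlapping random positions. Tandem
arrays duplicate one random ancestor with i.i.d. per-copy substitutions
(expected inter-unit identity ≈ (1 − r)² plus back-mutations). UTR
universes use log-normal lengths (median 1 kb, σ_log = 0.6), making
10-bin length matching nontrivial; targets get ⌈expected + 3⌉ planted
sites by default. Count matrices are negative-binomial (gene-wise
variance µ + φµ², default φ = 0.05, Poisson in the φ → 0 limit) around
log-normal baseline RPMs (median 200) at 5 M reads per sample, two
replicates per condition. FISH stacks (default 8×128×128) render
isotropic 3D Gaussian spots (σ = 1.5 px, matching the detection filter's
design point) at SNR 10 over Poisson + Gaussian read noise, with an
ellipsoidal nucleus in a DAPI channel and a 94%/6%
cytoplasmic/nuclear split at the published per-cell scale (68 molecules).

What the generators do **not** emulate: alignment and multi-mapping
artifacts, isoform structure, GC-stratified genomic backgrounds, optical
aberrations and uneven illumination, cell-to-cell variability, or
overlapping/clustered spots beyond the enforced minimum separation.
Passing tests therefore demonstrate correctness of the statistics and
detection machinery under their stated assumptions, not robustness to
every artifact of real libraries or microscopes.

## Problem sizes and numerical conventions

The bundled tests and the acceptance script run at reduced but
non-trivial scales chosen to exercise each method's regime: 5.3-kb
transcripts with 1,000 shuffles, UTR universes of 60–500 genes (200
shuffles per UTR), expression designs of 400–1,000 genes with 200–300
targets, 1,000 null simulations for calibration, 12×300-nt tandem arrays,
and ten 8×128×128 FISH stacks. Empirical p-values use the add-one rule;
rank-sum enumeration treats deviations equal to the observed one as
extreme (≥ with a 1e-9 slack against float error); quantile bin edges are
right-closed with the top bin absorbing the maximum; all RNGs are numpy
`default_rng` (PCG64) seeded explicitly.
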