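# Methods

## Model and procedure

`pioneerscan` operationalizes a simple biophysical premise: a
transcription factor that tolerates or prefers nucleosomal DNA leaves
its ChIP-supported binding motifs *on* nucleosome footprints, while a
factor restricted to naked DNA leaves them in nucleosome-depleted
regions. Everything in the package serves to measure that contrast at
base-pair resolution.

### Dyad calling

Dyad positions are estimated as midpoints of tightly size-selected
(146–148 bp) mono-nucleosome fragments. Per-base midpoint counts
`d(j)` are smoothed with a triweight kernel,

    K(u) = (1 − (u/h)²)³   for |u| ≤ h, else 0
    D(i) = (1/(N·h)) · Σⱼ K(i−j) · d(j)

with bandwidth `h = 15` bp (small enough to keep single-nucleosome
resolution) and `N` the chromosome length. The `1/(N·h)` factor is a
global monotone scale retained for fidelity to the formula; it cannot
move any maximum. Local maxima of `D` are thinned to a minimum
separation of 150 bp (roughly one nucleosome repeat length); within a
60-bp half-open window `[m−30, m+30)` around each retained maximum the
raw-count argmax becomes the representative dyad, with ties resolved
first toward the maximum and then toward the lower coordinate. Each
dyad defines the 147-bp nucleosome region `[dyad−73, dyad+74)`;
regions that would cross a chromosome edge are dropped and counted.

Deterministic tie-break choices (documented because the underlying
rules are silent on them): plateaus of equal smoothed values yield
their leftmost base; conflicting maxima closer than 150 bp are kept
greedily in order of descending height, ties toward the lower
coordinate; representative-dyad ties at equal count and equal distance
go to the lower coordinate.

### NDRs, occupancy and region annotation

NDRs are the maximal intervals covered by *no* 120–180 bp fragment
pooled across replicates — the complement of the fragment union — so a
base is in an NDR exactly when its mono-nucleosome occupancy (fragment
coverage, the standard numeric reading of "occupancy") is zero.

Open chromatin is the ±1000 bp neighborhood of each DNase-seq peak
summit (midpoint when no summit is called); overlapping regions are
not merged, and the alternative (merging before overlap computation)
would slightly change overlap denominators for stacked peaks. Active
enhancers are open regions overlapping (≥ 1 bp) both H3K27ac and
H3K4me1 peaks. Comparing one cell line against others classifies each
region by the fraction of its bases covered by the comparator's region
union (denominator = the region's own length): conserved when > 0.8
for at least one comparator, differentially open when < 0.2 against
*every* comparator, otherwise unclassified. The direction of the
differential comparison (closed-in-stem vs closed-in-differentiated)
is a caller choice, since the biologically appropriate direction
depends on whether the factors of interest act in differentiation or
in reprogramming.

### Motif scanning

The scanner is a self-contained log-odds PWM engine. Counts are turned
into scores as

    entry(b,k) = log2( ((n_bk + pc·bg_b) / (N_k + pc)) / bg_b )

with pseudocount `pc = 0.1` distributed in proportion to the
background `bg` (uniform by default; both are assumptions, exposed as
parameters, since only the p-value cutoff is prescribed). Exact
p-values come from a dynamic program over integer-discretized
per-position scores (1000 bins for the widest column range); for
motifs up to 8 bp the survival function equals full 4^L enumeration at
the discretization resolution, which the tests assert. Both strands
are scanned; minus-strand hits are reported in plus-strand
coordinates. Hits with p < 10⁻⁴ are kept, overlapping hits of one TF
are all retained (downstream counting uses base-pair unions, not
sites), and hits identical in (chrom, start, end, strand) across peak
files of one TF are deduplicated.

### Profiles and their statistics

Each hit is assigned to the closest representative dyad (hit center,
left-of-center for even lengths; ties to the lower-coordinate dyad).
The motif profile counts motif base pairs at every signed offset in
±1000 bp from the assigned dyads. Statistics:

- **Occupancy correlation**: Pearson r between the motif profile and
  the mean fragment-coverage profile over the same dyads, on ±400 bp.
  r ≥ 0.2 with p < 0.05 flags a potential nucleosome binder; r ≤ −0.4
  with p < 0.05 the canonical depletion pattern.
- **End/dyad ratio**: motif bp at |SHL| ∈ [5.5, 7] over motif bp at
  |SHL| ≤ 1.5, at 10.5 bp per superhelical location (147 bp / 14
  SHLs). `round(7·10.5) = 74` exceeds the wrapped DNA, so the end
  window is capped at the ±73 bp edge, giving |offset| ∈ [58, 73] over
  |offset| ≤ 16. Base pairs (not site centers) are summed, consistent
  with profile counting. An empty dyad window returns no-call rather
  than infinity.
- **Symmetry**: Pearson r between counts at offsets +1..+73 and the
  mirrored −1..−73. The nucleosome's two-fold symmetry predicts high
  values for well-sampled profiles, so low values indicate
  under-sampling; profiles with r < 0.4 or fewer than 500 motif bp on
  NRs are excluded from clustering.
- **Dinucleotide profiles**: per-offset frequency of WW/SS (W=A/T,
  S=G/C) or YY/RR (R=A/G, Y=C/T) dinucleotides over aligned NRs, the
  dinucleotide at offset o starting at dyad+o (the last NR base has
  none). The ~10-bp phasing of WW/SS is a positive control for dyad
  quality. Note AG/GA are RR dinucleotides by definition.

### Mode clustering

Profiles restricted to ±60 bp (entry/exit DNA is excluded because
MNase's A/T cleavage bias distorts counts near fragment ends) are
folded — `value[o] = counts[+o] + counts[−o]`, dyad kept once — and
min-max normalized. Folded profiles are embedded in 2-D by t-SNE
(perplexity 10, 1000 iterations, PCA init, seeded) and partitioned by
k-medoids with k = 6. The PAM search is deterministic (greedy BUILD
init, best-improvement SWAP), silhouette widths are computed on the
same 2-D distances that were clustered, and members with width ≤ 0.25
are flagged outliers. k and the embedding are configurable; a
`silhouette_scan` utility supports choosing k, and clustering directly
on folded profiles (no embedding) is available when embedding
stochasticity is unwanted. Constant folded profiles have no defined
normalization and are excluded with a flag.

### Enrichment and evaluation

Motif bp are counted on the unions of hits and of regions (a base in
two overlapping hits or regions counts once). The odds ratio
`(a/c)/(b/d)` is Haldane–Anscombe-corrected (+0.5 on all cells,
flagged) when any cell is zero, where it is otherwise undefined.
Fisher's two-sided exact test (probability-≤-observed rule) gives
significance; underflowed p-values are floored at the smallest
positive float to preserve the (0, 1] contract. FDR is
Benjamini–Hochberg (the q-value procedure is otherwise unspecified).
Ranking is by descending score with lexicographic tie-breaks;
`highly_expressed` is RPKM ≥ 10, with TFs absent from the expression
table flagged unknown rather than assumed silent. Classifier quality
uses rank-based ROC AUC (ties averaged), step-interpolated average
precision, and MCC maximized over all `score ≥ t` thresholds.

## Synthetic data: what it emulates, and what it does not

The generator builds a single ~116-kb chromosome: 25 arrays of 20
nucleosomes phased at a 200-bp repeat, separated by 600-bp designated
NDR stretches, inside 1-kb margins. Each nucleosome emits 100
fragments per replicate (2 replicates) with lengths from a discrete
triangular distribution on [120, 180] peaking at 147 — reproducing
mono-nucleosome size selection without modeling MNase chemistry — and
centers jittered by rounded N(0, 2 bp) clipped to ±5 bp. Fragments are
placed so their floor-midpoint equals the jittered center, matching
the caller's midpoint convention for every fragment length. The
coverage level reflects the high-coverage MNase-seq the method
assumes; at it, ≥ 95 % of true dyads are recovered within ±2 bp.

Motif implants write a PFM consensus centered at ±round(SHL·10.5) bp
from each dyad (both halves, alternating strands, ±2 bp placement
jitter) or tiled every 150 bp inside NDR stretches; each planted site
gets a 200-bp narrowPeak with the summit at the site start. Optional
10-bp-periodic WW dinucleotides under nucleosomes emulate rotational
positioning signals.

Deliberately absent: sequencing errors and read-level (FASTQ)
structure, MNase sequence bias, nucleosome fuzziness or sub-repeat
spacing variation, linker-length heterogeneity, chromatin-state
heterogeneity across loci, and real motif degeneracy (implants are
consensus sequences so recovery is exact). Passing tests therefore
demonstrate that the implementation recovers the structure it assumes,
at realistic coverage and noise — not that the method is robust to
biases real MNase-seq data carry.

## Problem sizes and numerical choices

Tests and the acceptance script run the full pipeline on the 500-
nucleosome fixture (seconds on one CPU), oracle comparisons on 500-bp
tracks (double-loop smoothing, ≤ 1e−12 relative error), 4^L word
enumeration for L ≤ 8, hypergeometric enumeration for margins ≤ 40
(≤ 1e−9), the random-classifier baseline at 32 positives / 160
negatives × 1000 replicates, and mode-recovery on 6 Gaussian-bump
templates × 15 profiles at noise SD = 20 % of the unit range. These
sizes were chosen to exercise every code path at full fidelity while
keeping a complete run fast enough for routine development.

Degenerate inputs are explicit no-calls or errors rather than silent
values: constant vectors cannot be min-max normalized, zero-variance
vectors have no correlation, empty dyad windows give no end/dyad
ratio, empty region sets cannot form a contingency table, and
single-class label sets cannot be evaluated.

## Known limitations

- Coordinates are genome-agnostic (0-based half-open throughout); no
  assembly is assumed or validated beyond chromosome-size bounds.
- The scanner supports 0-order backgrounds only; no higher-order
  Markov background, no de-novo motif discovery.
- Occupancy is plain fragment coverage; no GC or MNase-bias
  correction, no fuzziness scores, no sub-base dyad interpolation.
- t-SNE coordinates (hence silhouettes near the outlier threshold)
  depend on the seed; the no-embedding mode trades visual structure
  for exact reproducibility across library versions.
- Classification accuracy on real genome-scale ENCODE/Roadmap data is
  not evaluated here — that requires the full public data sets, whose
  retrieval is out of scope; the tests verify the machinery on
  synthetic data with known truth.
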