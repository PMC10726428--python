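# Methods

This note documents the statistical models, the defaults that matter,
the synthetic-data design, and the numerical choices made where the
design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Region catalog

Open-chromatin regions of interest are built from subtype-level peak
summits and per-sample narrowPeak calls (consumed after the reader-side
q < 0.05 gate, i.e. `-log10 q > 1.301`). A summit survives when peaks
from at least `min_support` (default 2) distinct samples of the same
subtype contain it — "reproducible among multiple samples" read as at
least two; the check is point containment of the summit by default,
with peak-overlap of the extended interval available as
`support_mode="interval"` since either reading is defensible. Surviving
summits are extended symmetrically to `[s−150, s+151)`, the only
symmetric reading that yields the stated odd 301-bp width, merged when
overlapping (book-ended intervals stay separate so covered bases are
conserved exactly), and any merged interval intersecting the blacklist
by ≥1 bp is removed.

Windowing tiles each region left-to-right into fixed-width (default
250 bp) windows; a final partial window shorter than half the width is
absorbed into the previous window, which avoids sub-125-bp fragments
while conserving coverage — no convention fixes the remainder rule, so
it is pinned down here and tested.

Annotation assigns each region by its midpoint with precedence
promoter > 5'UTR > 3'UTR > exon > intron > distal intergenic. The
promoter window defaults to (−2000, +500) around the TSS in gene
orientation; annotation tooling conventions vary, so the window is
explicit and configurable. UTRs require CDS bounds (BED12 thick
interval) and degrade gracefully to plain exon calls without them.
Chromatin states follow the histone-mark truth table: active =
(H3K27ac ∨ H3K4me1) ∧ ¬H3K27me3; bivalent/poised = H3K27me3 with an
active mark; repressed = H3K27me3 alone; else unmarked. The four states
partition any region set by construction.

## Count model

Normalization is median-of-ratios over all-positive reference rows; a
`pseudo_reference` flag switches to positive-entry geometric means for
sparse matrices. The stabilized signal is `log2(count/s + 1)` — a
monotone, parameter-free transform adequate for heatmaps and classifier
features; it is not the reference regularized-log transform, and the
difference is deliberate (no fitted parameters to document or drift).

Dispersion: per region, a moment estimate on normalized counts,
`α̂ = max((v − m)/m², 1e−8)`, where `m` and `v` pool within-group
moments when group labels are supplied (group-wise means, pooled
residual variance) so real effects do not masquerade as dispersion.
A Tukey-bisquare line of `log α̂` on `log m` supplies a trend, and
estimates are shrunk halfway toward it in log space **from below
only**: estimates above the trend are kept unshrunk. Symmetric
shrinkage systematically understates the standard error of exactly
those regions that hundreds of thousands of tests select for (the
low-dispersion tail), which manufactures spurious depleted calls; the
asymmetric rule is the same idea as the "maximum of fitted and
per-gene" sharing mode of early count-model tools.

Testing: per region, an NB log-link GLM with fixed dispersion and
offset `log s_j`, fit by IRLS vectorized across all regions at once
(batched weighted normal equations, `einsum` + batched solve; 50
iterations max, 1e−6 coefficient tolerance; non-converged regions get
missing p-values, are excluded from BH, and are counted in the log).
The Wald statistic for the contrast coefficient is referred to a t
distribution with `n − p` degrees of freedom rather than a normal: the
dispersion is plugged in, and at cohort-scale sample sizes the normal
tail is visibly too light (a 10,000-region null then yields BH false
discoveries purely from the approximation). No fold-change shrinkage,
independent filtering, or outlier handling is applied. BH adjustment is
computed within each contrast over converged regions.

Selection rules: a DAS passes `padj < 0.05` and `|log2FC| ≥ 1` in its
contrast. One-vs-rest runs each subtype (≥2 samples; singletons are
skipped and logged, and catch-all labels can be excluded from the rest
pool) against all other samples pooled; the exclusivity filter keeps
regions significant in exactly one subtype. Progenitor identity loci
use the stricter `padj < 0.005` and take the union across stage
contrasts without exclusivity. The leukemia-vs-Pro-B contrast runs
without covariates by default (a flag enables them); categorical
covariates elsewhere are one-hot with first-level reference, numeric
covariates centered.

## Classifiers

k-NN: Euclidean distance on locus-standardized stabilized signal,
k = 5 by default (neither k nor metric is dictated by the underlying
procedure; both are parameters). Majority vote; vote ties go to the
single nearest neighbor's label.

Stepwise PCA–LDA: features (subtype-enriched regions) are centered and
scaled, projected by SVD-derived principal axes with a deterministic
sign convention, and classified by nearest class mean under the
regularized pooled within-class covariance
`S_γ = (1−γ)S + γ diag(S)`, γ = 0.1 — features exceed samples even
after PCA, and the diagonal shrinkage stabilizes inversion. The PC
count is selected over a grid (default 2..min(50, n−2)) by
leave-one-out cross-validation that refits standardization, PCA and LDA
in every fold while keeping the feature set fixed; the smallest count
wins ties, and exact distance ties at prediction go to the
lexicographically first label. Keeping the feature set fixed across
folds mirrors how such classifiers are built in practice (the DAS
catalog is derived once from the full cohort) and carries the
corresponding optimistic bias; the validation-cohort projection, which
re-normalizes the new cohort independently (per-cohort size factors),
is the unbiased check. Held-out samples are classified through the
stored centering/scaling constants and axes; projection of training
data through the stored axes reproduces the fitted discriminant scores
exactly.

## Footprints

Insertion profiles cover `[−50, motif, +50]` bp; the score uses 30-bp
flanks adjacent to the core with no gap and requires ≥20 insertions per
window (all configurable — footprinting tools differ in their window
conventions, so the values are explicit parameters here). Profiles are normalized to unit mean, making FPS
invariant to depth; no Tn5 hexamer bias correction is applied (it needs
genome sequence context; a hook for a bias table is the natural
extension). Group profiles are pooled across samples before scoring.
Bound/unbound calls fit a 2-component Gaussian mixture (k-means
initialization, fixed seed) with posterior 0.5 as the boundary and a
mean + 1 sd threshold fallback when the components collapse (means
within 0.1 pooled sd). Group ΔFPS averages per-occurrence score
differences over occurrences scored in both groups; the permutation
null flips the sign of each per-occurrence difference (label exchange
within occurrence), two-sided with the add-one rule. The per-subtype
selection takes, for each motif and subtype, the median **signed** ΔFPS
against every other subtype (enrichment-seeking; absolute values would
reward factors merely variable across subtypes) and ranks descending
with lexicographic tie-breaks.

## ATAC-QTL

Candidates are biallelic SNVs inside catalog regions with imputation
R² ≥ 0.80 (missing R² means directly genotyped and counts as 1.0) and
sample MAF ≥ 0.05. The total-count test is OLS of stabilized region
signal on `dosage/2` (plus optional covariates), so β is the log2
accessibility difference between the homozygous genotype classes — the
convention is fixed this way so that the generator's planted β and the
estimator agree by definition. The allelic test pools reads across
heterozygotes (≥2 informative hets, ≥10 pooled reads) and applies the
exact two-sided binomial test of π = 0.5, with an optional
beta-binomial variant using a moment-estimated intraclass correlation
when ≥5 hets are available. The two p-values combine by Fisher's
method (degrading to the available one when a side is missing), and BH
runs genome-wide across all pairs with significance at q < 0.1; the
per-variant FDR is primary, with a per-region lead-variant flag
(smallest combined p, position breaking ties) emitted alongside. This
two-part combined test is an explicit, testable replacement for joint
total/allelic likelihood tools whose internals are not re-implementable
from their description.

## ABC networks

Activity is `sqrt((ATAC + pc)(H3K27ac + pc))`; contact is the summed
loop score joining an element to the gene's promoter window, zero
without a loop (capture Hi-C loop calls stand in for a contact matrix;
no powerlaw normalization or pseudo-contacts). Candidate elements are
those within 2 Mb of the TSS — matching the loop-span cap — and default
to the enriched-DAS universe, with a flag for all catalog regions —
either universe is a defensible modeling choice. The
gene promoter can be added as its own candidate with the gene's maximum
observed contact (standard ABC practice; off by flag). Scores normalize
to 1 per gene and predictions are kept at ABC ≥ 0.04. The network join
keeps (motif, gene) pairs where a bound occurrence sits in an enriched
DAS with a retained ABC link to a gene-set member, ranked by mean
differential footprint signal (TFs) and expression (genes).

## Synthetic data

The generators emulate: negative-binomial counts with log-normal region
means (median 50), log-normal dispersions (median 0.2, log-sd 0.5) and
log-normal size factors (geometric mean 1); per-subtype enriched blocks
(1% of regions, log2 effect 2) disjoint except for a designated
correlated pair sharing 60% of its block — producing the realistic
confusion between two biologically adjacent subtypes; a progenitor
staircase (each stage's loci elevated in that stage only, a
leukemia-like group sharing the terminal Pro-B profile); Poisson
insertion profiles with multiplicative core depletion at bound
occurrences; Hardy-Weinberg genotypes whose causal variants scale the
region mean by `2^{β·dosage/2}` and skew het reads to π; and a toy
annotated genome with planted chromatin states and loops.

Default cohort scale (10 subtypes × 8 samples, 20,000 regions) is
deliberately desk-scale: large enough that one-vs-rest testing,
exclusivity filtering and LOOCV behave as they do on real cohorts,
small enough that the full pipeline runs in seconds per cohort. The
staircase recovery check uses 10 samples per stage because the strict
`padj < 0.005` gate at 6 per stage is genuinely power-limited — an
honest property of the gate, not of the implementation. Causal QTL
variants are drawn only from variants passing the R²/MAF gates: a
causal variant removed by QC would measure QC, not the statistics.

What the generators do **not** emulate: GC/accessibility-coupled
technical biases, batch structure correlated with subtype, linkage
between variants, read-level artifacts, footprint sequence bias, or
realistic genome architecture. Passing tests therefore demonstrate the
statistical machinery is correct under its stated model, not that the
model captures every property of patient data.

Recovery bookkeeping: the correlated pair's shared block is planted in
*two* subtypes, so the exclusivity filter must drop it; recall is
measured over regions planted in exactly one subtype (the recoverable
truth) and precision over all planted (region, subtype) assignments.

## Numerical choices and degenerate inputs

IRLS: η clipped to ±30, ridge 1e−10 on the normal equations, init from
a log-linear least-squares fit. Constant rows give α at the 1e−8 floor
and Wald p = 1. Empty flank/core configurations, empty region sets,
non-partitioning label groups, rank-deficient designs and feature
mismatches raise typed errors rather than propagating NaNs. All
randomness (mixture fits, permutation tests, generators) takes explicit
integer seeds; classifier fitting is deterministic, including PCA sign
conventions and tie-breaks.

## Known limitations

The NB Wald stage omits fold-change shrinkage, independent filtering
and outlier handling, so its padj values differ in detail from the
reference differential tool on the same data. The LOOCV used to choose
the PC count is optimistically biased by the fixed feature set (see
above). The beta-binomial allelic option uses a moment, not ML,
overdispersion estimate. The ABC contact model inherits whatever
incompleteness the loop calls have — elements without called loops get
zero contact even when truly contacting.
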