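# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `drmchip`, and what the synthetic benchmark does
and does not demonstrate about real data.

## Coordinates and overlap

All internal coordinates are 0-based, half-open (BED convention); 1-based
dialects would be converted at the reader boundary. Two intervals overlap
when they share at least one base on the same chromosome; abutting
half-open intervals do not overlap. Strand is ignored for peak–peak
overlap (ChIP peaks are unstranded) and honoured only when promoter and
TTS windows are built. Peak "center" means the summit when one was
called, otherwise the interval midpoint; a consensus peak's center is the
integer median of its members' centers.

## Consensus DRM sites

Peak merging is single-linkage: peaks connected by a chain of ≥ 1 bp
overlaps form one cluster (computed by a sorted sweep, which is exact for
intervals). This choice is deliberate — it is the behaviour of common
merge tools, it is order-independent, and it is checkable against a
brute-force connected-components oracle, which the test suite does on
thousands of random instances.

Replicate reproducibility is the same clustering applied across one
subunit's replicates, keeping clusters represented in ≥ `min_replicates`
(default 2 of 3) distinct replicates. This is a deliberately simple,
fully specified stand-in for model-based replicate-consistency filters
(IDR-style): it serves the same function — discarding peaks seen in only
one replicate — without an irreproducibility model. Merged peaks take
the union span (conservative for downstream annotation) and the median of
member summits.

The tiered vote defines a DRM site as the triple overlap of (i) an
E2F-DP region (both DPL-1 and EFL-1), (ii) a LIN-35 peak, and (iii) a
MuvB region (≥ `muvb_vote_k` = 3 of 4 assayed MuvB subunits). A subunit
contributing several peaks to one cluster counts once. Every DRM site's
membership map therefore contains LIN-35, both E2F-DP subunits and ≥ 3
MuvB subunits — an invariant the tests assert. Retention in the mutant is
binary: a WT site "retains" a component when it overlaps ≥ 1 mutant
consensus region for that component (no quantitative retention threshold
is imposed).

## Differential occupancy

Counts are fragments whose midpoint falls inside the site (each fragment
counted at most once). Size factors are median-of-ratios:
`s_j = median_i c_ij / (Π_j c_ij)^{1/m}` over rows with all-positive
counts, then rescaled to geometric mean 1 so identical samples get
factors of exactly 1. If no all-positive row exists the caller is
directed to a documented +1 pseudocount fallback.

The per-row test is a negative-binomial Wald test with a
method-of-moments dispersion:

* normalized counts `y_ij = c_ij / s_j`; group means `μ_WT`, `μ_mut`;
* `α̂ = max(1e−8, (pooled within-group variance − pooled mean) / pooled mean²)`,
  pooling the within-group sums of squares over n − 2 degrees of freedom;
* `log2FC = log2((μ_mut + 0.5) / (μ_WT + 0.5))` — the 0.5 pseudocount
  keeps zero-mean rows finite;
* `SE² = (1/ln 2)² [ (1/n_WT)(1/(μ_WT+0.5) + α̂) + (1/n_mut)(1/(μ_mut+0.5) + α̂) ]`,
  the delta-method variance of a log mean ratio under NB sampling;
* `z = log2FC / SE`, two-sided normal p-value.

This is intentionally a desk-verifiable simplification of shrinkage-based
NB frameworks: no dispersion sharing across rows, no GLM. Two measured
consequences, reproduced by `scripts/acceptance.py`, should be kept in
mind:

1. **Anticonservative nulls at n = 3 + 3.** The plug-in α̂ has ~4 degrees
   of freedom, so null p-values are inflated: the measured null p < 0.05
   fraction is ≈ 0.11 (nominal 0.05) at mean 200 and dispersion 0.05, and
   the BH-controlled false Class I rate is correspondingly above nominal.
   A dispersion-shrinking test would fix this; it is out of scope here,
   and the calibration numbers are reported rather than hidden.
2. **Normalization absorbs global shifts.** When nearly every row carries
   a negative occupancy change (the regime of interest), median-of-ratios
   factors soak up much of the genome-wide decrease into the mutant
   samples' scale. Fold changes are then *relative to the typical site*:
   strongly affected sites still stand out (Class I recall 0.99 on the
   synthetic benchmark), weakly affected sites do not (specificity 1.0),
   but weak sites can register apparent *increases*, and true sample
   scale is not separately identifiable from biology. For this reason
   size-factor *parameter recovery* is assessed on null counts (no
   planted effect), where recovery is within 5% median relative error;
   under a global shift no normalization method could recover them.

BH FDR is computed per subunit (the multiplicity family in which Class
membership is defined), via the standard step-up procedure
(statsmodels), cross-checked in the tests against an independent
implementation. Class I means ≥ 1 of the 6 tested subunits significantly
decreased at FDR < `fdr_alpha` (0.05); Class II is the complement; the
classes partition the peaks by construction. LIN-35 is excluded from
mutant testing — in a protein-null mutant its ChIP is a negative control.

## Annotation

The peak center decides the category — a wide peak cannot land in two
categories — with precedence promoter > intron > TTS > intergenic.
Promoter windows are −1000/+100 bp around the TSS in gene orientation,
clipped at the chromosome start (width exactly 1100 bp unclipped, both
strands — a tested invariant). "Bidirectional" means the center lies in
≥ 2 promoter windows regardless of the genes' relative orientation; both
genes become targets. The TTS window is symmetric ±1000 bp since no
direction is implied by "within 1000 bp". Target genes are the union of
promoter-category gene lists; intron/TTS/intergenic peaks contribute
none.

## Motifs, conservation and enrichment

IUPAC matching is per-position set membership; `N` in the sequence
matches nothing, including the fully degenerate pattern symbol. Both
strands are scanned by default; a reverse-strand hit is a match of the
reverse-complemented pattern on the + sequence, reported in +
coordinates, so palindromic instances (e.g. TTCGAA for the CHR) yield
paired ± hits at one span. The mismatch budget defaults to 1 for the CDE
(`BSSSSS`) and 0 for the CHR (`TTYRAA`).

Conservation is aggregated over the match span as the **mean** per-base
score by default ("min" gives an every-base criterion and is exposed as
a config option); hits are kept when the aggregate strictly exceeds the
threshold (0.7). Uncovered bases score 0, and overlapping bedGraph rows
resolve last-wins. A region is motif-positive when ≥ 1 (conserved) hit
lies fully inside it, counted once.

Enrichment is the hypergeometric upper tail P(X ≥ k) computed in log
space (`scipy.stats.hypergeom.sf`), with the universe given explicitly by
the caller (target regions plus background promoters, mirroring the
background-promoter construction used for genome-wide motif
enrichment). Class association uses the 1-df Pearson chi-squared without
continuity correction and refuses tables with a zero marginal rather
than silently approximating.

## Expression, Group A/B and qPCR

DE calls are thresholded at q < 0.05 and linear fold change > 1.5
applied symmetrically (|log2FC| > log2 1.5); the fit that produced the
table is upstream of this package. A DRM target gene is Group A when
"up" in ≥ 1 experiment (any-of semantics across the provided
experiments, with supporting labels recorded), else Group B; A and B
partition the targets on every input.

RT-qPCR relative quantity uses efficiency-corrected ΔCt without standard
curves: `Rq = E_ref^{Ct_ref} / E_tgt^{Ct_tgt}`, efficiencies defaulting
to 2.0; with equal efficiencies Rq depends only on `Ct_ref − Ct_tgt` (a
tested invariant). ChIP-qPCR log₂ fold enrichment assumes efficiency 2
at all amplicons:
`(Ct_chip^ctrl − Ct_input^ctrl) − (Ct_chip^tgt − Ct_input^tgt)`, which is
exactly antisymmetric under swapping target and control regions.

## The synthetic benchmark

The generator's defaults define the study conditions: 2 chromosomes of
1 Mb; 400 genes (30% in divergent pairs sharing promoter sequence); 150
co-bound sites planted inside promoter windows; per-subunit,
per-replicate detection probability 0.9 in WT with N(0, 50 bp) boundary
jitter and N(300, 100 bp) peak widths (width fixed per site × subunit so
that zero jitter makes replicates identical); 30 noise peaks per subunit
and replicate; 3 replicates per genotype; NB counts at baseline mean 200
and dispersion 0.05 with per-sample size factors U(0.7, 1.4); 60% of
sites with strong per-subunit drops log2FC ~ N(−2, 0.5) (truth Class I)
and 40% weak N(−0.3, 0.2) (truth Class II); a planted retention pattern
of 40% keep-both / 45% keep-neither / 15% keep-one; CHR planted in 60%
and CDE in 45% of sites as exact instances on a GC ≈ 0.36 background,
with conservation U(0.8, 1.0) over planted spans and Beta(1, 3) near
sites (bases far from sites are absent from the track); and 40% of bound
genes upregulated (log2FC ~ N(1.2, 0.3), q ~ U(0.001, 0.04)) in ≥ 1 of
three labelled experiments, defining truth Group A. Planted fractions
use exact counts (a random subset of round(f·n) sites) so truth
denominators are stable. Truth Group A is derived from the emitted
expression values by the same thresholds the pipeline applies — the
generator's arithmetic, not the pipeline's code — so truth and files
cannot disagree.

Randomness is structured: component c draws from
`numpy.random.default_rng([seed, c])` with fixed component ids, so the
same (params, seed) reproduces the bundle byte for byte and components
can be regenerated independently.

What passing the benchmark does **not** show about real data: peaks are
emitted directly (no read pileup, mappability or peak-caller artifacts);
detection dropout is independent across subunits and replicates, unlike
correlated antibody or extract effects; fragment counts are exactly NB
with a shared dispersion; conservation outside site neighbourhoods is
absent rather than noisy; and expression tables carry planted q-values
rather than a fitted model's. The benchmark validates the pipeline's
logic and calibration under its stated model, not the biology of any
particular dataset.

## Problem sizes and tolerances

The test suite and acceptance script use the default scenario (150
sites, 2 Mb, 3 + 3 replicates), a null count matrix of ~2000 rows for
calibration, and 1000-instance randomized oracle comparisons; the full
suite runs in a few seconds on one CPU. Closed-form spot values are
asserted to 1e−9 relative tolerance; oracle equivalences to 1e−12;
Monte-Carlo fractions are asserted within two binomial standard errors
of their targets, since a point assertion at the expected value would
fail by sampling noise alone roughly half the time.
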