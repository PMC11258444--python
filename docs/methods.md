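# Methods

## Scope and model

`entropyscape` quantifies epigenetic noise in blood WGBS methylomes and asks
whether long-lived individuals (LLI, >90 y) maintain regions of unusually
*ordered* methylation against the age-related rise in disorder. The unit of
analysis is the 3-CpG segment: for each segment and sample, sequencing reads
covering all three CpGs are classified into the 2^3 = 8 binary methylation
patterns, and the methylation entropy is

    ME = (1/b) * sum_i -(n_i/N) log2(n_i/N),     b = 3,

with `n_i` reads of pattern i out of N total. ME is 0 when every read shows
the same pattern and 1 when all eight patterns are equally frequent. With
N < 2^b reads the attainable maximum is log2(N)/b; reported values are not
rescaled by this bound, matching the plain formula.

Global per-sample noise summaries are the coefficient of variation of
per-site methylation levels (sample sd / mean), quantization-based entropy
(QE: Shannon entropy in bits of the per-site beta histogram over k
equal-width bins, bin 1 closed at 0, other bins left-open), and the
Martin–Plastino–Rosso statistical complexity of the genome-position-ordered
beta profile (Bandt–Pompe ordinal patterns, D = 4, delay 1, ties broken by
temporal order; entropy in nats normalized by ln D!; complexity = normalized
Jensen–Shannon disequilibrium x normalized entropy).

## Differential entropy inference

Cell composition confounds bulk methylomes, so six blood cell-type fractions
(B, CD4T, CD8T, Mono, Neutro, NK) are first estimated per sample by robust
partial correlation: Huber-loss (t = 1.345) iteratively reweighted regression
of the sample's betas at reference sites on the reference panel columns with
an intercept, negative coefficients truncated and the rest renormalized to
the simplex.

Per segment, the association between group membership (comparison group
coded 1) and ME is the partial Kendall correlation given the cell fractions:
the pairwise tau-b matrix of [group, ME, covariates] is inverted and the
partial correlation read off the inverse; p-values use the normal
approximation z = pcor * sqrt(9 n (n-1-g) / (2 (2(n-g)+5))), two-sided.
Because the six fractions sum to one, one covariate column (neutrophil, the
largest) is dropped by default; a flag restores all six with a
pseudo-inverse. Benjamini–Hochberg FDR is applied across segments per
contrast. Aging DERs come from elder vs younger; segments significant with
*higher* entropy in elders are high-DERs; high-DERs that are also
significant with *lower* entropy in LLI vs elder form the LLI-specific LER
set. The default threshold is q < 0.05 (the stricter 0.01 used in parts of
the original analysis is a parameter). Whether the LLI contrast should be
FDR-corrected over all segments or only over high-DERs is ambiguous in the
source material; the default corrects over all segments.

Cell-type attribution follows the CellDMC interaction design: per segment,
OLS of ME on the six fractions plus the six fraction-x-phenotype products,
no global intercept (the fractions span it). The interaction coefficient
gamma_c estimates the phenotype effect in cell type c; per-cell-type BH
across segments, and in the default "exclusive" mode a segment is assigned
to c only when no other cell type is significant. Near-singular designs
(a cell type with no fraction variance) yield NA coefficients with a
warning. The z-approximation for partial Kendall p-values is asymptotic;
exact small-n Kendall null distributions are out of scope.

Region-set enrichment is the classic 2x2 association of a query segment set
against its universe by >= 1 bp interval overlap (segment span = first to
last CpG, converted to 0-based half-open): sample odds ratio with Haldane
0.5 correction only when a zero cell occurs (flagged), Fisher's exact p when
the smallest margin is <= 10^4, otherwise a chi-square approximation
(flagged). Two-sided by default since the original test's sidedness is
unstated; one-sided available. Promoters are classed into CpG O/E tertiles
((CpG count x L)/(C x G), N bases excluded) with linear-interpolation
quantiles and boundary ties falling to the lower class.

Classical (Torgerson) MDS embeds samples from Euclidean distances over the
most variable called segments (top 20,000 at genome scale; the bundled
analysis uses the most variable 2,000 of the called set), with a
deterministic sign convention (largest-magnitude loading positive).

## Transcriptional noise (MAV)

For scRNA counts, cells with >= 500 expressed genes and <= 5% mitochondrial
counts are retained (both inclusive; the bundled synthetic analyses use
looser thresholds suited to the 2,000-gene simulation), counts are
log-normalized as ln(1 + count/cell_total x 10^4), and a gene's
mean-adjusted variability (MAV) within a donor group is its squared CV of
normalized expression divided by the median squared CV of its mean-
expression bin (20 equal-count bins; bins under 5 genes merged downward).
The exact MAV formula used by the original study is not printed in it; this
bin-median-normalized squared CV is positive and ratio-interpretable, is
isolated behind one function so a loess-residual variant can be swapped in,
and self-normalizes to 1 for typical genes. MAV is computed over all cells
of a group rather than per cell type — the per-cell-type alternative is an
open choice the data formats support.

The noise contrast for a gene set is the mean MAV_LLI/MAV_non-LLI ratio,
tested one-sided (lower) against `n_boot = 1000` equal-size gene sets drawn
without replacement from the complement; p = (1 + #{null <= obs})/(n_boot+1),
so the attainable floor is 1/1001 — the resolution needed to state
p < 0.001.

## Synthetic cohorts

The generator produces the statistical structure the inference assumes, with
planted ground truth, in the file formats the IO layer reads.

Ages are drawn per group (LLI 101 +/- 3.5, elder 74.4 +/- 2.5, younger
58.6 +/- 5.7 years, clipped at 3 sd) for 79/20/34 samples. Each cell type in
each segment has a base pattern distribution built from per-CpG methylation
probabilities drawn from a bimodal Beta(0.3,3)/Beta(3,0.3) mixture (young
methylomes are ordered; the same bimodal draw builds the deconvolution
reference, which keeps it well separated). Drift: a sample of age `a` keeps
its base distribution with weight w = alpha/(alpha+1), where
alpha = alpha0 exp(-drift_slope * a), and mixes toward the uniform pattern
distribution with weight 1-w. In planted LER segments of LLI samples, alpha
is multiplied by `lli_suppression`, restoring order — in all cell types
("all") or only in a responsible cell type. Cell fractions are Dirichlet
around blood-like means (neutrophil 0.55); read counts per segment are
N = 5 + Poisson(coverage_mean - 5) (the 5-read floor mirrors the coverage
filter), drawn Dirichlet-multinomial around the fraction-weighted mixture
with replicate concentration kappa. Per-site betas are the pattern
marginals; additive sum-to-zero batch offsets (+/- 0.02 over two batches)
are applied to betas, then clipped to [0,1]. Reference-site betas are
reference x fractions plus N(0, 0.02) noise and the batch offset. All
randomness flows from one seed; equal seeds give byte-identical files.

Default preset (chosen once from the cohort structure and held fixed):
alpha0 = 40, drift_slope = 0.045/yr, lli_suppression = 8, kappa = 60,
coverage_mean = 30, fraction concentration 25, 20,000 segments, 10% planted
LERs. These values put the elder/younger ME gap near 0.11 and the planted
LLI suppression near 0.13 below the elder mean — effects a 20/34-sample
contrast detects through rank statistics without being trivial.

The cell-type experiment (responsible cell type = neutrophil) uses
lli_suppression = 60, kappa = 160, fraction_conc = 10, coverage_mean = 60.
The interaction design walks a narrow power corridor at 79 LLI vs 20 elder
samples: the shared aging effect between the groups loads on *every*
fraction-x-phenotype column, so an over-powered experiment makes other cell
types significant and breaks exclusive attribution, while an under-powered
one loses the neutrophil term whenever the elder group's fraction spread
comes out small. The chosen point detects the planted cell type in ~82-93%
of planted segments across seeds while other cell types stay below
threshold.

scRNA counts are gamma-Poisson with variance mu + disp * mu^2, lognormal
gene means and library sizes, 12 donors (7 LLI / 5 controls), 300 cells
each, ~2.5% mitochondrial genes; the planted 100-gene set has its
overdispersion coefficient multiplied by 0.5 in LLI cells.

### What the generator does and does not emulate

It reproduces: age-monotone read-pattern entropy, group structure and
LLI-specific regional suppression, compositional confounding with a usable
reference panel, batch offsets, overdispersed read sampling, and
variability-shifted scRNA counts. It does not reproduce: genomic
autocorrelation of methylation (segments are independent), realistic CpG
spacing or strand effects, cell-type-specific aging rates, or the empirical
*global* direction of site-level dispersion with age — under strong pattern
drift the simulated betas converge on 0.5, so per-sample CV *falls* with
age and QE saturates once middle bins dominate (QE's drift response is
monotone only for drift_slope <= ~0.03/yr, which is how the property test
probes it; ME is monotone over the full range). Passing recovery tests
therefore demonstrate the inference machinery under the assumed drift
model, not the full texture of real WGBS data.

## Numerical choices

- Zero coverage, zero mean, constant vectors: NaN sentinels, never silent 0.
- 0 log 0 = 0 throughout entropy code; QE clips betas to [0,1] first.
- CV uses the sample (n-1) standard deviation by default (ddof parameter).
- Site filter: "coverage >= 10x in over 60% of samples" is a strict >;
  an inclusive >= switch exists. Group coverage uses ceil(frac x group
  size), reproducing thresholds (40, 17, 10) for sizes (79, 34, 20).
- Segment windows slide by one CpG by default (disjoint tiling available).
  Strand-merging of CpG dinucleotides is off by default.
- Batch correction fits sum-to-zero contrasts per feature and subtracts the
  re-centered batch component, so per-feature means are preserved exactly
  even for unbalanced batches; it is idempotent to 1e-8.
- Tau-b uses the O(n log n) library routine; the batched per-segment version
  is an O(n^2) sign-pair sum validated against it. Tau matrices are inverted
  exactly, with pseudo-inverse fallback (warned) near singularity.
- MDS clamps negative eigenvalues to zero coordinates.
- Bootstrap draws use order statistics of uniform keys, vectorized, seeded.

## Problem sizes

Recovery analyses run 20,000 segments x 133 samples (3 seeds), the
cell-type experiment 4,000 segments, null calibrations 4,000 segments, and
the MAV analysis 2,000 genes x 3,600 cells with 1,000-set bootstraps and a
200-replicate null calibration. These sizes keep every planted count large
enough for stable rates (>= 200 planted segments per run) while the full
acceptance script completes in a few minutes on one CPU.

## Known limitations

- The partial-Kendall p-value is asymptotic; at very small n it is
  anti-conservative and the per-segment skip rule (>= 3 complete samples per
  group) is a floor, not a guarantee of calibration.
- Exclusive-mode cell-type attribution inherits the compositional leakage
  described above; with very strong signals, "exclusive" becomes strict and
  the "any" mode is the better screen.
- The MAV definition is one reasonable reading of an unprinted formula; the
  bootstrap comparison is valid for any fixed per-gene score, but absolute
  MAV values are not comparable across definitions.
- Enrichment p-values for very large tables use a chi-square approximation;
  at genome scale the practical answer ("p < 2.2e-16") is unaffected.
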