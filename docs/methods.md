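# Methods

This note documents the models and procedures implemented in `brainchrom`,
the choices made where the design was genuinely open, and what the
synthetic harness does and does not establish about real data.

## The synthetic cohort

All analyses run on generated data with known ground truth
(`brainchrom.synthgen`). The generator emulates a bulk ATAC-seq
case–control study of postmortem prefrontal cortex at desk scale.

**Genome.** A configurable number of autosomes (default 2 × 1 Mb) plus
chrX and a half-length chrY; TSS positions uniform per chromosome with
strands and expression-quartile labels (Q0–Q4) drawn uniformly; a
blacklist of random 0.5–2 kb intervals covering a configurable fraction
(default 2%) of each chromosome; the mappable track is the full genome
(upstream mappability filtering is represented by the mask itself).

**Metadata.** Cohort variables are shaped like a schizophrenia brain bank
series: cases skew male (68% vs 53%), ages ≈ 74 ± 13–18 y in both groups,
case PMIs gamma-distributed around 24 h vs 11 h for controls, RIN slightly
lower in cases, plus batch and GC-content technical variables. These give
the covariate-selection and matching steps realistic structure to find.

**Genotypes.** Block-exchangeable LD rather than coalescent simulation:
each block of (default) 10 consecutive SNPs shares a latent biallelic
haplotype per chromosome copy; SNP alleles flip the latent allele with a
probability rising from 0 to 0.05 along the block, so r² decays with
intra-block distance (≈1 → ≈0.8) and vanishes between blocks. This is
sufficient for cis-window and LD-score behavior and is cheap. Dosages are
haplotype sums in {0, 1, 2}; empirical MAF stays within ±0.05 of the
configured band by construction (flip probability ≤ 0.05). An optional
``block_jitter`` draws block lengths uniformly around the target size:
with equal blocks every SNP has nearly the same base LD score, which
leaves the base τ and the regression intercept barely identifiable in the
stratified regression; jittered blocks restore the variable LD landscape
that identifies them (the width experiment uses jitter 8).

**Counts.** Negative-binomial with
log μ_gs = log baseline_g + log libfactor_s + ln2·log2FC_g·I(case_s)
+ slopes·(age_z, pmi_z) + batch shift + β_cqtl·(dosage − mean). Baselines
are log-normal around the configured mean depth (default 100
reads/peak/sample); library factors log-normal (σ = 0.25); dispersion
default 0.2, with the Poisson limit below 1e-8. chrY peak counts are
zeroed in females so the male-only rule is exercisable. Fragment
placements (for the quantification/QC stages) follow a triangular density
peaking at the summit inside peaks and a uniform background over the
mappable genome — center-concentrated signal is what makes the peak-width
heritability experiment meaningful.

**GWAS summary statistics.** Per-SNP effects β_j ~ N(0, Σ_c τ_c a_jc);
genetic values are formed on the reference cohort, marginal standardized
effects are α = X'(Xβ)/n, and observed z_j = √N·α_j + N(0, 1). This gives
E[χ²_j] = 1 + N·Σ_c τ_c ℓ(j, c) without simulating N individuals. A
finite reference panel leaks a near-uniform noise term (∝ M/n) into every
χ²; it is absorbed by the regression intercept, but experiments that need
a clean signal-to-noise ratio (the width series) simulate the GWAS on a
larger cohort (n = 1000) and compute LD scores on a 200-sample subpanel,
as in real applications where the reference is smaller than the study.

**Allelic reads.** For heterozygotes at a peak-resident SNP, alt reads ~
Binomial(depth, σ(β)) with σ the logistic function and β the cQTL effect;
β = 0 gives the balanced null. Homozygotes emit no record; SNPs outside
their peak are skipped and counted.

Generator magnitudes (effect sizes, noise scales, coupling strengths) are
free parameters of the harness, not estimates from any cohort; defaults
were chosen once to be detectable but not trivial at the default scale
(288 × 5,000 × 20,000; the analysis drivers and tests run a smaller
96 × 600 × 3,000 configuration).

## Peak matrix

**Merging.** Per-sample peak calls are unioned across samples per
chromosome (strict >0 bp overlap, 0-based half-open); union regions
supported by fewer than 2 samples are dropped; each survivor becomes one
300-bp peak centered on the *median* of the contributing summits (lower
coordinate on half-integer medians). The median was chosen over the mean
for robustness to a single outlying summit; ties break toward the lower
coordinate.

**Quantification.** Fragments are extended to 300 bp from their start;
a fragment counts for every peak its extension overlaps by ≥1 bp.

**TMM.** M and A values over peaks positive in both sample and reference;
the top/bottom 30% of M and 5% of A (by rank) are discarded; the factor is
2^(weighted mean M) with inverse asymptotic-variance weights
(N−y)/(Ny) + (N_r−y_r)/(N_r y_r); factors are rescaled to geometric
mean 1. The reference sample is the one whose 75th-percentile count
fraction is closest to the mean (the edgeR convention); the test suite
cross-checks factors against edgeR's `calcNormFactors` when Rscript is
available.

**Shuffle-null enrichment.** Peaks are re-placed uniformly (rejection
sampling over the cumulative length map of mappable − blacklist −
excluded), non-overlapping with each other. Per-sample enrichment is total
reads in real peaks / mean over shuffles of reads in shuffled peaks;
per-peak scores divide observed reads by the median shuffled-peak count,
floored at 0.5 reads because the median is often 0 at low depth.

**Replicate concordance.** Statistic = mean within-pair Spearman ρ −
mean between-pair ρ on log2 CPM; the null re-pairs random samples;
p = (1 + #{perm ≥ obs})/(1 + n_perm).

**TSS annotation.** Distance from peak center to nearest TSS, signed by
TSS strand (positive = downstream); classes ±5 kb / 5–25 kb / >25 kb with
closed boundaries at 5,000 and 25,000. Chromosomes with no TSS yield +∞ /
">25kb". Only upstream/downstream orientation is emitted — the genome
model carries TSS points, not gene bodies, so a within-gene flag would be
undefined.

## Covariates

Screening drops invariant variables, variables >5% missing, and
categoricals with >30 levels; diagnosis and sex are protected.
Imputation is deliberately simple — numeric medians, categorical draws
from observed level frequencies with a seed — because downstream stages
only require completeness; tree-based imputation would add an external
model without changing what is being tested here.

Diagnosis association uses one-way regression F tests for numeric
variables and Pearson χ² *without* continuity correction for categoricals
(the uncorrected statistic is the convention for cohort tables of this
size; the test suite pins the 2×2 and 4×2 worked examples to 6.30 and
7.92).

Covariate selection iterates: PCA (centered, unscaled) of
log2(count/(lib·f_k)·1e6 + 0.5); simple regressions of every variable on
each of the top 20 PCs (each PC separately); Bonferroni threshold
α/(n_vars × n_PCs); among passing variables pick by (1) technical tag,
(2) largest R² on its best PC, (3) fewest parameters, (4) name;
residualize the matrix against the selected set and repeat, capped at 25
iterations. Variables that are significant in a round but collinear with
the selected design (condition number > 1e8) are recorded as unresolvable
and set the final status to `collinearity` — they cannot be corrected
for, mirroring what happens in real cohorts when, e.g., lane is collinear
with submission date.

Identity matching is rounded-dosage concordance over shared SNPs; under
Hardy–Weinberg with MAF 0.3 two unrelated samples agree at ≈ Σ P(g)² ≈
0.42 of sites, so the 0.8 mismatch threshold separates cleanly.

## Differential accessibility

Per-peak NB GLM with log link at fixed per-peak dispersion, fit by IRLS
batched across peaks (the design is shared, so the weighted least-squares
step is a stacked 3-index einsum). Dispersion: method-of-moments on
Poisson-fit residuals, Σ[(y−μ)² − μ]/Σμ² with an n/(n−p) correction,
floored at 1e-8, then shrunk 50/50 toward a fitted a₀ + a₁/mean trend —
a fixed-weight simplification of empirical-Bayes curves, documented as
such. Wald tests against the standard normal; effects reported as log2
fold changes of the case level (explicit case = 1 coding, so signs match
the generator's truth tables).

Routing: autosomes full model; chrX fit separately in males and females
and combined by inverse-variance weighting (a stratum that fails to
converge or has <3 samples degrades the route to single-stratum, flagged);
chrY males only with sex dropped. BH FDR across all peaks of a scan.
Offsets default to log(lib_size × TMM factor); a median-of-ratios
alternative is selectable (`size_factor="median-ratio"`) since NB count
pipelines differ on this point.

Matched subsets use greedy nearest-neighbor 1:1 matching within sex on
standardized Euclidean distance with a caliper, reporting standardized
mean differences.

## cQTL mapping

Phenotype = log2 CPM (rank-normal optional at the call site); covariates
(10 phenotype PCs computed before any residualization + 5 genotype PCs)
are residualized out of both phenotype and dosages once, then per-SNP
slopes use t tests with n − rank(C) − 1 degrees of freedom. The cis
window is ±5 kb around the *peak center*, boundary inclusive; ties on the
minimum p go to the nearest SNP, then lexicographic id.

Permutation adjustment permutes the residualized phenotype (default
1000), records per-permutation minima of the nominal p over the cis set,
fits Beta(a, b) by constrained ML (method-of-moments start; moment
fallback on optimizer failure), and evaluates the regularized incomplete
beta at the observed minimum. Degenerate permutation distributions fall
back to the empirical permutation p with a flag. The
effective-degrees-of-freedom refinement some cis-QTL tools apply to the
nominal p under permutation is *not* implemented; the direct Beta fit is
calibrated on these simulations (KS-uniform adjusted p under the null)
and b̂ recovers the effective test count (≈ K for K independent SNPs,
since the min of K uniforms is Beta(1, K)).

Storey q-values: π₀(λ) on the 0.05…0.95 grid, cubic polynomial
extrapolated to λ = 1, clipped to (0, 1]; q = π₀ × BH. Fewer than ~76
p-values trigger a π₀ = 1 (pure BH) fallback with a warning.

The interaction scan adds diagnosis and dosage×diagnosis terms on
residualized data and permutes diagnosis labels (default 10,000), exact
p = (1 + #{|t| ≥ |t_obs|})/(1 + n_perm).

Allelic validation: records with ≥10 reads; concordance is the fraction
of cQTL SNPs whose pooled alt fraction deviates from 0.5 in the direction
of the alt-allele effect; the χ² compares 10-bin alt-fraction histograms
(edges 0, 0.1, …, 1, closed on the right) of cQTL vs non-cQTL
heterozygote records.

## Integration

Sharing: one eQTL p per gene (random, most-, or least-significant mode),
π₁ = 1 − π₀ by the Storey estimator on the matched set. Direction
concordance: same-sign fraction with an exact two-sided binomial test;
zero effects are excluded and counted.

Colocalization: Wakefield log-ABF = ½log(1−r) + ½z²r with r = W/(V+W);
prior SDs W = 0.15 for quantitative traits and 0.2 for case–control
log-odds; priors p1 = p2 = 1e-4, p12 = 1e-5 (standard defaults,
overridable). Hypothesis sums run in log space (GWAS z up to ~40 would
overflow otherwise); H3 uses an exact off-diagonal log-sum-exp for ≤1000
SNPs and the algebraic S1·S2 − S12 identity above that. Inputs may be
(BETA, SE) or (P, MAF, N); the latter backs out the standardized effect.
A 2-SNP exhaustive enumeration oracle pins the configuration arithmetic
to 1e-12.

## Heritability

LD scores: ℓ(j, c) = Σ_k∈c,|pos_j−pos_k|≤window r²_adj(j, k) with
r²_adj = r² − (1−r²)/(n−2) and the self term included; a fixed 1 Mb
physical window stands in for the usual 1 cM (the synthetic genome has no
genetic map). Computation is chunked matrix products of standardized
dosages restricted per chromosome to the window's column range.

Regression: χ²_j on {N·ℓ(j, c)} + intercept, one-step WLS with
1/max(ℓ_base, 1) weights (a documented simplification of iterative LDSC
weighting). τ̂ maps to per-category h² via h²_c = Σ_j∈c Σ_c' τ̂_c' a_jc';
enrichment = (h²_c/h²_tot)/(M_c/M). Uncertainty from a 20-block
contiguous-SNP jackknife (desk-scale replacement for 200 blocks;
configurable): coefficient z = τ̂/SE_jack(τ̂), enrichment p from a
jackknife-t of (enrichment − 1).

Annotations: base (all SNPs), the peak set resized about summits at each
requested width, a ±500 bp companion *excluding* the peak (so peak and
companion partition the padded interval — the companion absorbs
flank LD that would otherwise inflate the focal estimate), conserved,
conserved∩peak, and GWA-locus membership; width resizes clip at
chromosome bounds with a counter.

The width experiment rebuilds annotations and reruns the regression per
width (100, 300, 1000, 2000, 5000, 10000 bp). With causal variants placed
at summits, the enrichment series should be non-increasing; the evaluation
allows one inversion within joint SEs, since adjacent widths share most of
their SNPs and the jackknife SEs at 0.5–1% SNP shares are wide.

## Evaluation harness and problem sizes

`brainchrom.experiments` fixes the evaluation conditions; the test suite
and `scripts/acceptance.py` both call it:

- permutation-null calibration: 200 peaks × 200 samples × 1000
  permutations, 10 cis SNPs per peak;
- Beta-null shape: 200 peaks × 50 independent cis SNPs;
- τ recovery: 100 runs at M = 20,000 SNPs, N = 50,000, fresh 200-sample
  panel per run (a fixed panel freezes its LD noise into every run and
  biases coverage; fresh panels make the 2-SE jackknife interval honest);
- width series: 300 summit-centered peaks on a 4 × 4 Mb genome with
  jittered LD blocks, GWAS cohort 1000, LD panel 200, base h² large enough
  (0.2) that the total-h² denominator of the enrichment ratio is stable;
- differential FDR: 5,000 peaks, 100 injected |log2FC| = 1.5 effects,
  50/50 cases/controls;
- sharing: 2,000 genes, 30% alternative mixture;
- allelic bias: 60 cQTL + 60 control SNPs, depth 50, |β| = 1.

## Known limitations

- The LD model has no recombination-distance structure beyond blocks; LD
  scores and cis scans see realistic magnitudes but not realistic decay
  shapes.
- Counts are conditionally independent across peaks given the design;
  real co-accessibility (footprints, domains) is absent, so multiple-
  testing behavior on real data may be more dependent than simulated.
- The stratified regression uses a small generic baseline (base + focal
  categories); the full multi-annotation baseline model used on real GWAS
  requires external annotation files and is out of scope.
- Imputation, dispersion shrinkage, and LDSC weighting are deliberately
  simple fixed-form versions of their production counterparts; each is
  flagged where implemented.
- Significant cQTL peaks on the small demo cohort include LD-neighbors of
  truly causal SNPs; precision against the truth table understates
  biological specificity for that reason.
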