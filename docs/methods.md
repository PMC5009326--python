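# Methods

This note documents the models and procedures implemented in `netsig`,
the assumptions behind them, the choices made where the design was
genuinely open, and what the synthetic data does and does not show.

## Rank-based signature classification

Expression profiles from two subject groups (APOE33 vs APOE44 carriers
with Alzheimer's disease) are compared without any cross-sample
normalization: all information enters through the *within-sample
ranking* of probes, which makes the method robust to monotone
per-sample distortions at the cost of discarding magnitude.

**Probe filter.** A two-sided Wilcoxon rank-sum test per probe
(`scipy.stats.mannwhitneyu`; exact null for small untied samples,
tie-corrected normal approximation otherwise). Probes with
p ≤ `alpha_filter` are retained, sorted by probe id so downstream
output never depends on input row order. Probes constant across both
groups get p = 1. If the filter retains fewer than `n1 + n2` probes it
is topped up with the smallest-p probes and a warning is logged.

**Signatures.** Within each sample the retained probes are sorted by
descending abundance (ties by ascending probe id — a deterministic
convention so results reproduce across platforms); the signature is the
first `n1` and last `n2` probe ids. `n1` and `n2` are shared by all
samples.

**Distance.** For a probe set S and a ranking R of P probes, the
weighted enrichment score ES(S | R) is the signed maximum deviation of
a running sum that gains `|s_i|^q / Σ|s_hits|^q` at members of S and
loses `1/(P − |S|)` elsewhere, where `s_i = 1 − 2(i−1)/(P−1)` is a
linear position score (+1 at the top, −1 at the bottom) and
q = `weight_exponent` (default 1). ES ∈ [−1, 1]: +1 when S occupies
the top of R, −1 when it occupies the bottom. When the largest positive
and negative deviations tie in magnitude the positive one is returned,
so the sign never depends on floating-point summation order. The
production path evaluates only the 2|S| candidate extrema of the
piecewise-linear running sum; a literal position-by-position oracle
backs it in the tests to 1e−12.

Two samples A, B with rankings R_A, R_B and signatures
(top_A, bot_A), (top_B, bot_B) are compared by cross-evaluation:

    s = ES(top_A | R_B) − ES(bot_A | R_B)
      + ES(top_B | R_A) − ES(bot_B | R_A)        s ∈ [−4, 4]
    d(A, B) = 1 − (s + 4) / 8                     d ∈ [0, 1]

Identical rankings give d = 0 (each top set sits at its own top, each
bottom set at its own bottom) and perfectly anti-correlated rankings
give d = 1. The affine map is fixed by those two anchor cases; a
two-way cross-evaluation with a differently scaled map cannot satisfy
both. d is symmetric by construction.

**Classification.** A sample takes the label of the group with the
smaller mean signature distance to its members. Exact ties go to the
lexicographically smaller label and are flagged.

**Cross-validation.** Stratified k-fold (default 10; reduced with a
warning when the smaller group has fewer members). The Wilcoxon filter
and all signatures are re-fit inside each training fold; test-fold
samples are ranked on the training fold's retained probes only, so no
test information reaches probe selection. Accuracy plus macro-averaged
precision and recall are reported per fold and summarized. A
label-permutation test in the suite confirms chance-level accuracy
under the null (no leakage).

**Permutation test.** The observed statistic is leave-one-out accuracy
computed from the full-data distance matrix, with the filter re-fit
for every permutation — cheap enough to repeat thousands of times,
unlike nested 10-fold CV, while preserving the selection step inside
the null. Two permutation units are provided: group labels (default)
and per-sample probe shuffling, which destroys the cross-sample rank
structure while keeping each sample's value distribution; the
field's phrasing for this test is ambiguous between the two, so both
are exposed and neither is claimed as canonical.
p = (1 + #{perm ≥ obs}) / (1 + n_perm), so p ∈ (0, 1] always.

**Genetic algorithm.** Individuals are index triples into candidate
grids for (n1, n2, alpha_filter). Fitness is mean CV accuracy minus
`λ_len (n1+n2)/P` (λ_len = 0.01, P = retained probes at that
stringency), expressing the goal of the *shortest* signature that
still discriminates. Tournament selection (size 3), uniform crossover
(p = 0.7), per-gene mutation (p = 0.1), elitism 1, population 40,
25 generations by default — small enough for desk-scale data; all
evaluations are memoized and the trajectory is deterministic for a
fixed seed. On small grids the GA provably reaches the exhaustive
grid-search optimum in the tests.

**Biomarker.** The union of all per-sample signatures, mapped to gene
symbols (many probes → one gene allowed). Gene-level p-values for the
network stage take the minimum filter p over a gene's probes.

## Random-walk network expansion

Node scores: biomarker genes present in the network carry −log₂ of
their filter p-value; all other nodes carry ε (default 10⁻³ of the
smallest positive biomarker score). The ε floor keeps the restart
vector strictly positive and the walk irreducible; genes absent from
the network are reported, not silently dropped.

The walk solves π = (1−r)·W·π + r·s with W the column-normalized
adjacency, s the normalized score vector, and restart probability
r = 0.5 (the customary default in this tool family; exposed as a
parameter). Power iteration to an L1 tolerance of 1e−10 (cap 10⁴
iterations, error with diagnostics on failure); the fixed point is
checked against a direct linear solve in the tests.

**Edge scoring.** The directed stationary flux along u→v is
π(u)·W(v|u) = π(u)/deg(u). The default edge score is

    score(u,v) = log₂ [ min(π_w(u)/deg(u), π_w(v)/deg(v))
                      / min(π_b(u)/deg(u), π_b(v)/deg(v)) ]

where π_w is the score-weighted walk and π_b a baseline walk with
uniform restart. Taking the *minimum* direction makes the score high
only when both endpoints carry elevated mass, which separates
module-internal edges sharply from edges that merely touch one seeded
gene; with the summed flux the one-seeded edges interpolate smoothly
between the module block and the background and no threshold can
isolate the module. The summed-flux ratio and the raw weighted flux
remain available via `mode="sum_ratio"` / `"raw"`. A uniformly seeded
walk scores every edge 0 under either ratio.

**Threshold.** Scores are sorted descending and the largest gap whose
upper value is at or above the median — and which has at least
`min_block` (10) edges above it — is located; its midpoint is the
threshold. The median restriction keeps the cut well above the bulk of
near-baseline scores, and the block-size floor prevents a single
outlying top edge from masquerading as "the step". If the winning gap
does not exceed 3× the median candidate gap the curve is declared
step-free and the top-k fallback (k = 10) is used with a warning; a
manual threshold is always accepted. The rule is scale-equivariant:
scaling all scores by c > 0 scales the threshold by c.

**Subnetwork.** Edges with score strictly above the threshold and
their induced genes. All connected components are kept by default
(sizes logged, largest flagged) since a disease process need not be
one component; `largest_only=True` restricts to the largest.

## Over-representation analysis

For query q against set S in universe U: k = |q∩S|, p = P(X ≥ k) for
X ~ Hypergeometric(|U|, |S|, |q|) (`scipy.stats.hypergeom.sf`; standard
tail, not mid-p). Benjamini–Hochberg across the collection; default
significance threshold q ≤ 0.001. Query genes outside the universe are
dropped with a warning. The DE filter reports the linear-scale
fold-change ratio (direction-aware) and a two-sided Welch t-test on
the log scale; a gene passes at FC ≥ 1.5 and p < 0.02 with *no*
multiplicity adjustment — deliberately matching the legacy
single-gene screening convention — while a BH column is included for
context. The Welch t-test stands in for a moderated (shrinkage)
t-statistic; with the ≥9 samples per group this filter is used on, the
difference is modest, but small-sample variance estimates are noisier
than a moderated analysis would give.

## APOE × SNP epistasis scan

**QC.** Samples with genotype call rate < 95% are removed first; then
SNPs that are non-autosomal, have call rate < 95%, or minor allele
frequency < 0.05 (computed on the retained samples). The order is
recorded in the report.

**Stratification.** Classical metric MDS (principal coordinates) of
the pairwise allele-sharing distance 1 − IBS, with
IBS = mean over co-observed SNPs of (2 − |d_i − d_j|)/2, computed via
one-hot matrix products so missing calls cost nothing extra. The top
three axes enter the regression as covariates; each axis's sign is
fixed by making its largest-magnitude loading positive, so coordinates
are deterministic and invariant to sample order. An outlier rule
(|coordinate| > 6 SD on any top axis) is provided for cohorts that
need it.

**Per-SNP model.** Ordinary least squares,

    AAO ~ 1 + APOE4 + dosage + APOE4·dosage + MDS1..3

with AAO the age at onset in years and APOE4 the ε4 allele count
(0/1/2 — this generalizes both a 33-vs-44 binary and allele dosage; a
binary coding can be obtained by recoding the phenotype column).
Missing dosages are handled per-SNP by complete-case analysis (no
imputation). The interaction coefficient, its SE, t and two-sided p
(t distribution, residual df) are reported; collinear designs
(monomorphic SNPs, < 10 complete cases) are flagged NA rather than
dropped. The in-package solver is cross-checked against statsmodels
OLS and a normal-equations oracle to 1e−10.

**Meta-analysis.** Per study z = sign(β)·Φ⁻¹(1 − p/2). Genomic
control per study before combining: λ = median(z²)/0.4549, z ← z/√λ
with λ floored at 1 (the convention of the standard GWAS meta-analysis
tools). Combined z = (√N₁·z₁ + √N₂·z₂)/√(N₁+N₂), p = 2Φ(−|z|).
Allele orientation is harmonized by A1/A2 matching (swapped alleles
flip the sign; incompatible alleles drop the SNP with a warning).
SNPs with discordant per-study directions are removed; survivors map
to genes whose 1-based inclusive [start, end] interval contains the
SNP position on the same chromosome (overlaps give multiple
assignments). FDR is Benjamini–Hochberg by default (deterministic,
assumption-light); a Storey-style variant with π₀ = min(1, 2·mean(p>0.5))
is available behind a flag — density-based local-FDR estimators give
slightly different q-values, a documented divergence. LD between
reported SNP pairs is summarized as r² and D′ from unphased dosages
via the standard two-locus EM (only the double heterozygote is
phase-ambiguous).

## Synthetic data

The generator produces data *with the statistical structure the
analysis assumes*, at the scale of the motivating studies:

- **Expression**: 43 vs 34 samples (the APOE33/APOE44 split of the
  cortical microarray study that motivated the defaults; the
  alternative 47/30 split reported elsewhere for the same cohort is
  reachable through `n_samples_per_group`), 1000 probes of which 50
  carry a between-group mean shift of exactly
  `effect_size · noise_sd`, alternating in sign so signatures gain
  both top and bottom markers. Gaussian noise on log-scale abundances
  (microarray-like); an RNA-seq-like variant draws negative-binomial
  counts around the same log2 means. Probe→gene is many-to-one.
- **Network**: a Barabási–Albert graph (500 genes, attachment 2) with
  a connected 50-node module grown by BFS and wired internally to
  density 0.15. Functional modules in curated interaction networks
  are far denser than the scale-free background; without the
  densification the module has ~0.05 internal density and no
  walk-based method can outline it. 80% of the informative genes are
  placed in the module, the rest outside.
- **Gene sets**: one "true" set drawn 90% from the module, the rest
  uniform from the network's gene universe.
- **Cohorts**: 600 samples × 500 SNPs each, MAF ~ U(0.1, 0.5) shared
  between cohorts, dosages Binomial(2, f). Age at onset
  = 75 − 2.5·APOE4 + 0.8·(APOE4·dosage) at 5 planted SNPs
  + structure offset + N(0, 3) years; the ε4 count lowers onset age,
  as established for this allele, and the planted interaction of 0.8
  years per allele-pair product is a plausible modifier-locus effect.
  Two latent subpopulations diverge in allele frequency by
  `0.1·structure_strength·√(f(1−f))` and in onset age by
  `structure_strength` years, making the MDS adjustment testable. 1%
  of calls are missing to exercise QC. APOE4 counts are drawn with
  probabilities (0.30, 0.47, 0.23), matching the AD-case genotype
  distributions of the motivating cohorts.

What passing tests on these data show: the pipeline recovers planted
structure of realistic effect size at realistic sample sizes, its
statistics are calibrated under the null, and its numerics agree with
independent oracles. What they do not show: robustness to correlated
probes, batch effects, LD between SNPs (cohort SNPs are independent —
LD summaries are exercised on constructed examples), haplotype
structure, genotyping error, or network curation bias. Absolute
accuracy/recovery numbers on real cohorts will differ.

## Numerical and procedural choices

- All randomness flows from one global seed through named per-stage
  substreams (`stage_seed`), so any stage can be re-run in isolation
  bit-identically; run manifests record config, seeds and output
  checksums and are written atomically.
- RWR: L1 tolerance 1e−10, iteration cap 10⁴; stationary vectors are
  asserted nonnegative and sum-to-one at 1e−9 on every run.
- Distance matrices are asserted symmetric, zero-diagonal and within
  [0, 1] on every run.
- Ranking ties break by ascending probe id; ES magnitude ties break
  positive; classification ties break to the lexicographically smaller
  label with a flag — every tie rule is deterministic.
- Degenerate inputs: constant probes (p = 1), monomorphic SNPs
  (flagged NA), empty queries/universes (errors), fewer than three
  distinct edge scores (error), step-free score curves (top-k fallback
  with a warning).
- Coordinates in files are 1-based inclusive; interval logic converts
  at the I/O boundary.

## Test problem sizes

Seed-averaged checks use 10 seeds at the study-scale defaults above
(the classifier and walk recovery checks each take ~1–2 s per seed).
Permutation-test calibration uses 100 replicates of a 16-sample,
40-probe null dataset at 49 permutations each; the type-I error check
pools 2000 null SNPs from 20 independent cohorts (one cohort's SNPs
share a phenotype vector, so pooling cohorts keeps the rejection-rate
estimator near-binomial); genomic-control λ is estimated from 5000
null z-scores, where the sample median of z² has ~2% relative SD.
These sizes make the full suite complete in a few minutes while
keeping each statistical assertion's noise level well inside its
tolerance.

## Known limitations

- The enrichment-score distance is one member of the family of
  rank-signature distances; the weight exponent changes the emphasis
  on extreme ranks and is exposed but defaults to 1.
- Genomic control assumes test statistics are exchangeable across
  SNPs; with very few SNPs (as in reduced test panels) λ is noisy and
  the floor at 1 means mild deflation is never "corrected" upward.
- The gene-boundary SNP mapping ignores regulatory regions beyond the
  gene body; a SNP tagging a causal variant in a neighboring gene will
  be attributed to the wrong gene, an inherent limit of gene-directed
  association scans.
- Multi-class (> 2 group) classification and binary genotype
  containers (PLINK BED, VCF) are out of scope; inputs are plain TSV.
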