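# Methods

This note documents the statistical models the package implements, the
generative model behind its synthetic data, the defaults that matter, and
the numerical choices made where the design was genuinely open.

## Summary-statistic model

All stages operate on GWAS summary statistics for rank-normal glycan traits:
per SNP and trait, an effect estimate β in standardized-trait units per
effect allele, its standard error, and the two-sided normal p-value of
z = β/se. For a standardized trait and allele frequency p (q = 1 − p), the
standard error of a marginal per-allele estimate at sample size N is
approximately 1/√(2pqN); the package uses this form both in the generator
and in the explained-variance calculus σ = 2pqβ².

**Meta-analysis.** Fixed-effect inverse variance: w_i = 1/se_i²,
β_meta = Σw_iβ_i/Σw_i, se_meta = 1/√Σw_i, with the pooled p-value taken from
z_meta (not from combining per-cohort p-values — the two disagree when
cohort weights differ). Alleles are harmonized first: a swapped record
negates β and reflects the frequency; strand flips are resolved by
complementing both alleles; palindromic (A/T, C/G) SNPs cannot be resolved
by complementation and are flagged but retained by default (a strict mode
drops them).

**Genomic control.** λ = median(z²)/0.4549 (the χ²₁ median). Standard
errors are inflated by √λ only when λ > 1; deflating sound statistics when
λ < 1 would manufacture significance, so sub-unity λ is recorded but not
applied. Whether the correction rescales se or χ² is equivalent at the
level of z and p; se-rescaling keeps β untouched.

## Locus mapping

Associations are called in three tiers with ≤ semantics at the boundaries:
genome-wide significant at α/m for m independent traits (default
5×10⁻⁸/21 ≈ 2.4×10⁻⁹ — glycan traits are strongly correlated, so the
effective number of independent traits, 21, replaces the raw 77), and
suggestive within one decade above. Loci are greedy LD clumps: visiting
called SNPs by ascending p, each unclaimed SNP seeds a locus and claims
called SNPs with r² ≥ 0.5 within 1 Mb; overlapping loci merge transitively
with the smallest-p member as lead. The r² floor and span are configurable —
no canonical values exist for this step — and deterministic tie-breaks
((p, snp id) lexicographic) make output independent of input row order.
Replication requires both p ≤ 0.05/(number of discovered loci) and a
discovery-concordant effect sign; the direction flag is reported separately
so sign-discordant near-misses remain visible.

## The effect-correlation network

A lead SNP's glycome-wide effect is its z-score vector over the retained
traits. Fifteen of the 77 traits are derived re-normalizations of directly
measured ones; because a derived trait is a monotone transform of its
parent, keeping it would double-count the parent's coordinate and inflate
|ρ| even between unrelated SNPs (a property the test suite demonstrates on
null SNP pairs), so derived traits are excluded, leaving 62 coordinates.

Edges are Spearman correlations with average ranks for ties. Edge p-values
use the t-approximation with n − 2 degrees of freedom — ample at n = 62; an
exact permutation p-value is available for short vectors (n < 10). The
network reports |ρ|: effect signs depend on the arbitrary choice of effect
allele, so only magnitude is informative. Pruning keeps edges with
p ≤ α/(number of edges tested).

**Permutation validation.** The null pool is built by removing from the
genome-wide SNP list (i) every SNP inside an associated locus and (ii) every
SNP with min-p ≤ 5×10⁻⁵ in any trait, with provenance counts recorded at
each stage. One sample of k SNPs (without replacement) is drawn once and
reused for every top SNP, matching the reading that the same random SNP set
serves all comparisons; per-top-SNP resampling is available by flag. The
reported quantile is upper-tail — the fraction of null |ρ| values at or
above the observed edge — so 0 means "no random SNP was as correlated".
Whether the quantile is taken of |ρ| or ρ² is immaterial: squaring is
monotone on [0,1] and leaves the quantile unchanged.

**Clustering.** Complete-linkage hierarchical clustering with Euclidean
distance on the rows of the absolute-correlation matrix (unit diagonal).
Absolute values are used for the same allele-orientation reason as above; a
signed-matrix mode exists for sensitivity analysis. The flat cut count k is
a user choice (default 3).

## Variance explained

σ_u = 2pqβ_u² per SNP and per-glycan totals over significant lead SNPs;
σ_J = 2pqβ_uβ_J for SNPs surviving an external conditional analysis (joint
estimates are inputs — stepwise conditional selection is out of scope).
Frequencies are folded to the minor allele; since the formula is symmetric
in p and q this is a reporting convention, not a correction. Negative joint
contributions (sign disagreement between marginal and joint estimates) are
reported, not clipped.

## TFBS disruption

PWMs (JASPAR counts or MEME letter-probability matrices, rescaled by nsites
to recover counts so both encodings give identical matrices) are converted
to log2-odds with a per-cell pseudocount (default 0.5) against a background
distribution (default uniform; GC-matched backgrounds can be supplied). An
allele's score is the best log-odds over all windows covering the SNP on
both strands. The score p-value is the background probability of an
equal-or-better score in a random motif-length sequence: exact enumeration
for motifs up to length 8, a dynamic program on a 10⁻⁴-resolution score grid
beyond (with a length-proportional tolerance absorbing quantization drift at
mass-point boundaries). An allele change **disrupts** a site when the
reference allele's match is significant and the alternate's is not, and
**introduces** one in the reverse case; alleles whose best scores differ by
less than 1 bit (configurable — no canonical value exists) are filtered to
no-effect regardless of significance. Enrichment compares the fraction of
SNPs with any disrupt/introduce call between associated and non-associated
SNPs and flags ratios ≥ 2. Non-associated SNPs are defined as nearby SNPs
with association p above 5×10⁻⁴ (the inclusive reading — SNPs below it are
associated — is available by flag).

## SMR and HEIDI

At the top SNP, b_xy = β_outcome/β_exposure estimates the outcome change per
exposure unit, tested with T_SMR = z_x²z_y²/(z_x²+z_y²) against χ²₁ —
a harmonic combination never exceeding min(z_x², z_y²), making the test
significant only when both associations are. Context thresholds: 1.9×10⁻⁵
for gene expression, 9.1×10⁻⁴ for complex traits.

The HEIDI-style test asks whether nearby SNPs in LD with the top SNP
estimate the *same* b_xy. Instruments are non-top SNPs with exposure
p < 1.6×10⁻⁴ and r² with the top SNP in [0.05, 0.90] (close proxies of the
top SNP carry no independent information; near-independent SNPs carry no
shared signal), capped at the 20 strongest. Each deviation
d_i = b_xy(i) − b_xy(top) is standardized by a delta-method variance
propagating both traits' sampling error and the LD-induced covariance with
the top SNP; Σz_d² is referred to χ² with (number of instruments) degrees of
freedom. This df choice ignores the correlation among the d_i — the refined
eigenvalue approximation is out of scope — making the test somewhat
anti-conservative under a shared causal variant; simulation calibration
(shared-scenario rejection near the nominal rate, strong linkage-scenario
power) bounds the practical effect, and verdicts are monotone: lowering
p_HEIDI can only move pleiotropy → linkage. Verdicts: **pleiotropy** when
SMR is significant and p_HEIDI ≥ 0.05, **linkage** when SMR is significant
with heterogeneous ratios, **not significant** otherwise; a significant SMR
with fewer than 3 usable instruments is **not testable**. The HLA region
(chr6:29,570,005–33,377,657, GRCh37) is excluded by default — its LD is too
complex for an LD-sensitive heterogeneity test.

## Synthetic data: what it emulates, what it does not

The generator's defaults mirror the study conditions: 62 direct + 15
derived = 77 traits, 27 loci in 3 latent regulatory clusters, four
discovery cohorts of 849/802/1960/4479 (N = 8090) and replication cohorts
of 575/552/494/747.

Lead-SNP effects follow β_lt = effect_scale·a_l·w_{c(l),t} + ε with one
template w_c ~ N(0,1) per cluster over direct traits, positive loadings
a_l ~ |N(1, 0.2)|, and ε ~ N(0, noise_sd²). This is the minimal structure
the network method assumes: same-cluster loci are monotone transforms of a
shared trait-effect pattern, so their z-vectors correlate perfectly at zero
noise. Defaults effect_scale = 0.15 and noise_sd = 0.02 put lead z-scores in
the 10–40 range typical of the strong glycan associations while keeping
within-cluster correlations high but not degenerate. Non-lead members are
attenuated by their LD with the lead (r = 0.95 per 5 kb step, tight enough
that any member tags the whole block at an r² ≥ 0.5 clumping floor);
background SNPs are exactly null, so their p-values are uniform. Derived
traits are positive affine copies of a parent with optional noise —
sufficient to make the exclusion step consequential — not the actual
total-area ratio re-normalization. Observed effects are drawn independently
per cohort around the same truth with se = 1/√(2pqN).

The LD panel generator copies haplotype alleles from a per-haplotype block
template with probability √r, which yields the target within-block genotype
correlation r exactly in expectation at any allele frequency (a Gaussian
threshold copula would attenuate it: a latent 0.9 becomes ≈ 0.71 after
dichotomization). Only r ∈ [0, 1) is representable; constant negative
correlation across a block is not realizable in general.

eQTL scenario regions draw marginal estimates from the standard
summary-statistic model β̂ ~ MVN(Rγ, R/n) over an AR(1)-style LD matrix
(r = 0.9 decay, 30 SNPs), with exposure n = 350 and effect 0.5 (a strong
cis-eQTL in a few-hundred-sample expression panel) and outcome n = 8090 and
effect 0.1 (a typical glycan association). The linkage scenario places the
second causal SNP 3 positions away (r² ≈ 0.53). Exposure and outcome draws
are independent — non-overlapping samples.

What the synthetic data does **not** model: compositional trait constraints
(real glycan traits sum to a constrained total after area normalization),
realistic LD beyond single blocks, allele-frequency spectra, imputation
error structure (info is decorative), batch structure, cryptic relatedness,
or sample overlap between cohorts. Passing tests therefore demonstrate that
each method recovers the structure it assumes when that structure is
present — not that the assumptions hold in real cohort data.

## Numerical choices and degenerate inputs

- Boundary p-values equal to a threshold fall in the stricter tier (≤).
- Constant effect vectors are a hard error in Spearman edges (rank
  correlation is undefined), as are missing (SNP, trait) meta results when
  building vectors — no silent imputation.
- Lead selection and locus definition break ties by (p, snp id)
  lexicographically; all stages are invariant to input row order, and two
  runs with the same seed produce byte-identical TSVs.
- The pipeline derives per-stage seeds from the global seed by fixed
  offsets (mod 2³¹ − 1), so any stage can be re-run in isolation.
- Problem sizes in the default test and acceptance runs (e.g. 10,000-SNP
  permutation pools, 10,000-replicate calibrations, 60-replicate scenario
  sweeps, 500 SNPs per TFBS class) are chosen so each check resolves its
  acceptance band with comfortable sampling margin while the whole suite
  runs in well under a minute per module on one CPU.

## Known limitations

- The HEIDI degrees-of-freedom approximation (see above).
- The locus definition operates on a supplied pairwise LD source; it does
  not estimate LD from genotypes itself (the LD panel generator exists to
  feed the eQTL machinery and tests).
- Stepwise conditional analysis (joint effect estimation) is consumed, not
  implemented.
- PWM score p-values assume positional independence of the background —
  standard, but wrong for repetitive genomic context.
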