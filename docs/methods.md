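# Methods

This note records the statistical models, conventions, and numerical choices
behind `divscan`, and what the synthetic-data validation does and does not
demonstrate.

## Data model and conventions

The pipeline operates on a biallelic SNP × individual dosage matrix
(alternate-allele counts in {0,1,2}, −1 = missing) with 1-based scaffold
coordinates and a sample→population map. Missing genotypes are never
imputed: every statistic uses observed allele counts. Exported intervals
(BED) are 0-based half-open; everything internal is 1-based inclusive.
Half-missing VCF genotypes count as missing. Read depth is treated as an
upstream genotype-calling concern; `read_vcf(min_dp=...)` optionally masks
genotypes below a FORMAT/DP threshold, nothing more.

Locus filters (defaults): genotyped in ≥80% of individuals *and* ≥5
individuals in every population; global minor-allele count ≥2 (singleton
alleles carry no frequency information and inflate the rank tails);
one SNP per RAD tag to curb intra-tag linkage. When no tag identifiers are
available the tag filter falls back to one SNP per non-overlapping 90 bp
bin per scaffold (a RAD-tag-length proxy). The presence and MAC filters are
applied jointly by default; both are per-locus, so filtering is idempotent.

## Pairwise F_ST

Weir & Cockerham (1984) θ from the a/b/c variance components (among
populations / among individuals within populations / within individuals),
with observed heterozygote proportions entering through h̄. Per-locus
negative estimates are retained — clipping at zero would bias every window
average upward. Loci monomorphic across a pair, or with fewer than two
genotyped individuals on average, are left missing and excluded from
smoothing input. The multilocus estimate is the ratio of sums Σa/Σ(a+b+c),
reported alongside the simple mean of per-locus θ (the former is the
standard low-bias combination; the two differ noticeably under skewed
locus information).

## Window smoothing and the empirical null

Smoothed statistic at a focal SNP: Gaussian-weighted mean of non-missing
values at loci within W/2 bp, weights exp(−d²/2σ²) with σ = W/6, so the
window edge sits at 3σ (weight ≈ 0.011). Window widths: 50 kb for F_ST
scans, 100 kb for ARR scans. Windows never span scaffolds.

Null distribution per focal SNP: B replicates, each drawing values i.i.d.
with replacement from the genome-wide pool of non-missing values and
re-smoothing with the original coordinates' weights. Drawing per-window
i.i.d. values is distributionally identical, window by window, to
resampling one full genome-wide vector per replicate (the draws are i.i.d.
from the empirical distribution either way); only the joint law across
windows differs, and P-values are marginal. The upper-tail P-value uses the
add-one (Davison–Hinkley) estimator (1 + #{rep ≥ obs})/(B+1), so P ∈
[1/(B+1), 1] and a resampling P of exactly zero cannot occur. Exceedance
counting uses a 1e-9 relative tolerance so exact ties (e.g. constant input)
count as exceedances; for continuous statistics this is measure-zero.
Thresholds are strict (<): production defaults P < 5×10⁻⁵ (F_ST windows,
B = 10⁶), P < 0.005 (XtX-ARR windows, B = 10⁴), P < 0.001 (trait windows).
When smoothing is restricted to candidate scaffolds (ARR scans), the
resampling pool still spans the entire dataset.

Calibration caveat: overlapping windows are positively correlated, so the
realized rejection rate at a nominal level scatters somewhat more than
binomial; the add-one estimator makes P conservative by ~1/B. Both effects
are visible in, and accepted by, the calibration tests.

## Hierarchical allele-frequency model

For locus *i* and populations k = 1..K:

    alt_ik ~ Binomial(n_ik, p_ik),  p_ik = clip(a_i + s_i x_ik, ε, 1−ε)
    x_i ~ MVN(β_i · env, Ω),        s_i = √(a_i(1−a_i)),  ε = 10⁻⁶
    a_i ~ Beta(1,1) on (10⁻³, 1−10⁻³),  β_i ~ N(0, σ_β²),  Ω ~ IW(K+2, 0.01·I)

Sampling is Metropolis-within-Gibbs, fully vectorised across loci (loci are
conditionally independent given Ω): random-walk updates of each x-column and
of a_i (step sizes adapted toward 30% acceptance during burn-in, the first
half of the chain), conjugate Gibbs draws of β_i, and — when Ω is being
estimated — a conjugate inverse-Wishart draw of Ω per sweep.

Two numerical decisions matter:

**Censoring, not truncation.** The latent x is unbounded; frequencies are
clipped only inside the binomial likelihood (a Tobit-style device). If x
itself were truncated to keep p in (0,1), the conjugate inverse-Wishart
update would ignore the truncation normalizer and visibly deflate Ω for
loci near fixation (we measured ~25% shortfall in contrast variances at
n = 20 alleles before adopting censoring; with censoring the same setting
recovers contrasts to within Monte-Carlo error).

**Gauge fixing.** With a free per-locus ancestral frequency, a common shift
of all x_ik trades off against a_i, so the component of Ω along 11' is not
identified: the likelihood determines only the centered projection AΩA'
(A = I − J/K). Estimates are therefore mapped to the minimal-off-diagonal
representative of the equivalence class Ω + v1' + 1v' (a closed-form linear
correction). For exchangeable independent populations — truth Ω = F·I, whose
projection is F(I − J/K) — this restores F·I exactly, which is what makes
the recovery of the diagonal testable at all. The gauge choice does not
affect XtX-based rankings in any way that matters downstream: XtX is used
only through within-run ranks.

The ancestral frequency is initialised at the pooled Beta(1,1) posterior
mean and then sampled; fixing it there would shrink the recovered
covariance diagonal by a factor approaching (K−1)/K.

**Scores.** XtX is the posterior mean of x'Ω⁻¹x (null expectation ≈ K).
The trait Bayes factor uses the Savage–Dickey ratio at β = 0 with a
Rao-Blackwellized posterior-density estimate: given x, β is conjugate
normal, so the posterior density at zero is averaged analytically over the
kept sweeps. σ_β = 1 on the standardized-trait scale (effects of order one
standard deviation of drift per trait SD); σ_β = 0 degenerates the
alternative onto the null and returns BF = 1 exactly. K = 2 Bayes factors
were cross-checked against direct 3-D quadrature of the same integrand
(agreement ~1%, asserted at 5%). Trait vectors are standardized to mean 0
and sample (n−1) SD 1 across populations.

This is a re-implementation of the model class, not a bit-compatible clone
of any particular sampler; all validation is statistical (parameter
recovery, ranking behaviour, oracle cross-checks), never value-equality
with another program's output.

## Average relative rank (ARR)

Within each replicate run, relative rank of locus i = #{j : score_j ≤
score_i}/N over the N non-missing loci — the unique top locus gets 1, a
unique bottom locus 1/N, ties share the count-based rank. ARR is the mean
across the R runs (default R = 20, scaled down in tests), with the sample
SD reported descriptively (it plays no role in selection). Ranks ascend
with the statistic. Candidate selection: ARR at or above the genome-wide
95th percentile (linear interpolation, inclusive ≥; computed before any
scaffold restriction). The scan variant smooths ARR over 100 kb windows on
scaffolds containing at least one 95th-percentile locus and requires both
criteria; with several traits, per-trait results are reported plus the
intersection count — the conjunction is informative but not enforced.

## Regions, consensus, enrichment

Candidate SNPs spawn [pos − 50 kb, pos + 50 kb] clamped to [1, scaffold
length]; intervals that overlap *or abut* merge (a 1 bp gap between flanks
is biologically meaningless; a deterministic rule is required). Merged
output is order-independent and conserves supporting-locus counts. Loci are
tiered by the number of supporting methods (F_ST scan, Bayesian scan,
optional external lists such as a Bayescan run — external tools are inputs,
never reimplemented); regions are built per tier. Genes attach to regions
on any ≥1 bp overlap (the permissive standard). Enrichment: one-sided
Fisher's exact per term on selected vs non-selected background genes,
Benjamini–Hochberg FDR across terms; terms are flat labels (no ontology
graph propagation).

## Synthetic data generator

Balding–Nichols: ancestral p ~ U(0.05, 0.95); population frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F) i.i.d. across populations; genotypes
Binomial(2, p_pop). This is exactly the exchangeable-covariance structure
the Bayesian model assumes (Ω = F·I on the standardized scale) and yields
closed-form truth. Defaults define the reference study conditions: K = 4
populations × 10 diploids, 10⁴ SNPs on 100 scaffolds of 1 Mb, background
F = 0.07 (inside the 0.05–0.09 genome-wide range typical of recently
diverged species flocks).

Planted signals: divergent loci displace one population's frequency by
±0.5 (toward the far boundary, clipped to [0.01, 0.99]; an inflated-F
redraw mode exists for symmetric two-population designs); trait-linked loci
apply a logit-scale shift slope·z_k *on top of* the drift draw, so slope = 0
is exactly neutral. Planted loci are placed in clusters (default width
20 kb) on randomly chosen scaffolds so that window scans see contiguous
signal; neutral loci are uniform. The default trait vector has one
population distinctly lower than the rest (0.24 vs 0.31–0.33) — the pattern
of a single phenotypically divergent species — standardized internally.

What the generator does **not** emulate: linkage disequilibrium beyond
co-located clusters (no recombination map), locus-sharing dropout patterns
of real RAD libraries, depth-dependent genotyping error, reference bias, or
non-exchangeable population history (no phylogenetic covariance in the
truth). Passing tests therefore demonstrate correctness of the estimators
and the machinery under the model's own assumptions, and power under clean
planted signals — not robustness to demographic misspecification.

## Problem sizes and thresholds in the shipped tests

Production defaults mirror the full protocol (B = 10⁶ F_ST bootstrap,
B = 10⁴ ARR permutations, 10 × 5000-SNP covariance subsets, 20 replicate
runs). The test and analysis profile scales these to desk size: B ≈ 2×10³
(F_ST) and 10³ (ARR), 2 covariance subsets of 500–2500 SNPs at 1200–1600
sweeps, 8 replicate runs of 800 sweeps, 2000–5000-locus datasets. At
B ≈ 2×10³ the add-one floor 1/(B+1) exceeds 5×10⁻⁵, so the scaled profile
uses an F_ST window threshold of 10⁻³ — a floor-arithmetic consequence, not
a tuning choice. Key validation checks: W&C θ against an independently
coded two-population oracle (10⁻¹²); smoothing closed forms; null
calibration of window P-values at 2000 SNPs / 2000 replicates within 3
binomial SEs of the nominal 5%; Ω recovery from 5000 model-simulated loci
(diagonal within 3 posterior SDs of F, elementwise correlation with truth
> 0.9); ≥90% of strongly displaced planted clusters intersecting a
tier-≥2 consensus region across 10 seeds, with near-empty null scans; K = 2
Bayes factors within 5% of quadrature; region arithmetic against a
brute-force interval-union oracle.

## Known limitations

- The Ω gauge correction assumes the minimal-off-diagonal representative is
  the scientifically intended one; under strong genuinely shared drift
  between subsets of populations the reported common component is a
  convention, and only contrasts should be interpreted.
- Savage–Dickey BF estimates degrade for |log₁₀BF| ≳ 3 (the posterior
  density at zero becomes a rare-event estimate); ranks, which are all the
  ARR pipeline consumes, remain stable much longer.
- The bootstrap null treats loci as exchangeable; under strong genome-wide
  autocorrelation of the statistic the empirical null is anti-conservative.
  Window P-values are screening devices, not calibrated genome-wide error
  rates — hence the fixed thresholds and the consensus tiering instead of
  FDR over windows.
- Monomorphic-in-pair loci are excluded from (not zeroed in) smoothing
  input, so sparse scaffolds can have windows supported by a single SNP;
  `n_contributing` is reported for exactly this reason.
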