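# Methods

## Model

`polyadapt` tests whether the loci identified by a GWAS show coordinated
allele-frequency differentiation among populations beyond what neutral drift
and shared history explain.

**Genetic values.** For L loci with trait-increasing effect sizes
α = (α₁, …, α_L) and effect-allele frequencies p_{lm} in population m, the
population's mean genetic value is Z_m = 2 Σ_l α_l p_{lm} (the 2 is
diploidy). Inputs are oriented at load time so every α_l ≥ 0.

**Drift null.** Each locus's frequency vector across M populations is
modeled as multivariate normal around its (unobserved) ancestral frequency
ε: p ~ MVN(ε·1, ε(1−ε)·F), where F is an M×M covariance shared by all loci
that absorbs population history, gene flow and — because it is estimated
from sample frequencies — finite-sample noise (binomial sampling inflates
the diagonal by roughly 1/(2n_m)-order terms, which automatically controls
for unequal sample sizes). A genetic value is a weighted sum over many such
loci, so Z ~ MVN(μ·1, 2V_A·F) with V_A = 2 Σ_l α_l² ε̄_l(1−ε̄_l), the
additive variance the loci contribute at the grand-mean frequencies; even
when per-locus normality is shaky, the CLT at the genetic-value level keeps
this a good approximation.

**Centering and whitening.** The ancestral mean is replaced by the sample
mean: every length-M vector is multiplied by the (M−1)×M projection T with
1−1/M on the diagonal and −1/M elsewhere (mean-center, drop one
population). Which population is dropped is arbitrary — any M−1 rows of the
full centering matrix span the same subspace, and all statistics are
invariant to the choice (asserted to 1e−8 in the tests). F is estimated
from K matched null SNPs as the sample covariance (divisor K−1) of the
projected standardized deviations s_m = (p_m − ε̄)/√(ε̄(1−ε̄)), with ε̄ the
unweighted across-population mean; SNPs with ε̄ ∈ {0,1} carry no
information and are excluded. With C the lower Cholesky factor of the
estimated F, the whitened values x′ = C⁻¹ T Z / √(2V_A) are iid standard
normal under the null. The same T-and-Cholesky transform (without the
variance scaling, since the environment keeps its own units) standardizes
environmental vectors.

## Statistics

* **Q_X** = Σ x′² — excess variance of genetic values, ~χ²_{M−1} under
  neutrality. Significance nonetheless comes from the matched empirical
  null (below), with the χ² law serving as a diagnostic.
* **Decomposition.** Passing each locus's frequencies through the same
  transform (x′_l = C⁻¹T p_l) gives the exact identity
  Q_X = [Σ_m Σ_l (2α_l)² x′_{lm}²]/2V_A + [Σ_m Σ_{l≠l′} (2α_l)(2α_l′) x′_{lm} x′_{l′m}]/2V_A,
  an F_ST-like per-locus variance term plus an LD-like cross-locus
  covariance term. The second has mean zero under neutrality; coordinated
  selection makes like-effect alleles covary and drives it up — in the
  power simulations it carries nearly all of Q_X's power.
* **Environmental correlations.** The no-intercept slope β of x′ on the
  whitened environment y′ (no intercept because both vectors are mean-free
  by construction; an intercept would spend a spurious degree of freedom),
  the squared Pearson correlation r², and Spearman's ρ (average ranks on
  ties). β and ρ are tested two-sided; r² upper-tail, which is equivalent
  to a two-sided test of the signed correlation. The report keeps r² and
  the slope's sign separately rather than a "signed r²".
* **Per-locus view.** Modeling each locus's slope as β_l = α_l·B, the
  stacked ML estimate is B̂ = Σ α_l β_l / Σ α_l², and B̂ equals the
  genetic-value slope (on the unscaled transform) times 1/(2Σα_l²) — an
  exact identity asserted at 1e−8. The genetic-value regression is thus the
  effect-size-weighted summary of the per-locus regressions.
* **Conditional outliers.** For a partition into tested (group 1) and
  conditioning (group 2) populations, the covariance of standardized
  deviations is re-estimated centered on group 2's mean (group-1 columns
  keep identity; group-2 columns get 1−1/M₂ / −1/M₂), because divergence
  from a subgroup mean exceeds divergence from the global mean even under
  neutrality. Standard MVN conditioning (with a pseudo-inverse on the
  group-2 block, whose rank is M₂−1 by construction) yields the expected
  mean and covariance of group 1, and
  z = (mean(Z₁) − mean(μ_cond)) / √(mean of σ_cond elements) is standard
  normal under the null. A significant z cannot by itself locate selection:
  conditioning on selected relatives contaminates the score.

## Empirical null by matched resampling

GWAS ascertainment correlates with minor allele frequency, imputation
status, and background-selection environment, any of which could bias the
statistics. Null SNPs are therefore drawn from a genome-wide pool binned in
a 25 (MAF, width 0.02) × 2 (imputed) × 10 (B value, width 0.1) contingency
table. Each null set samples one pool SNP from the same cell as each GWAS
SNP and inherits that SNP's effect size; within a set the draws for GWAS
SNPs sharing a cell are distinct (without replacement), across sets draws
are independent. Cells too sparse to serve are widened by ±1 then ±2 MAF
bins at fixed imputation/B coordinates, with a logged fallback; still-empty
cells raise an error naming the offending SNPs. The SNPs behind F come from
the same matching procedure (whole matched sets, deduplicated — repeated
rows add no information to a covariance but shrink its effective sample
size). Each null set's statistics use that set's own 2V_A computed from its
own loci, exactly as the observed set does. For an admixed ascertainment
population with no direct reference panel, a weighted mean of two reference
populations' frequencies, folded to MAF ≤ 0.5, serves as the binning proxy.

Empirical p-values use the add-one rule p = (r+1)/(K+1), so p is never 0;
two-sided tests double the smaller tail, capped at 1. For the type-I-error
experiments K = 159 null sets per replicate, chosen so the 5% level is
exactly attainable under exchangeability: (r+1)/160 ≤ 0.05 iff the
observation ranks in the top 8 of 160, probability exactly 8/160 = 0.05
(and likewise 4+4 ranks for the two-sided rule).

## Selection simulations

Neutral frequency sets are perturbed, not forward-simulated — drift and
history are already present in the resampled data:
p′ = clip(p + s·α_l·Y_m·p(1−p), 0, 1), with Y the mean-centered
environment. Shifts grow with environmental extremity, effect size, and
heterozygosity. The exact printed form of this perturbation was not
recoverable from the source material; this expression is the minimal
additive form with those three monotonicities, and the shift function is a
plain function that callers can swap. Variants:

* **Pleiotropy**: the effect selection acts on, γ, is drawn from the
  conditional law of a mean-zero equal-variance bivariate normal with
  correlation ρ to the measured α — γ|α ~ N(ρα, (1−ρ²)·rms(α)²). The rms
  (second moment about zero) is the right shared variance for
  orientation-positive effects: it keeps the magnitude of the selected
  effects, hence the per-locus shift scale, constant across ρ, which is
  what makes the single-locus enrichment test's power flat in ρ. A
  consequence worth noting: the realized sample correlation between γ and α
  is below ρ (the regression slope of γ on α, not the correlation, equals
  ρ).
* **Downsampling**: a uniform subsample of n loci, optionally with effect
  sizes rescaled by the scalar that restores the full set's V_A — the
  "same variance explained, fewer mapped loci" experiment.
* **Targeted shifts**: a raw 0/1 indicator environment (deliberately not
  mean-centered) shifts a single population or a labeled region.

Power at each grid point is the fraction of perturbed replicates beyond the
5% critical value established from the same experiment's s = 0 replicates
(two-sided for the environmental statistics). The comparators are the
naive counterparts computed without whitening (raw mean-centered genetic
values against the raw environment) and the single-locus enrichment test:
count GWAS loci whose per-locus transformed-frequency correlation with the
environment is in the empirical 5% tail of the matched per-locus null, then
test the count against Binomial(L, 0.05).

The shift-strength anchor for the pleiotropy and downsampling experiments
is the smallest gradient at which the full-locus Q_X power saturates
(≥ 0.95) in the gradient sweep. The strength parameter s has units of
(trait units × environment units)⁻¹, so a numeric value is meaningful only
relative to a dataset's effect sizes, environmental spread and drift noise;
anchoring at saturation reproduces the original experiments' use of a
saturated-but-moderate strength in a way that transfers across datasets.

## Synthetic studies

The fixture generator runs the null model forwards: ε ~ U[0.05, 0.95],
population frequencies MVN(ε·1, ε(1−ε)F) truncated (not reflected) to
[0,1] — truncation is the simple choice, and its rate is surfaced on the
dataset object — then binomial sample frequencies with n_m chromosomes, so
the sampling inflation of F's diagonal is present exactly as in real
panels. Defaults emulate an HGDP-scale study: M = 52 populations on a star
tree with drift c = 0.02 per branch (small enough that the normal
approximation holds and the truncation rate stays below 1%; at c = 0.05
truncation reaches ~2% and visibly distorts the conditional-Z calibration),
161 loci, 50 chromosomes per population, α ~ |N(0, 0.1)| trait units,
latitude-like environment U[0, 60], B ~ U[0,1] and imputation flags
independent of frequency (only the matching mechanics need exercising, not
a background-selection model), and ascertainment MAF from an independent
2000-chromosome binomial sample of ε, folded.

What the fixtures do not emulate: LD between loci, tree-like or
isolation-by-distance covariance (except through explicit F matrices),
ascertainment that correlates effect size with frequency deviation, and
non-Gaussian drift at strongly drifted loci. Passing calibration on these
fixtures therefore shows the machinery is correct under its own
assumptions, not that the assumptions hold for any particular real panel.

## Problem sizes and numerical choices

The calibration experiments use desk-scale stand-ins for genome-wide data,
sized so the resampling machinery behaves as it would against a ~3M-SNP
pool: the null-SNP pool must be large relative to the resampling demand,
else null sets share pool SNPs, become positively correlated, and the
empirical test over-rejects. The null-distribution experiment (10,000 null
sets) uses a 200,000-SNP pool with F from 40,000 distinct matched SNPs; the
type-I experiments (1000 fresh studies × 159 null sets) use 60,000-SNP
pools with F from 8,000 matched SNPs; the conditional-Z calibration scores
10,000 fresh neutral replicates, rotating the left-out population.

Numerical details: the covariance uses divisor K−1 (the choice cannot
affect calibration — the same estimator whitens observed and null sets);
a singular estimated F (duplicate populations, too few null SNPs) first
retries with a logged ridge of 1e−10·trace/(M−1) and otherwise errors at
whitening time rather than being silently regularized; pseudo-inverses use
rcond = 1e−10; perturbed frequencies are clipped to [0,1] with a logged
count; Spearman ties get average ranks; all randomness flows through
`numpy.random.Generator` seeds, and every experiment is reproducible from a
single integer seed.

## Known limitations

* The MVN drift approximation fails under strong drift; the generator's
  truncation rate is a proxy for how far a configuration strays.
* The empirical-null machinery assumes the pool is exchangeable with the
  GWAS loci after binning; unmodeled ascertainment (e.g. effect sizes
  correlated with frequency deviations, as in a structured-GWAS) produces
  false positives by design, not by bug.
* Environmental tests identify correlation, not causation; the conditional
  Z-scores identify outliers, not the populations where selection acted.
* Strand-ambiguous (A/T, C/G) SNP harmonization between the GWAS and the
  frequency panel is assumed done upstream.
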