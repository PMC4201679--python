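# Methods

`gpcross` studies genomic prediction in a small crossbred population: a
three-generation intercross between two divergent chicken lines, with
phenotypes recorded only on the F2 generation. The package simulates
such populations, estimates variance components, predicts breeding
values with four models, and evaluates prediction accuracy and bias
under two cross-validation designs that differ in how related the test
birds are to the training birds.

## Population model

**Founder genetics.** Each SNP is given a shared ancestral frequency
p0 ~ U(0.05, 0.95). The two founder lines draw their frequencies from a
Beta distribution centred on p0 with concentration (1 − F)/F, where
F ∈ [0, 1) is the `divergence` parameter — a Balding–Nichols-style
construction in which F plays the role of the between-line fixation
index. F = 0 collapses both lines onto p0; the default F = 0.3 gives
two clearly differentiated lines, which is what creates long-range
linkage disequilibrium and segregation variance in the F2. Founder
haplotypes are independent Bernoulli draws at the line frequency.

**Cross design.** The default cohort sizes are 20 F0 (10 per line),
51 F1 from between-line matings, and 511 F2 in 8 paternal half-sib
families whose sizes follow the balanced-remainder rule
(511 = 8·63 + 7 → seven families of 64 and one of 63). F1 dams are
nested within sires (no dam is mated to two sires), so holding out a
sire family removes all half- and full-sib information about its
members. How the 51 F1 arise from the 20 F0 is not constrained by the
study design; the generator mates F0 pairs round-robin, which makes
many F1 full or half sibs of one another — deliberate, since a small
founder cohort cannot produce 51 unrelated F1. Hatch (batch) labels
cycle round-robin within family over 4 levels; the level count is a
free design choice exposed in the configuration.

**Meiosis.** Crossover counts per chromosome are Poisson(L/100) for a
chromosome of length L cM with positions uniform — the Haldane map
function, i.e. no crossover interference. The default map is 10
chromosomes of 100 cM carrying 5,000 markers in total (scaled down
from a 60K-chip-after-QC panel of ~47k markers on ~28 chromosomes;
the full scale is reachable through the configuration but is not the
desk default). Interference models can be substituted by replacing
`drop_gametes`.

**Traits.** Five traits are predefined with the heritabilities and
phenotypic scales of the study population: body weight at 6 and 12
weeks (h² = 0.26, 0.13), eviscerating percentage (0.44), breast muscle
percentage (0.39) and leg muscle percentage (0.39), with means/SDs
802/134 g, 2027/360 g, 66.6/1.8 %, 17.4/1.4 %, 23.7/2.6 %. Each trait
is purely additive: 200 QTL are drawn uniformly among the simulated
markers, effects are drawn normal and rescaled so that the realised
additive variance in the F2 equals h²·σp²; the residual variance is
(1 − h²)·σp². Because the QTL remain inside the marker panel, markers
capture all additive variance — matching the study population, where a
model with an extra polygenic term did not improve prediction. Fixed
effects are a sex effect of ±0.25 σp (dimorphism on the weights) and
four hatch effects spaced at 0.1 σp; both are arbitrary but
consequential only through the corrected-phenotype step, which removes
them again.

**What the simulator does not emulate:** genotyping-intensity artefacts
(a GenTrain-style score filter is accepted only as an externally
computed keep-mask), dominance and epistasis, selection between
generations, and real-chip LD structure. Passing tests therefore show
that the estimators behave correctly under a clean additive
F2 architecture, not that real-data accuracies are reproduced — the
original genotypes and phenotypes were never deposited, so headline
real-data correlations are out of reach by construction.

## Quality control

SNPs are removed when call rate < 0.95 or minor allele frequency
< 0.01, both strict inequalities ("less than"), with MAF computed on
called dosages over all genotyped individuals (whether the original
analysis used all 582 birds or F2 only is unstated; the base is
configurable). Remaining missing dosages are replaced by the per-SNP
mean of called dosages; at ≥95% call rate the imputation method is
immaterial, so the neutral mean rule is used rather than family-aware
imputation.

## Relationship matrices

A is built by the tabular method (A_ii = 1 + ½A_sd; unknown parents
contribute zero). G follows VanRaden's first method,
G = ZZ′ / (2Σp_j(1−p_j)) with Z column-centred by 2p_j; frequencies
default to the observed sample (configurable to an external vector,
e.g. base-population frequencies). Centring makes 1′Z = 0, so G is
singular by construction; the solver never inverts K directly (below),
but a ridge of 1e-6 on the diagonal (recorded in metadata) keeps
factorisations of G itself well posed where they occur. The ridge can
be set to 0, which the algebraic-equivalence tests do.

## Mixed models

Both BLUP (K = A) and GBLUP (K = G) use y = Xb + Za + e with
a ~ N(0, K σa²), e ~ N(0, I σe²). Fixed factors (sex, hatch) are coded
full-rank: intercept plus dummies for all but the first level.

The solver works through the phenotypic covariance
V = σa² ZKZ′ + σe² I rather than the Henderson system: b̂ is GLS and
â = σa² K Z′ V⁻¹(y − Xb̂) for *every* individual in K, so record-free
individuals are predicted in the same pass. The two routes coincide
whenever K is invertible (asserted in the tests), and the V route also
handles the singular centred G exactly.

AI-REML estimates (σa², σe²) after a one-time eigendecomposition of
ZKZ′, which turns every iteration into diagonal arithmetic. Updates
use the average-information matrix with an EM fallback whenever an AI
step would leave the parameter space; convergence is declared at
relative change < 1e-8 (max 200 iterations, flag returned rather than
raised on non-convergence). Standard errors come from the inverse AI
matrix; SE(h²) by the delta method. Start values are
σa² = σe² = var(y)/2.

## Bayesian whole-genome regression

Model: y = Xb + Mq + e with M the column-centred dosages
(m_ij − 2p̄_j, centring constants frozen from the training set so test
individuals are centred identically). GEBV_i = Σ_j m_ij q̂_j.

Both samplers run on the *standardised* response (zero mean, unit
variance) and back-transform all effects and variance traces; the
hyperprior settings below are therefore scale-free statements about
variance ratios, and identical traits measured in grams or percent get
identical shrinkage behaviour.

**BayesLASSO.** Marker effects have a double-exponential prior,
implemented through the exponential scale mixture
q_j | τ_j² ~ N(0, τ_j²), τ_j² ~ Exp(λ²/2), with inverse-Gaussian full
conditionals for 1/τ_j². The rate λ has a uniform prior on (0, λ_max]
and a Gamma(k+1, Σ|q_j|) full conditional truncated to the support
(rejection-sampled; the collapsed draw is valid because τ is refreshed
from p(τ | q, λ) immediately after). The support bound matters: for
k ≫ n the marginal likelihood of λ flattens to the null-model value as
λ → ∞, so the posterior on an unbounded flat prior is improper and a
chain will drift to whatever bound is imposed, collapsing the scale of
the predictions (their ranking, and hence accuracy, is almost
unaffected — verified against a fixed-λ/ridge oracle — but the
regression of phenotype on GEBV inflates severely). λ_max is therefore
calibrated rather than "generous": it is the rate whose implied
effect variance 2/λ² equals the equal-share polygenic variance at
h² = 0.5, i.e. σq,ref² = 0.5·var(y)/Σ_j var(m_j). The posterior then
concentrates near a polygenically sensible rate, and prediction scale
is preserved.

**BayesMix4.** Effects are drawn from a mixture of four normals with
fixed proportions π = (0.889, 0.1, 0.01, 0.001), component 1 having
the smallest variance. Per cycle: the component indicator of each
marker is drawn from its multinomial conditional with the effect
integrated out; the effect from its normal conditional given the
assigned component variance; the four component variances from
scaled-inverse-χ² conditionals (ν = 4.2) with slot scales spanning
four orders of magnitude (ratio 10), re-sorted ascending each cycle to
prevent label switching. The common scale factor uses the same
equal-share anchor as λ_max, so the two Bayesian models share their
notion of "polygenic prior mass". An empty component keeps a proper
variance through its prior.

**Common blocks.** Fixed effects get flat priors (normal full
conditionals); σe² a flat scaled-inverse-χ² (ν = −2), i.e.
σe² | e ~ e′e/χ²_{n−2}. Chains are single, seeded, and bit-reproducible.
The full schedule is 50,000 cycles, 20,000 burn-in, every 20th sample
saved (1,500 saved samples); the desk schedule used by the tests and
the acceptance study is 10,000/4,000/10 (600 saved samples) — chosen
because doubling the post-burn-in sample moves GEBV accuracies by
< 0.01 (asserted in the tests), so the longer schedule buys nothing at
these problem sizes. The samplers' inner loops are numba-compiled.

## Cross-validation and evaluation

**Folds.** Family sample: whole paternal half-sib families are
assigned to k = 4 folds by deterministic greedy bin-packing (largest
family first into the currently smallest fold with capacity
⌈families/k⌉, ties by sire id) — with 8 families this puts exactly 2
per fold and test individuals have no half or full sibs in training.
Random sample: a seeded shuffle into folds of ⌈n/k⌉ / ⌊n/k⌋, giving
test sizes 128/128/128/127 and training sizes 383/383/383/384 at
n = 511.

**Statistics.** y_c = y − estimated sex effect − estimated hatch
effect, with estimates from the full-data pedigree BLUP (the intercept
stays in y_c; it shifts nothing that matters). Accuracy is the Pearson
correlation between predictions and y_c pooled over the concatenated
test sets (pooling the data, not averaging fold correlations — the two
differ, as a constructed counterexample in the tests shows). Bias is
the OLS slope of y_c on the prediction (1 = unbiased; < 1 inflated
predictions). Models are compared by a paired t-test over folds,
t = d̄/(S_D/√k) with k − 1 df, two-sided, significance at 0.05 without
multiplicity correction. Each pooled correlation gets the power of the
two-sided test of ρ = 0 at α = 0.05 under the Fisher-z normal
approximation (the approximation is checked against a 50,000-replicate
Monte-Carlo oracle in the tests; the power method used originally is
cited there but not described, so Fisher-z is this package's
documented stand-in). Per-fold model fits see training records only —
masking is by exclusion, and scrambling held-out phenotypes provably
changes no prediction.

## Problem sizes and numerical choices

The acceptance study simulates the reference design (582 birds, 8
families) with a 2,000-SNP panel and the desk MCMC schedule, runs all
five traits through all four models in both scenarios, and summarises
accuracies as trait means — the scale at which the study's qualitative
claims (random > family for every model; pedigree EBV ≈ 0 without
close relatives; the three genomic models within 0.03 of one another;
GBLUP slope near 1) are stable against fold-sampling noise. Absolute
synthetic accuracies are lower than the real-data ones (≈0.3 vs ≈0.43
in the random scenario) because the synthetic panel and LD structure
are not the real chip's; the package asserts directions and contrasts,
not real-data values. REML recovery checks use 20 replicates of
multivariate-normal trait draws from pedigree A at n = 2,000
(full-sib families) and at the reference design (511 F2).

Other numerics: relationship matrices are validated symmetric to
1e-12; A-matrix construction is the O(n²) vectorised tabular
recursion; V factorisations use Cholesky; the MME residual invariant
is checked at 1e-8 relative; degenerate inputs (zero-variance
correlations, S_D = 0 with d̄ ≠ 0, monomorphic panels, fully missing
SNPs) raise explicit errors rather than returning NaN.

## Known limitations

- Single-trait models only; no maternal, permanent-environment or
  dominance effects; no multi-trait or single-step (H-matrix) variants.
- The λ-support calibration makes the BayesLASSO behave like an
  empirically anchored shrinkage model; inference *about* λ itself
  should not be read off the traces.
- The mixture model's component-variance hyperprior (ν = 4.2, 10×
  scale ladder) is a documented default, not an estimated quantity;
  π is fixed, never estimated.
- Dense linear algebra throughout: intended for n up to a few
  thousand, not 10⁵-scale national evaluations.
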