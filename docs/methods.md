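# Methods

## Model and estimation

The trait model is `y = μ1 + Xγ + g + e` with `e ~ N(0, σ²ₑ I)` and a
residual polygenic effect `g ~ N(0, σ²_g A)`, `A` the additive relationship
matrix built from the pedigree by the tabular recursion (exact under
inbreeding; founders have diagonal 1 and mutual relationship 0). Genotypes
are coded 1/0/−1 for AA/Aa/aa with "A" the major allele (lexicographic
tie-break); missing calls are mean-imputed per SNP (value 2pⱼ−1) before any
model fit, since the joint model assumes a complete design matrix.

Each SNP effect gets the adaptive Lasso hierarchy
`γⱼ|τ²ⱼ ~ N(0, τ²ⱼ)`, `τ²ⱼ|λ²ⱼ ~ Exp(rate λ²ⱼ/2)` (Park–Casella
convention, so γⱼ|λⱼ is double-exponential with rate λⱼ = √λ²ⱼ), and an
independent per-SNP hyperprior `λ²ⱼ ~ Gamma(shape a, rate b)` with
`a = b = 10⁻⁶`. μ is flat, `p(σ²ₑ) ∝ 1/σ²ₑ`, σ²_g flat.

EM treats `g` and the `τ²ⱼ` as missing data.

**E-step.** `ĝ = σ²_g A (σ²_g A + σ²ₑ I)⁻¹ r` with `r = y − μ1 − Xγ`, and
the posterior covariance `V_g`; both come from the eigendecomposition of A,
computed once and cached, so an EM iteration costs O(np) in the rotated
basis. The latent-scale conditional is generalized-inverse-Gaussian with
closed moments `E[1/τ²ⱼ] = λⱼ/|γⱼ|` and `E[τ²ⱼ] = |γⱼ|/λⱼ + 1/λ²ⱼ`
(validated against adaptive quadrature in the test suite); `E[1/τ²ⱼ]` is
capped at `λⱼ·10¹²` when `|γⱼ| < 10⁻¹²`.

**M-step**, cyclic, each block the exact maximizer of its objective given
its predecessors:

* `μ ← mean(y − Xγ − ĝ)`;
* `γⱼ ← xⱼᵀ(partial residual)/(xⱼᵀxⱼ + σ²ₑ E[1/τ²ⱼ])`, swept in genome
  order;
* `λ²ⱼ ← (1+a)/(E[τ²ⱼ]/2 + b)` — the mean of the conjugate
  Gamma(a+1, b+E[τ²ⱼ]/2) conditional, equivalently the maximizer of
  `(1+a)·log λ² − (b+E[τ²]/2)·λ²`. The strictly modal update
  `a/(E[τ²]/2+b)` collapses to ~0 at a = 10⁻⁶ and removes all shrinkage;
  the conditional-mean update is what produces the adaptive penalty
  `≈ 2σ²ₑ(1+a)/γⱼ²` at its fixed point — near-unbiased for well-supported
  effects, divergent for null ones. Its null-SNP cap is `(1+a)/b`, which is
  why a Gamma(0,0) hyperprior is rejected outright: with b = 0 nothing
  bounds the penalty recursion.
* `σ²_g ← (ĝᵀA⁻¹ĝ + tr(A⁻¹V_g))/n`; `σ²ₑ ← (E‖y−μ1−Xγ−g‖²)/(n+2)` (mode
  under the scale-invariant prior).

Every block is cross-checked in the tests against 1-D numeric argmax of its
objective on seeded small instances (≤ 10⁻⁶ relative).

**Initialization.** `μ = mean(y)`, `σ²_g = σ²ₑ = Var(y)/2`,
`γⱼ = 0.05 ×` (marginal least-squares estimate), and `λ²ⱼ = 1/γⱼ,init²`
(capped at `(1+a)/b`), i.e. the hyperparameter starts at its fixed point
for the scaled-down effect start. Two facts force this design: an exactly
zero γⱼ is an absorbing state of the multiplicative update, so the start
must be nonzero; and a weak initial penalty (λ² = 1) lags one EM cycle
behind γ, letting every coordinate rebound to its unpenalized estimate
before the penalty engages — which would leave any noise SNP with marginal
|z| ≳ 2.8 stranded at a nonzero local mode. With the equilibrated start, a
coordinate only escapes zero if its signal overcomes the live penalty
(roughly |z|² > 1/(δ(1−δ)) ≈ 21 at δ = 0.05), reproducing the method's
defining behavior: complete shrinkage of null effects and a near-zero
false-positive rate, at the price of conservative power — the trade-off the
replicated experiments quantify.

**Convergence and monitoring.** Iterations stop when the largest absolute
change across (μ, γ, σ²_g, σ²ₑ) falls below 10⁻⁸ (default; max 10⁴
iterations). On small instances (n ≤ 20, p ≤ 5) the per-iteration trace
stores the observed-data log posterior — g integrated analytically, each
γⱼ's prior fully marginalized over (τ²ⱼ, λ²ⱼ) by 1-D quadrature — and a
decrease beyond 10⁻⁶ raises an error; ascent within 10⁻⁸ is asserted in the
tests. On larger instances the trace stores the expected complete-data
value instead (flagged `objective_kind="q"`), which the conditional-mean λ²
update does not guarantee to be monotone. A SNP whose |γⱼ| stays below
10⁻¹² for 3 consecutive iterations is clamped to exactly 0 and skipped;
the clamped SNP with the largest partial-residual correlation may re-enter.

**Heritability and significance.** `h²ⱼ = 2pⱼ(1−pⱼ)γⱼ²/Var(y)` with pⱼ the
sample allele frequency and Var(y) the sample phenotypic variance (the
choice of denominator is a convention; alternatives differ by O(h²)).
Genome-wide thresholds are the empirical (1−α) quantile (type-7) of the
per-permutation maximum statistic — max h²ⱼ for MEML, max −log₁₀p for
SMMA — over whole-phenotype shuffles. Shuffling breaks the pedigree–
phenotype link too, so the null is fully exchangeable; this slightly
misrepresents the polygenic null and is the standard, documented
approximation. The prescreened SNP subset is held fixed across
permutations (stage-1 selection is not repeated), matching the two-stage
design; thresholds therefore carry the usual selection caveat.

## SMMA

The single-marker baseline/prescreen fits the null model
`y = μ1 + g + e` by REML (profiled over δ = σ²ₑ/σ²_g, bounded scalar search
of log δ on [10⁻⁵, 10⁵] in the eigenbasis of A; boundary solutions and the
A ≈ cI non-identifiable case are flagged), then tests each SNP by
generalized least squares with the covariance *structure* fixed at the null
estimates and the residual scale re-estimated per SNP. The Wald statistic
is compared to the standard normal. With σ²_g = 0 this reduces exactly to
the OLS t-statistic with normal p-values, the oracle used in the tests.
Per-SNP REML refits are deliberately out of scope; the fixed-structure
approximation is standard for a screen. The prescreen keeps the k smallest
p-values (default 500), stable-sorted so ties resolve to the earlier genome
position.

## Simulator

The generator mirrors a two-generation full-sib design: a base population
(default 100 individuals) with alleles at frequency 0.5 random-mates for
100 generations to build LD (gene dropping; crossovers per chromosome are
Poisson with mean the map length in Morgans, positions uniform — Haldane,
no interference; loci drifting to fixation are re-polymorphized by one
random allele flip, logged). Generation 1: 50 full-sib families × 40
offspring from founder parents drawn without replacement; generation 2: 20
families × 100 offspring whose parents come from distinct generation-1
families — 2,000 individuals per generation. The default genome is 6
chromosomes × 1,000 evenly spaced SNPs on 1 Morgan each (0.1 cM spacing).
Phenotypes are `1 + Σ x·β + e` with residual variance 1.

The 43-QTL default panel (15 major, 28 minor; `data/default_qtl.json`) is a
synthetic stand-in: effects were drawn once with a fixed seed and frozen,
scaled so the major QTL jointly explain ≈30% and the minor ≈5% of
phenotypic variance at frequency 0.5. Positions are stored as chromosome
fractions and resolve onto any grid size. Realized per-QTL variances are
smaller and heterogeneous because 100 generations of drift move allele
frequencies (var(p) at Ne = base size), occasionally fixing a QTL — a
faithful property of gene-dropping designs worth remembering when reading
power numbers.

Scoring follows the ±1-locus rule: a significant SNP within one grid
position of a true QTL (same chromosome) credits that QTL once; all other
significant SNPs are false positives, and the per-replicate non-QTL locus
count is `total SNPs − 3 × #QTL`.

What the simulator does **not** emulate: genotyping error and missingness
(QC paths are tested on separately constructed panels), selection,
non-random mating within generations, dominance/epistasis, and multi-trait
correlation. Passing tests therefore demonstrate correct behavior of the
estimators under the stated generative model, not robustness to those
real-data features.

## Problem sizes in the tests and the reproduction script

The replicated power/FPR contrast runs at the full design's marker density
(0.1 cM) but a quarter-size population (25×20 + 10×50 = 1,000 phenotyped
individuals), 3 replicates, 100 permutations, prescreen k = 100, and EM
capped at 2,500 iterations inside permutation fits — sizes chosen so the
whole suite runs on one CPU in minutes. At this scale the qualitative
contrast is stable — the joint fit's false-positive rate sits an order of
magnitude below the scan's while the scan retains more power — but the
absolute percentages are smaller than a full-scale study's, since a
quarter of the sample size means roughly a quarter of the per-QTL
non-centrality. The permutation-calibration check uses the SMMA statistic
(n = 200, p = 100, 200 permutations × 100 outer replicates); the
calibration property is statistic-agnostic by construction of the
max-statistic test.

## Numerical choices and degenerate inputs

* Monomorphic SNPs: flagged untested in scans, never selected by the
  prescreen, permanently zero in the joint fit; HWE p-value 1 by
  convention.
* All-missing SNPs: undefined frequency, excluded; imputation refuses them.
* Constant phenotypes are errors; `tol = ∞` performs exactly one EM pass
  and reports non-convergence.
* `a = b = 0` is rejected at configuration time (see the λ² update).
* Scale equivariance (y → cy ⇒ γ̂ → cγ̂, h² unchanged) holds only up to
  O(a, b) ≈ 10⁻⁵ relative, because the Gamma hyperprior fixes an absolute
  scale; the property test asserts it at that tolerance.
* Eigenvalues of A are clipped at zero (tolerance 10⁻⁸ relative);
  `(shift·I + A)` solves use cached Cholesky factorizations and refuse
  singular systems at shift 0.

## Known limitations

* The two-stage threshold inherits stage-1 selection bias; fully
  permutation-consistent selection would re-run the prescreen per shuffle.
* EM convergence near variance boundaries (σ²_g → 0) is slow; fits may use
  many cheap iterations rather than fail.
* The conservative initialization deliberately sacrifices power for
  false-positive control; borderline effects (|z| ≲ 4.5 marginally) shrink
  to zero by design.
* Only text PLINK, single continuous traits, and autosome-style handling
  of all markers are supported.
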