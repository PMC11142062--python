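# Methods

`mixscore` is a desk-scale engine for two-step generalized linear mixed
model (GLMM) GWAS on cohorts with cryptic or familial relatedness and
unbalanced case–control ratios.  This note records the model, the numerical
scheme, the synthetic study conditions used for validation, and the design
choices that were genuinely open.

## Model

For a binary trait y on N samples with covariates X (intercept, then e.g.
age, sex, genetic PCs) the null model is

    logit(E[y]) = X α + b,      b ~ N(0, τ ψ),

where ψ is the genetic relationship matrix (GRM) built from M standardized
genotype columns, ψ = (1/M) A Aᵀ.  Quantitative traits use the identity
link with covariance τ ψ + σ² I and both components estimated.  Per-variant
association is a score test at the null fit: with dosages g residualized
against the covariates under the working weights W,
g̃ = g − X(XᵀWX)⁻¹XᵀWg, the statistic is T = g̃ᵀ(y − μ̂) with null variance
g̃ᵀPg̃, P = Σ⁻¹ − Σ⁻¹X(XᵀΣ⁻¹X)⁻¹XᵀΣ⁻¹ and Σ = W⁻¹ + τ̂ψ.

## Matrix-free GRM

ψ is never formed: a dense GRM at biobank N is infeasible (the planner
module reproduces the arithmetic — 4N² bytes is ~794 GB at N=445,444).
The operator holds column partitions A[:, sᵢ:eᵢ] sized to a byte budget
(4 bytes per value, mirroring single-precision device buffers) and
evaluates ψv = (1/M) Σᵢ A₍ᵢ₎(A₍ᵢ₎ᵀ v) as two GEMVs per partition with a
double-precision accumulator.  Partitioning is an implementation detail of
the product: results are identical (≤1e-10 relative in the full-double
mode, ≤1e-6 in single precision) for any partition count, which the test
suite checks against a dense oracle.  No distribution semantics are
promised; a worker pool or accelerator backend may evaluate partitions as
long as results agree to 1e-6.

## Null-model fitting

Penalized quasi-likelihood (PQL) with working-response linearization:
each outer iteration forms z = Xα + b + W⁻¹(y − μ), solves the GLS system
under Σ = φW⁻¹ + τψ by preconditioned conjugate gradient (Jacobi
preconditioner on diag(Σ), using the exact per-partition GRM diagonal),
updates (α, b), and takes one average-information REML step for τ with
trace terms estimated by Rademacher probes (Hutchinson; 30 probes by
default, drawn once per fit from a recorded seed so the whole fit is
bit-reproducible).  Defaults: outer tolerance 1e-4 on relative parameter
changes, 30 outer iterations, PCG tolerance 1e-5 with the true residual
recomputed every 50 iterations, τ clamped at zero with step-halving.
τ initializes at 0.1 for binary traits and at half the phenotypic variance
for quantitative ones.  Quantitative traits may optionally be rank-based
inverse-normal transformed before fitting.

The working-scale dispersion φ is fixed at 1 by default, the standard
binary-GLMM convention.  An `estimate_dispersion` option frees φ
(Breslow–Clayton quasi-likelihood).  The free-φ variant substantially
reduces PQL's downward bias in τ̂ when ψ is a family-factor matrix (it
matches `MASS::glmmPQL` on such designs), but it is *unidentified* when ψ
has a unit diagonal and the working weights are near-constant: the
identity component (1−r)τI of a family-block kinship is then collinear
with φW⁻¹, and the profile likelihood has a ridge along which φ→0 and
τ→∞.  The default is therefore the stable fixed-φ scheme used by the
field's production tools.

With ψ = I and τ pinned at 0 the binary fit reduces exactly to logistic
IRLS (the GLS solution is invariant to the scalar φ), which the tests use
as a degeneracy oracle; the quantitative fit with ψ = I recovers the
single-component REML variance through the identifiable total τ̂ + σ̂²
(the 2×2 average-information system is singular there and is solved in
the minimum-norm sense).

### Known limitation: attenuation of τ̂ for binary traits

PQL underestimates variance components for Bernoulli data.  On the
package's own recovery experiment (200 families of 10, within-family
relatedness 0.5, prevalence 0.1, τ = 1, the kinship held exactly in the
operator) the mean estimate over 20 replicates is ≈0.56.  This is a
property of the estimator and of the information in the data, not of the
implementation: a dense-matrix PQL reference reproduces the matrix-free
numbers, and even exact-likelihood estimators are limited here, because
the individual-level share (1−r)τ of a unit-diagonal kinship is nearly
unidentifiable from Bernoulli observations (the same fact that makes
observation-level random effects in binomial GLMMs ill-posed).  Downstream
testing is insulated from this bias by the variance-ratio calibration and
the saddlepoint correction; the calibration experiment below shows the
type-I error and genomic inflation stay in band despite τ̂ < τ.

## Step two

Variants stream from dosage VCFs; per variant the engine mean-imputes
missing dosages, recomputes ALT frequency and minor-allele count on the
analysis samples, applies the inclusion rule (MAC ≥ 40, imputation quality
strictly > 0.3; both configurable), residualizes, and computes T.  The
null variance is either exact (one PCG solve per variant through P) or
`variance_ratio`: r̂·g̃ᵀWg̃ with r̂ the mean of (g̃ᵀPg̃)/(g̃ᵀWg̃) over ≥30
random markers, calibrated once at step one and stored in the artifact —
the standard trick that makes per-variant cost independent of the mixed
model.  Observed per-marker ratio spread is tiny (CV < 0.01 on the
synthetic cohorts); a CV above 0.1 logs a warning.

P-values are two-sided normal by default; when |z| exceeds the SPA
trigger (default 2.0) the tail is recomputed by the saddlepoint
approximation to the conditional distribution of T = Σ g̃ᵢ(yᵢ − μ̂ᵢ):
K(t) = Σ log(1 − μ̂ᵢ + μ̂ᵢ e^{g̃ᵢt}) − tΣg̃ᵢμ̂ᵢ, saddlepoint by safeguarded
Newton/bisection, tail by the Barndorff-Nielsen formula with
w = sign(ζ)√(2(ζq − K(ζ))) and u = ζ√(K″(ζ)), both tails evaluated at
±|T|.  Near the mean (|w| < 1e-5) the normal limit is used; root-finder
failure falls back to the normal p with a flag.  For statistics supported
on a unit lattice (as in the enumeration oracle) an optional Daniels
correction replaces ζ by 1 − e^{−ζ} in u; production dosage statistics
are continuous and use the plain formula.

When the final p falls at or below the Firth trigger (default 0.01) the
effect size and standard error are re-estimated by Jeffreys-penalized
logistic regression (penalty ½ log det XᵀWX, modified Fisher scoring with
step capping, 50 iterations), which stays finite under separation; the
p-value itself remains the score/SPA one.  In score mode the reported
effect is beta = T/var(T), se = 1/√var(T).  Zero-variance variants are
counted as untestable rather than emitted with p = 1.

Output is a fixed-layout TSV; rows are a pure function of (null fit,
shard, configuration), so processing a shard whole or split and merged is
byte-identical — the property the sharded production workflow relies on,
asserted in the tests.

## Resource planner

Device counts follow n_gpu = ceil(4MN / (mem_GB·10⁹)) with decimal
gigabytes; dense-GRM memory is 4N²/10⁹ GB.  The partition planner's byte
budget rule gives floor(budget/4N) columns per partition with an optional
explicit partition count for even device splits.  Sharding of variant
lists is contiguous with sizes differing by at most one, and concatenation
reproduces the input exactly.

## Synthetic cohorts

The generator emulates the features the engine must survive: familial
relatedness, a liability-scale variance component, and case–control
imbalance.  Kinship is block-diagonal (families of configurable size,
one within-family coefficient; 0.5 — full siblings — by default).
Genotypes follow a liability-threshold model: one latent Gaussian per
marker with the kinship as correlation, cut at Hardy–Weinberg quantiles
of a MAF drawn uniformly from [0.05, 0.5].  Binary traits are drawn from
the model's own generative direction with b ~ N(0, τK) and the intercept
bisected so the expected case fraction hits the target prevalence
(supporting 1% cases).  All randomness derives from one master seed
through named substreams.  A writer emits BED/BIM/FAM + dosage VCF +
phenotype TSV so the real readers are exercised end to end.

What the generator does **not** emulate: linkage disequilibrium,
admixture, genotyping error, and the coupling of trait to the genotyped
markers (b comes from the family kinship, not from the simulated marker
effects, unless causal effects are requested).  Passing tests therefore
demonstrate correctness of the machinery under idealized relatedness, not
robustness to real-data artifacts.

### Standing experiments (sizes chosen as the package's validation scale)

- **Recovery**: 20 replicates, 200 families × 10, relatedness 0.5,
  prevalence 0.1, τ = 1; fit against the exact kinship via its Cholesky
  factor, 10 probes, outer tolerance 1e-3.  The exact-kinship operator
  isolates estimator behavior from genotype-sampling noise in an
  empirical GRM (which attenuates τ̂ further, to ≈0.33 at M = 2,000).
- **Calibration**: one cohort of 500 families × 5, relatedness 0.5,
  prevalence 0.2, τ = 1; 5,000 fresh kinship-structured null variants
  tested in variance-ratio mode with the SPA trigger active.  Reported:
  empirical type-I error at α = 0.05, genomic inflation λGC (median z²
  over the χ²₁ median), and a Kolmogorov–Smirnov uniformity check.
- **SPA accuracy**: n = 20 instance with 10 heterozygote and 10
  homozygote carriers and per-sample case probabilities drawn around
  0.05; the exact distribution of T by convolution; SPA compared at every
  lattice tail point below 0.05 where the normal tail errs by more than
  2×.

## Numerical choices and degenerate inputs

- Monomorphic columns are dropped (reported) at standardization; a block
  with no polymorphic column is an error.
- Working weights floored at 1e-8; fitted binary means stay in (0,1).
- PCG refuses non-SPD directions (breakdown error) and reports
  non-convergence as a flag, not an exception, at max_iter.
- Rank-deficient designs are rejected naming the dependent columns
  (pivoted QR).
- The AI update step-halves on negativity; τ exactly 0 with a negative
  score stays 0.
- Filter boundaries: MAC inclusive (≥), imputation quality strict (>);
  records with no quality key pass the quality rule.
- p-values are floored at 1e-300 and capped at 1.
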