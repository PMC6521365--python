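# Methods

This note records the statistical models, algorithmic choices and known
limitations behind `cohortqc`, in the spirit of the methods documentation of
mature statistical packages.

## Data model and preparation

The unit of analysis is a participants-by-variables numeric table (n rows,
p columns, missing entries allowed).  Detection runs on *prepared* matrices:

1. **Covariate adjustment (optional).**  Each variable is replaced by its
   ordinary-least-squares residuals from the full-factorial model
   `1 + age + sex + education + age:sex + age:education + sex:education +
   age:sex:education` (8 columns), fitted on the rows where the variable is
   observed.  Sex is a 0/1 indicator; which level is coded 1 is the caller's
   choice and is recorded on the covariate table.  A rank-deficient design
   is an error that names the collinear terms.
2. **Mean imputation.**  Missing entries are filled with the column mean of
   the observed entries; the imputation mask is retained.
3. **Standardization.**  Every column is scaled to mean 0 and *sample*
   (n−1) standard deviation 1.

Order matters and is deliberate: adjusting on observed rows first keeps the
imputation constant out of the regression slopes, and standardizing last
makes the mean-0/sd-1 property exact on the full column, with imputed cells
landing exactly at 0.  The standalone `standardize` operation, used outside
the pipeline, computes moments from observed entries only.

Constant columns (including residual columns from variables that are exact
functions of the design) are centered, kept on scale 1, and excluded from
multivariate MCD input — a zero-variance column necessarily makes the
covariance singular, so "keep if invertible" is never satisfiable.  They are
retained for univariate boxplots; the uMCD excludes them with a
zero-robust-variance reason.

## MCD pipeline

* **Subset size.**  `h = ⌊2m − n + 2α(n − m)⌋`, `m = ⌊(n+p+1)/2⌋`.  Defaults
  α = 0.8, ε_MCD = 0.99, 100 threshold simulations — the parameter set used
  in the reference cohort analyses this toolkit generalizes.
* **Search.**  500 random (p+1)-point starts by default (capped by
  `max_subsets`, default 100 000).  A start whose covariance is singular is
  grown one random point at a time until it supports a distance ranking.
  C-steps use the maximum-likelihood (1/h) subset covariance; ties in the
  "h smallest distances" ranking break by row order, making every run
  deterministic given its seed.  If every start degenerates the data are
  rank-deficient and an error is raised.  Subsets whose converged covariance
  is numerically singular (smallest squared Cholesky diagonal ≤ 1e−12 of the
  largest variance) are treated as degenerate rather than reported as
  spuriously tiny determinants.
* **Consistency.**  Σ̂ is multiplied by c₀ = (h/n) / F_{χ²(p+2)}(χ²_p
  quantile of h/n).  No finite-sample correction factor is applied; the
  factor equals 1 at h = n.  The p = 1 case agrees with the truncated-normal
  variance correction to quadrature accuracy (tested).
* **Threshold.**  100 MVN samples of size n from (μ̂, Σ̂) are scored against
  the same parameters; all 100·n outlyingness values are *pooled* and the
  ε_MCD empirical quantile taken.  Pooling is the default because it uses
  100× more order statistics per threshold than averaging per-sample
  percentiles; the per-sample variant is available
  (`pooling="per_sample"`).  Flags are strict (`r > threshold`).
* **Explanations.**  The corr-max transformation uses the symmetric
  eigendecomposition branch of the inverse square root.  The conservation
  identity Σⱼŵ²ᵢⱼ = m²ᵢ is exact up to floating point and is enforced by
  test.

## RPCA pipeline

* **Inner solver.**  The decomposition at a fixed λ is solved by inexact
  augmented-Lagrangian alternation: singular-value soft-thresholding at 1/μ
  for L, elementwise soft-thresholding at λ/μ for S, a multiplier update on
  X − L − S, and μ growing geometrically (ρ = 1.5, capped).  Stopping rule
  ‖X−L−S‖_F ≤ 1e−7·‖X‖_F, 500 iterations maximum (non-convergence is
  returned with a flag, not raised).  This is the standard way to make the
  two thresholding steps drive the reconstruction gap to numerical zero
  while S retains exact zeros.
* **Sparsity target.**  λ starts at 1/√max(n,p).  If nnz(S)/(np) ≥ τ the ℓ1
  weight is *strengthened*, λ ← λ/decay with decay = 0.9, and the
  decomposition re-run; under the objective min ‖L‖\*+λ‖S‖₁ a larger λ
  always sparsifies S, so the loop terminates (guarded at 200 passes).  The
  direction is a deliberate design choice: with this parametrization it is
  the only direction that can reach the target, and the empirical
  monotonicity of nnz(S) in λ is tested.
* **Outlyingness.**  Deviation is |o_LS/o_XS − 1| by default; the
  orientation is a config switch (`xs_over_ls` inverts the ratio) because
  either proportion is defensible and neither is asserted as canonical.
  Ordering |ratio − 1| catches both tails.  The threshold is the ε_RPCA
  empirical quantile (linear-interpolation convention) of the deviations,
  and rows exactly at the threshold are flagged — inclusive, so the flagged
  fraction of an n-row table is deterministically ⌈(1−ε)·n⌉ in the absence
  of ties.  Note this is a *relative* rule: some rows are always flagged,
  and on clean data they are simply the least-well-explained ones.
* **Contributions.**  A flagged row's nonzero S entries, ranked by absolute
  value.  Rows can in principle be flagged with an empty S row; such rows
  carry no RPCA contributions.

## Univariate comparators

The uMCD is exact, not approximate: the minimal-variance h-subset of a
univariate sample is contiguous in sort order, so a cumulative-sum window
scan finds the global optimum in O(n log n) (the contiguity is additionally
verified against full h-subset enumeration in tests).  Thresholds reuse the
multivariate simulation machinery at p = 1 with the same seed-spawning
layout, so a p = 1 multivariate run and a uMCD run with the same seed
produce identical flag sets (tested).  Boxplot fences use type-7
(linear-interpolation) quartiles — the convention is recorded in every
result because fence positions depend on it — and flag strictly beyond the
fences, so a constant vector flags nothing.

## Aggregation and iteration

Participants flagged by ≥ `min_flags` (default 2) of the four approaches are
listed for verification.  Contribution rankings are merged across methods by
per-method rank, ties broken by absolute value, each variable keeping full
per-method provenance.  Corrections are always supplied externally —
verification against source documents is a human step and the tool never
auto-corrects.  Convergence requires an iteration with no corrections whose
listed set matches the previous iteration's.

Seeds default to `seed_policy="fixed"`: every iteration reuses the run seed,
so re-detection on unchanged data is bit-identical and convergence is a
property of the data rather than of Monte-Carlo jitter in the simulated
thresholds.  A `per_iteration` policy (seed derived from iteration index) is
available for users who prefer fresh simulations per pass, at the cost of a
possibly flickering listed set near the threshold.

## Synthetic cohorts and error injection

The generator emulates the structure that makes multivariate detection
worthwhile, on a Gaussian-copula backbone: raw/transformed pairs with
within-pair correlation 0.9 (the transformed member is a linear monotone map
of the raw member plus noise calibrated against the raw column's empirical
sd), task blocks sharing a latent factor (within-block correlation 0.7),
covariate-dependent means, and demographics drawn from truncated normals
whose *post-truncation* moments are calibrated by a root solve to the target
cohort profile (age 68.72 (7.42) years on [55, 85], education 14.61 (2.92)
years ≥ 6, male fraction 110/161).  Defaults (161 participants, 8 pairs, two
6-variable blocks) give a 28-variable table; all parameters are overridable.

Error mechanisms:

* `transcription` — a random cell takes another participant's value;
* `transform_miscalc` — the transformed member of a pair is moved to the
  fitted pair line ± 5 residual sd (retrying at 4.5 and 4), subject to
  staying strictly inside that variable's boxplot fences; if no in-fence
  placement exists the value is placed just outside the fence and logged as
  "gross";
* `block_miscount` — all variables of one block are scaled by (s±1)/s for a
  plausible step count s ∈ [8, 15].

Real assessment scores are bounded and discrete; the generator is continuous
because the detectors operate on standardized values where the Gaussian
working model matches the MVN threshold simulations.  Passing tests on these
cohorts therefore demonstrates sensitivity to relationship-breaking and
block-scaling errors under Gaussian-like structure — not performance on
skewed, censored or heavily categorical real tables.

## Problem sizes used in validation

The validation suite runs the exhaustive-MCD comparison at n = 12, p = 2
(792 subsets per instance), C-step monotonicity over 1 000 random steps,
corr-max conservation over 1 000 draws, the RPCA contract over 50
rank-3-plus-spikes instances at 100×20, null calibration over 50 cohorts of
200×10, and the sensitivity study over 20 cohorts of 200×28 with 5 injected
in-fence errors each.  The acceptance script repeats the same computations
at moderately smaller replicate counts and reports every measured value with
the size used.

## Known limitations

* The MCD requires n > p; wide tables must rely on the RPCA route.
* Continuous variables only; categorical or mixed-type tables are out of
  scope.
* Mean imputation before detection shrinks imputed cells to the center,
  so errors *in missing-data handling* are invisible by construction.
* The RPCA percentile rule always flags a fixed fraction; its output is a
  ranking, not a calibrated test.
* No reweighted or deterministic MCD refinements, no missing-data RPCA, no
  MAD/adjusted-boxplot univariate variants.
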