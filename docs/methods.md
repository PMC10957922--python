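# Methods

## The 1-NN spatial-relationship model

A spatial relationship (SR) is the distribution of Euclidean distances
from each cell of a reference type to its nearest cell of a target type,
computed on the whole slide (no compartment stratification, distances
may cross focus boundaries). For a self-self SR a cell is excluded as
its own neighbor. The statistic is directional: the A→B and B→A
distributions are different objects and are modeled separately.

Per sample, the raw distance vector is turned into a smoothed empirical
density: at every integer micrometer t the distances inside the
half-open window [t − 2.5, t + 2.5) are counted (each distance therefore
contributes to exactly five grid points), and the curve is divided by
its trapezoidal area so it integrates to one. The window width (5 μm) is
of the order of one cell diameter; the resulting curve is the input to
the cohort fit.

The cohort model treats each sample's curve as a Weibull density plus
homoscedastic Gaussian noise on the common 1-μm grid restricted to
[0, 99th percentile of pooled distances]:

    y_i(t) = f(t; a_i, b_i) + ε_it,  ε_it ~ N(0, σ²)
    a_i = 10/(1 + e^(−A_i)),  b_i = 500/(1 + e^(−B_i))
    (A_i, B_i) = (A, B) + u_i,  u_i ~ N(0, diag(τ_A², τ_B²))

The logistic links keep shape in (0, 10) and scale in (0, 500) μm while
the optimization runs unconstrained; the bounds are wide relative to any
observed SR (tissue sections are a few mm across). The grid point t = 0
represents the first smoothing bin, so the model density there is
evaluated at x = 0.5 μm (bin-center convention); this keeps candidates
with shape < 1, whose density diverges at zero, finite during
optimization.

### Estimation

The marginal likelihood integrates the random effects out by a Laplace
approximation: for each sample a penalized Gauss–Newton inner iteration
(analytic Jacobians through the logistic chain rule, Levenberg damping)
finds the posterior mode û_i, and the Gauss–Newton Hessian supplies the
Laplace determinant. An REML-style fixed-effects profile correction
−½ log det Σᵢ XᵢᵀVᵢ⁻¹Xᵢ (linearized design Xᵢ = ∂f/∂(A,B) at the modes,
Vᵢ = σ²I + Xᵢ diag(τ²) Xᵢᵀ, evaluated by the Woodbury identity) is added
to reduce variance-component bias. The five outer parameters
(A, B, log τ_A, log τ_B, log σ) are optimized by Nelder–Mead with the
standard control constants (1000 outer iterations, 200 inner iterations,
inner step tolerance 1e−1, convergence tolerance 1e−6), followed by a
tighter restart; the fit is declared converged when the objective is
stable between the two stages and the linearized fixed-effects
information matrix is positive definite. Initialization comes from
per-sample raw-distance Weibull MLEs pushed through the inverse links;
the population start is their mean and the random-effect SD start their
spread.

Per-sample reported parameters are fixed effect + posterior-mode random
effect (empirical-Bayes predictions), which is what per-sample scatter
plots and the median-distance comparisons use.

### Standard errors

The smoothing window correlates residuals across neighboring grid
points, so model-based (inverse-information) standard errors of (A, B)
overstate precision. The package instead reports cluster-robust SEs from
a delete-one-sample jackknife on the linearized mixed-model equations,
scaled by the small-sample t-calibration factor t_{n−1}(Φ(2))/2 so that
the conventional ±2·SE band has its nominal coverage with cohort-sized
sample counts (~24). Calibration was verified by simulation: joint
two-parameter ±2·SE coverage ≈ 0.95 across replicate cohorts drawn at
the generator defaults.

### The cell-count filter ladder

When a cohort fit fails to converge, samples with fewer than 20 cells of
either the reference or target type are dropped and the fit retried,
escalating through 50, 70 and 100 cells. An SR still non-convergent
after the last rung is *rejected* — a recorded first-class outcome
(rare cell types produce noisy distance distributions that resist
fitting; a small rejection rate is expected operation). Samples whose
distance vectors are degenerate (constant, or too few distances for an
MLE) are excluded with a recorded reason before fitting.

## Derived summaries

* Analytic CDF (the Weibull G-function): CDF(r) = 1 − exp(−(r/b)^a).
* Median 1-NN distance: b·(ln 2)^(1/a). Note (ln 2)^(1/a) → 1 only
  slowly: at a = 10 the median still sits 3.6% below the scale.
* Weibull-G-AUC-T: ∫₀ᵀ CDF(r) dr by adaptive quadrature (abs. tol.
  1e−8); at a = 1 it has the closed form T − b(1 − e^(−T/b)).
* Empirical G-function: the raw ECDF of the 1-NN distances (no edge
  correction) on a 1-μm grid; a reduced-sample border-corrected variant
  is available behind a flag. G-AUC-T is its trapezoidal integral on
  [0, T]; it is non-decreasing and 1-Lipschitz in T, which is exactly
  why a single-threshold summary is fragile — the package's point of
  comparison for the threshold-free Weibull summary.

## Segmentation

Foci (tissue islands) are split by DBSCAN over all cell positions with
ε = 300 μm and minPts = 50; non-core-reachable cells are noise
(focus −1) but still receive a compartment label. Per focus, Gaussian
kernel intensity surfaces of cancer and negative cells are computed on a
10-μm pixel grid (≥64 px per axis) padded two pixels beyond the focus
bounding box. The kernel bandwidth maximizes the leave-one-out
point-process log-likelihood over 16 log-spaced values spanning
[2 μm, focus-diagonal/4]; a boundary maximum (monotone likelihood)
falls back to Scott's rule. Both surfaces are max-normalized and
compared at each cell position by bilinear interpolation: tumor where
the cancer surface is strictly greater, stroma otherwise (ties are
stroma). A focus with no cancer cells is entirely stroma; with no
negative cells, entirely tumor. Compartment areas count pixels with
normalized intensity ≥ 0.1 (tumor surface for tumor area; the sum of
both surfaces for total tissue; stroma = total − tumor, clipped at
zero), summed over foci; per-focus normalization is used throughout.
The distal-stroma trim removes stroma-compartment cells whose nearest
cancer cell lies beyond 150 μm; a slide without cancer cells is left
unchanged with a warning. Segmentation depends on coordinates only
through pairwise geometry, so it is invariant (up to pixel
discretization) under rigid motions.

## Density metrics

Densities are counts per compartment area, reported per mm². The
exclusion ratio (stromal / intratumoral density of an immune type) uses
a 0.5-cell continuity correction in both counts so it stays finite and
log-transformable when a compartment is empty; raw densities carry no
correction. Zero-area compartments yield missing values, not errors.

## Association battery

Group tests are two-sided Welch t-tests (the unequal-variance default of
standard statistical environments; a pooled-variance switch exists) on
each metric's analysis scale: logarithmic for densities, exclusion
ratios, the Weibull scale, G-AUC and medians; linear for the shape.
Benjamini–Hochberg adjustment runs within each declared metric family
(shape across SRs, scale across SRs, densities, ...), with significance
at FDR < 0.10; the fold change is the difference of group means on the
analysis scale (a log-ratio for log-scale metrics). Median 1-NN
distances per sample come from the per-sample Weibull parameters and are
compared by an exact two-sided Mann–Whitney test (normal approximation
above 20 per group). Predictive power uses unpenalized logistic
regression (IRLS; perfect separation is flagged and the capped fit
used): the ROC is built from in-sample fitted probabilities — an
optimistic estimate, stated as such — with AUC by the rank statistic,
95% CIs by class-stratified bootstrap (n = 500, seeded), significance
against AUC = 0.5 by the two-sided rank test on fitted scores, model
comparisons by a paired bootstrap of AUC differences (one-sided t-test)
and by leave-one-out residual-deviance vectors (two-sided t-test).

## Synthetic cohorts

The generator emulates what the statistics need from real slides, not
their biology: cancer cells in Thomas-process nests (8 nests of 60-μm
Gaussian radius per 1-mm² slide at 2·10³ cells/mm²), a negative-cell
stroma repelled from the nests, and immune populations one to two
orders of magnitude rarer (CD8⁺ T 200/mm², macrophage 150/mm², B cell
100/mm², T-helper 100/mm², FoxP3⁺ T 50/mm²) placed by distance-kernel
thinning toward or away from cancer cells (e-folding depth 30 μm,
effect size 0.9): responders attract, non-responders repel, producing
the group gap in immune-to-cancer proximity. Poisson (CSR) patterns
supply the closed-form Weibull oracle (a = 2, b = (πλ)^(−1/2));
distance cohorts drawn directly from per-sample Weibull laws with
Gaussian random effects on the link scale (defaults: 24 samples, 2000
distances, RE SDs 0.3/0.2) are the mixed-model recovery oracle. Four
scenario presets span the scale/shape taxonomy: a dense CSR target
(low scale, high shape), shared dense clusters plus a uniform reference
minority (low scale, low shape), tight target clusters with widely
spread references (high scale, low shape), and mutually displaced
cluster pairs (high scale, high shape).

What the generator does not emulate: marker-intensity noise,
segmentation/phenotyping errors, irregular tissue outlines, holes and
folds, anisotropic nest shapes, or multi-focus biopsies with
heterogeneous architecture. Passing tests therefore demonstrate
correctness of the statistical machinery under known generative models,
not robustness to imaging artifacts.

## Numerical choices and limitations

* The 5-μm moving-average smoothing biases fitted parameters slightly
  for SRs whose scale is comparable to the window: in the CSR oracle
  (true scale 7.98 μm) the recovered scale runs ~3% high and the shape
  ~3% low. The published curve-fit construction shares this property;
  it is accepted, not corrected.
* The empirical curve's first three grid points are attenuated by the
  window truncation at zero distance; the unit-area normalization
  redistributes that mass.
* Problem sizes in the test-suite and acceptance runs (24-sample
  cohorts, ~10³–10⁴ cells per slide, 20 recovery replicates) were chosen
  to exercise every code path at cohort-realistic scale on a single CPU.
* Optimizer determinism: no randomness enters the fit itself, so
  refitting identical inputs is bit-reproducible; all simulation entry
  points take explicit seeds.
* Degenerate inputs: all-equal distance vectors are rejected as
  carrying no distributional information; zero distances (coincident
  centroids) are floored at 0.01 μm before MLE; empty-target SRs raise
  a typed error carrying the (nFROM, nTO) counts so the filter ladder
  can record them.
* The tie rule at exactly equal tumor and negative surface intensity
  assigns stroma; ties occur on a measure-zero set and at the
  all-zero-surface degenerate case.
* ROC estimates use in-sample fitted probabilities and are optimistic;
  no cross-validated ROC is provided by design (the deviance comparison
  is the cross-validated view).
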