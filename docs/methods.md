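# Methods

## Model

The package estimates damped-linear-oscillator dynamics for a latent
process f observed indirectly through P indicator series on N persons at
T (approximately daily) occasions. The structural equation is

    f''_{jt} = η f_{jt} + ζ f'_{jt} + e_{jt},   e ~ N(0, V_e),

with η (1/time², negative for oscillation) governing frequency and ζ
(1/time, negative for damping) governing amplitude decay. η and ζ are
assumed constant across persons; person heterogeneity enters only through
the equilibrium (latent intercept) means m_j. The implied wavelength is
λ = 2π·Δt / √(−η − ζ²/4), defined only on the underdamped region
−η − ζ²/4 > 0.

### Time-delay embedding

Each person's series is restructured into overlapping windows of length D
(lag τ between window columns; τ = 1 throughout, per standard practice),
and the per-series embedded matrices are column-bound series-major.
Windows never span two persons. Occasion gaps inside a person's range are
retained as missing cells on the occasion grid, never silently compressed:
a person with a contiguous span of S occasions yields max(0, S − (D−1)τ)
rows regardless of interior missingness. A window spans (D−1)·τ·Δt time
units; the sampling-limit check requires this span to be strictly below
the wavelength and is reported as a warning with the span/λ ratio, not a
hard stop, because λ is only known after fitting.

### Measurement structure

The loading matrix is a fixed Taylor basis: for lag i with centered offset
o_i = (i − (D−1)/2)·Δt and derivative order k, the loading of embedded
column (s, i) on the k-th latent derivative is l_s · o_i^k / k!, with
l_1 ≡ 1 and l_2, …, l_P free. Centering keeps the zeroth derivative
referenced to the window midpoint for any D; even D yields half-integer
offsets, the natural symmetric extension of the odd-D pattern. The
second-order model (SOLDE) carries q = 3 latent derivatives; the
constrained fourth-order model (FOLDE) carries q = 5 and regresses each of
the three consecutive derivative pairs onto the one below with the same
(η, ζ). D ≥ q is enforced for identification.

Free parameters: η, ζ; P−1 series loadings; the exogenous covariance of
(f, f') — V(f), V(f'), Cov(f, f') — with latent means fixed at 0;
structural residual variances (one for SOLDE, three free and unequal for
FOLDE, which fixes the FOLDE−SOLDE difference at exactly 2 parameters and
hence 2 degrees of freedom for the likelihood-ratio test); P unique
variances u_s, each constrained equal across the D embedded columns of its
series; and N person equilibrium means, modeled as fixed effects
("mean grouped by individual"), not as a random effect. All covariances
between the exogenous block and structural residuals, and among residuals,
are fixed at 0. The implied moments are Σ = L Ψ L' + Θ with
Ψ = (I−A)⁻¹ Φ* (I−A)⁻ᵀ and μ_j = m_j · (first column of L).

## Estimation

Full-information maximum likelihood: each embedded row contributes the
multivariate-normal log-density of its observed cells, using the person's
sub-mean and the missingness pattern's marginal covariance (valid under
missing-at-random). Rows with no observed cells contribute zero. Pattern
index sets, data blocks and the per-pattern Cholesky/precision factors are
cached and batched by pattern size.

**Rows are treated as independent although adjacent windows overlap.**
This is the standard estimation convention for this model family and it is
what the likelihood above encodes; point estimates are consistent targets
of the same estimating equations, but the information is overcounted, so
all reported standard errors are *naive* (understated). This caveat is
printed in every summary.

Person means enter the likelihood linearly given Σ, so they are profiled
out of the numerical search: at each candidate Σ the inner maximum is the
per-person generalized-least-squares mean
m̂_j = (Σ_rows L0'Σ⁻¹w) / (Σ_rows L0'Σ⁻¹L0) over person j's rows (observed
sub-patterns). The profiled likelihood equals the joint maximum exactly,
and the means are reported as ordinary parameters. By the envelope
theorem the gradient of the profiled objective is the partial gradient at
the inner optimum; the package supplies this gradient analytically (exact
matrix-calculus contractions against d(ll)/dΣ), verified against central
finite differences in the tests.

Optimization is L-BFGS-B on an unconstrained scale: variances are
log-transformed, and the (f, f') covariance block goes through a
log-Cholesky map so it remains positive definite. Transformed
log-standard-deviation coordinates are box-bounded at ±30 — data simulated
from exact deterministic trajectories legitimately drive structural
residual variances to zero, and the bound keeps such boundary solutions
finite. The objective is scaled per row so finite-precision effects do
not depend on panel size. Starting values are data-driven: η from the
heuristic −(2π/(T/2))², ζ = 0, loadings 1, variance parameters from
within-person moment splits.

Restart policy (retry until confirmed): after the first search, at least one
additional search always runs from the incumbent optimum perturbed by
Uniform(−h, h) per parameter, scaled to each parameter's magnitude
(absolute perturbations of ±1 would throw η and ζ, both of order 0.01–0.1,
far outside the admissible region). Restarts continue while they improve
the best fit or fail, up to 30 extra attempts; the best confirmed solution
is returned. A line-search failure at a sharp optimum (L-BFGS-B status 2)
is treated as convergence, since it means no representable step improves
the fit. Non-convergence never raises; the best point is returned
flagged. The full attempt history is retained.

Standard errors come from the observed information of the profile
likelihood — equal to the corresponding block of the full-parameter
inverse information — computed by finite differences on the smooth
transformed scale and mapped to the natural scale by the delta method;
variance parameters resting on the boundary get NaN, as their curvature is
uninformative there. Person-mean standard errors are the GLS conditional
ones, 1/√(Σ L0'Σ⁻¹L0). Negative likelihood-ratio statistics (optimizer
noise between two separately fitted models) are clipped to zero with a
warning.

## Embedding-dimension selection

The frequency estimate is typically unstable below some D and settles
once windows carry enough curvature information. Practice identifies the
stabilization point visually; this package must be algorithmic, so two
explicit interpretations are provided, both documented as such rather
than as prescriptions:

* **relative-change** (default, threshold 0.10): the smallest D whose η̂
  is reproduced within the threshold by *every* larger D in range
  (persistence guards against transient plateaus); the largest D in range
  can never qualify, since stabilization cannot be confirmed there;
* **max-curvature**: the D maximizing the discrete second difference of
  the η̂ sequence.

Each dimension is fitted independently with its own data-driven start
(optional warm starts reuse the previous dimension's estimates, off by
default). Non-identified dimensions are skipped with a logged reason;
the wavelength is reported only where the estimates are underdamped.

## Factor scores and vector fields

After fitting, per-row scores for the latent derivatives use the fitted
person means for centering (not person sample means). The regression
method, F̂ = Ψ̂L'Σ̂⁻¹(w − μ̂), weights by the latent covariance and is
shrunken (minimum MSE); the Bartlett method,
F̂ = (L'Θ̂⁻¹L)⁻¹L'Θ̂⁻¹(w − μ̂), is conditionally unbiased (its weights
left-invert L exactly, so noiseless rows are scored exactly). Missing
cells are handled by pattern-wise submatrices; rows with fewer observed
cells than latent factors are skipped with a log entry. Vector fields bin
the (f, f') scores on a grid (default 10×10 over the central 95% range)
and draw the mean (f', f'') arrow for bins holding at least 5 rows — the
empirical phase-plane flow implied by the scores.

## Synthetic data

The simulator is the package's substitute for the kind of data the method
targets: a daily-diary panel with N = 41 persons, T = 56 occasions
(Δt = 1 day) and P = 3 indicators of one latent oscillation. Latent
trajectories are the exact closed-form solution
x(t) = e^{(ζ/2)t}[A cos ωt + B sin ωt], ω = √(−η − ζ²/4), per person from
random initial conditions; non-oscillating parameter pairs are refused
unless explicitly overridden. Default conditions, chosen once on
substantive grounds: η = −0.00997, ζ = −0.05 (wavelength exactly 65 days,
mild damping, the scale typical of slow stress-regulation cycles, and —
deliberately — a wavelength *longer* than the observation window, the
regime that makes small-T estimation hard); loadings (1, 0.9, 1.1);
equilibria N(15, 5²) on a perceived-stress-composite-like scale; initial
position sd 3 and velocity sd 3·ω ≈ 0.3; measurement noise sd 1.0 per
series (within-person indicator reliability ≈ 0.9); 5% of cells deleted
completely at random (diary compliance). Initial conditions are drawn
independently of equilibria.

What the simulator does *not* emulate: dynamic (process) noise is off by
default, because this model family cannot separate endogenous from
exogenous disturbances — an optional Euler–Maruyama process-noise term
exists for robustness experiments only; there is no person variation in
(η, ζ), no regime switching, no nonlinearity, and missingness is MCAR
(sufficient for exercising MAR-based estimation, but not a test of
MAR-vs-MNAR robustness). Passing tests therefore certify the estimation
machinery under the model's own assumptions, not robustness to their
violation.

## Problem sizes used in the checks

Replicated studies are sized to run comfortably on one CPU: the
diary-scale recovery study uses 20 replicate panels at the default
conditions (fourth-order fits at D = 6), the low-noise benchmark uses
3 replicates at N = 50, T = 100, noise sd 10⁻³, and the null-calibration
check of the SOLDE-vs-FOLDE test uses 40 univariate replicates at N = 10,
T = 45 — small enough to finish in minutes, large enough for median-based
and rate-based assertions at the tolerances tested. The acceptance script
uses 5 recovery replicates and a D = 5..8 scan. At 40 replicates only the
upper bound of the null rejection rate is meaningfully testable; the test
asserts no inflation (rate ≤ 0.12), with boundary effects on the two added
variance parameters expected to make the test conservative.

## Known limitations

* Standard errors are naive throughout (window-overlap dependence is
  ignored by construction); no sandwich correction is provided.
* The elbow rules are explicit operationalizations of a visual heuristic;
  threshold 0.10 is this package's choice.
* Wavelength is highly sensitive near the overdamped boundary: small
  (η, ζ) changes can move λ by tens of percent (this propagation is a
  feature of the parameterization, demonstrated in the tests, and a
  reason to take the dimension scan seriously).
* Fixed-effect equilibria cost one parameter per person; a
  random-equilibrium variant is out of scope.
* No automatic τ selection, no likelihood-based D selection, no Bayesian
  or state-space estimation, no multiple imputation.
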