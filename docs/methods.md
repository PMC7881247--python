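# Methods

## Model and fitting

The Poisson regression model takes counts y_i ~ Poisson(μ_i) with
log link μ_i = exp(η_i), η_i = x_i′β, where the design matrix X carries an
explicit intercept column. The log-likelihood
l(β) = Σ yᵢηᵢ − μᵢ − ln yᵢ! is maximized by Fisher scoring,
β ← β + I(β)⁻¹S(β) with score S = X′(y−μ) and expected information
I = X′WX. For the canonical log link Fisher scoring coincides with
Newton's method and with IRLS on the working response z = η + (y−μ)/μ.

Numerical choices:

- **Initialization**: OLS of ln(y + 0.5) on X — deterministic and robust.
- **Convergence**: sup-norm of the update < 1e-8 *and* score sup-norm
  < 1e-6; at most 100 iterations; up to 20 step-halvings whenever a full
  step would decrease the log-likelihood, so the likelihood path is
  non-decreasing by construction.
- **Degenerate input**: y ≡ 0 is rejected (the intercept MLE diverges);
  a numerically singular information matrix raises an error naming its
  condition number; non-convergence is flagged, never silent.

Two weight conventions are exposed for the reported weights and the
cross-product X′ŴX: the canonical `mu` (Ŵ = diag(μ̂), the default, matching
the Poisson ridge/Liu literature) and `mu_squared` (Ŵ = diag(μ̂²), with
working response z = η + (y−μ)/μ²). Both share the score X′(y−μ) and hence
the same MLE — verified in the tests — so the iteration always uses the
canonical metric (quadratic convergence; the μ²-metric fixed point iteration
is only linearly convergent) and the convention is applied to the final
weights. The choice matters for the shrinkage spectra, which are built from
X′ŴX.

The eigendecomposition X′ŴX = QΛQ′ uses a fixed sign convention (each
eigenvector's largest-magnitude entry positive) so the canonical
coefficients α̂ = Q′β̂ are reproducible across linear-algebra backends.
Eigenvalues are sorted descending; an eigenvalue below 1e-10 triggers an
ill-conditioning warning rather than a failure. The intercept column
participates in the cross-product and is shrunk like any other coordinate.
Regressors are not standardized by default (a `standardize`-free design was
chosen because the estimators are defined directly on X′ŴX; the CSV
workflow documents that users who want scale-invariance should pre-scale).

## Estimators and risk

All four estimators are diagonal in the eigenbasis (see README for the
factors). The data-driven rules evaluate the population formulas at the
plug-in quantities (λ̂ᵢ, α̂ᵢ) from the MLE fit. The Liu d is clamped into
[0, 1] because the raw rule can leave the estimator's defined range. The
Kibria–Lukman k may exceed λ_min, in which case the affected coordinates
flip sign; this is reported as a warning, not an error, because the
aggregate rules (minimum, then square root) keep k small in practice.

Risks are computed in canonical coordinates from first principles:
MSEM = Q(AΛ⁻¹A′ + bb′)Q′ with A the shrinkage matrix and b = (A−I)α the
bias, rotated by Q only when a matrix in original coordinates is requested.
The scalar risk is the trace, variance Σaᵢ²/λᵢ plus squared bias Σbᵢ²; the
reduction identities (k = 0 or d = 1 recover the MLE risk Σ1/λᵢ) hold
exactly. Differentiating the scalar Kibria–Lukman risk in k yields the
per-coordinate optimum k = λ/(1+2λα²), which the tests recover by grid
search. Dominance reports give both the analytic per-coordinate
sufficient-condition values (variance-part comparisons) and, independently,
the smallest eigenvalue of the full MSEM difference, since the analytic
conditions ignore the bias terms and are only sufficient.

## Simulation design

The generator emulates a controlled-collinearity count-regression study:

- **Design**: x_ij = √(1−ρ²) w_ij + ρ w_{i,p+1} with w iid standard normal,
  giving unit-variance columns with pairwise correlation ρ². The standard
  normal law was chosen because it makes the stated correlation structure
  exact. Defaults: ρ ∈ {0.8, 0.9, 0.95, 0.99, 0.999}, p ∈ {4, 7},
  n ∈ {50, 75, 100, 200}.
- **Coefficients**: slopes equal with Σβⱼ² = 1 (βⱼ = 1/√p); intercept
  β₀ ∈ {−1, 0, 1} sets the mean count level (≈ e^{β₀} up to the log-normal
  factor from the random design).
- **Response**: y_i ~ Poisson(exp(x_i′β)); a draw with any η_i > 30 is
  treated as pathological and redrawn.
- **Replications**: 1000 by default. The design matrix is regenerated every
  replication (matching the independence assumption behind the Monte Carlo
  standard errors); a `fix_design` flag provides the fixed-design variant.
- **Estimated risk**: MSE(β̂) = (1/R) Σᵣ ‖β̂ᵣ − β‖², summed over all p+1
  coefficients including the intercept (an `mse_excludes_intercept` flag
  supports sensitivity analysis), reported with per-cell Monte Carlo
  standard errors and, via the stored per-replication errors, paired
  standard errors for estimator contrasts.
- **Seeding**: a master seed spawns one child stream per cell and one per
  replication, so any cell is reproducible in isolation and in parallel.
  Non-converged replications are redrawn (logged) up to a 5% budget; beyond
  that the cell is flagged invalid rather than silently dropped.

Problem sizes used by the shipped checks: the stable-cell table
(n = 200, ρ = 0.8) runs at the full 1000 replications; the 120-cell default
grid is swept at 400 replications per cell, which keeps the whole suite to
a few minutes while paired contrasts at ρ ≥ 0.95 remain 10–18 standard
errors wide.

What the generator does *not* emulate: overdispersion, offsets/exposure,
discrete or skewed regressors, model misspecification. Passing tests
therefore demonstrate correctness of the estimators and the experiment
under the idealized equidispersed, Gaussian-design conditions, not
robustness on messy real data.

## Known limitations and open points

- **Published-table reproduction.** Re-running the experiment reproduces
  the qualitative structure of the published study exactly (risk ordering,
  growth in ρ, decay in n, PKLE2 minimal) and several stable cells
  quantitatively, but not every printed value: the printed stable-cell MSEs
  scale between intercept levels by factors of ≈4.2 and ≈1.8, whereas any
  generator of the stated form scales the risk log-linearly in the
  intercept (≈ e per unit, confirmed both by simulation and by direct
  evaluation of E tr(X′ŴX)⁻¹ under every convention variant we tried:
  intercept in or out of the error sum, correlation ρ vs ρ², fixed vs
  regenerated designs). The corresponding acceptance test is therefore
  expected to fail for some cells; the dominance and ordering claims all
  reproduce.
- **PKLE2 vs MLE near-ties.** At ρ = 0.8 and large n the two estimators
  differ by < 1% in risk; under some seeds a single grid cell out of 120
  can flip the sign of the estimated difference. The paired-contrast test
  at ρ ≥ 0.95, where the claim has content, is stable.
- **Real-data diagnostics.** For the 30-mission aircraft-damage dataset the
  literature prints three eigenvalues for a four-coefficient model, a
  condition number (219.365) inconsistent with those eigenvalues
  (√(2085.2251/4.3333) ≈ 21.94), and an MLE risk (1.0290) inconsistent with
  both. The package computes CN = √(λ_max/λ_min) from its own fit and
  treats that example as a qualitative check (sign agreement; risk ordering
  PKLE2 < PKLE1 < PRRE < PLE < PMLE). The dataset is textbook data and is
  not redistributed; `pklreg fit` accepts it as a CSV with columns y, x1
  (aircraft type), x2 (bomb load), x3 (aircrew experience).
- Two-parameter and jackknifed ridge estimators, other GLM families,
  offsets and robust covariances are out of scope.
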