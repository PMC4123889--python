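# Methods

## Model

`spfmlm` fits the two-level Gaussian mixed model

    Y_ij = γ00 + γ01 Z_j + γ10 X_ij + u_0j + u_1j X_ij + r_ij,

with individual error r_ij ~ N(0, σ²), area random intercept
u_0j ~ N(0, τ00), and at most one area random slope u_1j ~ N(0, τ11). The
intercept and slope are independent by default (a diagonal 2×2 covariance);
an unstructured covariance is available via `MLMSpec(random_structure=
"unstructured")`. The diagonal default matches the usual reporting style for
this model family (two variance components, no covariance) and is one fewer
parameter to estimate.

Estimation defaults to maximum likelihood (ML), not REML, because the
pipeline compares models that differ in their fixed effects by AIC and
log-likelihood, and REML objective values are not comparable across
fixed-effect structures. REML remains available for final-model variance
reporting. Fitting is delegated to statsmodels `MixedLM`; the random slope
enters as a variance component (`vc_formula`) so the diagonal structure is
exact.

AIC is computed in-package as −2·loglik + 2·k with k = number of fixed
effects + number of variance parameters (σ², τ00, and τ11 when a slope is
present, plus the covariance under the unstructured option) — the convention
of mainstream mixed-model software.

ICC is τ00/(τ00 + σ²) from the null (covariate-free) model; requesting it
from a covariate model is an error, since the variance partition is only a
variance decomposition of the outcome in the empty model.

### Optimizer strategy

`MixedLM`'s default L-BFGS occasionally stalls at a spurious boundary
solution — sometimes with an infinite "likelihood" and a converged flag. Each
fit therefore runs L-BFGS and then Powell (and Nelder–Mead as a last resort
when neither converges), keeping the solution with the best finite
log-likelihood. Zero variance estimates are boundary warnings, not errors;
negative ones are errors.

### Conditional modes

The "neighborhood-level residuals" that the spatial diagnosis consumes are by
default the conditional modes (empirical-Bayes BLUPs) of u_0j. On balanced
random-intercept data these equal the closed-form shrinkage
τ00/(τ00 + σ²/n_j)·(ȳ_j − ŷ_j), which the tests verify. Raw per-area means
of the marginal residuals are available as an alternative
(`residual_source="area-means"`); when τ00 is estimated at the zero boundary
the modes are identically zero, and the pipeline falls back to the area-mean
residuals for the Moran diagnosis rather than testing a constant vector.

## Moran's I

For per-area values y and binary symmetric weights v (never
row-standardized here — both the statistic and the eigenvector extraction
consume the raw entries):

    I = n/S0 · Σ_ij v_ij (y_i − ȳ)(y_j − ȳ) / Σ_i (y_i − ȳ)²

The z-score uses the null moments under the normality assumption:
E[I] = −1/(n−1) and the standard closed-form variance built from
S0 = Σv_ij, S1 = ½Σ(v_ij+v_ji)², S2 = Σ_i(Σ_j v_ij + Σ_j v_ji)². The
p-value is two-sided standard normal. A conditional permutation test
((rank+1)/(n_perm+1)) provides a distribution-free cross-check; the suite
verifies its 5%-level rejection rate on white noise and its power on
clustered patterns. A constant input vector is an error (the statistic is
0/0), not I = 0.

## Eigenvector extraction

Eigenvectors come from the doubly-projected symmetrized weight matrix
M·((V+Vᵀ)/2)·M with M = I − X(XᵀX)⁻¹Xᵀ, the SAR-family quadratic form.
Numerically the decomposition is done on Qᵀ((V+Vᵀ)/2)Q where Q is an
orthonormal basis (from the full SVD of X) of the orthocomplement of
col(X): every returned eigenvector is then exactly orthogonal to the
projected-out design, the k trivial zero eigenvalues never appear, and the
eigenvectors of the restricted matrix are eigenvectors of M W M with the same
eigenvalues. For the intercept-only projector, Moran's I of eigenvector i
equals (J/S0)·λ_i, an identity the tests check on lattices up to 20×20.

The projector defaults to intercept-only (X = 1) at the area level, which
keeps the basis model-independent; projecting out the area covariates is
available (`projector="area-covariates"`), and the report records the
choice. Eigenvectors are sign-indeterminate, so each column is flipped to
make its first coordinate of magnitude > 1e-12 positive; columns are stored
in descending order of Moran's I, and report labels follow that numbering
(e_1 = highest Moran's I).

## Stepwise selection

Candidates default to eigenvectors with Moran's I > 0 (positive spatial
dependency patterns); a relative-eigenvalue threshold rule
(λ/λ_max ≥ c) is available. Selection is greedy Moran's-I minimization: at
each step every remaining candidate is evaluated through a residual-producing
model contract, and the one minimizing |z(Moran's I)| of the residuals is
appended, stopping when |z| < threshold (default 0.1 — the z-score, not the
statistic itself), the pool or the `max_vectors` guard
(default min(J−k, 100)) is exhausted, or no candidate avoids increasing |z|
(a worsening step is never accepted). Ties within 1e-12 in |z| prefer the
candidate with the higher Moran's I, then the lower index, making the
procedure fully deterministic.

Two residual contracts bracket the plausible readings of filtering in a
multilevel setting:

* **fast-OLS** (default): the mixed model is fit once; candidates are
  evaluated by area-level OLS of its neighborhood residual vector on the
  candidate columns. This matches the single-level behavior of standard
  spatial-filtering implementations and costs one mixed-model fit per
  selection round.
* **exact-refit**: every candidate evaluation refits the full mixed model
  with the expanded eigenvectors as fixed effects. Faithful to the
  multilevel interpretation, and J-times slower; the tests verify both
  contracts choose the same first eigenvector on planted-signal data.

Because fast-OLS minimizes |z| of *OLS-filtered* residuals, the refit mixed
model's residuals can land back above the threshold. The pipeline therefore
re-bases selection on the refit model and repeats, up to `max_rounds`
(default 3) rounds, accumulating eigenvectors; the round with the smallest
refit |z| is kept. Selected eigenvectors enter the model as fixed effects
only — the random structure is unchanged from the Level-2 model.

## Pipeline and report

The orchestrated sequence is null → Level-1 (individual covariates) →
Level-2 (both levels) → Moran diagnosis of the Level-2 neighborhood
residuals → filtering (only if |z| ≥ threshold) → the spatially filtered
model. The report carries, per model, the fixed-effect table with
significance stars (* p<0.05, ** p<0.01, *** p<0.001), variance components,
AIC and log-likelihood, plus ICC, before/after Moran results, the selection
path, the selected per-area eigenvector values (exported as CSV for mapping
in external tools), and provenance (config echo, seed, library versions).
Areas present in the weights but absent from the data are dropped with a
note; islands (zero-neighbor areas) abort the run unless `drop_islands=True`
is set, because Moran inference and the eigenbasis are ill-conditioned with
disconnected singletons.

## Synthetic data generator

The generator emulates a two-level health-survey analysis: binary individual
covariates (female 0.578, unemployed 0.603, low stress 0.787), a heavily
right-skewed monthly income (log-normal, mean 1382, sd 1988), three
continuous area covariates (a deprivation index, physicians per 1000, a
fiscal-independence percentage), an outcome on a 0–1000 utility-index scale,
and default coefficients and variance components in the ranges typical of
such analyses (σ² = 52225, τ00 = 1062, τ11 = 0.0036, random income slope).
All randomness flows from a single seed.

Spatial structure in u_0j is planted either as a mixture of the lattice's
own Moran eigenvectors (ground truth expressible in the filtering basis;
`eigen_coefficient` converts a variance fraction to a coefficient so the
total Var(u_0j) stays at τ00) or as a SAR process (I − ρW̃)⁻¹ε with
row-standardized W̃ — used only inside the generator — for signal not aligned
to the basis. A neighborhood covariate can share eigenvectors with the
planted signal (`nbh_spatial`) to create spatial confounding.

What the generator does **not** emulate: survey design (stratification,
sampling weights), measurement structure of utility indices (simulated
outcomes are unbounded Gaussians, not bounded index values), real
administrative geographies (regular lattices stand in for irregular census
tracts), and covariate spatial autocorrelation beyond the explicit
`nbh_spatial` hook. Passing tests therefore demonstrate correctness of the
estimators and the filtering machinery under the model's own assumptions,
not robustness to survey artifacts or misspecified outcome distributions.

## Test problem sizes and statistical test design

The planted-signal study conditions in the acceptance suite use a 15×15
Queen lattice (J = 225) with 40 individuals per area and one planted
eigenvector carrying 18% of the τ00 budget — calibrated once so the realized
area effects have Moran z ≈ 5 — across 5 seeds; unit and property tests use
lattices from 2×2 up to 20×20 and replicate counts of 10–25, sized so the
full suite runs in a few minutes on one CPU.

Bias checks over replicates account for the sampling distribution actually
in play: with R replicates the studentized mean-bias is t_{R−1}, not normal,
and the fitted parameters are strongly correlated (the intercept against
area covariates with large means), so joint checks use Hotelling's T² or
Bonferroni-corrected t quantiles rather than a per-parameter 2-SE rule,
which would reject a perfectly unbiased estimator in a large fraction of
runs.

## Known limitations

* Gaussian outcomes only; no generalized (binomial/Poisson) filtering.
* One random slope; no cross-classified or 3-level structures.
* Greedy selection is not best-subset: it can stop at a local plateau
  (`converged=False`) in rare draws, which the pipeline reports rather than
  hides.
* Dense linear algebra throughout: comfortable to a few thousand areas,
  not intended for national-scale lattices beyond that.
* Coefficients depend on the outcome's scale; no rescaling is applied
  internally.
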