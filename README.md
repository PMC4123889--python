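# spfmlm — spatially filtered multilevel models

`spfmlm` fits two-level linear mixed models for individual outcomes nested in
neighborhoods and removes spatial dependency from the neighborhood-level
residuals with Moran-eigenvector spatial filtering. It is aimed at
epidemiologists and health geographers who analyze survey outcomes (e.g. a
self-rated health index) against individual covariates and area covariates,
where nearby areas are more alike than the independence assumption of a
conventional multilevel model allows.

## The model

The conventional two-level model for individual *i* in neighborhood *j*:

```
individual level:     Y_ij = β0j + β1j X_ij + r_ij
neighborhood level:   β0j  = γ00 + γ01 Z_j + u_0j
                      β1j  = γ10 + u_1j
```

with r_ij ~ N(0, σ²), a random intercept u_0j ~ N(0, τ00) and a random slope
u_1j ~ N(0, τ11) (independent by default). The intra-class correlation
ICC = τ00 / (τ00 + σ²) from the null model measures the between-neighborhood
share of outcome variance.

When the u_0j are spatially autocorrelated — diagnosed by Moran's I of the
conditional modes (BLUPs) of u_0j over a binary Queen-contiguity weight
matrix V — the model is augmented with Moran eigenvectors: the eigenvectors
of the doubly-projected symmetrized weight matrix

```
M ((V + Vᵀ)/2) M,     M = I − X(XᵀX)⁻¹Xᵀ
```

associated with the simultaneous-autoregressive (SAR) family. Each
eigenvector is an area-level map pattern with a characteristic Moran's I;
they are mutually orthogonal, so the selected subset E enters the fixed part
as synthetic covariates without collinearity:

```
Y_ij = γ00 + γ01 Z_j + γ10 X_ij + Σ_k γ_k e_kj + u'_0j + u'_1j X_ij + r_ij
```

Selection is a greedy Moran's-I minimization: at each step the candidate
eigenvector that most reduces |z(Moran's I)| of the neighborhood-level
residuals is added, until |z| < 0.1 (configurable). The filtered model leaves
spatially white neighborhood residuals, an improved AIC, and unbiased area
covariate estimates when spatial signal confounds them.

## Worked example

`python examples/03_spatially_filtered_model.py` simulates a survey-like
dataset on an 8×8 Queen lattice (64 neighborhoods × 40 respondents, outcome
on a 0–1000 utility-index scale) with one planted spatially smooth
eigenvector in the neighborhood effects, then runs the model sequence. It
prints:

```
Variables                    Null      Level-1     Level-2     Spatially filtered
---------------------------------------------------------------------------------
female                       -         -41.18***   -41.33***   -41.92***
income                       -         0.08837***  0.08949***  0.08964***
unemployed                   -         -137***     -137.3***   -138.6***
low_stress                   -         145.7***    146.3***    144.5***
deprivation                  -         -           -18.6*      -14.9*
doctors_per_1000             -         -           11.5**      9.401**
lgfi                         -         -           0.3719      0.4286
e_2                          -         -           -           244.2***
e_1                          -         -           -           -124.5**
Variance (individual)        1.19e+05  5.284e+04   5.287e+04   5.274e+04
Variance (slope)             -         0.003667    0.003581    0.003652
Variance (neighborhood)      9050      1996        958.8       5.277e-06
Constant                     985***    852.3***    810.3***    811.8***
Eigenvector selection        -         -           -           2 eigenvectors
Moran's I of nbhd residuals  -         -           0.317***    -0.020
AIC                          37278.4   35332.2     35320.0     35295.3
Log-likelihood               -18636.2  -17658.1    -17649.0    -17634.6

ICC (null model): 0.071
Selected eigenvectors (2): e_2, e_1; |z| path ['1.437', '0.070']; converged=True
```

Reading the table: individual covariates explain most of the variance at both
levels (Level-1 vs null); the Level-2 residuals are spatially dependent
(Moran's I = 0.317, starred significant); filtering selects two eigenvectors,
drops the residual Moran's I to −0.020 (|z| below the 0.1 threshold), lowers
the AIC by ~25, and leaves the covariate estimates essentially unchanged —
the signature of spatial dependency that was confounding the random part but
not the fixed part.

The other examples cover weights + Moran's I basics (`01`), the eigenvector
basis itself (`02`), and bias recovery under a spatially confounded covariate
(`04`).

## Command line

```
spfmlm simulate --config sim.yaml --out data/
spfmlm fit --individuals data/individuals.csv --neighborhoods data/neighborhoods.csv \
           --weights data/weights.gal --config model.yaml --out results/
spfmlm report --in results/
```

Weights can come from a GAL neighbor list, an edge-list CSV (`src,dst`), or a
GeoJSON FeatureCollection (Queen contiguity derived from the polygons, with
`--id-field` naming the area-id property).

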