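"""The full spatially filtered multilevel model on synthetic survey data.

Simulates a two-level health-survey-like dataset on an 8x8 Queen lattice with
a spatially structured neighborhood effect (one planted Moran eigenvector),
runs the model sequence null -> Level-1 -> Level-2 -> eigenvector filtering,
and prints the comparison table.
"""

import spfmlm as sf

weights = sf.make_lattice_weights(8, 8, "queen")
coef = sf.eigen_coefficient(var_intercept=1062.0, n_areas=64, fraction=0.8)
config = sf.SyntheticConfig(
    rows=8,
    cols=8,
    n_per_area=40,
    spatial_signal={"kind": "eigenvector", "indices": [1], "coefficients": [coef]},
    seed=13,
)
data, truth = sf.simulate(config, weights)
print(f"simulated {data.n_individuals} individuals in {data.n_areas} neighborhoods")

pipeline_config = sf.PipelineConfig(
    fixed_individual=("female", "income", "unemployed", "low_stress"),
    fixed_neighborhood=("deprivation", "doctors_per_1000", "lgfi"),
    random_slope="income",
    threshold=0.1,
    seed=13,
)
report = sf.run_pipeline(data, weights, pipeline_config)
print()
print(report.to_text())
print(
    "The Moran's I row shows the spatial dependency of the neighborhood-level"
    "\nresiduals before and after filtering; the selected eigenvectors absorb the"
    "\nplanted spatial signal, the |z| falls below the 0.1 threshold, and the"
    "\nfiltered model's AIC improves on the conventional Level-2 model while the"
    "\ncovariate estimates barely move."
)
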