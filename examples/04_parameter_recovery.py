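"""Bias of conventional vs filtered fits when spatial signal confounds a covariate.

The planted neighborhood effect shares a Moran eigenvector with the
deprivation covariate, so the conventional multilevel model attributes part
of the spatial signal to deprivation.  The recovery experiment measures the
per-parameter bias and RMSE of both models over simulated replicates.
"""

import spfmlm as sf

config = sf.SyntheticConfig(
    rows=6,
    cols=6,
    n_per_area=40,
    spatial_signal={
        "kind": "eigenvector",
        "indices": [1],
        "coefficients": [sf.eigen_coefficient(1062.0, 36, 0.8)],
    },
    nbh_spatial={"deprivation": {"indices": [1], "coefficients": [4.0]}},
    seed=0,
)
table = sf.recovery_experiment(config, n_replicates=10)

cols = ["model", "parameter", "truth", "bias", "rmse"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:9.3f}"))
print(f"\nresidual-Moran pass rate (|z| < 0.1 after filtering): "
      f"{table.attrs['residual_moran_pass_rate']:.0%}")
print(f"filtered AIC better than conventional: {table.attrs['aic_improved_rate']:.0%}")
print(
    "\nFor the confounded 'deprivation' coefficient the filtered model's bias is"
    "\nsmaller in absolute value than the conventional model's; unconfounded"
    "\nparameters are recovered by both models."
)
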