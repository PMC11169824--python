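"""Compute the 20-index vegetation-index catalog and its stagewise
correlations with agronomic traits.

The indices come from plot-level 5-band reflectance (blue, green, red,
red edge, NIR) at four flights (Feekes 6/8/10/11). Correlations with grain
yield vary by growth stage because the generator links canopy vigor to
yield with stage-dependent strength.
"""

import phenogs as pg
from phenogs.spectral import INDEX_REGISTRY, compute_vi_table, stagewise_trait_correlations

bundle = pg.simulate_bundle(pg.SimConfig(n_lines=162, n_markers=500, seed=1))
vi = compute_vi_table(bundle.reflectance)

print("catalog:", ", ".join(INDEX_REGISTRY))
print("\nNDVI formula:", INDEX_REGISTRY["NDVI"].formula)

corr = stagewise_trait_correlations(vi, bundle.pheno[["plot_id", "GY", "TW", "GPC"]])
ndvi_gy = corr[(corr["index"] == "NDVI") & (corr["trait"] == "GY")]
print("\nNDVI-GY correlation by flight (strongest mid-season, as in wheat canopies):")
print(ndvi_gy[["stage", "r", "n"]].to_string(index=False))
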