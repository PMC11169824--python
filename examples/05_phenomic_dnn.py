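"""Phenomic prediction of grain yield with the feedforward network, and
forward prediction into a preliminary nursery.

Features are the 20 vegetation indices at each of 4 flights (80 columns);
the network is trained on a random 70% of plots and scored on the rest
(R2, RMSE with n-1 denominator, relative RMSE), then retrained on all
advanced-trial plots to predict preliminary-trial plots it never saw.
"""

import phenogs as pg
from phenogs.phenomic import DNNConfig, forward_predict, train_predict
from phenogs.spectral import build_feature_matrix, compute_vi_table

adv = pg.simdata.line_names(162)
pyt = pg.simdata.line_names(200, prefix="P")
cfg = pg.SimConfig(
    n_lines=162, n_markers=500, n_locations=2,
    designs=(
        pg.TrialDesign("ELITE", tuple(adv[:36]), "rcbd", n_reps=3),
        pg.TrialDesign("AYT", tuple(adv[36:]), "rcbd", n_reps=2),
        pg.TrialDesign("PYT", tuple(pyt), "augmented", n_blocks=8, checks=tuple(adv[:7])),
    ),
    seed=5,
)
bundle = pg.simulate_bundle(cfg)
vi = compute_vi_table(bundle.reflectance)
ph = bundle.pheno
advanced = ph["trial"].isin(["ELITE", "AYT"])

net = DNNConfig(hidden_sizes=(64, 128), dropout=0.1, epochs=80, seed=5)

fm = build_feature_matrix(vi, ph[advanced], targets=("GY",))
_, metrics = train_predict(fm, "GY", net)
print("held-out 30% of advanced plots:", metrics)

fm_test = build_feature_matrix(vi, ph[(ph.trial == "PYT") & (ph.location == "LOC1")],
                               targets=("GY",))
for label, mask in (("single-location", advanced & (ph.location == "LOC1")),
                    ("two-location", advanced)):
    fm_train = build_feature_matrix(vi, ph[mask], targets=("GY",))
    fwd = forward_predict(fm_train, fm_test, "GY", net)
    print(f"forward R2 into PYT, {label} training: {fwd.r2:.3f} (n={fwd.n})")
# Two-location training generally generalizes better to the unseen
# nursery: more plots, and the site-to-site variation it spans is partly
# visible in the canopy features.
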