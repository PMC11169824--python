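import numpy as np
import pandas as pd
import pytest

import phenogs as pg


@pytest.fixture(scope="session")
def small_bundle():
    """One small synthetic trial suite shared across read-only tests:
    50 lines, 200 markers, 2 locations, RCBD."""
    cfg = pg.SimConfig(n_lines=50, n_markers=200, seed=11)
    return pg.simulate_bundle(cfg)


@pytest.fixture(scope="session")
def gs_dataset():
    """Simulated two-trait line-level dataset for GBLUP tests:
    n=150 lines, p=600 markers, h2 = 0.5/0.6, r_g = 0.6."""
    C = np.array([[1.0, 0.6], [0.6, 1.0]])
    geno = pg.simulate_genotypes(150, 600, seed=21)
    truth = pg.simulate_genetic_values(
        geno, {"P": 0.5, "S": 0.6}, C, seed=22, trait_names=("P", "S")
    )
    bv = truth.breeding_values.to_numpy()
    rng = np.random.default_rng(23)
    Y = bv + rng.normal(0.0, np.sqrt([0.5, 0.4]), bv.shape)
    grm = pg.compute_grm(geno)
    return {"geno": geno, "truth": truth, "Y": Y, "grm": grm}


def rcbd_config(n_lines, n_reps, h2=0.5, seed=0, n_markers=300, **kw):
    """One single-location RCBD trial config."""
    lines = pg.simdata.line_names(n_lines)
    return pg.SimConfig(
        n_lines=n_lines,
        n_markers=n_markers,
        h2={"GY": h2, "TW": h2, "GPC": h2},
        n_locations=1,
        designs=(pg.TrialDesign("T", tuple(lines), "rcbd", n_reps=n_reps),),
        seed=seed,
        **kw,
    )
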