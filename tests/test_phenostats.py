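"""BLUEs, REML variance components and heritability."""

import warnings

import numpy as np
import pandas as pd
import pytest

import phenogs as pg
from conftest import rcbd_config
from phenogs.phenostats import (
    estimate_heritability,
    fit_blues,
    heritability_from_components,
    trait_correlation_matrix,
)


def _rcbd_table(line_effects, rep_effects, resid=None):
    """Deterministic balanced RCBD table from given effects."""
    rows = []
    k = 0
    for r, re in enumerate(rep_effects, start=1):
        for ln, ge in line_effects.items():
            k += 1
            e = 0.0 if resid is None else resid[k - 1]
            rows.append({"location": "LOC1", "trial": "T", "block": r, "replicate": r,
                         "line": ln, "plot_id": f"P{k}", "GY": 10.0 + re + ge + e})
    return pd.DataFrame(rows)


class TestBlues:
    def test_noise_free_blues_equal_plot_means(self):
        tbl = _rcbd_table({"A": 1.0, "B": -1.0, "C": 0.5}, [0.0, 0.0])
        blues = fit_blues(tbl, "GY").set_index("line")["blue"]
        means = tbl.groupby("line")["GY"].mean()
        assert np.allclose(blues.loc[means.index], means, atol=1e-6)

    def test_balanced_replicate_effects_cancel(self):
        """With replicate effects +c/-c in a complete design, BLUEs equal
        raw line means."""
        rng = np.random.default_rng(3)
        effs = dict(zip("ABCDEFGH", rng.normal(size=8)))
        tbl = _rcbd_table(effs, [0.7, -0.7], resid=rng.normal(0, 0.1, 16))
        blues = fit_blues(tbl, "GY").set_index("line")["blue"]
        means = tbl.groupby("line")["GY"].mean()
        assert np.allclose(blues.loc[means.index], means, atol=1e-6)

    def test_missing_trait_rejected(self):
        tbl = _rcbd_table({"A": 0, "B": 1}, [0, 0])
        with pytest.raises(KeyError):
            fit_blues(tbl, "YIELD")

    def test_blues_track_breeding_values(self):
        cfg = rcbd_config(200, 3, h2=0.7, seed=13, gxl_sd=0.0)
        b = pg.simulate_bundle(cfg)
        blues = fit_blues(b.pheno, "GY").set_index("line")["blue"]
        bv = b.truth.breeding_values["GY"]
        r = np.corrcoef(blues.loc[bv.index], bv)[0, 1]
        assert r >= 0.8

    def test_multi_location_average_and_pooled_agree_roughly(self):
        cfg = pg.SimConfig(n_lines=40, n_markers=60, seed=17)
        b = pg.simulate_bundle(cfg)
        avg = fit_blues(b.pheno, "GY", combine="average").set_index("line")["blue"]
        pooled = fit_blues(b.pheno, "GY", combine="pooled").set_index("line")["blue"]
        assert np.corrcoef(avg, pooled.loc[avg.index])[0, 1] > 0.98


class TestHeritability:
    @pytest.mark.parametrize(
        "sg, se, nrep, expected",
        [(1.0, 1.0, 2, 2 / 3), (1.0, 0.0, 3, 1.0), (0.0, 1.0, 2, 0.0), (2.0, 1.0, 1, 2 / 3)],
    )
    def test_formula(self, sg, se, nrep, expected):
        assert heritability_from_components(sg, se, nrep) == pytest.approx(expected)

    def test_monotone_in_replicates(self):
        vals = [heritability_from_components(1.0, 2.0, r) for r in (1, 2, 3, 5)]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert all(0 <= v <= 1 for v in vals)

    def test_reml_matches_statsmodels(self):
        """Independent oracle: the one-random-effect REML fit agrees with
        statsmodels MixedLM on the same data."""
        import statsmodels.formula.api as smf

        cfg = rcbd_config(60, 3, h2=0.5, seed=19)
        b = pg.simulate_bundle(cfg)
        ours = estimate_heritability(b.pheno, "GY")
        md = smf.mixedlm("GY ~ C(block)", b.pheno, groups=b.pheno["line"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = md.fit(reml=True)
        assert ours.sigma2_g == pytest.approx(float(fit.cov_re.iloc[0, 0]), rel=0.02)
        assert ours.sigma2_e == pytest.approx(float(fit.scale), rel=0.02)

    def test_single_replicate_flagged(self):
        cfg = rcbd_config(30, 1, seed=23)
        b = pg.simulate_bundle(cfg)
        with pytest.warns(UserWarning):
            vc = estimate_heritability(b.pheno, "GY")
        assert not vc.reliable

    def test_estimates_tighten_with_more_lines(self):
        """REML consistency: spread of H2 estimates shrinks from n=50 to
        n=500 lines."""

        def spread(n_lines, seeds):
            ests = [
                estimate_heritability(
                    pg.simulate_bundle(rcbd_config(n_lines, 2, h2=0.5, seed=s, n_markers=100)).pheno,
                    "GY",
                ).H2
                for s in seeds
            ]
            return np.mean(np.abs(np.array(ests) - 0.5))

        assert spread(500, range(6)) < spread(50, range(6))


class TestTraitCorrelations:
    def test_identities_and_zero_variance_flag(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        df = pd.DataFrame({"A": x, "B": -x, "FLAT": np.ones(50)})
        with pytest.warns(UserWarning):
            corr = trait_correlation_matrix(df)
        assert corr.loc["A", "A"] == pytest.approx(1.0)
        assert corr.loc["A", "B"] == pytest.approx(-1.0)
        assert np.isnan(corr.loc["A", "FLAT"])

    def test_independent_traits_uncorrelated(self):
        cfg = rcbd_config(200, 3, h2=0.7, seed=29, genetic_corr=np.eye(3))
        b = pg.simulate_bundle(cfg)
        blues = pg.phenostats.blues_wide(b.pheno, ("GY", "TW"))
        corr = trait_correlation_matrix(blues)
        assert abs(corr.loc["GY", "TW"]) < 0.15

    def test_planted_genetic_correlation_recovered(self):
        """BLUE correlations estimate r_g attenuated by entry-mean
        reliability, so high-heritability traits are required to land near
        the planted value."""
        C = np.eye(3)
        C[0, 1] = C[1, 0] = 0.8
        ests = []
        for seed in (31, 32, 33):
            cfg = rcbd_config(200, 3, h2=0.9, seed=seed, genetic_corr=C, gxl_sd=0.0)
            b = pg.simulate_bundle(cfg)
            blues = pg.phenostats.blues_wide(b.pheno, ("GY", "TW"))
            ests.append(trait_correlation_matrix(blues).loc["GY", "TW"])
        assert np.mean(ests) == pytest.approx(0.8, abs=0.15)
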