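"""Synthetic-data generator: genotypes, genetic values, field designs,
reflectance, and on-disk bundles."""

import hashlib

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import phenogs as pg
from conftest import rcbd_config


class TestGenotypes:
    def test_shape_matches_configuration(self):
        g = pg.simulate_genotypes(162, 10009, (0.05, 0.5), seed=1)
        assert g.dosages.shape == (162, 10009)
        assert g.markers["id"].is_unique

    def test_dosage_support(self):
        g = pg.simulate_genotypes(2, 1, (0.5, 0.5), seed=99)
        assert set(np.unique(g.dosages)) <= {0.0, 1.0, 2.0}

    def test_deterministic_given_seed(self):
        a = pg.simulate_genotypes(30, 50, seed=4)
        b = pg.simulate_genotypes(30, 50, seed=4)
        c = pg.simulate_genotypes(30, 50, seed=5)
        assert np.array_equal(a.dosages, b.dosages)
        assert not np.array_equal(a.dosages, c.dosages)

    def test_invalid_maf_range_rejected(self):
        with pytest.raises(ValueError):
            pg.simulate_genotypes(10, 10, (0.0, 0.6), seed=1)

    def test_empirical_maf_uniform(self):
        g = pg.simulate_genotypes(500, 2000, (0.05, 0.5), seed=7)
        ks = stats.kstest(g.maf(), stats.uniform(loc=0.05, scale=0.45).cdf)
        assert ks.pvalue > 0.01


class TestGeneticValues:
    def test_identity_correlation_recovery(self):
        offs = []
        for seed in range(20):
            g = pg.simulate_genotypes(500, 2000, seed=seed)
            tv = pg.simulate_genetic_values(g, 0.5, np.eye(3), seed=seed + 100)
            C = tv.realized_genetic_corr
            offs.append(C[np.triu_indices(3, 1)])
        assert np.all(np.abs(np.mean(offs, axis=0)) < 0.1)

    def test_planted_correlation_recovery(self):
        C = np.eye(3)
        C[0, 1] = C[1, 0] = 0.8
        ests = []
        for seed in range(20):
            g = pg.simulate_genotypes(500, 2000, seed=seed)
            tv = pg.simulate_genetic_values(g, 0.5, C, seed=seed + 100)
            ests.append(tv.realized_genetic_corr[0, 1])
        assert np.mean(ests) == pytest.approx(0.8, abs=0.1)

    def test_breeding_values_are_additive_in_markers(self):
        g = pg.simulate_genotypes(60, 100, seed=3)
        tv = pg.simulate_genetic_values(g, 0.5, np.eye(3), seed=4)
        Xc = g.dosages - g.dosages.mean(axis=0)
        assert np.allclose(tv.breeding_values.to_numpy(), Xc @ tv.marker_effects)

    def test_non_psd_correlation_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        g = pg.simulate_genotypes(10, 20, seed=1)
        with pytest.raises(ValueError):
            pg.simulate_genetic_values(g, 0.5, bad, seed=1, trait_names=("A", "B"))


class TestFieldTrial:
    def test_rcbd_plot_count(self):
        """An RCBD trial of 36 lines and 3 replicates yields 108 plots."""
        cfg = rcbd_config(36, 3, seed=2)
        b = pg.simulate_bundle(cfg)
        assert len(b.pheno) == 108

    def test_rcbd_design_integrity(self, small_bundle):
        ph = small_bundle.pheno
        counts = ph.groupby(["location", "trial", "replicate"])["line"].nunique()
        per_rep = ph.groupby(["location", "trial", "replicate", "line"]).size()
        assert (per_rep == 1).all()
        for (_, trial, _), n in counts.items():
            design = next(d for d in small_bundle.config.designs if d.name == trial)
            assert n == len(design.lines)

    def test_augmented_checks_in_every_block(self):
        lines = pg.simdata.line_names(100, prefix="P")
        checks = ("C1", "C2", "C3")
        cfg = pg.SimConfig(
            n_lines=100, n_markers=50, n_locations=1,
            designs=(pg.TrialDesign("PYT", tuple(lines), "augmented", n_blocks=5, checks=checks),),
            seed=3,
        )
        b = pg.simulate_bundle(cfg)
        ph = b.pheno
        assert len(ph) == 100 + 5 * 3
        for blk, grp in ph.groupby("block"):
            assert set(checks) <= set(grp["line"])
        test_lines = ph[~ph["line"].isin(checks)]
        assert (test_lines.groupby("line").size() == 1).all()

    def test_augmented_without_checks_rejected(self):
        with pytest.raises(ValueError):
            pg.TrialDesign("PYT", ("A", "B"), "augmented", n_blocks=2, checks=())

    def test_noise_free_plots_equal_breeding_values(self):
        cfg = rcbd_config(20, 1, h2=1.0, seed=5, rep_effect_sd=0.0,
                          loc_effect_sd=0.0, gxl_sd=0.0)
        b = pg.simulate_bundle(cfg)
        ph = pg.simulate_field_trial(b.truth, cfg, in_field_units=False)
        got = ph.set_index("line")["GY"]
        want = b.truth.breeding_values["GY"]
        assert np.allclose(got.loc[want.index], want)

    def test_heritability_recoverable(self):
        """Entry-mean H2 estimated from simulated tables averages near the
        target (reduced-seed version; the 50-seed run lives in the
        acceptance suite)."""
        ests = []
        for seed in range(12):
            cfg = rcbd_config(200, 2, h2=0.5, seed=seed)
            b = pg.simulate_bundle(cfg)
            ests.append(pg.estimate_heritability(b.pheno, "GY").H2)
        assert np.mean(ests) == pytest.approx(0.5, abs=0.1)


class TestReflectance:
    def test_noiseless_unit_loading_orders_with_yield(self):
        cfg = rcbd_config(500, 1, seed=1, reflectance_noise_sd=0.0,
                          vigor_loadings={s: 1.0 for s in pg.spectral.STAGES})
        b = pg.simulate_bundle(cfg)
        vi = pg.compute_vi_table(b.reflectance)
        sub = vi[vi.stage == "F11"].set_index("plot_id")
        lines = b.pheno.set_index("plot_id")["line"]
        bv = b.truth.breeding_values["GY"].loc[lines.loc[sub.index]].to_numpy()
        assert stats.spearmanr(sub["NDVI"], bv).statistic == pytest.approx(1.0)
        assert np.corrcoef(sub["NDVI"], bv)[0, 1] >= 0.99

    def test_bands_bounded(self, small_bundle):
        refl = small_bundle.reflectance
        for band in pg.spectral.BANDS:
            assert refl[band].between(0, 1).all()

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            rcbd_config(10, 1, reflectance_noise_sd=-0.1)


class TestDatasetBundle:
    def test_byte_identical_reruns(self, tmp_path):
        cfg = rcbd_config(20, 2, seed=8, n_markers=40)
        a = pg.simulate_dataset(cfg, tmp_path / "a")
        b = pg.simulate_dataset(cfg, tmp_path / "b")
        assert a["checksums"] == b["checksums"]

    def test_seed_changes_genotypes(self, tmp_path):
        a = pg.simulate_dataset(rcbd_config(20, 2, seed=8, n_markers=40), tmp_path / "a")
        c = pg.simulate_dataset(rcbd_config(20, 2, seed=9, n_markers=40), tmp_path / "c")
        assert a["checksums"]["genotypes"] != c["checksums"]["genotypes"]

    def test_breeding_program_layout(self):
        adv, pyt = pg.breeding_program_config(seed=1)
        assert adv.n_locations == 2
        assert sum(len(d.lines) for d in adv.designs) == 162
        (pyt_design,) = pyt.designs
        assert pyt_design.n_blocks == 22
        assert len(pyt_design.lines) == 590
        assert len(pyt_design.checks) == 7
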