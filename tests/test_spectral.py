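"""Vegetation-index formulas, zonal statistics and feature assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phenogs as pg
from phenogs.spectral import (
    BANDS,
    INDEX_NAMES,
    INDEX_REGISTRY,
    build_feature_matrix,
    compute_index,
    compute_vi_table,
    stagewise_trait_correlations,
    zonal_mean,
)

BAND5 = {"blue": 0.05, "green": 0.1, "red": 0.1, "red_edge": 0.3, "nir": 0.5}

reflectance = st.floats(min_value=0.01, max_value=1.0, allow_nan=False)


def test_catalog_has_twenty_indices_including_named_ones():
    assert len(INDEX_NAMES) == 20
    for name in ("NDVI", "GNDVI", "GCI", "RVI_2", "ARI", "ARI_2", "PSRI",
                 "IKAW", "NDWI", "SAVI_2", "ENDVI", "EVI_2", "MCARI", "TCARI_OSAVI"):
        assert name in INDEX_REGISTRY


@pytest.mark.parametrize(
    "bands, name, expected",
    [
        (dict(BAND5, nir=0.5, red=0.1), "NDVI", (0.5 - 0.1) / (0.5 + 0.1)),
        (dict(BAND5, nir=0.3, red=0.3), "NDVI", 0.0),
        (dict(BAND5, nir=0.5, green=0.1), "GCI", 4.0),
        (dict(BAND5, nir=0.5, green=0.1), "RVI_2", 5.0),
        (dict(BAND5, green=0.2, nir=0.6), "NDWI", (0.2 - 0.6) / (0.2 + 0.6)),
        (dict(BAND5, green=0.25, red_edge=0.5), "ARI", 1 / 0.25 - 1 / 0.5),
    ],
)
def test_hand_computed_index_values(bands, name, expected):
    assert compute_index(bands, name) == pytest.approx(expected, abs=1e-10)


def test_unknown_index_and_invalid_bands_rejected():
    with pytest.raises(KeyError):
        compute_index(BAND5, "NOPE")
    with pytest.raises(ValueError):
        compute_index(dict(BAND5, nir=1.5), "NDVI")


def test_near_zero_denominator_flags_missing():
    assert np.isnan(compute_index(dict(BAND5, nir=0.0, red=0.0), "NDVI"))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(nir=reflectance, red=reflectance)
def test_normalized_difference_bounded_and_antisymmetric(nir, red):
    v = compute_index(dict(BAND5, nir=nir, red=red), "NDVI")
    assert -1.0 <= v <= 1.0
    swapped = compute_index(dict(BAND5, nir=red, red=nir), "NDVI")
    assert swapped == pytest.approx(-v, abs=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(scale=st.floats(min_value=0.1, max_value=1.0), green=reflectance, nir=reflectance)
def test_ratio_indices_scale_invariant(scale, green, nir):
    """Ratio-type indices are invariant to multiplying all bands by c > 0."""
    b1 = dict(BAND5, green=green, nir=nir)
    b2 = {k: v * scale for k, v in b1.items()}
    for name in ("GCI", "RVI", "RVI_2"):
        assert compute_index(b2, name) == pytest.approx(compute_index(b1, name), rel=1e-9)


def test_zonal_mean_matches_brute_force():
    rng = np.random.default_rng(5)
    grid = rng.uniform(0, 1, (5, 8, 6))
    mask = rng.integers(0, 4, (8, 6))
    out = zonal_mean(grid, mask)
    for plot in out.index:
        cells = mask == plot
        for i, band in enumerate(BANDS):
            assert out.loc[plot, band] == pytest.approx(grid[i][cells].mean())


def test_zonal_mean_small_cases():
    grid = np.array([[0.1, 0.2], [0.3, 0.4]])
    assert zonal_mean(grid, np.ones((2, 2), int))["value"].iloc[0] == pytest.approx(0.25)
    mask = np.array([[1, 0], [0, 0]])
    assert zonal_mean(grid, mask)["value"].iloc[0] == pytest.approx(0.1)
    const = np.full((3, 3), 0.7)
    assert zonal_mean(const, np.ones((3, 3), int))["value"].iloc[0] == pytest.approx(0.7)
    with pytest.raises(ValueError):
        zonal_mean(grid, np.zeros((2, 2), int))  # no labels
    with pytest.raises(ValueError):
        zonal_mean(grid, np.ones((3, 3), int))  # shape mismatch


def test_feature_matrix_column_counts(small_bundle):
    vi = compute_vi_table(small_bundle.reflectance)
    fm = build_feature_matrix(vi, small_bundle.pheno)
    assert len(fm.attrs["feature_columns"]) == 20 * 4
    fm1 = build_feature_matrix(vi, small_bundle.pheno, stages=["F11"])
    assert len(fm1.attrs["feature_columns"]) == 20
    with pytest.raises(ValueError):
        build_feature_matrix(vi, small_bundle.pheno, stages=[])
    other = small_bundle.pheno.copy()
    other["plot_id"] = "X" + other["plot_id"]
    with pytest.raises(ValueError):
        build_feature_matrix(vi, other)


def test_stagewise_correlation_identities():
    rng = np.random.default_rng(1)
    n = 40
    vals = rng.normal(size=n)
    vi = pd.DataFrame({"plot_id": [f"P{i}" for i in range(n)], "stage": "F8", "IDX": vals})
    traits = pd.DataFrame({
        "plot_id": [f"P{i}" for i in range(n)],
        "SAME": vals, "NEG": -vals, "FLAT": np.ones(n),
    })
    out = stagewise_trait_correlations(vi, traits).set_index("trait")["r"]
    assert out["SAME"] == pytest.approx(1.0)
    assert out["NEG"] == pytest.approx(-1.0)
    assert np.isnan(out["FLAT"])


def test_zero_loading_stage_uncorrelated():
    """A flight whose vigor loading is zero carries no yield signal."""
    from conftest import rcbd_config

    cfg = rcbd_config(
        500, 1, seed=7,
        vigor_loadings={"F6": 0.0, "F8": 0.8, "F10": 0.8, "F11": 0.6},
        reflectance_noise_sd=0.5,
    )
    b = pg.simulate_bundle(cfg)
    vi = compute_vi_table(b.reflectance)
    lines = b.pheno.set_index("plot_id")["line"]
    traits = pd.DataFrame({
        "plot_id": b.pheno["plot_id"],
        "GYBV": b.truth.breeding_values["GY"].loc[lines].to_numpy(),
    })
    out = stagewise_trait_correlations(vi, traits)
    r_f6 = out[(out.stage == "F6") & (out["index"] == "NDVI")]["r"].iloc[0]
    r_f8 = out[(out.stage == "F8") & (out["index"] == "NDVI")]["r"].iloc[0]
    assert abs(r_f6) < 0.1
    assert r_f8 > 0.5
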