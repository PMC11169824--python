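"""Vegetation-index computation from 5-band canopy reflectance.

Plot-level mean reflectance in the five Altum-PT bands (blue, green, red,
red_edge, nir) is turned into a catalog of 20 vegetation indices (VIs), per
flight / growth stage, and assembled into plot x (index, stage) feature
matrices for downstream phenomic and multi-trait genomic models.

Each registry entry carries the literature formula actually computed; the
registry is a plain dict and can be extended or overridden by users
(``INDEX_REGISTRY["MYVI"] = IndexDef(...)``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Band order of the MicaSense Altum-PT multispectral sensor.
BANDS = ("blue", "green", "red", "red_edge", "nir")

#: Growth-stage codes for the four flights (Feekes scale).
STAGES = ("F6", "F8", "F10", "F11")

STAGE_LABELS = {
    "F6": "Feekes 6 (jointing)",
    "F8": "Feekes 8 (flag leaf)",
    "F10": "Feekes 10 (booting)",
    "F11": "Feekes 11 (milky ripe)",
}

#: Denominators smaller than this (absolute value) flag the index as missing.
DIVISION_EPS = 1e-9


def _safe_div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = np.abs(den) >= DIVISION_EPS
    np.divide(num, den, out=out, where=ok)
    return out


@dataclass(frozen=True)
class IndexDef:
    """One vegetation index: formula, algebraic kind, and citation."""

    name: str
    func: Callable[..., np.ndarray]
    #: "normalized_difference" (bounded in [-1, 1], antisymmetric),
    #: "ratio" (invariant to scaling all bands), or "other".
    kind: str
    formula: str
    citation: str


def _nd(a, b):
    """Normalized difference (a - b)/(a + b)."""
    return _safe_div(a - b, a + b)


_R = {}  # populated below; module-level INDEX_REGISTRY aliases it


def _register(name, kind, formula, citation):
    def deco(func):
        _R[name] = IndexDef(name, func, kind, formula, citation)
        return func

    return deco


@_register("NDVI", "normalized_difference", "(NIR - Red)/(NIR + Red)", "Rouse et al. 1974")
def _ndvi(blue, green, red, red_edge, nir):
    return _nd(nir, red)


@_register("GNDVI", "normalized_difference", "(NIR - Green)/(NIR + Green)", "Gitelson et al. 1996")
def _gndvi(blue, green, red, red_edge, nir):
    return _nd(nir, green)


@_register("NDRE", "normalized_difference", "(NIR - RedEdge)/(NIR + RedEdge)", "Barnes et al. 2000")
def _ndre(blue, green, red, red_edge, nir):
    return _nd(nir, red_edge)


@_register("GCI", "ratio", "NIR/Green - 1", "Gitelson et al. 2003")
def _gci(blue, green, red, red_edge, nir):
    return _safe_div(nir, green) - 1.0


@_register("RVI", "ratio", "NIR/Red", "Jordan 1969")
def _rvi(blue, green, red, red_edge, nir):
    return _safe_div(nir, red)


@_register("RVI_2", "ratio", "NIR/Green", "Sripada et al. 2006")
def _rvi2(blue, green, red, red_edge, nir):
    return _safe_div(nir, green)


@_register("ARI", "other", "1/Green - 1/RedEdge", "Gitelson et al. 2001")
def _ari(blue, green, red, red_edge, nir):
    return _safe_div(1.0, green) - _safe_div(1.0, red_edge)


@_register("ARI_2", "other", "NIR * (1/Green - 1/RedEdge)", "Gitelson et al. 2001")
def _ari2(blue, green, red, red_edge, nir):
    return nir * (_safe_div(1.0, green) - _safe_div(1.0, red_edge))


@_register("PSRI", "other", "(Red - Green)/RedEdge", "Merzlyak et al. 1999")
def _psri(blue, green, red, red_edge, nir):
    return _safe_div(red - green, red_edge)


@_register("IKAW", "normalized_difference", "(Red - Blue)/(Red + Blue)", "Kawashima & Nakatani 1998")
def _ikaw(blue, green, red, red_edge, nir):
    return _nd(red, blue)


@_register("NDWI", "normalized_difference", "(Green - NIR)/(Green + NIR)", "McFeeters 1996")
def _ndwi(blue, green, red, red_edge, nir):
    return _nd(green, nir)


@_register("SAVI", "other", "1.5*(NIR - Red)/(NIR + Red + 0.5)", "Huete 1988")
def _savi(blue, green, red, red_edge, nir):
    return 1.5 * _safe_div(nir - red, nir + red + 0.5)


@_register("SAVI_2", "other", "NIR/(Red + 0.5)", "Major et al. 1990")
def _savi2(blue, green, red, red_edge, nir):
    return _safe_div(nir, red + 0.5)


@_register("ENDVI", "other", "((NIR + Green) - 2*Blue)/((NIR + Green) + 2*Blue)", "MaxMax 2015")
def _endvi(blue, green, red, red_edge, nir):
    return _safe_div((nir + green) - 2.0 * blue, (nir + green) + 2.0 * blue)


@_register("EVI", "other", "2.5*(NIR - Red)/(NIR + 6*Red - 7.5*Blue + 1)", "Huete et al. 2002")
def _evi(blue, green, red, red_edge, nir):
    return 2.5 * _safe_div(nir - red, nir + 6.0 * red - 7.5 * blue + 1.0)


@_register("EVI_2", "other", "2.5*(NIR - Red)/(NIR + 2.4*Red + 1)", "Jiang et al. 2008")
def _evi2(blue, green, red, red_edge, nir):
    return 2.5 * _safe_div(nir - red, nir + 2.4 * red + 1.0)


@_register("MCARI", "other", "((RedEdge - Red) - 0.2*(RedEdge - Green))*(RedEdge/Red)", "Daughtry et al. 2000")
def _mcari(blue, green, red, red_edge, nir):
    return ((red_edge - red) - 0.2 * (red_edge - green)) * _safe_div(red_edge, red)


@_register("TCARI", "other", "3*((RedEdge - Red) - 0.2*(RedEdge - Green)*(RedEdge/Red))", "Haboudane et al. 2002")
def _tcari(blue, green, red, red_edge, nir):
    return 3.0 * ((red_edge - red) - 0.2 * (red_edge - green) * _safe_div(red_edge, red))


@_register("OSAVI", "other", "1.16*(NIR - Red)/(NIR + Red + 0.16)", "Rondeaux et al. 1996")
def _osavi(blue, green, red, red_edge, nir):
    return 1.16 * _safe_div(nir - red, nir + red + 0.16)


@_register("TCARI_OSAVI", "other", "TCARI/OSAVI", "Haboudane et al. 2002")
def _tcari_osavi(blue, green, red, red_edge, nir):
    return _safe_div(_tcari(blue, green, red, red_edge, nir), _osavi(blue, green, red, red_edge, nir))


#: The 20-index catalog, name -> :class:`IndexDef`.
INDEX_REGISTRY: dict[str, IndexDef] = _R

INDEX_NAMES = tuple(INDEX_REGISTRY)
assert len(INDEX_NAMES) == 20


def compute_index(bands: Mapping[str, float] | Sequence[float], name: str) -> float | np.ndarray:
    """Compute one vegetation index from 5-band reflectance.

    Parameters
    ----------
    bands
        Mapping with keys ``blue, green, red, red_edge, nir`` or a sequence
        in that order; values may be scalars or arrays in [0, 1].
    name
        Index name from :data:`INDEX_REGISTRY`.

    Returns
    -------
    The index value; NaN where a denominator falls below ``DIVISION_EPS``.
    """
    if name not in INDEX_REGISTRY:
        raise KeyError(f"unknown vegetation index {name!r}; known: {sorted(INDEX_REGISTRY)}")
    if isinstance(bands, Mapping):
        vals = [np.asarray(bands[b], dtype=float) for b in BANDS]
    else:
        if len(bands) != 5:
            raise ValueError("expected five band values (blue, green, red, red_edge, nir)")
        vals = [np.asarray(v, dtype=float) for v in bands]
    for bname, v in zip(BANDS, vals):
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"band {bname!r} outside [0, 1]: reflectance expected")
    out = INDEX_REGISTRY[name].func(*vals)
    if out.ndim == 0:
        return float(out)
    return out


def compute_vi_table(reflectance: pd.DataFrame, indices: Iterable[str] | None = None) -> pd.DataFrame:
    """Vectorized VI table from a plot-level reflectance table.

    ``reflectance`` needs columns ``plot_id, stage`` plus the five bands.
    Returns one row per (plot_id, stage) with one column per index.
    """
    missing = [c for c in ("plot_id", "stage", *BANDS) if c not in reflectance.columns]
    if missing:
        raise ValueError(f"reflectance table missing columns {missing}")
    names = list(indices) if indices is not None else list(INDEX_NAMES)
    out = reflectance[["plot_id", "stage"]].copy()
    band_vals = {b: reflectance[b].to_numpy(dtype=float) for b in BANDS}
    for b, v in band_vals.items():
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"band {b!r} has values outside [0, 1]")
    for name in names:
        out[name] = compute_index([band_vals[b] for b in BANDS], name)
    return out


def zonal_mean(grid: np.ndarray, mask: np.ndarray) -> pd.DataFrame:
    """Per-plot mean reflectance from a gridded image and a plot-label mask.

    Parameters
    ----------
    grid
        Array of shape (5, H, W) with band order :data:`BANDS`, or (H, W)
        for a single band.
    mask
        Integer array of shape (H, W); positive labels are plot ids, 0 is
        background.

    Returns
    -------
    DataFrame indexed by plot id with one column per band (or ``value`` for
    single-band input).
    """
    grid = np.asarray(grid, dtype=float)
    mask = np.asarray(mask)
    single = grid.ndim == 2
    if single:
        grid = grid[None]
    if grid.ndim != 3 or grid.shape[0] not in (1, 5):
        raise ValueError("grid must be (H, W) or (5, H, W)")
    if grid.shape[1:] != mask.shape:
        raise ValueError(f"grid {grid.shape[1:]} and mask {mask.shape} shapes differ")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("mask contains no plot labels")
    cols = ["value"] if single else list(BANDS)
    data = {
        c: ndimage.mean(grid[i], labels=mask, index=labels) for i, c in enumerate(cols)
    }
    return pd.DataFrame(data, index=pd.Index(labels, name="plot_id"))


def feature_name(index: str, stage: str) -> str:
    """Unambiguous column name for an (index, stage) feature."""
    return f"{index}@{stage}"


def build_feature_matrix(
    vi: pd.DataFrame,
    pheno: pd.DataFrame,
    stages: Sequence[str] | None = None,
    targets: Sequence[str] = ("GY", "TW", "GPC"),
) -> pd.DataFrame:
    """Assemble the plot x (index, stage) feature matrix with targets.

    Rows are plots; feature columns are named ``INDEX@STAGE``; the trait
    columns in ``targets`` are carried over from ``pheno`` (joined on
    ``plot_id``). Plots missing any requested feature or target are dropped
    and the drop count logged.
    """
    stages = list(stages) if stages is not None else sorted(vi["stage"].unique())
    if not stages:
        raise ValueError("empty stage subset")
    sub = vi[vi["stage"].isin(stages)]
    index_cols = [c for c in sub.columns if c not in ("plot_id", "stage")]
    wide = sub.pivot(index="plot_id", columns="stage", values=index_cols)
    wide.columns = [feature_name(idx, st) for idx, st in wide.columns]
    # deterministic column order: stage-major within each index, catalog order
    ordered = [feature_name(i, s) for i in index_cols for s in stages if feature_name(i, s) in wide.columns]
    wide = wide[ordered]
    targets = [t for t in targets if t in pheno.columns]
    joined = wide.join(pheno.set_index("plot_id")[targets], how="inner")
    if joined.empty:
        raise ValueError("no plots shared between the VI table and the phenotype table")
    n0 = len(joined)
    joined = joined.dropna()
    if len(joined) < n0:
        logger.info("build_feature_matrix: dropped %d incomplete plots", n0 - len(joined))
    joined.attrs["feature_columns"] = ordered
    joined.attrs["target_columns"] = targets
    joined.attrs["stages"] = stages
    return joined


def stagewise_trait_correlations(vi: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every (index, stage) with every primary trait.

    ``traits`` is keyed by ``plot_id`` (plot-level values) or ``line``-level
    BLUEs with a ``plot_id`` column mapping. Returns a tidy frame with
    columns (index, stage, trait, r, n); zero-variance pairs get NaN r.
    """
    if "plot_id" not in traits.columns:
        raise ValueError("traits table needs a plot_id column to join on")
    trait_cols = [c for c in traits.columns if c != "plot_id"]
    index_cols = [c for c in vi.columns if c not in ("plot_id", "stage")]
    merged = vi.merge(traits, on="plot_id", how="inner")
    if len(merged) < 3:
        raise ValueError("need at least 3 joined records to correlate")
    rows = []
    for stage, grp in merged.groupby("stage", sort=True):
        for idx in index_cols:
            x = grp[idx].to_numpy(dtype=float)
            for tr in trait_cols:
                y = grp[tr].to_numpy(dtype=float)
                ok = np.isfinite(x) & np.isfinite(y)
                r = np.nan
                if ok.sum() >= 3 and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
                    r = float(np.corrcoef(x[ok], y[ok])[0, 1])
                rows.append({"index": idx, "stage": stage, "trait": tr, "r": r, "n": int(ok.sum())})
    return pd.DataFrame(rows)
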