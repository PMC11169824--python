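"""Plot-level phenotype analysis: BLUEs, broad-sense heritability, trait
correlations.

The workhorse is a mixed model with a single random effect::

    y = X b + Z u + e,   u ~ N(0, sigma2_u I),   e ~ N(0, sigma2_e I)

solved by profile REML on the variance ratio ``lambda = sigma2_u/sigma2_e``
(bounded scalar optimization over log-lambda) with a GLS back-solve for the
fixed effects. For line BLUEs the genotype is fixed and the replicate (or
incomplete block, in augmented trials) random; for heritability the roles
swap — genotype random, replicate fixed — and

    H2 = sigma2_g / (sigma2_g + sigma2_e / nRep)

on an entry-mean basis, with nRep the (mean) number of plots per line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar


@dataclass
class VarianceComponents:
    """REML variance components and entry-mean heritability."""

    sigma2_g: float
    sigma2_e: float
    n_rep: float
    H2: float
    reliable: bool = True  # False when estimated from a single replicate


@dataclass
class MixedFit:
    beta: np.ndarray
    se: np.ndarray
    sigma2_u: float
    sigma2_e: float
    loglik: float


def heritability_from_components(sigma2_g: float, sigma2_e: float, n_rep: float) -> float:
    """Entry-mean broad-sense heritability sg2 / (sg2 + se2/nRep)."""
    if sigma2_g < 0 or sigma2_e < 0 or n_rep <= 0:
        raise ValueError("variances must be nonnegative and n_rep positive")
    if sigma2_g == 0 and sigma2_e == 0:
        return 0.0
    return sigma2_g / (sigma2_g + sigma2_e / n_rep)


def _reml_one_random(y: np.ndarray, X: np.ndarray, Z: np.ndarray) -> MixedFit:
    """Profile REML for one random effect.

    Eigendecomposes ZZ' once; each candidate ratio costs O(n q^2) for q
    fixed effects. Negative-variance solutions are truncated at the
    lambda -> 0 boundary.
    """
    n, q = X.shape
    ZZt = Z @ Z.T
    d, Q = np.linalg.eigh(ZZt)
    d = np.maximum(d, 0.0)
    yt = Q.T @ y
    Xt = Q.T @ X

    def neg_reml(log_lam):
        lam = np.exp(log_lam)
        w = 1.0 / (1.0 + lam * d)
        XtWX = Xt.T @ (w[:, None] * Xt)
        XtWy = Xt.T @ (w * yt)
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return np.inf
        r = yt - Xt @ beta
        rss = float(r @ (w * r))
        if rss <= 0:
            return np.inf
        sign, logdet_XtWX = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        logdet_V = float(-np.sum(np.log(w)))
        return 0.5 * ((n - q) * np.log(rss) + logdet_V + logdet_XtWX)

    res = minimize_scalar(neg_reml, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    # boundary check: if the optimum hugs the lower bound, call it zero
    if res.x <= -11.5 or neg_reml(-12.0) <= res.fun + 1e-10:
        lam = 0.0
        warnings.warn("random-effect variance estimated at zero (truncated)", stacklevel=3)
    w = 1.0 / (1.0 + lam * d)
    XtWX = Xt.T @ (w[:, None] * Xt)
    beta = np.linalg.solve(XtWX, Xt.T @ (w * yt))
    r = yt - Xt @ beta
    sigma2_e = float(r @ (w * r)) / (n - q)
    sigma2_u = lam * sigma2_e
    cov = sigma2_e * np.linalg.inv(XtWX)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return MixedFit(beta=beta, se=se, sigma2_u=sigma2_u, sigma2_e=sigma2_e,
                    loglik=-float(res.fun))


def _single_location(pheno: pd.DataFrame) -> list[tuple[str, pd.DataFrame]]:
    if "location" in pheno.columns:
        return [(str(loc), grp) for loc, grp in pheno.groupby("location", sort=True)]
    return [("ALL", pheno)]


def _fit_blues_once(df: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Genotype fixed, block random, within one location (trials pooled;
    the block factor is nested in trial)."""
    df = df.dropna(subset=[trait])
    lines = pd.Index(sorted(df["line"].unique()), name="line")
    if len(lines) < 2:
        raise ValueError("need at least 2 lines")
    y = df[trait].to_numpy(dtype=float)
    X = pd.get_dummies(pd.Categorical(df["line"], categories=lines)).to_numpy(dtype=float)
    block_key = df["trial"].astype(str) + ":" + df["block"].astype(str) if "trial" in df.columns else df["block"].astype(str)
    blocks = pd.get_dummies(block_key).to_numpy(dtype=float)
    if blocks.shape[1] < 2:
        # single replicate: model degenerates to raw plot values per line
        est = df.groupby("line")[trait].mean().reindex(lines)
        return pd.DataFrame({"line": lines, "blue": est.to_numpy(), "se": np.nan})
    fit = _reml_one_random(y, X, blocks)
    return pd.DataFrame({"line": lines, "blue": fit.beta, "se": fit.se})


def fit_blues(
    pheno: pd.DataFrame, trait: str, combine: str = "average"
) -> pd.DataFrame:
    """Per-line BLUEs (mu + genotype effect) for one trait.

    With several locations, ``combine="average"`` fits each location
    separately and averages the per-line estimates; ``combine="pooled"``
    fits one model with location as an additional fixed effect.
    Returns a frame with columns ``line, blue, se``.
    """
    if trait not in pheno.columns:
        raise KeyError(f"trait {trait!r} not in phenotype table")
    groups = _single_location(pheno)
    if len(groups) == 1 or combine == "pooled":
        df = pheno.dropna(subset=[trait])
        if len(groups) > 1:
            # location as fixed effect: absorb into the design
            lines = pd.Index(sorted(df["line"].unique()), name="line")
            y = df[trait].to_numpy(dtype=float)
            Xg = pd.get_dummies(pd.Categorical(df["line"], categories=lines)).to_numpy(dtype=float)
            Xl = pd.get_dummies(df["location"], drop_first=True).to_numpy(dtype=float)
            X = np.hstack([Xg, Xl])
            key = df["location"].astype(str) + ":" + df["trial"].astype(str) + ":" + df["block"].astype(str)
            Z = pd.get_dummies(key).to_numpy(dtype=float)
            fit = _reml_one_random(y, X, Z)
            return pd.DataFrame({"line": lines, "blue": fit.beta[: len(lines)], "se": fit.se[: len(lines)]})
        return _fit_blues_once(groups[0][1], trait)
    per_loc = [_fit_blues_once(grp, trait).set_index("line") for _, grp in groups]
    merged = pd.concat(per_loc, axis=1, keys=range(len(per_loc)))
    blue = merged.xs("blue", axis=1, level=1).mean(axis=1)
    se = np.sqrt((merged.xs("se", axis=1, level=1) ** 2).mean(axis=1)) / np.sqrt(
        merged.xs("se", axis=1, level=1).notna().sum(axis=1).clip(lower=1)
    )
    out = pd.DataFrame({"line": blue.index, "blue": blue.to_numpy(), "se": se.to_numpy()})
    return out.reset_index(drop=True)


def estimate_heritability(pheno: pd.DataFrame, trait: str) -> VarianceComponents:
    """REML variance components with genotype random, replicate/block fixed,
    and entry-mean H2. Pools locations by treating (location, trial, block)
    cells as the fixed stratification."""
    if trait not in pheno.columns:
        raise KeyError(f"trait {trait!r} not in phenotype table")
    df = pheno.dropna(subset=[trait])
    y = df[trait].to_numpy(dtype=float)
    lines = pd.Index(sorted(df["line"].unique()))
    parts = [df[c].astype(str) for c in ("location", "trial", "block") if c in df.columns]
    key = parts[0]
    for p in parts[1:]:
        key = key + ":" + p
    X = pd.get_dummies(key).to_numpy(dtype=float)
    Z = pd.get_dummies(pd.Categorical(df["line"], categories=lines)).to_numpy(dtype=float)
    n_rep = len(df) / len(lines)
    if n_rep <= 1.0 + 1e-9:
        warnings.warn("single replicate: heritability estimate is unreliable", stacklevel=2)
    fit = _reml_one_random(y, X, Z)
    sigma2_g = max(fit.sigma2_u, 0.0)
    sigma2_e = max(fit.sigma2_e, 0.0)
    return VarianceComponents(
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        n_rep=float(n_rep),
        H2=heritability_from_components(sigma2_g, sigma2_e, n_rep),
        reliable=n_rep > 1.0 + 1e-9,
    )


def trait_correlation_matrix(blues: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations among trait BLUEs.

    ``blues`` is line x trait (wide); zero-variance traits yield NaN in
    their rows/columns with a warning rather than an error.
    """
    num = blues.select_dtypes(include=[np.number])
    if len(num) < 3:
        raise ValueError("need at least 3 lines")
    zero_var = num.std(ddof=1) == 0
    if zero_var.any():
        warnings.warn(f"zero-variance traits: {list(num.columns[zero_var])}", stacklevel=2)
    corr = num.corr(method="pearson")
    corr.loc[zero_var, :] = np.nan
    corr.loc[:, zero_var] = np.nan
    for c in num.columns[~zero_var]:
        corr.loc[c, c] = 1.0
    return corr


def blues_wide(pheno: pd.DataFrame, traits, combine: str = "average") -> pd.DataFrame:
    """Convenience: line x trait table of BLUEs for several traits."""
    cols = {}
    for tr in traits:
        cols[tr] = fit_blues(pheno, tr, combine=combine).set_index("line")["blue"]
    return pd.DataFrame(cols)
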