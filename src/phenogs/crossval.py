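"""Cross-validation schemes for genomic prediction and the
predictive-ability statistic.

ST-CV1: a random 80% of lines train the single-trait GBLUP (genotypes +
phenotypes); the held-out 20% contribute genotypes only and their
phenotypes are predicted through the joint model. Repeated (100 replicates
by convention) with fresh random splits.

MT-CV2: the same line split, but test lines keep their secondary
(HTP-derived) traits observed — only the primary trait is masked — so the
multi-trait model can borrow information through the genetic covariance.
Repeated 50 times by convention.

Predictive ability is the Pearson correlation between predicted genetic
values and the held-out observations. CV1 and CV2 runs with the same
scheme seed draw identical splits (paired by replicate), which reduces the
variance of scheme comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .gblup import GibbsConfig, fit_mt_gblup, fit_st_gblup
from .genomics import GRM

#: Chain settings used inside CV loops: shortened relative to the full
#: single-fit defaults; adequate for posterior means (see the oracle tests).
CV_CHAIN = dict(n_iter=6000, burn_in=2000, thin=5)


@dataclass(frozen=True)
class CVScheme:
    """Replicated random-split scheme descriptor."""

    name: str  # "ST-CV1" | "MT-CV2"
    train_fraction: float = 0.8
    n_reps: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class CVResult:
    """Per-replicate predictive abilities with aggregation."""

    scheme: CVScheme
    abilities: np.ndarray
    covariates: tuple[str, ...] = ()

    @property
    def mean(self) -> float:
        return float(np.mean(self.abilities))

    @property
    def sd(self) -> float:
        return float(np.std(self.abilities, ddof=1)) if len(self.abilities) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scheme": self.scheme.name,
                "replicate": np.arange(1, len(self.abilities) + 1),
                "ability": self.abilities,
            }
        )


def predictive_ability(gebv: np.ndarray, observed: np.ndarray) -> float:
    """Pearson correlation between predictions and held-out observations."""
    gebv = np.asarray(gebv, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if gebv.shape != observed.shape or gebv.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if len(gebv) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(gebv) == 0 or np.std(observed) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    return float(stats.pearsonr(gebv, observed).statistic)


def make_splits(n: int, scheme: CVScheme) -> list[np.ndarray]:
    """Deterministic per-replicate test-index sets.

    Training size is floor(train_fraction * n); replicate r uses the r-th
    child of the scheme seed, so the whole schedule is a pure function of
    (n, scheme).
    """
    n_train = int(np.floor(scheme.train_fraction * n))
    n_test = n - n_train
    if n_test < 3:
        raise ValueError(f"test set of {n_test} lines is too small to score (need >= 3)")
    children = np.random.SeedSequence(scheme.seed).spawn(scheme.n_reps)
    splits = []
    for child in children:
        rng = np.random.default_rng(child)
        perm = rng.permutation(n)
        splits.append(np.sort(perm[n_train:]))
    return splits


def run_st_cv1(
    y: np.ndarray,
    grm: GRM | np.ndarray,
    scheme: CVScheme | None = None,
    cfg: GibbsConfig | None = None,
) -> CVResult:
    """Replicated ST-CV1: mask test-line phenotypes, fit single-trait
    GBLUP with data augmentation, score masked lines."""
    scheme = scheme or CVScheme("ST-CV1", n_reps=100)
    y = np.asarray(y, dtype=float)
    n = len(y)
    base = cfg or GibbsConfig(**CV_CHAIN)
    abilities = np.empty(scheme.n_reps)
    for r, test_idx in enumerate(make_splits(n, scheme)):
        y_masked = y.copy()
        y_masked[test_idx] = np.nan
        fit = fit_st_gblup(y_masked, grm, replace(base, seed=base.seed + r))
        abilities[r] = predictive_ability(fit.gebv[test_idx], y[test_idx])
    return CVResult(scheme=scheme, abilities=abilities)


def run_mt_cv2(
    primary: np.ndarray,
    covariates: pd.DataFrame | np.ndarray,
    grm: GRM | np.ndarray,
    scheme: CVScheme | None = None,
    cfg: GibbsConfig | None = None,
) -> CVResult:
    """Replicated MT-CV2: the primary trait is masked on test lines while
    the HTP covariates stay observed for everyone; the multi-trait model
    predicts the masked entries and the posterior-mean genetic values of
    the primary trait are scored."""
    scheme = scheme or CVScheme("MT-CV2", n_reps=50)
    primary = np.asarray(primary, dtype=float)
    n = len(primary)
    if isinstance(covariates, pd.DataFrame):
        cov_names = tuple(covariates.columns)
        C = covariates.to_numpy(dtype=float)
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cov_names = tuple(f"cov{j}" for j in range(C.shape[1]))
    if C.shape[0] != n:
        raise ValueError("covariates and primary trait differ in length")
    if np.isnan(C).any():
        bad = np.flatnonzero(np.isnan(C).any(axis=1))
        raise ValueError(f"covariates missing for lines at index {bad[:5]}")
    base = cfg or GibbsConfig(**CV_CHAIN)
    abilities = np.empty(scheme.n_reps)
    for r, test_idx in enumerate(make_splits(n, scheme)):
        Y = np.column_stack([primary, C])
        Y[test_idx, 0] = np.nan
        fit = fit_mt_gblup(Y, grm, replace(base, seed=base.seed + r))
        abilities[r] = predictive_ability(fit.gebv[test_idx, 0], primary[test_idx])
    return CVResult(scheme=scheme, abilities=abilities, covariates=cov_names)


def compare_schemes(result_a: CVResult, result_b: CVResult) -> dict:
    """One-sided paired t-test that scheme b beats scheme a.

    Requires seed-paired replicates (equal counts); returns the mean gain
    and the p-value for mean(b - a) > 0.
    """
    a, b = result_a.abilities, result_b.abilities
    if len(a) != len(b):
        raise ValueError("paired comparison needs equal replicate counts")
    t = stats.ttest_rel(b, a, alternative="greater")
    return {
        "mean_a": float(np.mean(a)),
        "mean_b": float(np.mean(b)),
        "gain": float(np.mean(b - a)),
        "t": float(t.statistic),
        "p_value": float(t.pvalue),
    }
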