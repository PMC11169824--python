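"""Marker QC, genomic relationship matrix, and the closed-form GBLUP oracle.

Dosages are coded 0/1/2 copies of the alternate allele with ``NaN`` as the
missing sentinel. The genomic relationship matrix (GRM) follows
``G = X X' / p`` over centered, unit-variance-standardized marker columns
(the VanRaden ``2*sum(p*q)`` denominator is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix with marker metadata.

    ``dosages`` is float with entries in {0, 1, 2} or NaN (missing).
    ``markers`` has columns ``id``, ``chrom``, ``pos``; unmapped markers
    carry an empty/NaN ``chrom``.
    """

    dosages: np.ndarray
    line_ids: list[str]
    markers: pd.DataFrame

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (lines x markers)")
        if self.dosages.shape[0] != len(self.line_ids):
            raise ValueError("line_ids length does not match dosage rows")
        if self.dosages.shape[1] != len(self.markers):
            raise ValueError("marker metadata length does not match dosage columns")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            raise ValueError("observed dosages must be 0, 1 or 2")
        if self.markers["id"].duplicated().any():
            dup = self.markers["id"][self.markers["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker, over observed calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, keep],
            list(self.line_ids),
            self.markers.iloc[np.flatnonzero(keep) if keep.dtype == bool else keep].reset_index(drop=True),
        )


@dataclass
class QCReport:
    """Per-rule marker removal counts; removed + retained = input."""

    n_input: int
    removed_missing: int
    removed_maf: int
    removed_unmapped: int
    retained: int

    def __post_init__(self):
        total = self.removed_missing + self.removed_maf + self.removed_unmapped + self.retained
        if total != self.n_input:
            raise ValueError("QC accounting does not add up")


def qc_filter(
    geno: GenotypeMatrix,
    max_missing: float = 0.30,
    min_maf: float = 0.05,
    drop_unmapped: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers with >``max_missing`` missingness, MAF <``min_maf``,
    or no chromosome assignment.

    Both thresholds are strict, so a marker at exactly 30% missing or
    exactly 5% MAF is retained. A marker violating several rules is counted
    under the first rule in the order missingness, MAF, unmapped.
    """
    miss = geno.missing_rate()
    maf = geno.maf()
    bad_missing = miss > max_missing
    # markers that are entirely missing have undefined MAF; they fail missingness
    bad_maf = ~bad_missing & (np.nan_to_num(maf, nan=0.0) < min_maf)
    if drop_unmapped:
        chrom = geno.markers["chrom"]
        unmapped = chrom.isna() | (chrom.astype(str).str.strip().isin(["", "UN", "Un", "un"]))
        bad_unmapped = ~bad_missing & ~bad_maf & unmapped.to_numpy()
    else:
        bad_unmapped = np.zeros(geno.n_markers, dtype=bool)
    keep = ~(bad_missing | bad_maf | bad_unmapped)
    if not keep.any():
        raise ValueError("QC removed every marker: empty panel")
    report = QCReport(
        n_input=geno.n_markers,
        removed_missing=int(bad_missing.sum()),
        removed_maf=int(bad_maf.sum()),
        removed_unmapped=int(bad_unmapped.sum()),
        retained=int(keep.sum()),
    )
    return geno.subset_markers(keep), report


def impute_mean(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the per-marker mean of observed calls."""
    d = geno.dosages.copy()
    all_missing = np.isnan(d).all(axis=0)
    if all_missing.any():
        ids = geno.markers["id"][all_missing].tolist()
        raise ValueError(f"markers entirely missing (should have been QC-filtered): {ids[:5]}")
    col_mean = np.nanmean(d, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(d))
    d[nan_r, nan_c] = col_mean[nan_c]
    out = GenotypeMatrix.__new__(GenotypeMatrix)  # skip 0/1/2 check: imputed values are fractional
    out.dosages = d
    out.line_ids = list(geno.line_ids)
    out.markers = geno.markers.copy()
    return out


@dataclass
class GRM:
    """Genomic relationship matrix with its standardized marker matrix."""

    G: np.ndarray
    X: np.ndarray
    p: int
    line_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not np.allclose(self.G, self.G.T, atol=1e-10):
            raise ValueError("G must be symmetric")

    @property
    def n(self) -> int:
        return self.G.shape[0]


def compute_grm(geno: GenotypeMatrix, denominator: str = "sd") -> GRM:
    """G = XX'/p over centered, standardized markers.

    Parameters
    ----------
    denominator
        ``"sd"`` scales each marker by its observed standard deviation
        (unit-variance standardization; diagonal mean exactly 1).
        ``"vanraden"`` centers only and divides by ``2 * sum(p_j q_j)``.
    """
    d = geno.dosages
    if np.isnan(d).any():
        raise ValueError("GRM requires a complete matrix; impute first")
    mean = d.mean(axis=0)
    sd = d.std(axis=0)
    mono = sd == 0
    if mono.any():
        ids = geno.markers["id"][mono].tolist()
        raise ValueError(f"monomorphic markers (zero variance): {ids[:5]}")
    if denominator == "sd":
        X = (d - mean) / sd
        G = X @ X.T / geno.n_markers
    elif denominator == "vanraden":
        p = mean / 2.0
        X = d - 2.0 * p
        G = X @ X.T / (2.0 * np.sum(p * (1.0 - p)))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    G = (G + G.T) / 2.0
    return GRM(G=G, X=X, p=geno.n_markers, line_ids=list(geno.line_ids))


def st_gblup_closed_form(
    y: np.ndarray, grm: GRM | np.ndarray, sigma2_g: float, sigma2_e: float
) -> np.ndarray:
    """Deterministic GBLUP solution at fixed variance components.

    Solves the mixed model ``y = 1 mu + g + e`` with ``g ~ N(0, G sg2)``
    and ``e ~ N(0, I se2)``: the generalized-least-squares intercept is
    profiled out and ``g_hat = sg2 G V^-1 (y - mu_hat)`` with
    ``V = sg2 G + se2 I``.
    """
    G = grm.G if isinstance(grm, GRM) else np.asarray(grm, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if G.shape != (n, n):
        raise ValueError("G and y dimensions differ")
    if sigma2_g < 0 or sigma2_e <= 0:
        raise ValueError("need sigma2_g >= 0 and sigma2_e > 0")
    V = sigma2_g * G + sigma2_e * np.eye(n)
    Vinv_y = np.linalg.solve(V, y)
    Vinv_1 = np.linalg.solve(V, np.ones(n))
    mu = float(np.ones(n) @ Vinv_y / (np.ones(n) @ Vinv_1))
    return sigma2_g * G @ np.linalg.solve(V, y - mu)
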