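"""Synthetic winter-wheat breeding trials with known ground truth.

Generates everything the downstream stages consume: SNP genotypes, additive
(infinitesimal-model) breeding values for genetically correlated traits,
plot-level phenotypes under RCBD and augmented field designs at one or more
locations, and multitemporal 5-band canopy reflectance whose vegetation
indices correlate with yield with stage-controlled strength.

Conventions
-----------
* ``h2`` targets are entry-mean broad-sense heritabilities
  ``H2 = sg2 / (sg2 + se2/nRep)``; plot residual variance is derived as
  ``se2 = nRep * sg2 * (1 - h2) / h2`` so heritability-recovery analyses
  are well posed.
* Traits are simulated on a standardized scale (entry-mean phenotypic
  variance 1) and then mapped to field units through per-trait means and
  standard deviations (grain yield kg/ha, test weight kg/hl, grain protein
  %); heritabilities and correlations are affine-invariant.
* Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genomics import GenotypeMatrix
from .spectral import BANDS, STAGES

TRAITS = ("GY", "TW", "GPC")

#: Field-unit scale of the standardized traits (mean, sd).
TRAIT_SCALES = {"GY": (4500.0, 600.0), "TW": (76.0, 2.0), "GPC": (12.0, 0.8)}

#: Stage-dependent link between the yield breeding value and canopy vigor.
#: Later flights track genetic merit more strongly, mirroring the stronger
#: late-season index-yield correlations seen in wheat canopies.
DEFAULT_VIGOR_LOADINGS = {"F6": 0.4, "F8": 0.8, "F10": 0.8, "F11": 0.6}

#: Mean canopy development per stage on the latent vigor scale.
STAGE_BASELINES = {"F6": -0.8, "F8": 0.4, "F10": 0.8, "F11": 0.0}


@dataclass(frozen=True)
class TrialDesign:
    """One trial at one location: RCBD with ``n_reps``, or an augmented
    design with ``n_blocks`` blocks, unreplicated test lines and the given
    check lines repeated in every block."""

    name: str
    lines: tuple[str, ...]
    kind: str = "rcbd"  # "rcbd" | "augmented"
    n_reps: int = 3
    n_blocks: int = 0
    checks: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("rcbd", "augmented"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        if self.kind == "rcbd" and self.n_reps < 1:
            raise ValueError("RCBD needs n_reps >= 1")
        if self.kind == "augmented":
            if not self.checks:
                raise ValueError("augmented design requires check lines")
            if self.n_blocks < 1:
                raise ValueError("augmented design needs n_blocks >= 1")

    @property
    def effective_reps(self) -> float:
        return float(self.n_reps) if self.kind == "rcbd" else 1.0


@dataclass
class SimConfig:
    """Generator settings; defaults emulate the advanced-line trials
    (ELITE: 36 lines / 3 reps, AYT: 126 lines / 2 reps) at two locations
    with four flights."""

    n_lines: int = 162
    n_markers: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    trait_names: tuple[str, ...] = TRAITS
    h2: dict = field(default_factory=lambda: {"GY": 0.5, "TW": 0.7, "GPC": 0.4})
    genetic_corr: np.ndarray | None = None
    n_locations: int = 2
    designs: tuple[TrialDesign, ...] = ()
    flights: tuple[str, ...] = STAGES
    vigor_loadings: dict = field(default_factory=lambda: dict(DEFAULT_VIGOR_LOADINGS))
    reflectance_noise_sd: float = 0.5
    rep_effect_sd: float = 0.3
    loc_effect_sd: float = 0.5
    gxl_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for tr in self.trait_names:
            if not (0 < self.h2[tr] <= 1):
                raise ValueError(f"h2[{tr}] must be in (0, 1]")
        if self.reflectance_noise_sd < 0:
            raise ValueError("reflectance_noise_sd must be nonnegative")
        t = len(self.trait_names)
        if self.genetic_corr is None:
            self.genetic_corr = _default_genetic_corr(self.trait_names)
        self.genetic_corr = np.asarray(self.genetic_corr, dtype=float)
        _check_corr(self.genetic_corr, t)
        if not self.designs:
            lines = line_names(self.n_lines)
            n_elite = min(36, self.n_lines)
            self.designs = (
                TrialDesign("ELITE", tuple(lines[:n_elite]), "rcbd", n_reps=3),
                TrialDesign("AYT", tuple(lines[n_elite:]), "rcbd", n_reps=2)
                if self.n_lines > n_elite
                else TrialDesign("AYT", tuple(lines[:n_elite]), "rcbd", n_reps=2),
            )
        for st in self.flights:
            if st not in self.vigor_loadings:
                raise ValueError(f"vigor_loadings missing flight {st!r}")

    @property
    def all_lines(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in self.designs:
            for ln in (*d.lines, *d.checks):
                seen.setdefault(ln, None)
        return list(seen)


def _default_genetic_corr(trait_names):
    """Moderate positive GY-TW, weak negative GY-GPC trade-off, as is
    typical of hard winter wheat."""
    t = len(trait_names)
    C = np.eye(t)
    defaults = {("GY", "TW"): 0.3, ("GY", "GPC"): -0.3, ("TW", "GPC"): 0.1}
    for i in range(t):
        for j in range(i + 1, t):
            pair = (trait_names[i], trait_names[j])
            r = defaults.get(pair, defaults.get(pair[::-1], 0.0))
            C[i, j] = C[j, i] = r
    return C


def _check_corr(C, t):
    if C.shape != (t, t):
        raise ValueError("genetic_corr shape does not match trait count")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("genetic_corr must be symmetric")
    if not np.allclose(np.diag(C), 1.0):
        raise ValueError("genetic_corr must have unit diagonal")
    if np.linalg.eigvalsh(C).min() < -1e-8:
        raise ValueError("genetic_corr must be positive semi-definite")


def line_names(n: int, prefix: str = "L") -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


@dataclass
class TrueValues:
    """Simulation ground truth for recovery analyses."""

    breeding_values: pd.DataFrame  # line x trait, standardized scale
    marker_effects: np.ndarray  # markers x traits
    realized_h2: dict
    realized_genetic_corr: np.ndarray
    trait_names: tuple[str, ...]


def simulate_genotypes(
    n_lines: int,
    n_markers: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    n_chromosomes: int = 21,
) -> GenotypeMatrix:
    """Unlinked biallelic SNPs: per-marker allele frequency uniform on
    ``maf_range``, dosages Binomial(2, freq) per line (no LD, no pedigree)."""
    if n_lines < 2 or n_markers < 1:
        raise ValueError("need n_lines >= 2 and n_markers >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    freq = rng.uniform(lo, hi, size=n_markers)
    dosages = rng.binomial(2, freq, size=(n_lines, n_markers)).astype(float)
    # wheat-style map: markers spread over chromosomes, 1-based positions
    chrom = 1 + (np.arange(n_markers) % n_chromosomes)
    pos = 1 + 1000 * (np.arange(n_markers) // n_chromosomes)
    markers = pd.DataFrame(
        {
            "id": [f"S{c}_{p}" for c, p in zip(chrom, pos)],
            "chrom": [f"chr{c}" for c in chrom],
            "pos": pos,
        }
    )
    return GenotypeMatrix(dosages, line_names(n_lines), markers)


def simulate_genetic_values(
    geno: GenotypeMatrix,
    h2: dict | float,
    genetic_corr: np.ndarray | None = None,
    seed: int = 0,
    trait_names: tuple[str, ...] = TRAITS,
) -> TrueValues:
    """Additive breeding values from multivariate-normal marker effects.

    Marker effects for the t traits are iid across markers with covariance
    proportional to ``genetic_corr``; breeding values are the centered
    dosage matrix times the effects, rescaled per trait so the genetic
    variance equals the entry-mean heritability target (total entry-mean
    phenotypic variance 1).
    """
    t = len(trait_names)
    if isinstance(h2, float):
        h2 = {tr: h2 for tr in trait_names}
    C = np.asarray(genetic_corr, dtype=float) if genetic_corr is not None else np.eye(t)
    _check_corr(C, t)
    rng = np.random.default_rng(seed)
    # PSD factor (eigen route tolerates semi-definite C)
    w, Q = np.linalg.eigh(C)
    A = Q @ np.diag(np.sqrt(np.maximum(w, 0.0)))
    effects = rng.standard_normal((geno.n_markers, t)) @ A.T
    Xc = geno.dosages - geno.dosages.mean(axis=0)
    bv = Xc @ effects
    scale = np.ones(t)
    for k, tr in enumerate(trait_names):
        sd = bv[:, k].std(ddof=0)
        if sd > 0:
            scale[k] = np.sqrt(h2[tr]) / sd
    bv = bv * scale
    effects = effects * scale
    realized = np.corrcoef(bv.T) if t > 1 else np.ones((1, 1))
    return TrueValues(
        breeding_values=pd.DataFrame(bv, index=geno.line_ids, columns=list(trait_names)),
        marker_effects=effects,
        realized_h2={tr: float(bv[:, k].var(ddof=0)) for k, tr in enumerate(trait_names)},
        realized_genetic_corr=realized,
        trait_names=tuple(trait_names),
    )


def _design_plots(design: TrialDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Plot layout for one trial: (replicate/block, line) records."""
    rows = []
    if design.kind == "rcbd":
        for rep in range(1, design.n_reps + 1):
            order = list(design.lines)
            rng.shuffle(order)
            for ln in order:
                rows.append({"replicate": rep, "block": rep, "line": ln})
    else:
        test = list(design.lines)
        rng.shuffle(test)
        chunks = np.array_split(np.array(test, dtype=object), design.n_blocks)
        for b, chunk in enumerate(chunks, start=1):
            for ln in (*design.checks, *chunk):
                rows.append({"replicate": 1, "block": b, "line": str(ln)})
    return pd.DataFrame(rows)


def simulate_field_trial(
    true_vals: TrueValues,
    config: SimConfig,
    in_field_units: bool = True,
) -> pd.DataFrame:
    """Plot-level phenotypes for every configured trial and location.

    Each plot value is ``mu + location shift + replicate/block effect +
    breeding value + residual``; the residual variance per trait is derived
    from the entry-mean heritability target and the trial's replicate
    count. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 20]))
    bv = true_vals.breeding_values
    loc_effects = location_effects(config)
    records = []
    plot_counter = 0
    for loc in range(1, config.n_locations + 1):
        loc_shift = loc_effects[loc - 1]
        # genotype-by-location deviations, shared by all plots of a line at this site
        gxl = (
            rng.normal(0.0, config.gxl_sd, size=(len(bv), len(config.trait_names)))
            if config.gxl_sd > 0
            else np.zeros((len(bv), len(config.trait_names)))
        )
        gxl_df = pd.DataFrame(gxl, index=bv.index, columns=list(config.trait_names))
        for design in config.designs:
            missing = [ln for ln in (*design.lines, *design.checks) if ln not in bv.index]
            if missing:
                raise ValueError(f"no breeding values for lines {missing[:5]} in trial {design.name}")
            layout = _design_plots(design, rng)
            n_blocks = layout["block"].nunique()
            block_eff = rng.normal(0.0, config.rep_effect_sd, size=(n_blocks, len(config.trait_names)))
            for _, row in layout.iterrows():
                plot_counter += 1
                rec = {
                    "location": f"LOC{loc}",
                    "trial": design.name,
                    "block": int(row["block"]),
                    "replicate": int(row["replicate"]),
                    "line": row["line"],
                    "plot_id": f"P{plot_counter:05d}",
                }
                records.append(rec)
            # vectorized trait draw for this trial/location
            idx0 = plot_counter - len(layout)
            lines = layout["line"].to_numpy()
            blocks = layout["block"].to_numpy() - 1
            g = bv.loc[lines, list(config.trait_names)].to_numpy()
            for k, tr in enumerate(config.trait_names):
                sg2 = config.h2[tr]  # genetic variance on the standardized scale
                n_rep = design.effective_reps
                se2 = n_rep * sg2 * (1.0 - config.h2[tr]) / config.h2[tr] if config.h2[tr] < 1 else 0.0
                resid = rng.normal(0.0, np.sqrt(se2), size=len(layout)) if se2 > 0 else np.zeros(len(layout))
                y = loc_shift[k] + block_eff[blocks, k] + g[:, k] + gxl_df.loc[lines, tr].to_numpy() + resid
                if in_field_units:
                    mean, sd = TRAIT_SCALES.get(tr, (0.0, 1.0))
                    y = mean + sd * y
                for i, v in enumerate(y):
                    records[idx0 + i][tr] = float(v)
    return pd.DataFrame(records)


def location_effects(config: SimConfig) -> np.ndarray:
    """Additive per-location trait shifts (standardized scale), drawn from
    a stream independent of the plot-level noise so phenotype and
    reflectance simulation agree on them."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 25]))
    return rng.normal(0.0, config.loc_effect_sd,
                      size=(config.n_locations, len(config.trait_names)))


def _squash(v):
    return 1.0 / (1.0 + np.exp(-v))


#: Fixed affine maps from squashed vigor s = sigma(v) to band reflectance.
BAND_MAPS = {
    "blue": (0.06, 0.01),
    "green": (0.10, 0.06),
    "red": (0.25, -0.18),
    "red_edge": (0.18, 0.14),
    "nir": (0.25, 0.35),
}


def simulate_reflectance(
    true_vals: TrueValues,
    config: SimConfig,
    pheno: pd.DataFrame,
) -> pd.DataFrame:
    """Per-plot, per-flight 5-band reflectance driven by latent canopy vigor.

    ``v = loading(stage) * (standardized GY breeding value + location
    effect) + baseline(stage) + N(0, reflectance_noise_sd^2)``; each band
    is a fixed affine map of the logistic squash of v (NIR increasing, red
    decreasing), clipped to [0, 1]. NDVI-type indices therefore correlate
    with yield with stage-controlled strength, and a site's overall
    productivity shows in its canopy the way it does in the field.
    """
    if config.reflectance_noise_sd < 0:
        raise ValueError("reflectance_noise_sd must be nonnegative")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 30]))
    gy = true_vals.breeding_values.iloc[:, 0]
    sd = gy.std(ddof=0)
    gy_std = (gy - gy.mean()) / (sd if sd > 0 else 1.0)
    lines = pheno["line"].to_numpy()
    plot_ids = pheno["plot_id"].to_numpy()
    z = gy_std.loc[lines].to_numpy()
    loc_eff = location_effects(config)[:, 0]
    loc_index = pheno["location"].str.removeprefix("LOC").astype(int).to_numpy() - 1
    z = z + loc_eff[loc_index]
    frames = []
    for stage in config.flights:
        loading = config.vigor_loadings[stage]
        v = loading * z + STAGE_BASELINES.get(stage, 0.0)
        if config.reflectance_noise_sd > 0:
            v = v + rng.normal(0.0, config.reflectance_noise_sd, size=v.shape)
        s = _squash(v)
        rec = {"plot_id": plot_ids, "stage": stage}
        for band in BANDS:
            a, b = BAND_MAPS[band]
            rec[band] = np.clip(a + b * s, 0.0, 1.0)
        frames.append(pd.DataFrame(rec))
    return pd.concat(frames, ignore_index=True)


def breeding_program_config(seed: int = 0, n_markers: int = 2000) -> tuple[SimConfig, SimConfig]:
    """(advanced, preliminary) trial configs emulating the field layout:
    162 advanced lines (ELITE 36 / 3 reps + AYT 126 / 2 reps) at two
    locations, and a preliminary nursery of 590 lines in an augmented
    design with 7 checks across 22 blocks at one location."""
    adv_lines = line_names(162)
    adv = SimConfig(
        n_lines=162,
        n_markers=n_markers,
        n_locations=2,
        designs=(
            TrialDesign("ELITE", tuple(adv_lines[:36]), "rcbd", n_reps=3),
            TrialDesign("AYT", tuple(adv_lines[36:]), "rcbd", n_reps=2),
        ),
        seed=seed,
    )
    pyt_lines = line_names(590, prefix="P")
    pyt = SimConfig(
        n_lines=590,
        n_markers=n_markers,
        n_locations=1,
        designs=(
            TrialDesign(
                "PYT",
                tuple(pyt_lines),
                "augmented",
                n_blocks=22,
                checks=tuple(adv_lines[:7]),
            ),
        ),
        seed=seed,
    )
    return adv, pyt


@dataclass
class DatasetBundle:
    """In-memory synthetic dataset: genotypes, truth, phenotypes,
    reflectance."""

    geno: GenotypeMatrix
    truth: TrueValues
    pheno: pd.DataFrame
    reflectance: pd.DataFrame
    config: SimConfig


def simulate_bundle(config: SimConfig) -> DatasetBundle:
    """Full in-memory dataset for one config (pure function of config+seed)."""
    all_lines = config.all_lines
    geno = simulate_genotypes(
        len(all_lines), config.n_markers, config.maf_range, seed=config.seed
    )
    geno.line_ids = all_lines
    truth = simulate_genetic_values(
        geno, config.h2, config.genetic_corr, seed=config.seed + 1, trait_names=config.trait_names
    )
    pheno = simulate_field_trial(truth, config)
    refl = simulate_reflectance(truth, config, pheno)
    return DatasetBundle(geno, truth, pheno, refl, config)


def simulate_dataset(config: SimConfig, outdir) -> dict:
    """Write a dataset bundle to ``outdir``: VCF genotypes, CSV phenotypes,
    CSV reflectance, CSV ground truth. Re-running with the same config and
    seed is byte-identical. Returns the file paths and their checksums."""
    from pathlib import Path

    from .pipeline_io import write_vcf

    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output path {out} is not writable: {exc}") from exc
    bundle = simulate_bundle(config)
    paths = {
        "genotypes": out / "genotypes.vcf",
        "phenotypes": out / "phenotypes.csv",
        "reflectance": out / "reflectance.csv",
        "truth": out / "truth.csv",
    }
    write_vcf(bundle.geno, paths["genotypes"])
    bundle.pheno.to_csv(paths["phenotypes"], index=False, lineterminator="\n", float_format="%.6f")
    bundle.reflectance.to_csv(paths["reflectance"], index=False, lineterminator="\n", float_format="%.6f")
    truth_df = bundle.truth.breeding_values.rename_axis("line").reset_index()
    truth_df.to_csv(paths["truth"], index=False, lineterminator="\n", float_format="%.6f")
    checksums = {
        k: hashlib.sha256(p.read_bytes()).hexdigest() for k, p in paths.items()
    }
    return {"paths": {k: str(p) for k, p in paths.items()}, "checksums": checksums}
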