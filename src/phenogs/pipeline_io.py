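"""File formats, run configuration, and end-to-end orchestration.

Genotypes travel as plain VCF v4.2 (unphased GT) or dosage CSV; phenotypes,
reflectance, vegetation indices and model outputs as CSV; the pipeline
summary as JSON carrying the originating seed and a config hash, so two
runs with equal hashes are identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import crossval, genomics, gblup, phenomic, phenostats, simdata, spectral

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- genotypes

def write_vcf(geno: genomics.GenotypeMatrix, path) -> None:
    """Plain-text VCF v4.2 with unphased GT calls (0/0, 0/1, 1/1, ./.).

    Output is byte-reproducible: no timestamps, fixed REF/ALT alleles.
    """
    path = Path(path)
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=phenogs\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(geno.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.line_ids) + "\n")
        for j in range(geno.n_markers):
            m = geno.markers.iloc[j]
            calls = "\t".join(
                "./." if np.isnan(d) else code[d] for d in geno.dosages[:, j]
            )
            fh.write(f"{m['chrom']}\t{int(m['pos'])}\t{m['id']}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path) -> genomics.GenotypeMatrix:
    """Read a VCF into the dosage representation via cyvcf2.

    GT is mapped to alternate-allele dosage {0,1,2}; ``./.`` becomes the
    missing sentinel. Multi-allelic sites are rejected with their ids.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    line_ids = list(vcf.samples)
    rows, ids, chroms, poss = [], [], [], []
    multi = []
    for k, variant in enumerate(vcf):
        if len(variant.ALT) > 1:
            multi.append(variant.ID or f"record {k + 1}")
            continue
        # gts012: 0/1/2 dosage, 3 = missing
        gt = variant.gt_types.astype(float)
        gt[gt == 3] = np.nan
        rows.append(gt)
        ids.append(variant.ID or f"{variant.CHROM}_{variant.POS}")
        chroms.append(variant.CHROM)
        poss.append(variant.POS)
    if multi:
        raise ValueError(f"multi-allelic sites not supported: {multi[:5]}")
    if not rows:
        raise ValueError(f"no usable records in {path}")
    markers = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss})
    return genomics.GenotypeMatrix(np.array(rows).T, line_ids, markers)


def read_dosage_csv(path) -> genomics.GenotypeMatrix:
    """Dosage CSV: first column ``line``, remaining columns are markers."""
    df = pd.read_csv(path)
    if df.columns[0] != "line":
        raise ValueError("dosage CSV must have 'line' as its first column")
    marker_ids = list(df.columns[1:])
    markers = pd.DataFrame({"id": marker_ids, "chrom": "1", "pos": np.arange(1, len(marker_ids) + 1)})
    return genomics.GenotypeMatrix(
        df.iloc[:, 1:].to_numpy(dtype=float), df["line"].astype(str).tolist(), markers
    )


def read_genotypes(path) -> genomics.GenotypeMatrix:
    path = Path(path)
    if path.suffix in (".vcf", ".gz", ".bcf"):
        return read_vcf(path)
    return read_dosage_csv(path)


# ------------------------------------------------------------- orchestration

@dataclass
class RunConfig:
    """End-to-end pipeline settings (all stages optional)."""

    outdir: str = "phenogs_out"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "features", "blues", "gs", "dnn")
    n_lines: int = 162
    n_markers: int = 2000
    flights: tuple[str, ...] = spectral.STAGES
    traits: tuple[str, ...] = simdata.TRAITS
    cv_reps_st: int = 10
    cv_reps_mt: int = 10
    gs_covariate_index: str = "GCI"
    gs_covariate_stage: str = "F10"
    chain: dict = field(default_factory=lambda: dict(crossval.CV_CHAIN))
    dnn: dict = field(default_factory=lambda: dict(hidden_sizes=(64, 128), epochs=60, batch_size=32))
    genotype_path: str | None = None
    phenotype_path: str | None = None
    reflectance_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for p in (cfg.genotype_path, cfg.phenotype_path, cfg.reflectance_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg

    def hash(self) -> str:
        payload = {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def vi_line_blues(vi: pd.DataFrame, pheno: pd.DataFrame, index: str, stage: str) -> pd.Series:
    """Line-level BLUEs of one vegetation index at one stage (VIs are
    analyzed with the same replicate-random model as agronomic traits)."""
    sub = vi[vi["stage"] == stage][["plot_id", index]]
    merged = sub.merge(
        pheno[[c for c in ("plot_id", "location", "trial", "block", "replicate", "line") if c in pheno.columns]],
        on="plot_id",
    )
    merged = merged.rename(columns={index: "_vi"})
    return phenostats.fit_blues(merged, "_vi").set_index("line")["blue"]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages in dependency order.

    Writes CSV tables plus a machine-readable ``summary.json``; a stage
    failure halts downstream stages but preserves completed outputs.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "config_hash": cfg.hash(), "stages": {}}
    state: dict = {}

    def record(stage, t0, **info):
        summary["stages"][stage] = {"seconds": round(time.time() - t0, 2), **info}
        logger.info("stage %s done: %s", stage, info)

    try:
        if "simulate" in cfg.stages:
            t0 = time.time()
            sim = simdata.SimConfig(n_lines=cfg.n_lines, n_markers=cfg.n_markers,
                                    flights=cfg.flights, seed=cfg.seed)
            bundle = simdata.simulate_bundle(sim)
            files = simdata.simulate_dataset(sim, out / "data")
            state.update(geno=bundle.geno, pheno=bundle.pheno, refl=bundle.reflectance,
                         truth=bundle.truth)
            record("simulate", t0, n_lines=bundle.geno.n_lines,
                   n_markers=bundle.geno.n_markers, n_plots=len(bundle.pheno),
                   checksums=files["checksums"])
        else:
            if cfg.genotype_path:
                state["geno"] = read_genotypes(cfg.genotype_path)
            if cfg.phenotype_path:
                state["pheno"] = pd.read_csv(cfg.phenotype_path)
            if cfg.reflectance_path:
                state["refl"] = pd.read_csv(cfg.reflectance_path)

        if "features" in cfg.stages:
            t0 = time.time()
            vi = spectral.compute_vi_table(state["refl"])
            vi.to_csv(out / "vi_table.csv", index=False)
            corr = spectral.stagewise_trait_correlations(
                vi, state["pheno"][["plot_id", *cfg.traits]]
            )
            corr.to_csv(out / "vi_trait_correlations.csv", index=False)
            state["vi"] = vi
            record("features", t0, n_records=len(vi), n_indices=len(spectral.INDEX_NAMES))

        if "blues" in cfg.stages:
            t0 = time.time()
            blues = phenostats.blues_wide(state["pheno"], cfg.traits)
            blues.rename_axis("line").reset_index().to_csv(out / "blues.csv", index=False)
            herit = {
                tr: asdict(phenostats.estimate_heritability(state["pheno"], tr))
                for tr in cfg.traits
            }
            pd.DataFrame(herit).T.rename_axis("trait").reset_index().to_csv(
                out / "heritability.csv", index=False
            )
            state["blues"] = blues
            record("blues", t0, n_lines=len(blues),
                   H2={tr: round(h["H2"], 3) for tr, h in herit.items()})

        if "gs" in cfg.stages:
            t0 = time.time()
            geno_qc, report = genomics.qc_filter(state["geno"])
            grm = genomics.compute_grm(genomics.impute_mean(geno_qc))
            blues = state["blues"].reindex(grm.line_ids)
            keep = blues.notna().all(axis=1).to_numpy()
            grm_obs = genomics.GRM(grm.G[np.ix_(keep, keep)], grm.X[keep], grm.p,
                                   [l for l, k in zip(grm.line_ids, keep) if k])
            chain = gblup.GibbsConfig(**cfg.chain, seed=cfg.seed)
            gs_out = {}
            cov = vi_line_blues(state["vi"], state["pheno"],
                                cfg.gs_covariate_index, cfg.gs_covariate_stage)
            cov = cov.reindex(np.array(grm_obs.line_ids)).to_numpy()
            for tr in cfg.traits:
                y = blues.loc[keep, tr].to_numpy()
                st = crossval.run_st_cv1(
                    y, grm_obs, crossval.CVScheme("ST-CV1", n_reps=cfg.cv_reps_st, seed=cfg.seed), chain
                )
                mt = crossval.run_mt_cv2(
                    y, cov[:, None], grm_obs,
                    crossval.CVScheme("MT-CV2", n_reps=cfg.cv_reps_mt, seed=cfg.seed), chain
                )
                gs_out[tr] = {"st_cv1": round(st.mean, 4), "st_cv1_sd": round(st.sd, 4),
                              "mt_cv2": round(mt.mean, 4), "mt_cv2_sd": round(mt.sd, 4)}
                st.to_frame().assign(trait=tr).to_csv(out / f"cv_st_{tr}.csv", index=False)
                mt.to_frame().assign(trait=tr).to_csv(out / f"cv_mt_{tr}.csv", index=False)
            record("gs", t0, qc_retained=report.retained, predictive_ability=gs_out,
                   covariate=f"{cfg.gs_covariate_index}@{cfg.gs_covariate_stage}")

        if "dnn" in cfg.stages:
            t0 = time.time()
            fm = spectral.build_feature_matrix(state["vi"], state["pheno"], targets=cfg.traits)
            dnn_cfg = phenomic.DNNConfig(seed=cfg.seed, **{
                k: tuple(v) if isinstance(v, list) else v for k, v in cfg.dnn.items()
            })
            dnn_out = {}
            for tr in cfg.traits:
                _, metrics = phenomic.train_predict(fm, tr, dnn_cfg)
                dnn_out[tr] = {"r2": round(metrics.r2, 4), "rmse": round(metrics.rmse, 4),
                               "rmse_pct": round(metrics.rmse_pct, 4), "n_test": metrics.n}
            record("dnn", t0, metrics=dnn_out, n_features=len(fm.attrs["feature_columns"]))
    except Exception as exc:
        summary["error"] = f"{type(exc).__name__}: {exc}"
        logger.exception("pipeline halted")
        _write_summary(summary, out)
        raise

    _write_summary(summary, out)
    return summary


def _write_summary(summary: dict, out: Path) -> None:
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
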