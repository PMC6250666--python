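"""End-to-end orchestration on the synthetic two-cohort design.

simulate -> QC / normalise -> per-study cis-eQTL + meta -> permutation
calibration and eGene calls -> GWAS overlap -> RTC colocalisation -> MR ->
expression-phenotype meta-analysis.  Every stage communicates through TSV/JSON
artefacts in the run directory; the manifest records the configuration, the
seeds and a SHA-256 per artefact, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import eqtl, expr_meta, io, mr, overlap, permfdr, qc, rtc, synth
from .containers import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds of the run; defaults follow the analysis conventions
    the package implements (1 Mb window, 2000 permutations, q < 0.05,
    r^2 > 0.8 proxies, RTC >= 0.9, MR instruments r^2 < 0.2 & P < 0.08)."""

    seed: int = 0
    sim: dict = field(default_factory=dict)
    cis_window: int = 1_000_000
    permutations: int = 2000
    fdr_target: float = 0.05
    hwe_p_min: float = 1e-6
    maf_min: float = 0.05
    n_hidden_factors: int = 2
    n_genotype_pcs: int = 3
    proxy_r2: float = 0.8
    rtc_threshold: float = 0.9
    mr_r2_max: float = 0.2
    mr_p_max: float = 0.08
    mr_m: int = 7
    mr_bootstrap: int = 500
    trait_scenario: str = "shared"
    trait_effect: float = 1.0
    gwas_p_threshold: float = 5e-8

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(io.load_yaml(path))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _study_prep(geno, expr, study_label, cfg: RunConfig):
    """QC, normalisation and covariate assembly for one cohort."""
    ids = geno.samples.index[geno.samples["study"] == study_label]
    g = geno.subset_samples(ids)
    e = expr.subset_samples(ids)
    g, vrep = qc.filter_variants(g, maf_min=cfg.maf_min, hwe_p_min=cfg.hwe_p_min)
    kept, srep = qc.filter_samples(g, e)
    g = g.subset_samples(kept)
    e = e.subset_samples(kept)
    e, grep = qc.filter_genes(e)
    base_cov = g.samples[["age", "sex"]].astype(float)
    norm = qc.normalize_expression(e, covariates=base_cov)
    pcs = qc.genotype_pcs(g, k=cfg.n_genotype_pcs)
    hf = qc.estimate_hidden_factors(norm, base_cov, k=cfg.n_hidden_factors)
    cov = pd.concat([base_cov, pcs, hf], axis=1)
    sd = eqtl.StudyData(expression=norm.values, dosages=g.dosages, covariates=cov)
    reports = {"variants": vrep.to_dict(), "samples": srep.to_dict(),
               "genes": grep.to_dict()}
    return sd, g, norm, reports


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages; returns the manifest (also written to manifest.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "artefacts": {}}
    stage = "init"

    def record(name: str, *paths):
        for p in paths:
            manifest["artefacts"][str(Path(p).relative_to(outdir))] = _sha256(Path(p))

    try:
        # --- simulate -----------------------------------------------------
        stage = "simulate"
        t0 = time.perf_counter()
        sim_cfg = synth.config_from_dict(dict(config.sim, seed=config.seed))
        geno = synth.simulate_genotypes(sim_cfg)
        expr, truth = synth.simulate_expression(geno, sim_cfg)
        trait, gwas = synth.simulate_trait(
            geno, expr, truth, scenario=config.trait_scenario,
            trait_effect=config.trait_effect, seed=config.seed,
        )
        io.write_genotypes(geno, outdir)
        io.write_expression(expr, outdir)
        io.write_gwas(gwas, outdir / "gwas.tsv")
        (outdir / "truth.json").write_text(truth.to_json() + "\n")
        record(stage, outdir / "dosages.tsv", outdir / "variants.tsv",
               outdir / "covariates.tsv", outdir / "expression.tsv",
               outdir / "genes.tsv", outdir / "gwas.tsv", outdir / "truth.json")
        log.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        # --- QC + normalisation per study ---------------------------------
        stage = "qc_normalise"
        t0 = time.perf_counter()
        s1, g1, n1, rep1 = _study_prep(geno, expr, "S1", config)
        s2, g2, n2, rep2 = _study_prep(geno, expr, "S2", config)
        manifest["stages"]["qc"] = {"S1": rep1, "S2": rep2}
        io.dump_json(manifest["stages"]["qc"], outdir / "qc_report.json")
        record(stage, outdir / "qc_report.json")
        log.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        # --- cis-eQTL meta-analysis ---------------------------------------
        stage = "eqtl"
        t0 = time.perf_counter()
        common_snps = g1.dosages.columns.intersection(g2.dosages.columns)
        s1 = eqtl.StudyData(s1.expression, g1.dosages[common_snps], s1.covariates)
        s2 = eqtl.StudyData(s2.expression, g2.dosages[common_snps], s2.covariates)
        variants = geno.variants.loc[common_snps]
        genes = n1.genes.loc[n1.values.index.intersection(n2.values.index)]
        pairs = eqtl.map_cis_pairs(genes, variants, window=config.cis_window)
        meta = eqtl.run_cis_eqtl([s1, s2], genes, variants,
                                 window=config.cis_window, pairs=pairs)
        meta.to_csv(outdir / "eqtl_meta.tsv", sep="\t", index=False, na_rep=".")
        record(stage, outdir / "eqtl_meta.tsv")
        log.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        # --- permutation calibration + eGene calls ------------------------
        stage = "calibrate"
        t0 = time.perf_counter()
        calib = permfdr.calibrate(
            meta, [s1, s2], pairs, B=config.permutations,
            seed=config.seed, fdr_target=config.fdr_target,
        )
        egenes, sig_pairs, best = permfdr.call_egenes_esnps(
            meta, calib, variants=variants, q_max=config.fdr_target
        )
        calib.table().to_csv(outdir / "egenes.tsv", sep="\t", na_rep=".")
        sig_pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False, na_rep=".")
        manifest["stages"]["egenes"] = {
            "n_egenes": len(egenes), "p_t": calib.p_t,
            "n_significant_pairs": int(len(sig_pairs)),
        }
        record(stage, outdir / "egenes.tsv", outdir / "pairs.tsv")
        log.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        # --- GWAS overlap --------------------------------------------------
        stage = "overlap"
        t0 = time.perf_counter()
        pooled_dos = pd.concat([g1.dosages[common_snps], g2.dosages[common_snps]])
        panel = overlap.LdPanel(pooled_dos, variants)
        gwas_hits = gwas[gwas["p"] < config.gwas_p_threshold]
        sentinels = (
            [gwas_hits["p"].idxmin()] if len(gwas_hits) else []
        )
        esnp_set = set(sig_pairs["snp"])
        best_set = set(best["snp"])
        proxies = overlap.expand_proxies(sentinels, panel, r2_min=config.proxy_r2)
        ovl = overlap.overlap_gwas_esnps(sentinels, proxies, esnp_set, best_set)
        manifest["stages"]["overlap"] = {
            "n_gwas_sentinels": ovl["n_gwas"], "n_overlap": ovl["n_overlap"],
            "n_overlap_best": ovl.get("n_overlap_best", 0),
        }
        io.dump_json(manifest["stages"]["overlap"], outdir / "overlap.json")
        record(stage, outdir / "overlap.json")
        log.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        # --- RTC ------------------------------------------------------------
        stage = "rtc"
        t0 = time.perf_counter()
        rtc_rows = []
        tm = truth.trait_model or {}
        driver = tm.get("driver_gene")
        if driver is not None and sentinels and driver in best["gene"].values:
            esnp = best.loc[best["gene"] == driver, "snp"].iloc[0]
            gstart, gend = genes.loc[driver, ["start", "end"]]
            in_ivl = variants[
                (variants["pos"] >= gstart - config.cis_window)
                & (variants["pos"] <= gend + config.cis_window)
            ].index
            expr_vec = pd.concat(
                [s1.expression.loc[driver], s2.expression.loc[driver]]
            ).to_numpy()
            covs = pd.concat(
                [s1.covariates.assign(study=0), s2.covariates.assign(study=1)]
            ).fillna(0.0)
            res = rtc.rtc_score(
                pooled_dos[in_ivl], expr_vec, sentinels[0], esnp,
                covariates=covs.to_numpy(dtype=float),
                interval_id=f"ivl_{driver}", egene=driver,
            )
            rtc_rows = rtc.call_colocalisation([res], threshold=config.rtc_threshold)
        rtc_tab = rtc.results_table(rtc_rows)
        rtc_tab.to_csv(outdir / "rtc.tsv", sep="\t", index=False, na_rep=".")
        manifest["stages"]["rtc"] = {
            "n_signals": int(len(rtc_tab)),
            "n_colocalised": int(rtc_tab["colocalised"].sum()) if len(rtc_tab) else 0,
        }
        record(stage, outdir / "rtc.tsv")
        log.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        # --- MR -------------------------------------------------------------
        stage = "mr"
        t0 = time.perf_counter()
        mr_out: dict = {"run": False}
        if driver is not None:
            gene_res = meta[meta["gene"] == driver].dropna(subset=["p_meta"])
            gene_res = gene_res.rename(columns={"p_meta": "p"})
            try:
                snps = mr.select_instruments(
                    gene_res, panel, r2_max=config.mr_r2_max, p_max=config.mr_p_max
                )
            except ValueError:
                snps = []
            if len(snps) >= 3:
                exposure = (
                    gene_res.set_index("snp")
                    .loc[snps, ["beta_meta", "se_meta"]]
                    .rename(columns={"beta_meta": "beta", "se_meta": "se"})
                )
                exposure["effect_allele"] = variants.loc[snps, "alt"].to_numpy()
                exposure["other_allele"] = variants.loc[snps, "ref"].to_numpy()
                outcome = gwas.loc[snps, ["effect_allele", "other_allele", "beta", "se"]]
                inst, _ = mr.harmonise(exposure, outcome, drop_palindromic=False)
                res = mr.run_mr(
                    inst, m=config.mr_m, n_boot=config.mr_bootstrap,
                    seed=config.seed,
                )
                mr_out = {
                    "run": True, "gene": driver,
                    "estimates": [dataclasses.asdict(e) for e in res["estimates"]],
                    "sensitivity": res["sensitivity"],
                    "verdict": res["verdict"],
                }
        manifest["stages"]["mr"] = mr_out
        io.dump_json(mr_out, outdir / "mr.json")
        record(stage, outdir / "mr.json")
        log.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        # --- expression-phenotype meta --------------------------------------
        stage = "expr_meta"
        t0 = time.perf_counter()
        em: dict = {"run": False}
        if driver is not None:
            studies = []
            for sd in (s1, s2):
                cols = sd.expression.columns
                r = float(np.corrcoef(
                    sd.expression.loc[driver].to_numpy(),
                    trait.loc[cols].to_numpy(),
                )[0, 1])
                studies.append({"r": r, "n": len(cols)})
            em = expr_meta.meta_analyse_gene(studies, mode="correlation", m=1)
            em["run"] = True
            em["gene"] = driver
        manifest["stages"]["expr_meta"] = em
        io.dump_json(em, outdir / "expr_meta.json")
        record(stage, outdir / "expr_meta.json")
        log.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

    except Exception:
        io.dump_json(manifest, outdir / "manifest.json")
        log.exception("pipeline failed at stage %r; partial outputs preserved", stage)
        raise

    io.dump_json(manifest, outdir / "manifest.json")
    return manifest
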