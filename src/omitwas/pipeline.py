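"""End-to-end pipeline driver: simulate -> preprocess -> associate -> report.

Every stage writes its artifacts plus a manifest (parameters and SHA-256
hashes of inputs/outputs), so identical inputs reproduce identical outputs
verifiably. Stage failures are re-raised as :class:`PipelineError` naming the
stage.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oio
from .mlm import run_trait
from .multiplicity import genomic_inflation, bh_adjust, phenotype_correlations, pick_candidates
from .preprocess import build_expression, qc_phenotypes
from .synth import SimConfig, simulate_counts, simulate_phenotypes

__all__ = ["PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage: {stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-labelled, not swallowed
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


@_stage("simulate")
def _simulate(cfg: oio.RunConfig, outdir: Path):
    sim = SimConfig(**cfg.simulate)
    counts = simulate_counts(sim)
    pheno, truth = simulate_phenotypes(counts, sim)
    counts_path = outdir / "counts.tsv"
    pheno_path = outdir / "phenotypes.tsv"
    oio.write_counts(counts, counts_path)
    oio.write_phenotypes(pheno, pheno_path)
    oio.write_truth(truth, sim, outdir)
    import yaml

    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(sim.to_dict(), fh, sort_keys=True)
    oio.write_manifest(
        outdir, "simulate", sim.to_dict(), {},
        {"counts": counts_path, "phenotypes": pheno_path},
    )
    return counts, pheno, counts_path, pheno_path


@_stage("preprocess")
def _preprocess(cfg: oio.RunConfig, counts, pheno, counts_path, pheno_path, outdir: Path):
    expr = build_expression(
        counts, min_count=cfg.min_count, min_frac=cfg.min_frac,
        log_cpm=cfg.log_cpm, trim_m=cfg.trim_m, trim_a=cfg.trim_a,
    )
    qc_report = qc_phenotypes(pheno, k=cfg.mad_k)
    cpm_path = outdir / "cpm.tsv"
    df = pd.DataFrame(expr.cpm, columns=expr.sample_ids)
    df.insert(0, "gene_id", expr.gene_ids)
    df.to_csv(cpm_path, sep="\t", index=False, float_format="%.6g")
    report = {
        "n_genes_input": int(counts.n_genes),
        "n_genes_expressed": int(len(expr.gene_ids)),
        "norm_factors": {str(s): float(f) for s, f in zip(expr.sample_ids, expr.norm_factors)},
        "phenotype_qc": qc_report,
    }
    qc_path = outdir / "qc_report.json"
    with open(qc_path, "w") as fh:
        json.dump(report, fh, indent=2)
    oio.write_manifest(
        outdir, "preprocess",
        {k: getattr(cfg, k) for k in ("min_count", "min_frac", "mad_k", "log_cpm", "trim_m", "trim_a")},
        {"counts": counts_path, "phenotypes": pheno_path},
        {"cpm": cpm_path, "qc_report": qc_path},
    )
    return expr, report


@_stage("assoc")
def _assoc(cfg: oio.RunConfig, counts, pheno, traits, outdir: Path):
    results = {}
    meta = {}
    outputs = {}
    for trait in traits:
        res = run_trait(
            trait, counts, pheno,
            min_count=cfg.min_count, min_frac=cfg.min_frac, mad_k=cfg.mad_k,
            log_cpm=cfg.log_cpm, candidates=tuple(cfg.candidates),
            vc_mode=cfg.vc_mode, exclude_target=cfg.exclude_target,
        )
        path = outdir / f"assoc_{trait}.tsv"
        res.table.to_csv(path, sep="\t", index=False)
        results[trait] = res
        outputs[f"assoc_{trait}"] = path
        meta[trait] = {
            "n_samples": res.n_samples,
            "m_genes": res.m_genes,
            "fixed_effects_selected": res.model.selected,
            "sigma_o2": res.vc.sigma_o2,
            "sigma_e2": res.vc.sigma_e2,
            "polygenic_fraction": res.vc.ratio,
            "reml_converged": res.vc.converged,
            "vc_mode": cfg.vc_mode,
            "exclusion": res.model.exclusion_mode,
        }
    meta_path = outdir / "assoc_meta.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)
    outputs["assoc_meta"] = meta_path
    oio.write_manifest(
        outdir, "assoc",
        {"traits": list(traits), "vc_mode": cfg.vc_mode, "exclude_target": cfg.exclude_target},
        {}, outputs,
    )
    return results


@_stage("report")
def _report(cfg: oio.RunConfig, results, pheno, outdir: Path):
    outputs = {}
    inflation = {}
    for trait, res in results.items():
        tab = res.table[res.table["ok"]].copy()
        adj, sig = bh_adjust(tab["p"].to_numpy(), alpha=cfg.alpha, method=cfg.fdr_method)
        tab["p_adj"] = adj
        tab["significant"] = sig
        cand = pick_candidates(tab, k=cfg.top_k, alpha=cfg.alpha, trait=trait)
        infl = genomic_inflation(tab["p"].to_numpy(), ci_method=cfg.lambda_ci_method, seed=cfg.seed)
        inflation[trait] = {
            "lambda": infl.lam, "ci_low": infl.ci_low, "ci_high": infl.ci_high,
            "n_tests": infl.n_tests,
        }
        adj_path = outdir / f"assoc_{trait}_adjusted.tsv"
        tab.to_csv(adj_path, sep="\t", index=False)
        qq_path = outdir / f"qq_{trait}.tsv"
        pd.DataFrame(
            {"expected_neglog10p": infl.qq_expected, "observed_neglog10p": infl.qq_observed}
        ).to_csv(qq_path, sep="\t", index=False, float_format="%.6g")
        top_path = outdir / f"top{cfg.top_k}_{trait}.txt"
        cand.top_k["gene_id"].to_csv(top_path, index=False, header=False)
        sig_path = outdir / f"significant_{trait}.tsv"
        cand.significant.to_csv(sig_path, sep="\t", index=False)
        outputs.update({
            f"adjusted_{trait}": adj_path, f"qq_{trait}": qq_path,
            f"top_{trait}": top_path, f"significant_{trait}": sig_path,
        })
    infl_path = outdir / "inflation.json"
    with open(infl_path, "w") as fh:
        json.dump(inflation, fh, indent=2)
    corr_path = outdir / "phenotype_correlations.tsv"
    phenotype_correlations(pheno).to_csv(corr_path, sep="\t", index=False, float_format="%.6g")
    outputs.update({"inflation": infl_path, "correlations": corr_path})
    oio.write_manifest(
        outdir, "report",
        {"alpha": cfg.alpha, "top_k": cfg.top_k, "fdr_method": cfg.fdr_method,
         "lambda_ci_method": cfg.lambda_ci_method},
        {}, outputs,
    )
    return inflation


def run_pipeline(cfg: oio.RunConfig) -> dict:
    """Run every configured stage; returns a summary dict of key outputs."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.simulate is not None:
        counts, pheno, counts_path, pheno_path = _simulate(cfg, outdir)
    else:
        try:
            counts = oio.read_counts(cfg.counts)
            pheno = oio.read_phenotypes(cfg.phenotypes)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("read", exc) from exc
        counts_path, pheno_path = Path(cfg.counts), Path(cfg.phenotypes)
    _preprocess(cfg, counts, pheno, counts_path, pheno_path, outdir)
    traits = cfg.traits if cfg.traits else list(pheno.traits)
    results = _assoc(cfg, counts, pheno, traits, outdir)
    inflation = _report(cfg, results, pheno, outdir)
    return {
        "outdir": str(outdir),
        "traits": {
            t: {
                "n_samples": results[t].n_samples,
                "m_genes": results[t].m_genes,
                "lambda": inflation[t]["lambda"],
            }
            for t in results
        },
    }
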