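"""TSV/JSON/YAML file formats and run configuration.

Conventions: expression data are TSV with genes as rows (first column
``gene_id``, remaining columns sample ids); phenotypes are TSV with samples
as rows (``sample_id``, ``sex``, ``season``, one column per trait, empty cell
= missing). Everything is plain text and round-trips exactly.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import CountMatrix, PhenotypeTable
from .synth import SimConfig, TruthTable

__all__ = [
    "RunConfig",
    "read_counts",
    "write_counts",
    "read_phenotypes",
    "write_phenotypes",
    "write_truth",
    "read_run_config",
    "sha256_file",
    "write_manifest",
]


@dataclass
class RunConfig:
    """Full pipeline configuration (see the YAML schema in the README)."""

    outdir: str
    counts: str | None = None
    phenotypes: str | None = None
    simulate: dict | None = None            # SimConfig fields, or None to use files
    traits: list | None = None              # default: all traits in the phenotype table
    candidates: list = field(default_factory=lambda: ["sex", "season"])
    min_count: int = 2
    min_frac: float = 0.30
    mad_k: float = 3.5
    log_cpm: bool = False
    trim_m: float = 0.30
    trim_a: float = 0.05
    vc_mode: str = "global_reml_plus_downdate"
    exclude_target: bool = True
    alpha: float = 0.05
    top_k: int = 20
    fdr_method: str = "bh"
    lambda_ci_method: str = "order_stat"
    seed: int = 0

    def validate(self) -> None:
        if self.simulate is None and (self.counts is None or self.phenotypes is None):
            raise ValueError("config must provide either 'simulate' or both 'counts' and 'phenotypes'")
        for name, lo, hi in (("min_frac", 0, 1), ("alpha", 0, 1), ("trim_m", 0, 0.5), ("trim_a", 0, 0.5)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name} must lie in [{lo}, {hi}] (got {v})")
        if self.min_count < 0 or self.mad_k <= 0 or self.top_k < 1:
            raise ValueError("min_count must be >= 0, mad_k > 0, top_k >= 1")


def read_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} is not a YAML mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def read_counts(path) -> CountMatrix:
    """Read a genes x samples count TSV, validating integrality and ids."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise ValueError(f"{path}: empty or malformed count file")
    gene_col = df.columns[0]
    gene_ids = df[gene_col].to_numpy(dtype=object)
    dupes = pd.Series(gene_ids)[pd.Series(gene_ids).duplicated()].unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicated gene id {dupes[0]!r}")
    sample_ids = np.asarray(df.columns[1:], dtype=object)
    raw = df.iloc[:, 1:].to_numpy()
    counts = np.empty(raw.shape, dtype=np.int64)
    for j, col in enumerate(df.columns[1:]):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() | (parsed != np.floor(parsed.fillna(0)))
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-integer count at gene {gene_ids[i]!r}, sample {col!r} "
                f"(value {raw[i, j]!r})"
            )
        counts[:, j] = parsed.to_numpy(dtype=np.int64)
    return CountMatrix(gene_ids=gene_ids, sample_ids=sample_ids, counts=counts)


def write_counts(cm: CountMatrix, path) -> None:
    df = pd.DataFrame(cm.counts, columns=cm.sample_ids)
    df.insert(0, "gene_id", cm.gene_ids)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path, covariates=("sex", "season")) -> PhenotypeTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[0] == 0 or df.columns[0] != "sample_id":
        raise ValueError(f"{path}: phenotype file must start with a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated sample id {dup!r}")
    df = df.set_index("sample_id")
    covariates = [c for c in covariates if c in df.columns]
    traits = [c for c in df.columns if c not in covariates]
    for t in traits:
        parsed = pd.to_numeric(df[t], errors="coerce")
        bad = parsed.isna() & df[t].notna() & (df[t].str.strip() != "")
        if bad.any():
            sid = df.index[np.flatnonzero(bad.to_numpy())[0]]
            raise ValueError(
                f"{path}: non-numeric value {df.loc[sid, t]!r} for trait {t!r}, sample {sid!r}"
            )
        df[t] = parsed
    return PhenotypeTable(data=df, traits=traits, covariates=covariates)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.data.to_csv(path, sep="\t", index=True, index_label="sample_id")


def write_truth(truth: TruthTable, config: SimConfig, outdir) -> dict:
    """Write the ground-truth record (gene effects TSV + summary JSON).

    Kept in separate files so analysis stages can prove they never read it.
    """
    outdir = Path(outdir)
    rows = []
    for trait in config.traits:
        causal = set(truth.causal_gene_ids[trait])
        cmap = dict(zip(truth.causal_gene_ids[trait], truth.causal_effects[trait]))
        for g, u in zip(truth.polygenic_gene_ids, truth.polygenic_effects[trait]):
            rows.append((trait, g, int(g in causal), cmap.get(g, 0.0), u))
    pd.DataFrame(
        rows, columns=["trait", "gene_id", "is_causal", "causal_effect", "polygenic_effect"]
    ).to_csv(outdir / "truth_effects.tsv", sep="\t", index=False)
    summary = {
        trait: {
            "causal_gene_ids": truth.causal_gene_ids[trait],
            "causal_effects": [float(b) for b in truth.causal_effects[trait]],
            "sigma_o2": truth.true_sigma_o2[trait],
            "sigma_e2": truth.true_sigma_e2[trait],
            "outlier_sample_ids": truth.outlier_sample_ids[trait],
        }
        for trait in config.traits
    }
    with open(outdir / "truth_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, stage: str, params: dict, inputs: dict, outputs: dict) -> Path:
    """Per-stage manifest: parameters plus input/output file hashes."""
    from . import __version__

    outdir = Path(outdir)
    manifest = {
        "stage": stage,
        "version": __version__,
        "parameters": params,
        "inputs": {k: sha256_file(v) for k, v in inputs.items()},
        "outputs": {k: sha256_file(v) for k, v in outputs.items()},
    }
    path = outdir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
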