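"""Plain-text readers and writers for the pipeline's interchange formats.

All formats are tab-separated text: a dosage matrix plus SNP map for
genotype panels, a gene/tissue expression table, SNP/CHR/BP/A1/A2/Z GWAS
summaries, commented-header weight files, square LD matrices with a SNP-id
header, and gene/chromosome/tissue/p_value/z_score association tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypePanel, LdMatrix, WeightSet, validate_gwas_summary
from .errors import InputError

ASSOC_COLUMNS = ["gene", "chromosome", "tissue", "p_value", "z_score", "n_snps", "model"]


def write_genotype_panel(panel: GenotypePanel, out_dir) -> dict[str, Path]:
    """Write ``dosages.tsv`` (individuals x SNPs) and ``snps.tsv`` (SNP map)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dosages = pd.DataFrame(panel.dosages, columns=panel.snp_ids)
    dosages.to_csv(out / "dosages.tsv", sep="\t", index=False, float_format="%g")
    snps = pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "chr": panel.chrom,
            "pos": panel.positions,
            "a1": panel.a1,
            "a2": panel.a2,
        }
    )
    snps.to_csv(out / "snps.tsv", sep="\t", index=False)
    return {"dosages": out / "dosages.tsv", "snps": out / "snps.tsv"}


def read_genotype_panel(in_dir) -> GenotypePanel:
    src = Path(in_dir)
    dosage_path, snp_path = src / "dosages.tsv", src / "snps.tsv"
    for p in (dosage_path, snp_path):
        if not p.exists():
            raise InputError(f"missing panel file: {p}")
    dosages = pd.read_csv(dosage_path, sep="\t")
    snps = pd.read_csv(snp_path, sep="\t")
    if list(dosages.columns) != list(snps["snp_id"]):
        raise InputError("dosage columns and SNP map disagree on SNP ids/order")
    return GenotypePanel(
        dosages=dosages.to_numpy(dtype=float),
        snp_ids=list(snps["snp_id"]),
        chrom=[str(c) for c in snps["chr"]],
        positions=snps["pos"].to_numpy(dtype=np.int64),
        a1=list(snps["a1"]),
        a2=list(snps["a2"]),
    )


def write_expression(expression: pd.DataFrame, path) -> Path:
    """Write a gene/tissue expression table (one row per gene-tissue)."""
    path = Path(path)
    expression.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_expression(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing expression file: {path}")
    return pd.read_csv(path, sep="\t")


def write_gwas_summary(summary: pd.DataFrame, path) -> Path:
    validate_gwas_summary(summary)
    path = Path(path)
    summary.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_gwas_summary(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing GWAS summary file: {path}")
    return validate_gwas_summary(pd.read_csv(path, sep="\t"))


def write_weight_set(weights: WeightSet, path) -> Path:
    """Weight TSV: gene/tissue/model/cv_r2 as comment lines, one row per SNP."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# gene={weights.gene}\n")
        fh.write(f"# tissue={weights.tissue}\n")
        fh.write(f"# model={weights.model}\n")
        fh.write(f"# cv_r2={weights.cv_r2:.6g}\n")
        fh.write(f"# n_folds={weights.n_folds}\n")
        fh.write("snp_id\tchr\tpos\ta1\ta2\tweight\n")
        for i, snp in enumerate(weights.snp_ids):
            fh.write(
                f"{snp}\t{weights.chrom[i]}\t{weights.positions[i]}\t"
                f"{weights.a1[i]}\t{weights.a2[i]}\t{weights.weights[i]:.8g}\n"
            )
    return path


def read_weight_set(path) -> WeightSet:
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing weight file: {path}")
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    from io import StringIO

    table = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    required = {"gene", "tissue", "model", "cv_r2"}
    if not required.issubset(meta):
        raise InputError(f"weight file header is missing {sorted(required - set(meta))}")
    return WeightSet(
        gene=meta["gene"],
        tissue=meta["tissue"],
        snp_ids=list(table["snp_id"]),
        chrom=[str(c) for c in table["chr"]],
        positions=table["pos"].to_numpy(dtype=np.int64),
        a1=list(table["a1"]),
        a2=list(table["a2"]),
        weights=table["weight"].to_numpy(dtype=float),
        model=meta["model"],
        cv_r2=float(meta["cv_r2"]),
        n_folds=int(meta.get("n_folds", 0)),
    )


def write_ld_matrix(ld: LdMatrix, path) -> Path:
    """Square correlation matrix with a SNP-id header row."""
    path = Path(path)
    pd.DataFrame(ld.values, columns=ld.snp_ids).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )
    return path


def read_ld_matrix(path) -> LdMatrix:
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing LD matrix file: {path}")
    table = pd.read_csv(path, sep="\t")
    return LdMatrix(list(table.columns), table.to_numpy(dtype=float), source=str(path))


def write_association(results: pd.DataFrame, path) -> Path:
    """Association TSV with the gene/chromosome/tissue/p_value/z_score layout."""
    path = Path(path)
    cols = [c for c in ASSOC_COLUMNS if c in results.columns]
    cols += [c for c in results.columns if c not in cols]
    results[cols].to_csv(path, sep="\t", index=False, float_format="%.8g")
    return path


def read_association(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing association file: {path}")
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene", "tissue", "p_value") if c not in table.columns]
    if missing:
        raise InputError(f"association file is missing columns {missing}")
    return table
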