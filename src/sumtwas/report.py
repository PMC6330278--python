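"""Multi-tissue aggregation, packaged result-table fixtures, and the
end-to-end pipeline driver.

The packaged fixtures hold the two published result tables of the
Alzheimer's-disease multi-tissue analysis this pipeline re-implements: the
strict (Bonferroni) gene list and the additional genes admitted by the
Benjamini-Hochberg procedure.  They are read-only data used to validate
unique-gene accounting and z/p internal consistency; no pipeline run ever
mutates them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .association import ld_from_panel, run_locus, zscore_to_pvalue
from .correction import CONVENTIONAL_M, annotate_calls, apply_per_tissue
from .datatypes import TISSUES, ArchitectureConfig, LocusConfig, MODEL_PRECEDENCE
from .errors import InputError, UntestableGeneError
from .simulate import simulate_study
from .weights import train_weight_set

logger = logging.getLogger(__name__)

#: Conventional strict significance threshold alpha / 15000.
STRICT_THRESHOLD = 0.05 / CONVENTIONAL_M


def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("sumtwas").joinpath(f"data/{name}").open("r") as fh:
        table = pd.read_csv(fh, sep="\t")
    table["p_value"] = table["p_value"].astype(float)
    table["z_score"] = table["z_score"].astype(float)
    return table


def load_table1() -> pd.DataFrame:
    """The 18 gene-tissue rows significant under the strict Bonferroni regime."""
    return _load_fixture("table1.tsv")


def load_table2() -> pd.DataFrame:
    """The 34 additional gene-tissue rows admitted by the BH procedure."""
    return _load_fixture("table2.tsv")


def count_unique_significant(
    rows: pd.DataFrame, threshold: float | None = None
) -> tuple[int, list[str]]:
    """Count distinct gene symbols among rows with p < threshold.

    With ``threshold=None`` every row counts.  A gene appearing in several
    tissue rows counts once.  Empty input yields 0.
    """
    if "gene" not in rows.columns or "p_value" not in rows.columns:
        raise InputError("rows must carry 'gene' and 'p_value' columns")
    sub = rows if threshold is None else rows[rows["p_value"] < threshold]
    genes = sorted(set(sub["gene"]))
    return len(genes), genes


def consistency_check(
    rows: pd.DataFrame, sig_figs: int = 3, rel_tol: float = 0.05
) -> pd.DataFrame:
    """Recompute p = 2·Φ(−|z|) from each row's z and flag disagreements.

    A row passes when the recomputed p matches the printed p to ``sig_figs``
    significant figures or within ``rel_tol`` relative tolerance (printed
    z-scores are often truncated, so a small slack is expected).
    """
    out = rows.copy()
    recomputed = np.array([zscore_to_pvalue(z) for z in out["z_score"]])
    out["p_recomputed"] = recomputed
    printed = out["p_value"].to_numpy(dtype=float)

    def _round_sig(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        mag = np.floor(np.log10(np.abs(x)))
        factor = 10.0 ** (sig_figs - 1 - mag)
        return np.round(x * factor) / factor

    same_sig = _round_sig(recomputed) == _round_sig(printed)
    rel_ok = np.abs(recomputed - printed) <= rel_tol * printed
    out["consistent"] = same_sig | rel_ok
    return out


@dataclass
class GeneReport:
    """Per-gene roll-up across tissues: hits, best p, and significance tiers."""

    gene: str
    chromosome: str
    hits: list[tuple[str, float, float]]
    best_p: float
    significant_under: set = field(default_factory=set)


def gene_reports(calls: pd.DataFrame) -> list[GeneReport]:
    """Aggregate an annotated association table into one record per gene."""
    reports = []
    for gene, sub in calls.groupby("gene", sort=True):
        hits = [
            (row.tissue, float(row.p_value), float(row.z_score))
            for row in sub.itertuples()
        ]
        tiers = set()
        if "significant" in sub.columns and "method" in sub.columns:
            for row in sub.itertuples():
                if getattr(row, "significant", False):
                    tiers.add(row.method)
        reports.append(
            GeneReport(
                gene=gene,
                chromosome=str(sub["chromosome"].iloc[0]) if "chromosome" in sub else "NA",
                hits=hits,
                best_p=float(sub["p_value"].min()),
                significant_under=tiers,
            )
        )
    return reports


def render_report(calls: pd.DataFrame, path=None, fmt: str = "tsv") -> str:
    """Render an association/calls table sorted by ascending p within tier.

    ``fmt`` is ``"tsv"`` or ``"markdown"``.  Rows are ordered significant
    tier first, then ascending p, then gene/tissue — deterministic across
    reruns.  Returns the rendered text; writes it to ``path`` when given.
    """
    if fmt not in ("tsv", "markdown"):
        raise InputError(f"unknown report format {fmt!r}")
    table = calls.copy()
    sort_cols, ascending = ["p_value"], [True]
    if "significant" in table.columns:
        sort_cols = ["significant", "p_value"]
        ascending = [False, True]
    for extra in ("gene", "tissue"):
        if extra in table.columns:
            sort_cols.append(extra)
            ascending.append(True)
    table = table.sort_values(sort_cols, ascending=ascending, kind="stable")
    table = table.reset_index(drop=True)
    if fmt == "tsv":
        text = table.to_csv(sep="\t", index=False)
    else:
        header = "| " + " | ".join(table.columns) + " |"
        sep = "| " + " | ".join("---" for _ in table.columns) + " |"
        rows = ["| " + " | ".join(str(v) for v in rec) + " |"
                for rec in table.itertuples(index=False)]
        text = "\n".join([header, sep, *rows]) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


DEFAULT_PIPELINE_CONFIG = {
    "seed": 0,
    "scenario": "A",
    "n_genes": 5,
    "tissues": list(TISSUES),
    "n_snps": 10,
    "maf_low": 0.05,
    "maf_high": 0.5,
    "ld_rho": 0.4,
    "n_causal_eqtl": 2,
    "cis_h2": 0.3,
    "trait_h2_via_expression": 0.0,
    "direct_snp_effect": 0.0,
    "n_ref": 500,
    "n_gwas": 5000,
    "model": "auto",
    "alpha": 0.05,
    "bonferroni_m": None,
    "ld_ridge": 0.1,
    "ld_source": "gwas",
}


def run_pipeline(config: dict, out_dir) -> dict:
    """Simulate → train weights → associate → correct → report, end to end.

    ``config`` overrides :data:`DEFAULT_PIPELINE_CONFIG`; unknown keys are an
    error.  Every stage output lands under ``out_dir`` together with a
    ``run_log.json`` recording the seed, alpha, m, LD ridge, model precedence
    and per-stage file paths, so a run is auditable and reruns with the same
    config are bit-identical.
    """
    unknown = set(config) - set(DEFAULT_PIPELINE_CONFIG)
    if unknown:
        raise InputError(f"unknown pipeline config key(s): {sorted(unknown)}")
    cfg = {**DEFAULT_PIPELINE_CONFIG, **config}
    if cfg["ld_source"] not in ("gwas", "reference"):
        raise InputError("ld_source must be 'gwas' or 'reference'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    arch = ArchitectureConfig(
        n_causal_eqtl=cfg["n_causal_eqtl"],
        cis_h2=cfg["cis_h2"],
        trait_h2_via_expression=cfg["trait_h2_via_expression"],
        scenario=cfg["scenario"],
        direct_snp_effect=cfg["direct_snp_effect"],
    )
    gene_seeds = np.random.default_rng(cfg["seed"]).integers(2**31, size=cfg["n_genes"])

    rows, untestable = [], []
    for g in range(cfg["n_genes"]):
        gene = f"GENE{g + 1:04d}"
        locus = LocusConfig(
            n_snps=cfg["n_snps"],
            maf_range=(cfg["maf_low"], cfg["maf_high"]),
            ld_rho=cfg["ld_rho"],
            seed=int(gene_seeds[g]),
        )
        study = simulate_study(
            locus, arch, n_ref=cfg["n_ref"], n_gwas=cfg["n_gwas"],
            tissues=tuple(cfg["tissues"]), gene=gene,
        )
        ld_panel = (
            study.gwas_panel if cfg["ld_source"] == "gwas"
            else next(iter(study.reference.values())).panel
        )
        ld = ld_from_panel(ld_panel, source=cfg["ld_source"])
        for tissue, ref in study.reference.items():
            try:
                wset = train_weight_set(
                    ref.panel, ref.expression, gene=gene, tissue=tissue,
                    model=cfg["model"], random_state=int(gene_seeds[g]),
                )
                result = run_locus(wset, study.gwas_summary, ld, ld_ridge=cfg["ld_ridge"])
            except UntestableGeneError as exc:
                untestable.append({"gene": gene, "tissue": tissue, "reason": str(exc)})
                continue
            rows.append(result.to_dict())

    assoc = pd.DataFrame(rows, columns=sio.ASSOC_COLUMNS)
    assoc_path = sio.write_association(assoc, out / "associations.tsv")

    paths = {"associations": str(assoc_path)}
    for method in ("bonferroni", "bh"):
        calls = annotate_calls(assoc, method=method, alpha=cfg["alpha"],
                               bonferroni_m=cfg["bonferroni_m"])
        p = out / f"calls_{method}.tsv"
        render_report(calls, path=p, fmt="tsv")
        paths[f"calls_{method}"] = str(p)

    log = {
        "seed": cfg["seed"],
        "alpha": cfg["alpha"],
        "bonferroni_m": cfg["bonferroni_m"],
        "ld_ridge": cfg["ld_ridge"],
        "ld_source": cfg["ld_source"],
        "model": cfg["model"],
        "model_precedence": list(MODEL_PRECEDENCE),
        "cis_window_kb": 500,
        "scenario": cfg["scenario"],
        "n_genes": cfg["n_genes"],
        "tissues": list(cfg["tissues"]),
        "n_untestable": len(untestable),
        "untestable": untestable,
        "outputs": paths,
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
    paths["run_log"] = str(log_path)
    logger.info("pipeline complete: %d associations, %d untestable gene-tissue pairs",
                len(assoc), len(untestable))
    return {"associations": assoc, "paths": paths, "log": log}
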