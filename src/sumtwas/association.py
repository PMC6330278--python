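"""Summary-statistic expression-trait association.

The imputed association z-score for a gene is

    z_twas = W·Z / sqrt(W·S·Wt)

where ``W`` are the trained expression weights, ``Z`` the per-SNP GWAS
z-scores, and ``S`` the SNP correlation (LD) matrix, which gives the variance
of the linear combination ``W·Z``.  Before the quadratic form, a finite-panel
LD estimate is shrunk toward the identity, ``S ← (1-λ)·S + λ·I``, to guard
near-singular denominators.  Two-sided p-values come from the normal tail via
a complementary-error-function path that stays accurate far beyond |z| = 8.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .datatypes import GenotypePanel, LdMatrix, TwasResult, WeightSet, validate_gwas_summary
from .errors import DegenerateVarianceError, InputError, NoOverlappingSnpsError

logger = logging.getLogger(__name__)

#: Default identity-shrinkage weight for finite-panel LD estimates.
DEFAULT_LD_RIDGE = 0.1

#: Quadratic forms below this are treated as degenerate (gene untestable).
DEGENERATE_VARIANCE_TOL = 1e-10

_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}

#: Smallest positive double; p-values never underflow to exactly 0.
_P_FLOOR = 5e-324


def zscore_to_pvalue(z: float) -> float:
    """Two-sided normal p-value 2·Φ(−|z|), numerically stable for large |z|."""
    if not math.isfinite(z):
        raise InputError(f"z-score must be finite, got {z}")
    p = math.erfc(abs(z) / math.sqrt(2.0))
    return max(p, _P_FLOOR)


def ld_from_panel(panel: GenotypePanel, source: str | None = None) -> LdMatrix:
    """Sample SNP-SNP correlation matrix from a genotype panel."""
    x = panel.standardized()
    s = x.T @ x / panel.n_individuals
    # monomorphic SNPs give zero rows; restore the unit diagonal
    np.fill_diagonal(s, 1.0)
    return LdMatrix(list(panel.snp_ids), s, source=source or "panel")


def regularize_ld(values: np.ndarray, ld_ridge: float) -> np.ndarray:
    """Shrink a correlation matrix toward the identity: (1-λ)·S + λ·I."""
    if not (0.0 <= ld_ridge <= 1.0):
        raise InputError("ld_ridge must be in [0, 1]")
    if ld_ridge == 0.0:
        return values
    return (1.0 - ld_ridge) * values + ld_ridge * np.eye(values.shape[0])


def harmonize(
    weights: WeightSet,
    summary: pd.DataFrame,
    drop_palindromic: bool = True,
) -> tuple[np.ndarray, np.ndarray, list[str], dict]:
    """Align a weight set with a GWAS summary table on SNP id and alleles.

    SNPs present in the weights but missing from the summary are dropped and
    the remaining weight vector is used as-is.  Where effect/other alleles
    are swapped between the two sources the GWAS z flips sign.
    Strand-ambiguous (A/T, C/G) SNPs are dropped by default; SNPs whose
    allele pairs do not match at all are dropped with a warning.

    Returns ``(w, z, snp_ids, info)`` where ``info`` counts the dropped and
    flipped SNPs.
    """
    validate_gwas_summary(summary)
    by_id = {row.SNP: row for row in summary.itertuples()}
    w_out, z_out, ids_out = [], [], []
    info = {"n_missing": 0, "n_palindromic": 0, "n_mismatch": 0, "n_flipped": 0}
    for i, snp in enumerate(weights.snp_ids):
        row = by_id.get(snp)
        if row is None:
            info["n_missing"] += 1
            continue
        wa1, wa2 = weights.a1[i], weights.a2[i]
        if drop_palindromic and frozenset((wa1, wa2)) in _PALINDROMIC:
            info["n_palindromic"] += 1
            continue
        if (row.A1, row.A2) == (wa1, wa2):
            z = float(row.Z)
        elif (row.A1, row.A2) == (wa2, wa1):
            z = -float(row.Z)
            info["n_flipped"] += 1
        else:
            info["n_mismatch"] += 1
            continue
        w_out.append(weights.weights[i])
        z_out.append(z)
        ids_out.append(snp)
    if not ids_out:
        raise NoOverlappingSnpsError(
            f"no overlapping SNPs between weights for {weights.gene} and the GWAS summary"
        )
    dropped = info["n_missing"] + info["n_palindromic"] + info["n_mismatch"]
    if dropped:
        logger.info(
            "%s/%s: dropped %d SNP(s) during harmonization (%s)",
            weights.gene, weights.tissue, dropped, info,
        )
    return np.asarray(w_out), np.asarray(z_out), ids_out, info


def impute_association(
    w: np.ndarray, z: np.ndarray, ld, ld_ridge: float = 0.0
) -> float:
    """The imputed z-score W·Z / sqrt(W·S·Wt).

    ``ld`` may be an :class:`LdMatrix` or a raw correlation matrix; the
    identity shrinkage ``ld_ridge`` is applied before the quadratic form.
    Raises :class:`DegenerateVarianceError` when the variance of W·Z is
    numerically zero (e.g. w = (1, −1) on perfectly correlated SNPs).
    """
    w = np.asarray(w, dtype=float)
    z = np.asarray(z, dtype=float)
    values = ld.values if isinstance(ld, LdMatrix) else np.asarray(ld, dtype=float)
    if w.shape != z.shape or values.shape != (w.size, w.size):
        raise InputError("dimension mismatch between weights, z-scores and LD")
    s = regularize_ld(values, ld_ridge)
    variance = float(w @ s @ w)
    if variance <= DEGENERATE_VARIANCE_TOL:
        raise DegenerateVarianceError(
            f"variance of the imputed statistic is {variance:.3e}; gene untestable"
        )
    return float(w @ z / math.sqrt(variance))


def run_locus(
    weights: WeightSet,
    summary: pd.DataFrame,
    ld: LdMatrix,
    ld_ridge: float = DEFAULT_LD_RIDGE,
    drop_palindromic: bool = True,
) -> TwasResult:
    """Harmonize, impute and convert to a p-value for one gene.

    Composes :func:`harmonize` → :func:`impute_association` →
    :func:`zscore_to_pvalue`; errors from the components (no overlap,
    degenerate variance) propagate so untestable genes are reported rather
    than silently dropped.
    """
    w, z, snp_ids, _ = harmonize(weights, summary, drop_palindromic=drop_palindromic)
    sub = ld.subset(snp_ids)
    z_twas = impute_association(w, z, sub, ld_ridge=ld_ridge)
    return TwasResult(
        gene=weights.gene,
        tissue=weights.tissue,
        chromosome=weights.chrom[0] if weights.chrom else "NA",
        z_twas=z_twas,
        p_value=zscore_to_pvalue(z_twas),
        n_snps_used=len(snp_ids),
        model=weights.model,
    )
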