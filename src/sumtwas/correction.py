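"""Multiple-testing control: Bonferroni and Benjamini-Hochberg.

Two regimes are supported.  Bonferroni rejects tests with p < α/m; by default
m is the realized number of tests, with an option to fix m = 15000, the
conventional transcriptome-wide denominator.  The Benjamini-Hochberg step-up
procedure sorts p-values ascending, finds the largest rank k with
P_k ≤ (k/m)·α, and rejects ranks 1..k (including any intermediate p_i above
its own critical value).  Both procedures can be applied independently within
each tissue stratum of an association table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import CorrectionResult
from .errors import InputError

#: The conventional transcriptome-wide Bonferroni denominator.
CONVENTIONAL_M = 15000


def _check_pvalues(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise InputError("p-values must be one-dimensional")
    if p.size and (np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1):
        raise InputError("p-values must lie in [0, 1]")
    return p


def _labels_array(labels, n):
    if labels is None:
        return None
    labels = list(labels)
    if len(labels) != n:
        raise InputError("labels length must match the number of p-values")
    return labels


def bonferroni(
    pvalues,
    alpha: float = 0.05,
    m: int | None = None,
    labels=None,
    tissue: str | None = None,
) -> CorrectionResult:
    """Family-wise error control: reject tests with p < alpha/m.

    ``m`` defaults to the number of tests supplied; pass ``m=15000`` to
    reproduce the conventional fixed transcriptome-wide denominator.
    """
    p = _check_pvalues(pvalues)
    if not (0.0 < alpha < 1.0):
        raise InputError("alpha must be in (0, 1)")
    m_eff = int(m) if m is not None else p.size
    if m_eff < 1:
        raise InputError("m must be >= 1")
    threshold = alpha / m_eff
    reject = p < threshold
    lab = _labels_array(labels, p.size)
    rejected = (
        [lab[i] for i in np.nonzero(reject)[0]]
        if lab is not None
        else list(np.nonzero(reject)[0])
    )
    return CorrectionResult(
        method="bonferroni", alpha=alpha, m=m_eff, threshold_or_k=threshold,
        reject=reject, rejected=rejected, tissue=tissue,
    )


def benjamini_hochberg(
    pvalues,
    alpha: float = 0.05,
    labels=None,
    tissue: str | None = None,
) -> CorrectionResult:
    """Step-up false-discovery-rate control.

    Sorts p ascending (ties broken stably, by (p, label) when labels are
    supplied), finds the largest rank k with P_k ≤ (k/m)·α, and rejects
    ranks 1..k.  An empty input yields an empty result.
    """
    p = _check_pvalues(pvalues)
    if not (0.0 < alpha < 1.0):
        raise InputError("alpha must be in (0, 1)")
    m = p.size
    lab = _labels_array(labels, m)
    if m == 0:
        return CorrectionResult(
            method="bh", alpha=alpha, m=0, threshold_or_k=0,
            reject=np.zeros(0, dtype=bool), rejected=[], tissue=tissue,
        )
    if lab is not None:
        order = sorted(range(m), key=lambda i: (p[i], lab[i]))
        order = np.asarray(order)
    else:
        order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    below = p[order] <= ranks / m * alpha
    k_star = int(np.nonzero(below)[0][-1] + 1) if below.any() else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    rejected = (
        [lab[i] for i in order[:k_star]] if lab is not None else list(order[:k_star])
    )
    return CorrectionResult(
        method="bh", alpha=alpha, m=m, threshold_or_k=k_star,
        reject=reject, rejected=rejected, tissue=tissue,
    )


def apply_per_tissue(
    results: pd.DataFrame,
    method: str = "bh",
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
    tissues=None,
) -> dict[str, CorrectionResult]:
    """Apply a correction independently within each tissue stratum.

    ``results`` must carry ``gene``, ``tissue`` and ``p_value`` columns.
    ``tissues`` optionally restricts the call to named strata; an unknown
    label raises an error.  Returns ``{tissue: CorrectionResult}`` with
    (gene, tissue) pairs in each rejection set.
    """
    for col in ("gene", "tissue", "p_value"):
        if col not in results.columns:
            raise InputError(f"association table is missing column {col!r}")
    if method not in ("bonferroni", "bh"):
        raise InputError(f"method must be 'bonferroni' or 'bh', got {method!r}")
    present = list(dict.fromkeys(results["tissue"]))
    if tissues is not None:
        unknown = [t for t in tissues if t not in present]
        if unknown:
            raise InputError(f"unknown tissue label(s) in filter request: {unknown}")
        present = [t for t in present if t in set(tissues)]
    out: dict[str, CorrectionResult] = {}
    for tissue in present:
        sub = results[results["tissue"] == tissue]
        labels = list(zip(sub["gene"], sub["tissue"]))
        if method == "bonferroni":
            out[tissue] = bonferroni(
                sub["p_value"], alpha=alpha, m=bonferroni_m, labels=labels, tissue=tissue
            )
        else:
            out[tissue] = benjamini_hochberg(
                sub["p_value"], alpha=alpha, labels=labels, tissue=tissue
            )
    return out


def annotate_calls(
    results: pd.DataFrame,
    method: str = "bh",
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
) -> pd.DataFrame:
    """Return a copy of the association table with method/threshold/significant columns."""
    per_tissue = apply_per_tissue(results, method=method, alpha=alpha,
                                  bonferroni_m=bonferroni_m)
    out = results.copy()
    out["method"] = method
    out["threshold"] = np.nan
    out["significant"] = False
    for tissue, res in per_tissue.items():
        mask = out["tissue"] == tissue
        out.loc[mask, "threshold"] = res.threshold_or_k
        out.loc[mask, "significant"] = res.reject
    return out
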