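"""Synthetic genotype / expression / trait / GWAS-summary generator.

Every downstream stage of the pipeline (weight training, summary-statistic
association, multiple-testing correction) is exercised on data from this
module, so it is built for exactness where exactness makes tests sharp:

* Genotypes are drawn by thresholding correlated latent Gaussians per
  haplotype and summing two haplotypes, which gives exact control of the
  allele frequency.  Thresholding attenuates correlation, so the latent
  adjacent-pair correlations are solved by tetrachoric inversion to make the
  *dosage* correlation of adjacent SNPs hit ``ld_rho``; correlation decays
  AR(1)-style with distance.
* Expression is built from a sparse set of causal eQTLs whose effect sizes
  are rescaled so the realized in-sample R² between the genetic value and
  expression equals ``cis_h2`` exactly — no replicate-to-replicate
  heritability jitter.
* Traits follow one of eight causal scenarios (A–H).  Under the null modes
  A–D every trait component is orthogonalized in-sample against the gene's
  genetic expression value, making the null exact rather than approximate.

All randomness flows from explicit seeds; identical seeds give byte-identical
output.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .datatypes import (
    ArchitectureConfig,
    GenotypePanel,
    LocusConfig,
    SimulatedStudy,
    TissuePanel,
    TruthRecord,
    validate_gwas_summary,
)
from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

# Non-complementary allele pairs only: the generator never emits palindromic
# (A/T, C/G) SNPs, so strand-ambiguity filtering cannot silently thin
# synthetic loci.
_ALLELE_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(40)

#: MAFs are snapped to this grid so tetrachoric solves cache across loci.
_MAF_GRID = 0.005

#: Cap for the latent correlation; beyond this the bivariate CDF quadrature
#: and the haplotype recursion both degrade numerically.
_MAX_LATENT_R = 0.9995


def _bvn_p11(t1: float, t2: float, r: float) -> float:
    """P(Z1 < t1, Z2 < t2) for standard bivariate normal with correlation r.

    Uses the single-integral representation
    Phi2(t1, t2; r) = Phi(t1)Phi(t2) + (1/2pi) ∫_0^r exp(...) ds
    evaluated by Gauss-Legendre quadrature.
    """
    base = norm.cdf(t1) * norm.cdf(t2)
    if r == 0.0:
        return base
    s = 0.5 * r * (_GL_NODES + 1.0)
    w = 0.5 * r * _GL_WEIGHTS
    expo = -(t1 * t1 - 2.0 * s * t1 * t2 + t2 * t2) / (2.0 * (1.0 - s * s))
    integral = float(np.sum(w * np.exp(expo) / np.sqrt(1.0 - s * s))) / (2.0 * np.pi)
    return base + integral


@lru_cache(maxsize=None)
def _latent_adjacent_corr(maf1: float, maf2: float, rho: float) -> float:
    """Latent-Gaussian correlation giving allele (hence dosage) correlation rho.

    Solves the tetrachoric equation phi(r) = rho for two thresholded standard
    normals with thresholds Phi^-1(maf).  If rho exceeds the attainable bound
    for this MAF pair the latent correlation is capped at its maximum and a
    warning is logged once per pair.
    """
    if rho == 0.0:
        return 0.0
    t1, t2 = norm.ppf(maf1), norm.ppf(maf2)
    denom = np.sqrt(maf1 * (1 - maf1) * maf2 * (1 - maf2))

    def gap(r: float) -> float:
        return (_bvn_p11(t1, t2, r) - maf1 * maf2) / denom - rho

    if gap(_MAX_LATENT_R) < 0:
        logger.warning(
            "adjacent dosage correlation %.3f unattainable for MAF pair (%.3f, %.3f); "
            "capping at the tetrachoric bound", rho, maf1, maf2,
        )
        return _MAX_LATENT_R
    return float(brentq(gap, 0.0, _MAX_LATENT_R, xtol=1e-8))


class _LocusPopulation:
    """Frozen population-level parameters of a locus (MAFs, thresholds, LD)."""

    __slots__ = ("cfg", "mafs", "thresholds", "latent_r", "snp_ids", "a1", "a2")

    def __init__(self, cfg: LocusConfig, rng: np.random.Generator):
        lo, hi = cfg.maf_range
        raw = rng.uniform(lo, hi, size=cfg.n_snps)
        mafs = np.clip(np.round(raw / _MAF_GRID) * _MAF_GRID, lo, hi)
        self.cfg = cfg
        self.mafs = mafs
        self.thresholds = norm.ppf(mafs)
        self.latent_r = np.array(
            [
                _latent_adjacent_corr(float(mafs[j - 1]), float(mafs[j]), cfg.ld_rho)
                for j in range(1, cfg.n_snps)
            ]
        )
        pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=cfg.n_snps)
        self.a1 = [_ALLELE_PAIRS[i][0] for i in pair_idx]
        self.a2 = [_ALLELE_PAIRS[i][1] for i in pair_idx]
        self.snp_ids = [f"snp{j + 1:04d}" for j in range(cfg.n_snps)]

    def draw_panel(self, n_individuals: int, rng: np.random.Generator) -> GenotypePanel:
        m = self.cfg.n_snps
        latent = rng.standard_normal((2 * n_individuals, m))
        for j in range(1, m):
            r = self.latent_r[j - 1]
            if r != 0.0:
                latent[:, j] = r * latent[:, j - 1] + np.sqrt(1.0 - r * r) * latent[:, j]
        alleles = latent < self.thresholds  # P(allele) = maf exactly
        dosages = (
            alleles[:n_individuals].astype(float) + alleles[n_individuals:].astype(float)
        )
        return GenotypePanel(
            dosages=dosages,
            snp_ids=list(self.snp_ids),
            chrom=[self.cfg.chrom] * m,
            positions=self.cfg.resolved_positions(),
            a1=list(self.a1),
            a2=list(self.a2),
            mafs=self.mafs.copy(),
        )


def simulate_genotypes(
    cfg: LocusConfig, n_individuals: int, rng: np.random.Generator | None = None
) -> GenotypePanel:
    """Draw a dosage matrix for one cis locus.

    Dosages are in {0, 1, 2}; per-SNP allele frequencies land on the
    configured MAF grid and adjacent-SNP dosage correlations target
    ``cfg.ld_rho``.  Population parameters (MAFs, LD targets, alleles) are a
    deterministic function of ``cfg.seed``; pass ``rng`` to draw an
    independent cohort from the *same* population.
    """
    if n_individuals < 2:
        raise ConfigurationError("n_individuals must be >= 2")
    pop_rng, draw_rng = _spawn(cfg.seed, 2)
    pop = _LocusPopulation(cfg, pop_rng)
    return pop.draw_panel(n_individuals, rng if rng is not None else draw_rng)


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _center(v: np.ndarray) -> np.ndarray:
    return v - v.mean()


def _orthogonalize(v: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    for b in basis:
        nb = float(b @ b)
        if nb > 0:
            v = v - b * (float(b @ v) / nb)
    return v


def _expression_from_beta(
    panel: GenotypePanel,
    causal_idx: np.ndarray,
    beta: np.ndarray,
    cis_h2: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Expression vector with realized genetic R² equal to cis_h2 exactly."""
    n = panel.n_individuals
    weights = np.zeros(panel.n_snps)
    if cis_h2 > 0:
        weights[causal_idx] = beta
    x = panel.standardized()
    g = _center(x @ weights)
    norm_g = np.linalg.norm(g)
    if cis_h2 > 0:
        if norm_g == 0:
            raise ConfigurationError(
                "causal SNPs are monomorphic in this cohort; cannot realize cis_h2 > 0"
            )
        scale = np.sqrt(cis_h2 * n) / norm_g
        g = g * scale
        weights = weights * scale
    else:
        g = np.zeros(n)
    noise = _orthogonalize(_center(rng.standard_normal(n)), [g])
    if cis_h2 < 1:
        noise = noise * (np.sqrt((1.0 - cis_h2) * n) / np.linalg.norm(noise))
    else:
        noise = np.zeros(n)
    return g + noise, weights


def simulate_expression(
    panel: GenotypePanel,
    arch: ArchitectureConfig,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate one gene's expression on a genotype panel.

    Returns ``(expression, true_weights, causal_idx)`` where ``true_weights``
    is the causal effect vector on the standardized-dosage scale.  The
    in-sample R² between the genetic value and expression equals
    ``arch.cis_h2`` exactly by construction.
    """
    if arch.n_causal_eqtl > panel.n_snps:
        raise ConfigurationError("n_causal_eqtl cannot exceed the number of SNPs")
    if rng is None:
        rng = np.random.default_rng(seed)
    causal = np.sort(rng.choice(panel.n_snps, size=arch.n_causal_eqtl, replace=False))
    beta = rng.standard_normal(arch.n_causal_eqtl)
    expression, weights = _expression_from_beta(panel, causal, beta, arch.cis_h2, rng)
    return expression, weights, causal


def simulate_trait(
    gwas_panel: GenotypePanel,
    true_weights: np.ndarray,
    arch: ArchitectureConfig,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    causal_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate the GWAS trait under one of the eight causal scenarios.

    Scenario semantics (variance shares are exact in-sample):

    ========  ============================================================
    A         trait is pure noise
    B         trait loads on the *non-genetic* expression component only
    C         direct effect of a non-eQTL SNP (orthogonal to the genetic
              expression value)
    D         B + C combined
    E         mediation: trait loads on the genetic expression value with
              share ``trait_h2_via_expression``
    F         E + pleiotropic direct effect of a causal eQTL SNP
    G         E + direct effect of a linked non-eQTL SNP
    H         E + pleiotropic direct effect + environmental coupling
    ========  ============================================================

    Every *systematic* component (direct SNP effect, environmental coupling)
    is orthogonalized in-sample against the genetic expression value, so
    under A–D the trait's structural part is independent of it while the
    residual noise retains the natural O(1/sqrt(n)) sampling correlation —
    the fluctuation that gives downstream test statistics their proper null
    distribution.  Under E–H the mediated share is exact in-sample.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    scenario = arch.scenario
    x = gwas_panel.standardized()
    n = gwas_panel.n_individuals
    true_weights = np.asarray(true_weights, dtype=float)
    g = _center(x @ true_weights)
    g_has_var = float(g @ g) > 0

    components: list[tuple[np.ndarray, float]] = []
    if scenario in ("E", "F", "G", "H") and arch.trait_h2_via_expression > 0:
        if not g_has_var:
            logger.warning(
                "scenario %s requested mediation but the true genetic value has zero "
                "variance (cis_h2=0?); trait reduces to the null", scenario,
            )
        else:
            components.append((g, arch.trait_h2_via_expression))
    if scenario in ("C", "D", "F", "G", "H") and arch.direct_snp_effect > 0:
        causal = np.asarray(causal_idx, dtype=int) if causal_idx is not None else np.array([], int)
        if scenario in ("F", "H"):
            if causal.size == 0:
                raise ConfigurationError(
                    f"scenario {scenario} needs a causal eQTL for the pleiotropic effect"
                )
            j = int(causal[0])
        else:
            non_causal = np.setdiff1d(np.arange(gwas_panel.n_snps), causal)
            if non_causal.size == 0:
                raise ConfigurationError(
                    "no non-eQTL SNP available for the direct linkage effect"
                )
            j = int(rng.choice(non_causal))
        components.append((x[:, j].copy(), arch.direct_snp_effect))
    if scenario in ("B", "D", "H") and arch.env_share > 0:
        # Stand-in for the gene's non-genetic expression component in the
        # GWAS cohort (never observed downstream).
        components.append((rng.standard_normal(n), arch.env_share))

    total_share = sum(share for _, share in components)
    if total_share > 1.0 + 1e-12:
        raise ConfigurationError(
            f"trait variance shares sum to {total_share:.3f} > 1"
        )

    # systematic components are orthogonalized against g and each other;
    # the noise term is orthogonalized only against components actually in
    # the trait (never against g alone), preserving the natural sampling
    # correlation between a null trait and the genetic value
    ortho_basis: list[np.ndarray] = [g] if g_has_var else []
    added: list[np.ndarray] = []
    trait = np.zeros(n)
    for vec, share in components:
        v = _center(vec)
        if vec is not g:
            v = _orthogonalize(v, ortho_basis)
        nv = np.linalg.norm(v)
        if nv == 0:
            raise ConfigurationError("degenerate trait component (zero variance)")
        v = v * (np.sqrt(share * n) / nv)
        trait = trait + v
        added.append(v)
        if vec is not g:
            ortho_basis.append(v)
    noise = _orthogonalize(_center(rng.standard_normal(n)), added)
    residual_share = 1.0 - total_share
    if residual_share > 0:
        noise = noise * (np.sqrt(residual_share * n) / np.linalg.norm(noise))
        trait = trait + noise
    return trait


# t-statistic cap applied where a SNP is exactly collinear with the trait.
_COLLINEAR_Z_FACTOR = 1e6


def compute_gwas_summary(panel: GenotypePanel, trait: np.ndarray) -> pd.DataFrame:
    """Per-SNP marginal association z-scores of the trait on each dosage.

    The z-score is the Wald statistic of the simple regression of the
    standardized trait on the standardized dosage,
    ``z = r * sqrt((n - 2) / (1 - r^2))``.  Zero-variance SNPs are excluded
    with a logged warning.  Returns a SNP/CHR/BP/A1/A2/Z table.
    """
    trait = np.asarray(trait, dtype=float)
    if trait.shape[0] != panel.n_individuals:
        raise InputError("trait length must match the number of individuals")
    n = panel.n_individuals
    sd = panel.dosages.std(axis=0)
    keep = sd > 0
    n_dropped = int(np.count_nonzero(~keep))
    if n_dropped:
        dropped = [panel.snp_ids[i] for i in np.nonzero(~keep)[0]]
        logger.warning("excluding %d zero-variance SNP(s): %s", n_dropped, dropped)
    x = panel.standardized()[:, keep]
    y = _center(trait)
    y_sd = y.std()
    if y_sd == 0:
        raise InputError("trait has zero variance")
    y = y / y_sd
    r = x.T @ y / n
    r2 = np.minimum(r * r, 1.0 - 1e-12)
    z = r * np.sqrt((n - 2) / (1.0 - r2))
    collinear = r * r >= 1.0 - 1e-12
    if np.any(collinear):
        z[collinear] = np.sign(r[collinear]) * np.sqrt(n - 2) * _COLLINEAR_Z_FACTOR
    idx = np.nonzero(keep)[0]
    return validate_gwas_summary(
        pd.DataFrame(
            {
                "SNP": [panel.snp_ids[i] for i in idx],
                "CHR": [panel.chrom[i] for i in idx],
                "BP": panel.positions[idx],
                "A1": [panel.a1[i] for i in idx],
                "A2": [panel.a2[i] for i in idx],
                "Z": z,
            }
        )
    )


def simulate_study(
    locus: LocusConfig,
    arch: ArchitectureConfig,
    n_ref: int = 500,
    n_gwas: int = 5000,
    tissues: tuple[str, ...] = ("Brain (CMC) RNA-seq",),
    gene: str = "GENE1",
    seed: int | None = None,
) -> SimulatedStudy:
    """Simulate a full study for one gene: reference panels, GWAS cohort, summary.

    The reference panels (one per tissue) and the GWAS cohort are independent
    draws from the same locus population, so SNP identity, ordering and
    allele coding match across cohorts.  All tissues share the causal-eQTL
    set and effect directions; expression noise is tissue-independent.  The
    trait is built on the GWAS cohort from the shared true weights according
    to ``arch.scenario``.
    """
    if n_ref < 2 or n_gwas < 2:
        raise ConfigurationError("cohort sizes must be >= 2")
    effective_seed = locus.seed if seed is None else seed
    rngs = _spawn(effective_seed, 4 + len(tissues))
    pop_rng, arch_rng, gwas_rng, trait_rng = rngs[:4]
    pop = _LocusPopulation(locus, pop_rng)

    if arch.n_causal_eqtl > locus.n_snps:
        raise ConfigurationError("n_causal_eqtl cannot exceed the number of SNPs")
    causal = np.sort(arch_rng.choice(locus.n_snps, size=arch.n_causal_eqtl, replace=False))
    beta = arch_rng.standard_normal(arch.n_causal_eqtl)

    reference: dict[str, TissuePanel] = {}
    true_weights: dict[str, np.ndarray] = {}
    for tissue, rng_t in zip(tissues, rngs[4:]):
        panel_t = pop.draw_panel(n_ref, rng_t)
        expr_t, w_t = _expression_from_beta(panel_t, causal, beta, arch.cis_h2, rng_t)
        reference[tissue] = TissuePanel(panel=panel_t, expression=expr_t, true_weights=w_t)
        true_weights[tissue] = w_t

    gwas_panel = pop.draw_panel(n_gwas, gwas_rng)
    w_gwas = np.zeros(locus.n_snps)
    if arch.cis_h2 > 0:
        w_gwas[causal] = beta
    trait = simulate_trait(gwas_panel, w_gwas, arch, rng=trait_rng, causal_idx=causal)
    summary = compute_gwas_summary(gwas_panel, trait)

    truth = TruthRecord(
        scenario=arch.scenario,
        causal_idx=causal,
        beta=beta,
        true_weights=true_weights,
        gwas_weights=w_gwas,
    )
    return SimulatedStudy(
        locus=locus,
        arch=arch,
        gene=gene,
        reference=reference,
        gwas_panel=gwas_panel,
        trait=trait,
        gwas_summary=summary,
        truth=truth,
    )
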