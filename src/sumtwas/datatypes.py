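"""Core containers shared across the pipeline.

The pipeline moves data between four stages — genotype/expression simulation
(or ingestion), cis-weight training, summary-statistic association, and
multiple-testing correction — and these dataclasses are the contracts between
them.  GWAS summary statistics travel as a plain pandas ``DataFrame`` with the
conventional column layout ``SNP/CHR/BP/A1/A2/Z`` (``A1`` is the effect
allele); :func:`validate_gwas_summary` enforces that contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

#: The five expression panels of the multi-tissue study design.
TISSUES = (
    "Brain (CMC) RNA-seq",
    "Brain (CMC) RNA-seq splicing",
    "Whole Blood (YFS) RNA Array",
    "Peripheral Blood (NTR) RNA Array",
    "Adipose (METSIM) RNA-seq",
)

#: Causal-diagram scenario labels.  A–D are null modes (trait independent of
#: the gene's genetic expression component), E–H are alternative modes.
SCENARIOS = tuple("ABCDEFGH")
NULL_SCENARIOS = tuple("ABCD")
ALT_SCENARIOS = tuple("EFGH")

#: Model menu for cis expression prediction, in tie-break precedence order.
MODEL_PRECEDENCE = ("lasso", "enet", "blup_ridge", "top1")
MODELS = MODEL_PRECEDENCE + ("marginal_impg",)

GWAS_COLUMNS = ("SNP", "CHR", "BP", "A1", "A2", "Z")


@dataclass(frozen=True)
class LocusConfig:
    """Configuration of a simulated cis locus.

    Parameters
    ----------
    n_snps
        Number of SNPs at the locus.
    maf_range
        Inclusive bounds for per-SNP minor-allele frequencies, in (0, 0.5].
    ld_rho
        Target correlation between *adjacent* SNP dosages, in [0, 1).
        Correlation decays AR(1)-style with SNP distance.
    positions
        Strictly increasing 1-based base-pair coordinates; evenly spaced
        5 kb apart by default.
    seed
        Seed for every random draw tied to this locus.
    """

    n_snps: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.0
    positions: tuple[int, ...] | None = None
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(
                f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}"
            )
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigurationError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if self.positions is not None:
            pos = tuple(int(p) for p in self.positions)
            if len(pos) != self.n_snps:
                raise ConfigurationError("positions length must equal n_snps")
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ConfigurationError("positions must be strictly increasing")
            object.__setattr__(self, "positions", pos)

    def resolved_positions(self) -> np.ndarray:
        if self.positions is not None:
            return np.asarray(self.positions, dtype=np.int64)
        return 1_000_000 + 5_000 * np.arange(self.n_snps, dtype=np.int64)


@dataclass(frozen=True)
class ArchitectureConfig:
    """Genetic architecture of a gene and its causal relation to the trait.

    ``scenario`` selects one of eight causal modes; A–D are null (the trait is
    independent of the gene's genetic expression component), E–H are
    alternatives where the trait loads on it.  ``trait_h2_via_expression`` is
    the trait-variance share mediated through genetically predicted
    expression; it must be 0 under the null scenarios.  ``direct_snp_effect``
    is a trait-variance share attached to a single SNP directly (a pleiotropic
    causal eQTL in F/H, a linked non-eQTL SNP in C/D/G).  ``env_share`` is the
    trait-variance share coupled to the *non-genetic* expression component
    (scenarios B/D/H).
    """

    n_causal_eqtl: int = 1
    cis_h2: float = 0.2
    trait_h2_via_expression: float = 0.0
    scenario: str = "A"
    direct_snp_effect: float = 0.0
    env_share: float = 0.1

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if not (0.0 <= self.cis_h2 <= 1.0):
            raise ConfigurationError(f"cis_h2 must be in [0, 1], got {self.cis_h2}")
        if not (0.0 <= self.trait_h2_via_expression <= 1.0):
            raise ConfigurationError("trait_h2_via_expression must be in [0, 1]")
        if self.scenario in NULL_SCENARIOS and self.trait_h2_via_expression > 0:
            raise ConfigurationError(
                "null scenarios A-D imply zero expression-mediated trait effect; "
                "set trait_h2_via_expression=0"
            )
        if self.n_causal_eqtl < 0:
            raise ConfigurationError("n_causal_eqtl must be >= 0")
        if self.cis_h2 > 0 and self.n_causal_eqtl < 1:
            raise ConfigurationError("cis_h2 > 0 requires n_causal_eqtl >= 1")
        if not (0.0 <= self.direct_snp_effect < 1.0):
            raise ConfigurationError("direct_snp_effect is a variance share in [0, 1)")
        if not (0.0 <= self.env_share < 1.0):
            raise ConfigurationError("env_share is a variance share in [0, 1)")

    @property
    def is_null(self) -> bool:
        return self.scenario in NULL_SCENARIOS


@dataclass
class GenotypePanel:
    """Dosage matrix (individuals x SNPs) with SNP metadata for one cis locus."""

    dosages: np.ndarray
    snp_ids: list[str]
    chrom: list[str]
    positions: np.ndarray
    a1: list[str]
    a2: list[str]
    mafs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise InputError("dosages must be a 2-D individuals x SNPs matrix")
        m = self.dosages.shape[1]
        for name in ("snp_ids", "chrom", "a1", "a2"):
            if len(getattr(self, name)) != m:
                raise InputError(f"{name} length must equal the number of SNP columns")
        self.positions = np.asarray(self.positions, dtype=np.int64)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Sample frequency of the counted (a1) allele."""
        return self.dosages.mean(axis=0) / 2.0

    def standardized(self) -> np.ndarray:
        """Column-standardized dosages; monomorphic SNPs map to all-zero columns."""
        x = self.dosages
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        safe = np.where(sd > 0, sd, 1.0)
        z = (x - mu) / safe
        z[:, sd == 0] = 0.0
        return z


@dataclass
class WeightSet:
    """Per-gene SNP weight vector on the standardized-dosage scale.

    This is the W entering the imputed association statistic
    z = W·Z / sqrt(W·S·Wt).
    """

    gene: str
    tissue: str
    snp_ids: list[str]
    chrom: list[str]
    positions: np.ndarray
    a1: list[str]
    a2: list[str]
    weights: np.ndarray
    model: str
    cv_r2: float = float("nan")
    n_folds: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.snp_ids) != self.weights.size:
            raise InputError("weights and snp_ids must have equal length")
        if self.model not in MODELS:
            raise InputError(f"model must be one of {MODELS}, got {self.model!r}")
        if np.isfinite(self.cv_r2) and self.cv_r2 > 1.0 + 1e-12:
            raise InputError("cv_r2 cannot exceed 1")
        self.positions = np.asarray(self.positions, dtype=np.int64)

    @classmethod
    def from_panel(
        cls,
        panel: GenotypePanel,
        weights: np.ndarray,
        gene: str,
        tissue: str,
        model: str,
        cv_r2: float = float("nan"),
        n_folds: int = 0,
    ) -> "WeightSet":
        return cls(
            gene=gene,
            tissue=tissue,
            snp_ids=list(panel.snp_ids),
            chrom=list(panel.chrom),
            positions=panel.positions.copy(),
            a1=list(panel.a1),
            a2=list(panel.a2),
            weights=np.asarray(weights, dtype=float),
            model=model,
            cv_r2=cv_r2,
            n_folds=n_folds,
        )


@dataclass
class LdMatrix:
    """SNP correlation matrix Σ_s,s with its SNP-id ordering."""

    snp_ids: list[str]
    values: np.ndarray
    source: str = "unspecified"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.snp_ids)
        if self.values.shape != (m, m):
            raise InputError("LD matrix shape must match the SNP id list")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise InputError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-6):
            raise InputError("LD matrix must have a unit diagonal")

    def subset(self, snp_ids: Sequence[str]) -> "LdMatrix":
        index = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            idx = [index[s] for s in snp_ids]
        except KeyError as exc:  # pragma: no cover - defensive
            raise InputError(f"SNP {exc.args[0]!r} not present in LD matrix") from exc
        return LdMatrix(list(snp_ids), self.values[np.ix_(idx, idx)], self.source)


@dataclass
class TwasResult:
    """Imputed expression-trait association for one gene in one tissue."""

    gene: str
    tissue: str
    chromosome: str
    z_twas: float
    p_value: float
    n_snps_used: int
    model: str

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "chromosome": self.chromosome,
            "tissue": self.tissue,
            "p_value": self.p_value,
            "z_score": self.z_twas,
            "n_snps": self.n_snps_used,
            "model": self.model,
        }


@dataclass
class CorrectionResult:
    """Rejection set of one multiple-testing procedure on one test stratum.

    ``threshold_or_k`` is the p-value threshold alpha/m for Bonferroni and the
    step-up rank k* for Benjamini-Hochberg.  ``reject`` is a boolean mask in
    the original input order; ``rejected`` lists the rejected (gene, tissue)
    labels when labels were supplied, otherwise the rejected indices.
    """

    method: str
    alpha: float
    m: int
    threshold_or_k: float
    reject: np.ndarray
    rejected: list = field(default_factory=list)
    tissue: str | None = None

    @property
    def n_rejected(self) -> int:
        return int(np.count_nonzero(self.reject))


@dataclass
class TruthRecord:
    """Ground truth of one simulated gene: enough to score recovery."""

    scenario: str
    causal_idx: np.ndarray
    beta: np.ndarray
    true_weights: dict[str, np.ndarray]
    gwas_weights: np.ndarray


@dataclass
class TissuePanel:
    """Reference-panel slice for one tissue: genotypes plus measured expression."""

    panel: GenotypePanel
    expression: np.ndarray
    true_weights: np.ndarray


@dataclass
class SimulatedStudy:
    """A complete synthetic study for one gene across one or more tissues."""

    locus: LocusConfig
    arch: ArchitectureConfig
    gene: str
    reference: dict[str, TissuePanel]
    gwas_panel: GenotypePanel
    trait: np.ndarray
    gwas_summary: pd.DataFrame
    truth: TruthRecord


def validate_gwas_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Check the SNP/CHR/BP/A1/A2/Z column contract of a GWAS summary table."""
    missing = [c for c in GWAS_COLUMNS if c not in summary.columns]
    if missing:
        raise InputError(f"GWAS summary is missing columns {missing}")
    if summary["SNP"].duplicated().any():
        raise InputError("GWAS summary has duplicated SNP ids")
    z = summary["Z"].to_numpy(dtype=float)
    if not np.all(np.isfinite(z)):
        raise InputError("GWAS summary contains non-finite z-scores")
    return summary
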