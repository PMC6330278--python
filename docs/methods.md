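# Methods

## The statistic

For one gene in one tissue, let **W** be the vector of expression weights
over the SNPs of its cis locus (trained on a reference panel on the
standardized-dosage scale), **Z** the per-SNP marginal GWAS z-scores, and
**Σ** the SNP correlation (LD) matrix.  The linear combination W·Z has
variance W·Σ·Wᵗ under the null, so the imputed expression–trait z-score is

    z_TWAS = W·Z / sqrt(W·Σ·Wᵗ),   p = 2·Φ(−|z_TWAS|).

The p-value uses the complementary error function, which stays accurate far
beyond |z| = 8 (the pipeline's own significant genes reach |z| > 12); a
result is floored at the smallest positive double rather than underflowing
to zero.  z_TWAS is invariant to positive rescaling of W and flips sign
with it; when Σ = I it reduces to (W·Z)/‖W‖, and for a single-SNP gene it
equals the (sign-aligned) GWAS z of that SNP.

Before the quadratic form, a finite-panel LD estimate is shrunk toward the
identity, Σ ← (1−λ)·Σ + λ·I with λ = 0.1 by default (exposed everywhere as
`ld_ridge`).  The shrinkage guards near-singular denominators when LD comes
from a few hundred reference individuals; it deliberately perturbs the
algebraic identity between the summary statistic and the individual-level
regression, so the oracle-agreement check below runs with λ = 0.  A
quadratic form below 1e−10 marks the gene untestable
(`DegenerateVarianceError`) rather than producing an unstable z.

Harmonization between a weight set and a summary table matches SNPs by id,
flips the z sign when the effect/other alleles are swapped, drops
strand-ambiguous (A/T, C/G) SNPs by default, and drops SNPs missing from
the summary while reusing the remaining weights as-is (counts of all drops
are reported).  The LD reference is the analyst's choice — GWAS cohort or
expression panel — and is recorded in the run log.

## Weight training

Models: `top1` (the single best marginal eQTL's univariate coefficient),
`lasso` and `enet` (penalty path by inner 5-fold CV; elastic-net mixing
fixed at 0.5), `blup_ridge` (ridge on all cis SNPs over a 13-point alpha
grid, serving as the BLUP of the menu; sparse Bayesian mixture models are
out of scope), and the closed-form `marginal_impg` weights
Σ_es·(Σ_ss + λI)⁻¹, which with λ = 0 on a full-rank locus equal the
multi-SNP OLS fit.  The penalized fits are scikit-learn estimators behind
the module surface; the competition itself is the sklearn-compatible
`CisWeightsRegressor`.

Model scoring uses 5-fold cross-validation with seeded fold assignment
(fold count is a package choice); `cv_r2` is the squared Pearson
correlation between the concatenated held-out predictions and observed
expression, reported as 0 when predictions are degenerate.  The winner is
the candidate with maximal cv_r2; exact ties break by the fixed precedence
lasso > enet > blup_ridge > top1.  A gene whose best usable candidate has
cv_r2 ≤ 0.01 (or only all-zero weight vectors) is marked untestable and
excluded downstream with a logged reason — the floor avoids dividing by
near-zero predictive variance later.  Expected cv_r2 is bounded above by
the cis-heritability; training is invariant to affine rescaling of raw
expression because dosages and expression are standardized internally.
The cis window is defined as ±500 kb around the gene start (1-based,
inclusive); the synthetic loci are built directly at that scale.

## Multiple testing

Bonferroni rejects p < α/m, with m defaulting to the realized number of
tests; `m = 15000` reproduces the conventional fixed transcriptome-wide
denominator.  Benjamini–Hochberg sorts p ascending (ties broken stably by
(p, gene, tissue)), finds the largest rank k with P_k ≤ (k/m)·α, and
rejects ranks 1..k — including intermediate ranks above their own critical
value, per the step-up rule.  Both are applied independently within each
tissue stratum; pooled presentation happens only at the report layer.
BH's rejection set always contains Bonferroni's at equal α and m, and is
monotone non-decreasing in α; the implementation is verified against both
a literal O(m²) evaluation of the definition and
`statsmodels.stats.multitest.multipletests`.

## The synthetic study generator

The generator emulates the study design end-to-end: a cis locus shared by
a GWAS cohort and up to five named tissue reference panels, sparse eQTL
architectures, and one of eight causal scenarios.

**Genotypes.**  Each haplotype is a thresholded latent Gaussian sequence;
dosage = sum of two independent haplotypes.  Thresholding gives exact
control of the allele frequency (MAFs drawn uniformly from `maf_range` and
snapped to a 0.005 grid), but attenuates correlation, so the latent
adjacent-pair correlations are solved by tetrachoric inversion
(bivariate-normal quadrature + Brent root-finding, cached per MAF pair) so
that the *dosage* correlation of adjacent SNPs equals `ld_rho`; correlation
decays AR(1)-style with distance.  When `ld_rho` exceeds the attainable
bound for an extreme MAF pair the latent correlation is capped at the
bound with a logged warning.  Allele pairs are drawn from the
non-complementary set only, so palindromic-SNP filtering never silently
thins synthetic loci.

**Expression.**  `n_causal_eqtl` SNPs get i.i.d. normal effects, rescaled
in-sample so the realized R² between the genetic value g = X·w and
expression equals `cis_h2` exactly — replicate-to-replicate heritability
jitter would otherwise dominate the sharpest tests.  All tissues share the
causal set and effect directions; expression noise is tissue-independent.

**Traits.**  Scenario semantics (A–D null, E–H alternative):

| scenario | trait composition |
|---|---|
| A | pure noise |
| B | non-genetic expression component (share `env_share`, default 0.1) |
| C | direct effect of a non-eQTL SNP (share `direct_snp_effect`) |
| D | B + C |
| E | mediation through predicted expression (share `trait_h2_via_expression`) |
| F | E + pleiotropic direct effect of a causal eQTL |
| G | E + direct effect of a linked non-eQTL SNP |
| H | E + pleiotropic effect + environmental coupling |

Systematic components are orthogonalized in-sample against the genetic
expression value and against each other, so variance shares are exact and
the null modes are structurally null.  The residual noise is deliberately
*not* orthogonalized against the genetic value: a null trait must retain
its natural O(1/√n) sampling correlation with g, because that fluctuation
is exactly what gives z_TWAS its N(0,1) null distribution.  (An earlier
design that orthogonalized the noise too produced an empirical null std of
0.15 and zero type-I error — a useful reminder that "more exact" nulls can
be wrong nulls.)

**GWAS summaries.**  The per-SNP z is the Wald statistic of the simple
regression of the standardized trait on the standardized dosage,
z = r·√((n−2)/(1−r²)); zero-variance SNPs are excluded with a warning, and
an exactly collinear SNP is capped at sign(r)·√(n−2)·10⁶ so the statistic
stays finite and retains its √n growth.  At the default cohort sizes
(reference n = 500 ≪ GWAS n = 5000, mirroring the eQTL-panel/GWAS
asymmetry) the t-vs-normal distinction is negligible; far-tail quantities
at much smaller n are visibly t-inflated, which constrains how far the
validation studies below can be scaled down.

## Validation studies and their problem sizes

All sizes are package choices, exposed as parameters of
`sumtwas.calibration`:

* **Type-I calibration** — 1000 scenario-A loci (20 SNPs, ld_rho 0.4,
  cis_h2 0.4, lasso weights, n_ref 500, n_gwas 5000); the rejection rate at
  α = 0.05 is checked against the exact binomial 95% band around 0.05.
* **FDR control** — 50 replicates of a global-null five-tissue study with
  200 genes (6 SNPs per locus, marginal-ImpG weights, n_ref 200,
  n_gwas 2000).  BH is per tissue, so the measured quantity is the
  per-tissue FDP averaged over tissues and replicates — the union of five
  separately corrected strata is *not* FDR-controlled at α when the same
  gene's tests are correlated across tissues, and is not the metric.
  Under a global null E[FDP] equals α exactly (FDP is Bernoulli), so the
  check is one-sided at 1.96 binomial standard errors: "not significantly
  above α" is the strongest statistically meaningful finite-replicate form
  of the control property.  The pooled-Bonferroni family-wise error is
  checked the same way.
* **Oracle agreement** — 100 scenario-E loci at n_gwas = 5000 with LD from
  the GWAS cohort and λ = 0; summary z_TWAS must match the Wald z of
  regressing the trait on the weighted genetic score within 2% relative
  error on every locus (both are functions of the same sample correlations
  and differ only in O(r²) terms).
* **Weight recovery** — 20 replicates at cis_h2 = 0.5, n_ref = 500,
  3 causal SNPs among 20 (ld_rho 0.3); mean correlation between fitted
  lasso weights and the true causal vector must exceed 0.8.
* **BH fidelity** — 1000 random p-vectors: exact agreement with the
  brute-force step-up definition and dominance over Bonferroni.

## What the synthetic studies do and do not show

They establish internal statistical correctness: null calibration, FDR/FWER
control, the summary/individual-level identity, and recoverability of
sparse architectures under the generator's assumptions.  They do not
reproduce real LD (block structure, long-range LD, population structure,
relatedness are absent), imputation error, expression batch/covariate
structure (no PEER-style correction), allele-coding ambiguity beyond the
modeled swap/palindrome cases, or the discovery lists of any real
consortium analysis — those would require the actual GWAS summary data and
expression panels.  Conclusions about real-data performance are therefore
limited to the correctness of the machinery, not to expected yields.

## Degenerate inputs and numerical choices

Monomorphic SNPs: standardized to zero columns, excluded from summaries
with a warning.  Empty weight/summary SNP intersection: explicit error.
W·Σ·Wᵗ ≤ 1e−10: untestable, reported not dropped.  LD matrices are
validated for symmetry (1e−8) and unit diagonal (1e−6).  Bonferroni uses
strict `<`; BH uses `≤` at its critical values.  All randomness flows from
explicit integer seeds through `numpy.random.SeedSequence` spawning;
identical seeds give byte-identical outputs, and every pipeline run writes
a JSON log with seed, α, m, λ, cis window and model precedence.
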