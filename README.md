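# sumtwas

Summary-statistic transcriptome-wide association testing (TWAS) with a
fully synthetic multi-tissue study simulator.

A TWAS asks whether the *genetically predicted* expression of a gene is
associated with a trait, using only GWAS summary statistics.  Per-gene SNP
weights **W** are trained on a reference panel with both genotypes and
measured expression; given the per-SNP GWAS z-scores **Z** at the locus and
the SNP correlation (LD) matrix **Σ**, the imputed expression–trait z-score
is

```
z_TWAS = W·Z / sqrt(W·Σ·Wᵗ)
```

with a two-sided p-value `p = 2·Φ(−|z_TWAS|)`.  Genes are called significant
per tissue under either strict Bonferroni control (conventionally
`p < 0.05/15000`) or the Benjamini–Hochberg step-up FDR procedure (largest
rank *k* with `P_k ≤ (k/m)·α`).

The package is for statistical geneticists who want a compact, tested
implementation of this pipeline — weight training by cross-validated model
competition (top1 / lasso / elastic net / ridge-BLUP, plus closed-form
marginal ImpG-style weights `Σ_es·Σ_ss⁻¹`), allele harmonization, LD-aware
z-score combination, and per-tissue multiple-testing control — together with
a synthetic-data generator covering eight causal scenarios (null modes A–D,
alternative modes E–H), so every statistical property can be verified
end-to-end without access to consortium data.

## Worked example

```python
import numpy as np
from sumtwas import (
    ArchitectureConfig, LocusConfig, ld_from_panel,
    run_locus, simulate_study, train_weight_set,
)

# a mediated (scenario E) gene: 3 causal eQTLs, cis-h2 0.5, 5% of trait
# variance flowing through expression
locus = LocusConfig(n_snps=15, ld_rho=0.4, seed=202)
arch = ArchitectureConfig(n_causal_eqtl=3, cis_h2=0.5, scenario="E",
                          trait_h2_via_expression=0.05)
study = simulate_study(locus, arch, n_ref=500, n_gwas=5000)

tissue, ref = next(iter(study.reference.items()))
wset = train_weight_set(ref.panel, ref.expression, gene="GENE1", tissue=tissue)
print(f"model={wset.model} cv_r2={wset.cv_r2:.3f}")

ld = ld_from_panel(study.gwas_panel)
res = run_locus(wset, study.gwas_summary, ld)
print(f"z_twas={res.z_twas:.3f} p={res.p_value:.3g} n_snps={res.n_snps_used}")
```

Output:

```
model=enet cv_r2=0.492
z_twas=15.898 p=6.57e-57 n_snps=15
```

The competition picked the elastic net with cross-validated
R² ≈ 0.49 (the ceiling is the simulated cis-heritability of 0.5), and the
imputed association is overwhelming — as it should be with 5% of trait
variance mediated through this gene's expression at n = 5000.

The same stages are available from the shell:

```bash
sumtwas simulate --scenario E --seed 42 --out study/
sumtwas train-weights --panel study/panel_Brain_(CMC)_RNA-seq \
    --expression study/expression.tsv --tissue "Brain (CMC) RNA-seq" --out w.tsv
sumtwas assoc --weights w.tsv --sumstats study/gwas.tsv --ld study/gwas_panel --out assoc.tsv
sumtwas correct --assoc assoc.tsv --method bh --alpha 0.05 --out calls.tsv
sumtwas pipeline --config cfg.yaml --seed 1 --out run/
```

## Packaged result tables

The package ships the two published gene lists of the Alzheimer's-disease
multi-tissue analysis this pipeline re-implements
(`sumtwas.load_table1()`, 18 rows, and `sumtwas.load_table2()`, 34 rows) as
read-only fixtures.  They drive the unique-gene accounting (15 genes under
strict control; 29 additional genes under BH) and the internal z/p
consistency checks.

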