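# fasterx

Tools for **faster-X analysis** of gene expression and protein-coding
divergence between two closely related species.

In XY systems, population-genetic theory predicts the X chromosome can
evolve faster than the autosomes: the X is hemizygous in males (exposing
recessive variants to selection), carries 3/4 as many copies as an
autosome at an equal sex ratio, and spends 2/3 of its time in females.
But X-linked and autosomal genes also differ systematically in gene
properties that correlate with evolutionary rate — expression level,
tissue specificity, and the number of protein interactions — so an
apparent faster-X signal may be a by-product of gene properties rather
than hemizygosity. This package implements the statistical machinery to
separate the two explanations, and a synthetic-data generator to
exercise it end to end:

- **Expression properties** (`fasterx.exprprops`): per-gene expression
  level, between-species divergence and within-species polymorphism from
  replicated log2 measurements; the tissue-specificity index
  τ = Σᵢ (1 − x̂ᵢ)/(N − 1) with x̂ᵢ = xᵢ/maxⱼ xⱼ; male-/female-/nonsex-
  biased gene classification (MBG/FBG/NBG) by log2 fold change.
- **Coding-sequence divergence** (`fasterx.codonevol`): Nei–Gojobori
  (1986) counting of synonymous/nonsynonymous sites and differences with
  Jukes–Cantor correction, and maximum-likelihood dN/dS under a
  single-ω codon substitution model (one dN/dS for all sites and
  lineages) with F3×4 equilibrium frequencies; a consensus-site
  depth/quality filter (coverage > 7×, phred-scaled quality > 40); and
  the gene exclusion rules (internal stop codons, zero observed
  synonymous changes, ω ≥ 9).
- **Statistical battery** (`fasterx.stats`): Mann–Whitney U and Wilcoxon
  signed-rank tests with exact small-sample branches, Spearman ρ,
  standardized multiple regression (response and covariates z-scored;
  slopes b\*) with residual X-vs-A contrasts, and the 3-dimensional
  decile-stratified matched comparison: level, τ and interaction degree
  are each cut into 10 equal-size rank bins, genes land in combined
  (bin, bin, bin) categories, and per-category X-mean − A-mean response
  differences are tested with the signed-rank T.
- **Synthetic data** (`fasterx.simdata`): datasets with the genome-wide
  correlation structure the analysis assumes (divergence decreasing in
  level and interactions, increasing in τ) plus a configurable
  multiplicative faster-X inflation of X-linked MBG expression
  divergence (`x_mbg_inflation`, 1.0 = null), codon pairs evolved under
  the same single-ω model the estimator fits, and closed-form
  chromosome-copy accounting.
- **Pipeline & CLI** (`fasterx.pipeline`, `fasterx` command): TSV/FASTA
  input parsing, orchestration, and tab-delimited reports with a
  checksum manifest.

## Worked example

```python
import numpy as np
from fasterx import (SimulationConfig, generate_dataset, gy94_ml,
                     fit_standardized_ols, residual_group_test,
                     stratified_xa_comparison)
import dataclasses

cfg = dataclasses.replace(SimulationConfig(), n_genes=7500,
                          x_mbg_inflation=1.5, with_sequences=False, seed=1)
genes = generate_dataset(cfg).gene_table
mbg = genes[genes.bias_class == "MBG"]
cov = {"Lev": mbg.level.to_numpy(), "Spe": mbg.tau.to_numpy(),
       "Int": mbg.degree.to_numpy(float)}

fit = fit_standardized_ols(mbg.divergence.to_numpy(), cov)
res = residual_group_test(fit, mbg.chromosome.to_numpy())
strat = stratified_xa_comparison(mbg.divergence.to_numpy(), cov,
                                 mbg.chromosome.to_numpy(), n_bins=10)
print(f"b* = { {k: round(v, 3) for k, v in fit.coefficients.items()} }")
print(f"residual X-vs-A U test: P = {res.p_value:.3g}")
print(f"stratified Wilcoxon: T = {strat.test.statistic:.1f}, "
      f"P = {strat.test.p_value:.3g}, "
      f"categories = {strat.n_categories_retained}")
```

Output:

```
b* = {'Lev': -0.371, 'Spe': 0.033, 'Int': -0.163}
residual X-vs-A U test: P = 7.57e-25
stratified Wilcoxon: T = 2830.0, P = 1.73e-10, categories = 163
```

The standardized slopes carry the signs of the built-in correlation
structure: divergence falls with expression level and interaction
count and rises with tissue specificity (weakly here, because
male-biased genes span a narrow τ range). Because the simulated X-linked male-biased
genes diverge 1.5× faster than autosomal ones *beyond* what those
properties explain, both the residual contrast and the
property-matched stratified comparison reject decisively — the same
dual-analysis logic used to attribute faster-X to hemizygosity rather
than to gene properties. Rerunning with `x_mbg_inflation=1.0` (the
null) makes both tests non-significant at the nominal rate.

The same analysis runs from the shell:

```
fasterx simulate --config sim.cfg --outdir data/
fasterx run --config sim.cfg --seed 1 --outdir report/
fasterx divergence --fasta-a data/species1.fa --fasta-b data/species2.fa \
    --method both --out dnds.tsv
```

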