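# Methods

This note documents the models, estimators, numerical choices and
limitations behind `fasterx`.

## Expression properties

Per-gene measurements are replicated log2 signals for two species.
Definitions:

- **Level** — the unweighted mean of the two species' mean log2 signals.
- **Expression divergence** — the absolute difference of the two species
  means on the log2 scale. This is symmetric in species and natural for
  log-scale array signals; it is the module default and pluggable, since
  upstream studies sometimes use platform-specific estimators.
- **Expression polymorphism** — the within-species standard deviation of
  the log2 signal, pooled across the two species by degrees of freedom
  (denominator n₁ + n₂ − 2). With fewer than two replicates in either
  species, polymorphism is reported as NaN, never as zero.
- **Tissue specificity** — Yanai's τ over N ≥ 2 tissues,
  τ = Σᵢ (1 − xᵢ/max x)/(N − 1): 0 for uniform expression, 1 for
  single-tissue expression, invariant to positive rescaling. All-zero
  or negative profiles are rejected rather than imputed.
- **Sex bias** — MBG when male − female ≥ 1 on the log2 scale (2-fold),
  FBG symmetrically, NBG otherwise. The 2-fold default is a
  reproducible criterion that needs no replicate-level variance model;
  the threshold is an explicit parameter everywhere it is used. Genes
  without a tissue profile carry τ = NaN and drop out of
  property-adjusted analyses listwise.

## Pairwise coding-sequence divergence

Two estimators share the QC path: terminal stop codons are trimmed
(the final codon column, if either sequence ends in a stop), codons
containing `N` or `-` in either sequence are removed pairwise, and an
internal stop codon in either sequence makes the gene unusable — the
same dispositions later reported by the pipeline.

**NG86 counting.** Each codon position contributes one site, split
between synonymous and nonsynonymous in proportion to the synonymous
fraction of its non-stop single-nucleotide neighbours (so sites per
codon always sum to 3, and mutations to stops are disregarded). Site
counts are averaged over both sequences. Differences between codons
separated at d positions are averaged over the d! minimal mutational
pathways; pathways through stop codons are excluded, and if every
pathway is blocked, all pathways are used with stop steps counted as
nonsynonymous (this situation does not arise for sense-to-sense pairs
at d ≤ 2 in practice). Proportions pS, pN are corrected with the
Jukes–Cantor formula d = −¾ ln(1 − 4p/3); a proportion ≥ ¾ yields NaN
for that class. dS is exactly 0 iff no synonymous difference is
observed — this observable, estimator-independent count also drives the
zero-synonymous-changes exclusion rule.

**Single-ω maximum likelihood.** The generator on the 61 sense codons
has qᵢⱼ = πⱼ·κ^[transition]·ω^[nonsynonymous] for single-position
changes, 0 otherwise, scaled to one expected substitution per codon per
unit t; stop codons are outside the state space. Equilibrium
frequencies are F3×4: products of position-specific nucleotide
frequencies observed in the pair (both sequences pooled), renormalized
over sense codons with a 1e-8 floor against zero-frequency codons.
A flag switches to third-position-only frequencies as a sensitivity
variant, since the two readings of "average nucleotide frequencies at
third codon positions" differ. The pairwise likelihood
Σ nᵢⱼ log(πᵢ Pᵢⱼ(t)) is reversible, hence invariant to swapping the
sequences. P(t) = exp(Qt) is computed by eigendecomposition of the
symmetrized generator D^½QD^(−½) (reversibility makes it symmetric),
with a scipy scaling-and-squaring fallback if the spectral
reconstruction loses stochasticity beyond 1e-8.

Optimization is bounded multi-start L-BFGS-B in log-parameter space,
bounds t ∈ [1e-6, 10], κ ∈ [0.01, 100], ω ∈ [1e-4, 99], with three
starts (NG86-informed, neutral ω = 1, ω = 0.1) plus any user-supplied
start; the best optimum is kept and flagged unreliable if no start
converges. An all-identical pair drives t to its floor, where dN and dS
are reported as exactly 0. dN and dS are decomposed from t by the
mutational-opportunity convention: with ρS the synonymous share of
equilibrium flux at the MLE and ρS¹ the same share at ω = 1, synonymous
sites per codon are 3ρS¹ and dS = t·ρS/(3ρS¹) (dN analogously), which
makes dN/dS equal ω identically.

**Filters.** The consensus-site rule keeps a site iff depth > 7 and
phred-scaled consensus quality > 40, both strict (a site at exactly the
threshold is masked). Gene-level exclusions apply in a fixed order so
each gene carries exactly one primary reason: internal stop → zero
observed synonymous changes → ω ≥ 9 (inclusive).

## Statistical battery

Rank tests use exact null enumeration whenever the relevant sample size
is ≤ 25 and ties do not prevent it, otherwise the normal approximation
with tie and continuity corrections (scipy backends; the exact branches
are verified against full enumeration oracles in the tests). The
signed-rank statistic T is reported as the smaller of the positive- and
negative-rank sums over midranks, zeros dropped. All tests default to
two-sided, with one-sided variants exposed; no multiple-testing
correction is applied anywhere and P values are reported raw.

The standardized regression z-scores the response and each covariate
(sample SD, ddof 1) and fits OLS with an intercept; slopes are then the
standardized coefficients b\*, R is the multiple correlation, residuals
live on the standardized-response scale and are orthogonal to every
covariate by construction. Collinearity (design condition number
> 1e10) is an error naming the most correlated covariate pair.
Per-coefficient P values are OLS t-test probabilities, which coincide
with partial-correlation tests for OLS.

The stratified comparison cuts each of the three covariates into
`n_bins` (default 10) equal-size rank bins **within the analyzed gene
subset** (e.g. MBGs only), with ties broken deterministically by input
order and remainder genes assigned to the lower bins, so bin membership
depends only on ranks and the comparison is invariant to monotone
transforms of the covariates. Genes land in combined 3-tuple
categories; only categories containing at least one X-linked and one
autosomal gene contribute a paired difference of class means, and at
least two such categories are required. Binning within the analyzed
subset (rather than genome-wide before subsetting) is a deliberate
choice: it keeps the bins equal-size in the sample actually tested.

## Synthetic data

The generator emulates the study inputs at desk scale. Defaults: 16%
X-linked genes; bias-class proportions 20/19/61% (MBG/FBG/NBG); 25
tissues; κ = 2; true ω ~ Gamma(shape 2, mean 0.1); divergence time
t ~ lognormal(mean ≈ 0.05 substitutions per codon, σ 0.4); CDS length
lognormal around 400 codons — shallow-divergence, purifying-selection
conditions of the order seen in very recently diverged *Drosophila*
sister species. Tissue profiles are symmetric Dirichlet draws with a
per-bias-class concentration (MBG 0.20 < FBG 0.35 < NBG 0.50), giving
male-biased genes the higher τ. Interaction degrees are negative
binomial with per-class means (MBG 5 < FBG 8 < NBG 10); the network is
a configuration-model graph on the drawn degrees, simplified by
discarding self-loops and parallel edges (cheaper than
reject-and-resample and adequate here); the gene table records the
*realized* degree so the covariate used downstream matches the graph
exactly.

Expression divergence is log-normal around a linear predictor:
log D = −1.2 − 0.12·level + 0.8·τ − 0.15·log(1+degree) + 0.5·ε, then
multiplied by `x_mbg_inflation` for genes that are both X-linked and
male-biased. Because covariate distributions depend on the bias class
only, X and A genes of a class are exchangeable at inflation 1 (the
null), and the mean X-MBG/A-MBG divergence ratio equals the inflation
exactly in expectation. Polymorphism follows the same form with
weaker coefficients and no inflation. The coefficient signs encode the
assumed genome-wide structure (divergence falling with level and
interactions, rising with specificity); magnitudes were chosen once to
give rank correlations of roughly 0.2–0.3 in absolute value, the order
reported for *Drosophila* genome-wide comparisons. No published
multiplicative effect size exists for faster-X expression divergence,
so `x_mbg_inflation` values other than 1 are power-study settings, not
calibrated estimates.

Replicated two-species measurements are constructed to reproduce the
gene-level summaries exactly (species means level ± divergence/2;
replicate spread with pooled SD equal to the polymorphism), so the
expression-summary stage inverts the generator without estimation
noise. Codon pairs draw an ancestral sequence from the configured codon
frequencies (uniform over the 61 sense codons by default) and sample
each descendant codon from the exact transition kernel exp(Qt) — under
reversibility this matches evolving two branches from a common
ancestor at total divergence t, and it is exact for all t, unlike
event-by-event simulation which it replaces.

Randomness: every gene has two fixed substreams of the master seed
(label-independent draws and class-dependent draws), so enlarging a
dataset never perturbs the label-independent draws of existing genes,
and class-dependent draws move only if the deterministic
largest-remainder quota relabels the gene. Class counts are quota-
rounded, not Bernoulli, so configured proportions hold exactly at any
n.

What the generator does **not** emulate: probe-level microarray noise,
read alignment and consensus-calling artifacts, dosage compensation,
codon usage bias, recombination-rate variation along chromosomes, and
any attempt to match a real species pair beyond orders of magnitude.
Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the assumed generative structure, not that
a particular biological dataset will show (or lack) a faster-X signal.

## Problem sizes and numerical choices

The calibration and power studies run at 2000 genes × 1000 replicates
(type-I error of the stratified test) and 7500 genes (≈ 1500 MBGs)
× 200 replicates (joint power at 1.5-fold inflation); ML parameter
recovery uses 100 pairs of 500 codons per true ω. These sizes give
binomial confidence intervals tight enough to detect miscalibration of
a 5% test (± 1.4 points) while keeping a full run on one core in the
tens of minutes. Optimizer tolerance is 1e-12 on the scaled objective;
likelihood probabilities are floored at 1e-300 before logs; codon
frequencies at 1e-8 before normalization. Ties in rank binning are
broken by input order (documented, deterministic); exact test branches
are limited to n ≤ 25 without ties.

## Known limitations

- The ML estimator is pairwise-only (no trees, no branch or site
  models) and assumes stationarity and reversibility under F3×4.
- The sampling distribution of ω̂ is right-skewed, so at 500 codons and
  t = 0.2 the *mean* estimate sits a few percent above the truth near
  neutrality (the acceptance script prints the recovery means); the
  effect shrinks with sequence length and is inherent to plug-in F3×4
  ML, not specific to this implementation.
- NG86 pathway averaging weights all minimal pathways equally, the
  classical convention, rather than weighting by likelihood.
- The expression divergence/polymorphism definitions are declared
  substitutes for platform-specific upstream estimators; analyses that
  depend on their exact scale should inject their own definitions.
- With few genes per combined category, per-category means are noisy;
  the signed-rank test remains valid under exchangeability but loses
  power — the type-I study covers exactly this regime.
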