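# Methods

This note documents the models, estimators and numerical choices behind
`compenseq`, what the synthetic data generator does and does not emulate,
and the known limitations of the approach.

## Study design and notation

Three strain groups: a progenitor outbred strain `W`, a strain `KM` derived
from it by long-term phenotypic selection, and a strain `0` (`ZERO`)
back-selected from `KM × W` hybrids for absence of the derived phenotype.
Counts are gene × sample integer matrices; all tables in this package are
genes-in-rows, samples-in-columns. The negative binomial is parameterised
throughout by mean μ and dispersion φ with variance μ + φμ² (φ = 1/size);
"BCV" below is √φ.

## Normalization

Trimmed-mean-of-M-values (TMM) factors with the conventional parameters:
the reference sample is the one whose upper-quartile count fraction is
closest to the mean across samples; per sample, gene-wise M-values (log2
ratios of count fractions against the reference) are trimmed by 30% from
each tail, A-values (average log abundances) by 5% from each tail, genes
with a zero in either sample are dropped, and the factor is the
inverse-variance-weighted mean of the surviving M-values (binomial
delta-method weights). Factors are rescaled to geometric mean 1, so the
effective library size is raw size × factor.

logCPM uses a prior count (default 0.5) scaled by relative effective
library size:

    logcpm[g, s] = log2( (y[g, s] + p_s) / (L_s + 2 p_s) * 1e6 ),
    p_s = prior * L_s / mean(L),  L_s = effective library size.

Two consequences worth knowing: logCPM is monotone in counts within a
sample, and exact depth-doubling changes logCPM only through the prior, by
at most log2(1 + 0.25/(c + 0.25)) at count c — about 0.034 at c = 10,
under 0.01 from c ≈ 50.

Genes with zero counts everywhere are kept in the tables but excluded from
DE testing by the expression filter (below), not silently dropped.

## Differential expression: the quasi-likelihood F-test

The two-group contrast (e.g. KM vs W, ZERO vs KM) is tested per gene with
a log-link NB GLM and a quasi-likelihood F statistic. Pipeline:

1. **Expression filter.** Keep genes with CPM ≥ `min_cpm` (default 1) in
   at least `min_samples` samples (default: the smallest group size).
   Filtered genes carry a `tested = False` flag and NA statistics, and do
   not enter the BH correction.

2. **GLM fitting.** For a one-way layout the MLE decomposes by group; each
   group's log-mean is found by a clipped 1-D Newton iteration on the NB
   score with offsets = log effective library sizes, vectorised across all
   genes (convergence |step| < 1e-10, 60 iterations cap; the problem is
   concave so this is effectively exact).

3. **Dispersion estimation.** Per gene, the Cox–Reid adjusted profile
   likelihood (APL) is evaluated on a 41-point log-spaced grid
   φ ∈ [1e-4, 10] and maximised with 3-point quadratic interpolation.
   The abundance trend is estimated by *pooling*: genes are split into up
   to 20 abundance-quantile bins, the summed APL of each bin is maximised
   on the grid, and per-gene trend values interpolate log φ across bin
   centres. Pooling before maximising matters — smoothing noisy per-gene
   maximisers on the log scale is biased low (a Jensen effect), which
   inflates deviances and visibly distorts null p-values. Tagwise
   estimates are squeezed toward the trend in log space with a prior df
   from moment matching (excess spread of log φ residuals over the
   trigamma sampling approximation). The GLM fits inside the F-test use
   the **trended** dispersion, the usual QL convention, so gene-level
   variability is carried by the quasi-dispersion instead.

4. **Quasi-dispersion and F statistic.** With full (two means) and reduced
   (one mean) fits, D = dev_reduced − dev_full and the residual
   quasi-dispersion is s² = dev_full / E₀[dev_full]. The null expectation
   is computed from tabulated moments of the NB unit deviance (exact pmf
   summation on a 48 × 25 grid in (μ, φ), interpolated in log space; both
   moments are flat in μ above a few hundred counts, so the table is
   clamped there). This correction is essential at moderate and small
   counts: the raw deviance is off-centre (≈ 1 + φ/6 per observation at
   large μ, worse at small μ), which otherwise makes the test
   conservative. An effective residual df per gene comes from Gamma
   moment matching of the deviance (df_eff = 2·E² / Var, clipped to
   [1, 4·df]). s² values are then moderated across genes: the prior
   location s₀²(A) is a lowess fit of s² on average logCPM on the
   *natural* scale (E[s²] = σ² needs no distributional shape assumption;
   log-scale or robust variants biased the prior by 5–15% in validation),
   and the prior df comes from the excess spread of log s² over its
   sampling trigamma. Finally

       F = D / s²_EB,   p = P(F(1, df_eff + df_prior) > F),

   with a χ²₁ reference when the prior df is infinite, and BH-adjusted
   FDR over tested genes. Zero-deviance ties are floored at s² = 1e-8.

Calibration, not numerical identity with any external package, is the
contract of this module: in null simulations at the design's scale
(n = 4 vs 4, NB dispersions on the generator's trend) the measured type-I
error at α = 0.05 is 0.047–0.055 and p-values pass a KS uniformity check
at α = 0.01 in 9/10 seeds; power at a 4-fold effect with n = 4 is ≈ 0.9.

**DEG selection** applies the analysis thresholds downstream: p < 0.05
(raw p, with FDR reported alongside) and, where a fold cutoff is used,
|logFC| > log2(1.5). The headline compensation summaries use the stricter
p < 0.01.

## Compensation statistic

For each gene, with group-mean logCPMs m_W, m_KM, m_0:

    coefficient = 100 · (m_KM − m_0) / (m_KM − m_W)   [percent]

undefined (NaN, class `undefined`) when |m_KM − m_W| ≤ ε, ε = 1e-6 logCPM
by default. Classes: `compensated` for coefficient in (0, 100],
`overcompensated` above 100, `uncompensated` at or below 0. The coefficient
is invariant to adding a constant to all three means (verified
numerically), and nothing else.

The boundary convention (0, 100] includes the 0–1% sliver; a literal
[1, 100] band is also reported by `fraction_compensated(..., interval="paper")`
for comparability with analyses that use it. Coefficients are computed for
all genes and thresholded at analysis time (`de_p_km_w < p`), so the same
table serves the p < 0.05 and p < 0.01 summaries.

Estimation caveat that matters for interpretation: the coefficient is a
ratio of noisy mean differences whose numerator and denominator share the
m_KM noise term. At realistic replicate numbers (n = 4) and biological
CVs (√φ ≈ 0.22) the per-gene coefficient has a sampling sd of roughly
10–30 points, and estimates regress toward 100 for selected genes. As a
result, class *fractions* estimated from noisy coefficients are biased
toward the compensated band when the true class distribution hugs the
0 or 100 boundaries; simulation shows faithful recovery of a 50–70%
compensated fraction but upward bias (≈ +0.15–0.19) when the true
fraction is 0.3. The coefficient itself is unbiased in location for fully
compensated genes (median ≈ 95–100 in validation).

Supporting summaries:

- **Concordance**: Spearman ρ (average ranks; clamped to exactly ±1 when
  within 1e-12) and the fraction of genes with opposite logFC signs
  (exact zeros count as non-opposite) between two contrasts, on a caller-
  chosen subset — the pipeline uses the union of both contrasts' DEGs at
  p < 0.01.
- **Coefficient density**: Gaussian-kernel KDE with Silverman's rule
  h = 0.9 · min(sd, IQR/1.34) · n^(−1/5), floored at 1e-6 × range so
  constant input stays finite, on a 512-point grid spanning
  [min − 4h, max + 4h]; four bandwidths of margin keep the trapezoid
  integral within 1e-3 of 1 even for tightly clustered coefficients.
- **Top partitions**: among DEGs, genes with coefficient > 50 and ≤ 50
  (configurable), the k = 50 most significant of each, displayed from the
  highest p-value at the top to the lowest at the bottom.
- **Z-transform**: per-gene (x − mean)/sd across samples (sample sd, n−1),
  constant rows flagged and zeroed, for heat-map display.

## Enrichment

Per gene set and DEG direction, a 2 × 2 Fisher's exact test of
{in set, not in set} × {in list, not in list} over a universe (default:
all tested genes, or the DEG list itself in the DEG-restricted variant).
Two-sided p-values use the point-probability convention — the sum of
hypergeometric probabilities of tables no more probable than the observed
one — and are verified in tests against exhaustive enumeration for every
configuration with universe ≤ 25. BH runs across sets within each
direction; that multiple-testing choice, and the universe default, are
package conventions rather than field standards. Ranked running-sum
(weighted Kolmogorov–Smirnov) GSEA is deliberately not implemented: the
set-level procedure here is over-representation of thresholded DEG lists,
with per-set members reported in decreasing-logFC order for display.
Venn partitions of 2–3 DEG lists are exact set algebra.

## Synthetic data generator

The generator emulates the three-strain bulk RNA-seq design so that every
downstream stage can be checked against known truth:

- per-gene baseline abundance exp(b_g), b_g uniform on [ln 2, ln 4000] —
  i.e. log-uniform mean counts from a few to a few thousand at study
  depth. Defaults for the study scale: 20,000 genes, W/KM/0 replicates
  4/3/4, library sizes 15–22 million. Tests and validation runs shrink
  genes and depth *together* (e.g. 2000 genes at 1.5–2.2 M reads) so the
  reads-per-gene regime — which controls count-level noise — matches the
  full-scale design;
- dispersion trend φ_g = φ₀ + s/exp(b_g) with φ₀ = 0.05 and s = 2.0:
  an asymptotic BCV of 0.22 typical of outbred animals, rising at low
  abundance;
- a fraction (default 0.08, matching DEG yields of roughly 1500/20,000 at
  p < 0.05) of genes differentially expressed between KM and W with
  |log2FC| = 1 (a 2-fold effect; the bulk of reported DEG fold changes
  sit within ±1 log2) and Rademacher signs;
- each DE gene carries a compensation class controlling the ZERO-vs-W
  effect δ relative to the KM-vs-W effect β: compensated δ = uβ,
  u ~ U[0, 0.3) (true coefficients spread over (70, 100] rather than
  degenerate at 100); uncompensated δ = vβ, v ~ U[1.0, 1.5];
  overcompensated δ = −wβ, w ~ U(0, 0.5]. Default class proportions
  (0.70, 0.15, 0.15) follow the motivating system's ~70% compensated and
  ≥15% uncompensated genes;
- expected count proportions are renormalised per sample before scaling
  by library size, and counts drawn NB(μ, φ) (Poisson when φ = 0).
  All randomness flows from a single integer seed; identical configs give
  bitwise-identical outputs.

What it does **not** emulate: GC/length and positional biases, batch
effects, correlated genes, read-level error, outlier samples, and
gene-specific dispersion scatter around the trend. Passing tests
therefore demonstrate the estimators' statistical behaviour under a clean
NB world — calibration, power, parameter recovery — not robustness to
real-data artefacts.

`counts_from_truth` redraws counts for an edited truth table (e.g.
forcing δ = 0 to study exact full compensation) under the same design.

## Numerical and degenerate-input conventions

- ε for the compensation denominator: 1e-6 logCPM.
- s² floor 1e-8 (zero-deviance genes); dispersion grid [1e-4, 10].
- Newton steps clipped to ±5 in log-mean space; all-zero groups start
  from a 0.125 pseudocount.
- TMM: samples identical to the reference short-circuit to factor 1;
  a sample sharing no expressed genes with the reference gets factor 1.
- KDE bandwidth floor 1e-6 × range (absolute 1e-6 for constant data).
- Venn supports exactly 2 or 3 sets; larger collections are rejected.
- BH via statsmodels `multipletests(method="fdr_bh")`; Fisher via
  `scipy.stats.fisher_exact`; lowess via statsmodels — each cross-checked
  against an independent oracle in the test suite.

## Problem sizes used in validation

Null calibration: 5000 genes × (4 + 4) samples, 10 seeds. Parameter
recovery: 2000 genes, 4 replicates per group, 5 seeds per condition.
Oracle sweeps: all Fisher tables with universe ≤ 25; 100 random genes for
the GLM deviance check. End-to-end: 1200–2000 genes. These sizes give
binomial/KS resolution well below the tolerances being asserted while
keeping the whole suite fast on a single CPU.

## Known limitations

- Two-group contrasts only; no multi-factor designs, no robust dispersion
  options, no exact-test or LRT user modes.
- The QL machinery is a self-contained rendition of the workflow, tuned
  for calibration; it will not numerically match any external
  implementation gene-by-gene.
- Class-fraction estimates from noisy coefficients are boundary-biased
  (see above); report them with the coefficient density, not alone.
- Gene identifiers are opaque strings; mapping to symbols or accessions,
  and retrieval of curated gene-set databases, are out of scope (gene
  sets are supplied as GMT).
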