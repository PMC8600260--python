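# compenseq

Bulk RNA-seq analysis of **expression reversion under back-selection**: given
three related strains — a progenitor (`W`), a strain derived from it by
long-term phenotypic selection (`KM`), and a strain back-selected from their
hybrids for *loss* of the derived phenotype (`"0"`/`ZERO`) — `compenseq`
quantifies, gene by gene, how far the back-selected strain's expression has
returned toward the progenitor. The motivating system is an audiogenic-epilepsy
rat model (midbrain transcriptomes of seizure-prone, progenitor and
back-selected strains), but the pipeline applies to any three-group design with
this structure.

It is aimed at researchers who want the full analysis chain — normalization,
differential expression, the compensation statistic, concordance and gene-set
enrichment — as tested, reusable Python, together with a synthetic count
generator carrying known per-gene truth so every stage can be validated.

## The statistics

**Differential expression** uses a from-scratch negative-binomial
quasi-likelihood F-test for two-group contrasts. For gene *g* with counts
*y<sub>gs</sub>* ~ NB(μ<sub>gs</sub>, φ<sub>g</sub>) (variance μ + φμ²) and
log-link mean model log μ<sub>gs</sub> = β<sub>g,group(s)</sub> +
log(effective library size<sub>s</sub>):

- TMM normalization factors and prior-count log<sub>2</sub>CPM;
- per-gene dispersions by Cox–Reid adjusted profile likelihood on a log-spaced
  grid, with an abundance trend from locally *pooled* adjusted likelihoods and
  empirical-Bayes squeezing toward it;
- the QL F statistic F = D / s²<sub>EB</sub>, where D is the full-vs-reduced
  deviance difference and s² the residual quasi-dispersion, bias-corrected by
  the exact expectation of the NB unit deviance and moderated across genes
  with a moment-matched prior; p-values from F(1, df<sub>eff</sub> + df<sub>prior</sub>),
  BH-adjusted.

**Compensation coefficient** (per gene, in percent, on mean log₂CPM):

```
coefficient = 100 · (mean_KM − mean_0) / (mean_KM − mean_W)
```

100 % ⇒ the back-selected strain is fully restored to the progenitor level;
≤ 0 ⇒ no compensation; > 100 ⇒ overcompensation; undefined when
|mean_KM − mean_W| ≤ ε. Companion summaries: the fraction of DEGs with
coefficient in (0, 100], a Gaussian-kernel density of coefficients
(Silverman bandwidth), top-compensated / least-compensated gene partitions,
and Z-transformed expression matrices for heat maps.

**Concordance**: Spearman correlation and opposite-sign fraction between the
log₂ fold changes of the KM-vs-W and 0-vs-KM contrasts; strongly negative
values indicate genome-scale expression reversion.

**Enrichment**: per gene set (GMT), two-sided Fisher's exact tests of the up-
and down-regulated DEG lists against a chosen universe, BH within direction,
plus exact 2- and 3-way Venn partitions of DEG lists.

## Worked example

```python
import compenseq as cq

# three-strain synthetic study: 2000 genes, W/KM/0 with 4/4/4 replicates,
# 70% of true DEGs compensated in the back-selected strain
cfg = cq.SimulationConfig(
    n_genes=2000, replicates={"W": 4, "KM": 4, "ZERO": 4},
    lib_size_range=(1_500_000, 2_200_000), seed=42,
)
counts, sheet, truth = cq.simulate_counts(cfg)

norm  = cq.log_cpm(counts, cq.tmm_factors(counts))
means = cq.group_mean_logcpm(norm, sheet)
de_km_w   = cq.qlf_test(counts, sheet, "W", "KM")    # logFC = KM over W
de_zero_km = cq.qlf_test(counts, sheet, "KM", "ZERO")

records = cq.compensation_table(means, de_km_w)
frac, n, _ = cq.fraction_compensated(records, p_threshold=0.01)
print(f"{n} DEGs at p<0.01; fraction compensated = {frac:.3f}")

sig = sorted(set(cq.select_degs(de_km_w, 0.01)["gene_id"])
             | set(cq.select_degs(de_zero_km, 0.01)["gene_id"]))
conc = cq.concordance(de_km_w.set_index("gene_id")["logFC"],
                      de_zero_km.set_index("gene_id")["logFC"], subset=sig)
print(f"Spearman rho = {conc.spearman_rho:.3f}, "
      f"opposite direction = {conc.opposite_fraction:.2%}")
```

Output:

```
138 DEGs at p<0.01; fraction compensated = 0.652
Spearman rho = -0.765, opposite direction = 91.23%
```

Read: of the genes significantly different between the derived strain and its
progenitor, ~65 % show expression in the back-selected strain moved back
toward the progenitor level (the generator's truth is 70 %, attenuated by
replicate noise at the class boundaries), and the two contrasts' fold changes
are strongly anti-correlated — the reversion signature.

The same analysis runs from the shell:

```bash
compenseq run-all --config config.yaml --seed 42
```

with a YAML config naming either input files (`counts`, `samples`, optional
`gmt`) or a `simulation:` block, writing DE tables, compensation records,
concordance, Venn partitions, enrichment tables, `summary.json` and a
markdown report into `out_dir`.

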