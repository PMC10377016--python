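# trnachip

Tools for studying how tumours choose among redundant tRNA genes, using
histone-acetylation ChIP-seq as a proxy for gene activity.

The human genome carries hundreds of tRNA genes with massive redundancy:
several genes share one anticodon (an **isoacceptor** family, e.g. the nine
tRNA-iMet-CAT genes behind the initiator methionine tRNA), and several
anticodons serve one amino acid (an **isotype**). H3K27ac ChIP-seq over
tumour cohorts shows that individual tRNA loci are switched on and off very
differently from tumour to tumour, while the summed activity of a family is
far more stable — redundancy appears to buffer expression. Family-level
expression, in turn, can correlate with patient survival.

`trnachip` implements that analysis as a reusable pipeline:

1. **annotation** — parse gtRNAdb-style gene names
   (`tRNA-<Isotype>-<Anticodon>-<Family>-<Copy>`), read BED6 / UCSC gene
   tables, apply high-confidence filtering, and derive ±flank windows
   around gene centres.
2. **quantify** — count DNA fragments (SAM/BAM or fragment BED) overlapping
   each window, scale to fragments per million, and divide ChIP by matched
   input: the per-gene, per-sample signal
   `Q_gs = (c_gs · 10⁶ / N_s) / (i_gs · 10⁶ / M_s + ε)`,
   with cells of inadequate input coverage recorded as missing.
3. **families** — sum Q-values to isodecoder / isoacceptor / isotype level;
   totals are conserved across levels and aggregation commutes with the
   hierarchy.
4. **heterogeneity** — pairwise Spearman ρ between samples at each level
   (the buffering signature is ρ_gene < ρ_isoacceptor < ρ_isotype),
   per-sample totals and fold range, median-based active/inactive calls,
   and Student-t group comparisons with Benjamini–Hochberg q-values.
5. **survival** — per-unit screening against patient survival: top-vs-bottom
   expression-quartile Kaplan–Meier curves with log-rank tests, and Cox
   proportional-hazards fits `h(t|z) = h₀(t)·exp(βz)` on standardized
   expression (HR per SD), both administratively censored at a 5-year
   horizon.
6. **synthetic** — a generative model of the whole study: family activity
   budgets `A_fs = exp(N(μ_f, σ_budget))` nearly conserved across samples,
   member weights `w_·s ~ Dirichlet(α_sel)` redrawn per sample (different
   tumours activate different members), Poisson fragment placement with
   matched input, and survival cohorts with a known log-hazard ratio —
   with all hidden parameters returned for recovery tests.

It is aimed at computational epigenomics groups who want to rerun or stress
the family-buffering analysis on their own cohorts, or to benchmark it on
simulated data where the truth is known.

## Worked example

```python
import trnachip as tc

cfg = tc.SyntheticConfig(seed=1)          # 12 tumours, 40 families x 5 genes
cohort = tc.simulate_chip_cohort(cfg)
qmat = tc.build_signal_matrix(cohort.sheet, cohort.annotation,
                              chrom_lengths=cohort.chrom_lengths)

corr = tc.correlation_hierarchy(qmat)
print(corr.groupby("level")["rho"].mean().round(3))
totals = tc.sample_totals(qmat)
print("fold range: %.2f (%s vs %s)"
      % (totals.fold_range, totals.max_sample, totals.min_sample))
print("active fraction: %.2f" % tc.classify_activity(qmat).values.mean(axis=None))
```

prints

```
level
gene           0.035
isoacceptor    0.685
isotype        0.921
Name: rho, dtype: float64
fold range: 1.12 (P_001 vs M_004)
active fraction: 0.50
```

Individual genes are almost uncorrelated between tumours (mean pairwise
ρ ≈ 0.04): each tumour has selected different members of each family. The
same data aggregated to isoacceptor families is strongly rank-correlated
(ρ ≈ 0.69), and isotypes even more so (ρ ≈ 0.92) — the buffering effect the
pipeline is built to measure. Overall signal differs only 1.12-fold between
the strongest and weakest sample here, and the median rule calls half of
all gene-sample cells "active" by construction.

The same steps are available from the shell:

```sh
trnachip simulate --seed 1 --out cohort/
trnachip quantify --genes cohort/genes.bed --samples cohort/sample_sheet.tsv \
                  --flank 500 --pseudocount 0.5 --min-input 5 --out qmatrix.tsv
trnachip correlate --matrix qmatrix.tsv --out correlations.tsv
trnachip compare-groups --matrix qmatrix.tsv --samples cohort/sample_sheet.tsv \
                  --out primary_vs_met.tsv
trnachip survival-screen --expr expr.tsv --surv surv.tsv --level isoacceptor \
                  --horizon 5 --out screen.tsv
```

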