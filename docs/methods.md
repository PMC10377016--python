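# Methods

## Signal model

The pipeline quantifies tRNA gene activity from H3K27ac ChIP-seq as a
window statistic. For gene *g* the quantification window is the ±`flank`
interval around the gene centre, `[⌊(start+end)/2⌋ − flank,
⌊(start+end)/2⌋ + flank)`, half-open and clipped at chromosome boundaries;
the default flank of 500 bp gives 1 kb windows. Strand is recorded but
ignored — ChIP fragments are unstranded. All coordinates are 0-based
half-open; UCSC table input is assumed 0-based (a reader flag decrements
1-based exports).

A "fragment" is the sequenced DNA molecule: for paired-end alignments the
template interval between mates (counted once, from the leftmost mate);
for single-end data each read extended to a configurable fragment length
(default 200 bp) from its 5′ end. Unmapped, secondary, supplementary and
duplicate-flagged records are dropped by default. The library size is the
number of fragments surviving these filters, computed once per source and
overridable for reproducibility.

Counting uses any-overlap semantics — a fragment sharing ≥ 1 bp with a
window counts there, and a fragment spanning *k* windows counts in all *k*
(windows are disjoint in practice; a midpoint mode is available for
sensitivity analyses). Counts are implemented with per-chromosome sorted
start/end arrays and binary search, and are checked exactly against an
exhaustive all-pairs oracle in the tests.

Normalization proceeds in two steps. Counts are scaled to fragments per
million, `rpm = c·10⁶/N`. The ChIP value is then divided by the matched
input: `Q = chip_rpm / (input_rpm + ε)`. The ratio form (rather than
subtraction) matches how relative signal is displayed in heat maps of this
kind. Two knobs are deliberately explicit because no published definition
exists for them:

* pseudocount `ε = 0.5` (RPM scale). Placing `ε` on the RPM scale keeps Q
  exactly invariant under whole-library duplication, which the tests
  assert.
* "inadequate data quality" — a cell is missing, with reason code
  `inadequate input`, when the raw input coverage in the window is below
  `min_input = 5` fragments. Missing cells carry their reason through the
  matrix and are rendered grey by the heat-map helper.

## Family hierarchy

Gene names follow the gtRNAdb convention
`tRNA-<Isotype>-<Anticodon>-<IsodecoderFamily>-<GeneCopy>`; parsing and
re-serialization are exact inverses on well-formed names (property-tested).
Non-canonical names (nmt-tRNA, tRNA-like predictions) are representable so
that raw gene tables can be loaded, and are removed by the filtering step,
which retains the supplied high-confidence ids plus explicit exceptions
(curated sets occasionally keep a locus, e.g. a selenocysteine gene,
outside the high-confidence list) and drops loci matching configurable
patterns (nmt- prefix, tRNA-like, unplaced/alt contigs). The set and the
exceptions are inputs, not constants, because gtRNAdb versions drift.

Aggregation sums member Q-values per family (`sum` is the primary
statistic; `mean` is available for unequal-family-size sensitivity
checks). Missing members are omitted by default with the effective member
count recorded per cell; a strict `propagate` policy blanks any group with
a missing member. With complete data, per-sample totals are identical at
every level and two-step aggregation equals direct aggregation (asserted
to 1e-9).

## Heterogeneity statistics

Pairwise sample similarity is Spearman's rank correlation on
pairwise-complete cells (≥ 3 pairs required; zero-variance vectors are
undefined and reported missing), computed on the matrix aggregated to each
requested level. The buffering signature is a strict increase of the mean
pairwise ρ from gene to isoacceptor to isotype level.

Activity classification is *not* formalized in the literature this
pipeline follows; the default `per_sample_median` rule (cell active iff
≥ its sample's median, ties active) reproduces the observation that about
half the loci are active in any given tumour *by construction*, and is
documented as a modelling choice. Global-quantile and fixed-threshold
rules are provided as alternatives.

Group comparisons use the classical equal-variance Student t-test
(two-sided) per unit, with Welch's correction as a flag. Raw p-values are
the primary output; Benjamini–Hochberg q-values over the tested units are
always reported alongside, because screens of ~400 units invite multiple
testing even where the original analyses reported raw p only.

## Survival screening

Follow-up is administratively censored at a 5-year horizon (configurable)
before any statistic is computed, so "5-year survival" means the same
thing in the Kaplan–Meier and Cox branches. Quartile comparisons split
patients at the empirical Q1/Q3 of a unit's expression with ties on the
closed side (≤ Q1 low, ≥ Q3 high; middle half excluded) and compare the
two Kaplan–Meier curves with the two-group log-rank test. Cox models use
expression as a continuous predictor, z-scored by default so hazard ratios
are per SD and comparable across units; Efron tie handling is the default
(lifelines), with a compact single-covariate Newton solver using Breslow
ties kept for cross-checks. Monotone-likelihood fits are flagged, not
raised, and a screen over many units records per-unit failures and
continues, ordering results by hazard ratio.

## Synthetic data generator

The generator encodes a minimal mechanism for the buffering phenomenon;
nothing in the analysed data dictates one, so the construction is a
modelling choice with two interpretable knobs:

* **Family budgets.** Each isoacceptor family f has a log-mean activity
  `μ_f ~ N(log 500, 0.4)` fixed across samples; sample s draws
  `A_fs = exp(N(μ_f, σ_budget))` with `σ_budget = 0.15`. Budgets are in
  expected fragments per family window set.
* **Member selection.** Within each family and sample, member weights are
  an independent `Dirichlet(α_sel·1)` draw with `α_sel = 0.3`; each gene
  receives `Poisson(A_fs · w_gs)` fragments placed uniformly in its
  window. Small α concentrates each family's budget on a few members that
  differ from sample to sample — the heterogeneous-selection phenomenon.
* **Isotype structure.** Families are assigned to isotypes unevenly
  (sizes cycling 5,4,4,3,3,3,2×6,1×6), mirroring the skewed
  families-per-isotype distribution of the real gene set. This matters:
  with equal-sized isotypes, summing k independent families shrinks signal
  and noise equally and the isotype level would gain nothing; the uneven
  sizes make isotype totals rank-stable, which is what the real data show.
  The between-family spread 0.4 was likewise chosen so that the
  isoacceptor level is not already saturated — the resulting level-wise
  mean correlations (~0.03 / 0.73 / 0.93 at default depth) bracket the
  magnitudes reported for real tumour pairs.
* **Tracks.** ChIP adds genome-wide uniform background at 2 fragments/kb;
  input is pure uniform coverage at 20 fragments/kb (≈ 20 fragments per
  1 kb window, so `min_input = 5` greys out only rare cells). Fragments
  are 200 bp; genes (72 bp) sit every 5 kb across 4 toy chromosomes, so
  1 kb windows never overlap. Metastatic samples reuse the primary
  parameters, with an optional per-family multiplicative log-normal shift
  (off by default).
* **Survival.** Patient hazards are `h_i = h₀·exp(β·z_i)` with h₀ =
  0.3/year, β = 0.6 and z the standardized expression of a chosen unit;
  event times are exponential, censoring is independent uniform with its
  upper bound calibrated by bisection to a 30% target fraction, and
  follow-up is truncated at the 5-year horizon. Default cohorts have 500
  patients.

Default cohorts are 12 samples (8 primary + 4 metastatic) over 40 families
of 5 genes (200 genes, ~25k ChIP fragments per sample); these sizes keep a
20-replicate experiment under a minute while leaving every statistic far
from its small-sample regime. All draws come from one seeded generator, so
a (config, seed) pair reproduces fragment files byte-for-byte.

What the generator does *not* emulate: peak shape (placement is uniform —
adequate because the analysis only counts overlaps), GC/mappability bias,
read-level errors, chromosomal clustering of tRNA genes, correlated
family budgets (isotype demand is not conserved beyond what summation
induces), and any real relation between H3K27ac and the survival
covariates. Passing recovery tests therefore demonstrate that the pipeline
measures what this model generates, not that real tumours follow the
model.

## Numerical choices

* Overlap test: half-open on both sides, so abutting intervals do not
  overlap; counts are order-independent by construction.
* Spearman uses average ranks for ties (checked against a
  rank-then-Pearson oracle).
* Degenerate t-test input (both groups constant and equal) is defined as
  t = 0, p = 1; groups with < 2 values are missing with reason.
* Cox Newton iterations stop at |Δβ| < 1e-8 or 50 iterations; Wald
  p-values and 95% CIs use the normal approximation.
* Fold range with a zero minimum total is reported as infinite with a
  warning rather than raising.
* Quartile cutpoints are empirical quantiles (linear interpolation);
  degenerate separation (Q1 = Q3) is an error.

## Known limitations

* Per-gene input ratios are noisy when input coverage is thin; the
  pseudocount and `min_input` defaults trade bias against data loss and
  should be revisited for shallow libraries.
* The activity rule is a convention, not an estimate of transcriptional
  state.
* The survival screen fits one unit at a time; no multivariable
  adjustment (stage, receptor status), competing risks, or
  proportional-hazards diagnostics beyond the convergence flag.
* Headline values from the real tumour and TCGA cohorts (specific
  correlation coefficients, hazard ratios, significant-gene counts)
  require the original controlled-access data and are deliberately out of
  scope for the test suite, which works on synthetic cohorts with known
  truth.
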