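# Methods

## Model and procedure

`tmmscope` treats telomere-maintenance-mechanism inference as a per-sample
gene-set enrichment problem with permutation calibration:

1. **Rank transform.** Within each sample, genes receive ascending average
   ranks (ties share the mean rank). Everything downstream is a function of
   ranks only, so any strictly increasing per-sample transform of the input
   (normalization, log, unit changes) leaves all scores bit-identical.
2. **Running-sum enrichment score.** For a set with k of G measured genes,
   the raw score sums, over all list positions in descending rank order, the
   difference between a rank-power-weighted in-set ECDF (weight `rank^alpha`,
   alpha = 0.25) and a uniform out-of-set ECDF (step 1/(G−k)). Because the
   sum is linear in each gene's "positions at or after me" count, the engine
   evaluates it in O(k) per sample directly from the rank matrix, without
   per-permutation sorting.
3. **Tie rule.** A fixed tie order (e.g. by gene symbol) would make scores of
   tied blocks depend on symbol spelling; instead the score is the average of
   the positional walk over all orderings of each tie block, which is exactly
   what substituting the average rank for the position count computes. A
   fully tied sample scores 0 for every set; tie-free data are unaffected.
4. **Permutation background.** The null resamples uniform random gene sets of
   matched size from the measured universe and scores them per sample — the
   standard competitive null for set scores. `n_perm` defaults to 2,000,
   which bounds the add-one empirical p at 1/2001 ≈ 5e-4; the knob accepts
   arbitrarily large values when finer resolution is worth the time.
5. **Decision rule.** Chromatin status is "upregulated" when the observed
   ALT_CHR score is at or above its per-sample null median (the only scale
   the calibration already owns). Upper-tail add-one p-values are BH-adjusted
   across samples within the set, and a sample is ALT-like iff upregulated
   with q strictly below the FDR threshold. The default threshold 0.5 is
   deliberately permissive but is the published operating point of this
   classification; it is surfaced prominently in configuration and logs.
   Each sample also carries a telomerase-axis status (per-sample max of the
   two telomerase-arm scores against the element-wise max of their nulls)
   and an ALT-axis status — the "two TMM subtypes" per sample.
6. **Downstream.** Welch t (default; pooled-variance switchable) per gene
   with BH for differential expression; Mann–Whitney rank-sum (exact when
   both groups ≤ 10, normal approximation with continuity correction
   otherwise) for score comparisons; Pearson r with the t-transform p for
   anchor panels and pair grids, BH over the whole grid, significance
   encoded as −log10(q); Kaplan–Meier and the log-rank test via lifelines;
   Harrell's C computed in-package because its pair rules are pinned
   (admissible pair: the strictly earlier time is an event; risk ties count
   0.5; no admissible pairs returns 0.5 with a warning — a convention that
   differs from lifelines' treatment of tied event times).
7. **Clustering.** Samples are clustered on log10(x+1) expression with
   one-minus-Pearson distance and average linkage (zero-variance genes
   dropped); the tree exports to Newick.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `weight_exponent` | 0.25 | rank weight in the in-set ECDF; 0 = unweighted, 1 = rank-proportional |
| `normalization` | `range` | divide all raw scores by the global max−min (cross-set comparability); `none` keeps raw |
| `n_perm` | 2000 | background size; p resolution = 1/(n_perm+1) |
| `fdr_threshold` | 0.5 | BH q cut for the ALT-like call (permissive by design) |
| `log10_offset` | 1.0 | offset in the clustering log transform |
| `seed` | — | drives every random draw; identical seeds give byte-identical outputs |

BH is applied across samples within a set, not across sets: the
classification is a per-sample decision and no cross-set family is defined.

## The synthetic cohort

`tmmscope.simulate` emulates the assumed structure of a ~497-sample
gastric-cancer cohort; its defaults are the study conditions of the test
suite and acceptance script:

* subtype composition 117/90/93/91/106 (stem-like/gastric/inflammatory/
  intestinal/mixed-stromal) out of 497, with per-subtype latent ALT-like
  rates 92.3/62.92/20/29.41/42.42% — jointly implying ~255 ALT-like samples;
* baseline expression log-normal (meanlog 3, sdlog 1), i.i.d. across genes
  and samples; the rank-based statistic is insensitive to the marginal, so
  structure matters more than realism here;
* a symmetric chromatin signal: ALT-arm genes shifted by
  ±`chr_effect_sd`·sdlog on the log scale (up in latent ALT-like samples,
  down in latent non-ALT), telomerase-arm genes by ∓`tel_effect_sd`·sdlog.
  The two-sided plant mirrors a bimodal upregulated/downregulated chromatin
  phenotype; a one-sided plant would leave non-ALT samples exactly on the
  null and cap any q<0.5-gated classifier near ~84% accuracy, which is a
  property of the decision rule, not of the implementation;
* anchor correlations (NR2F2–ZEB1 0.61, NR2F2–YAP1 0.54) planted as Gaussian
  correlations of log expression. Correlations of expression are
  conventionally computed on the log scale; the Pearson r of raw lognormal
  values is outlier-dominated and would be a needlessly unstable target;
* survival exponential with median 36 months, hazard ×2 for latent ALT-like
  samples, independent exponential censoring with its rate solved (Brent) so
  the expected censored fraction hits `censor_rate` (default 0.30);
* six literal anchor symbols (NR2F2, ZEB1, YAP1, ZNF827, EGR1, NR3C1) kept
  outside the TMM sets; EGR1 and NR3C1 get a mild (+0.5 sdlog) ALT-side
  shift as documented flavor. All other genes are synthetic `G%04d` symbols,
  the first 97 of which form the default TMM collection.

What the generator does **not** emulate: count-level RNA-seq noise (library
size, negative-binomial overdispersion), batch or cohort effects, correlated
co-expression modules beyond the planted ones, or any real gene membership —
the shipped 97-gene collection is a structural placeholder. Passing tests
therefore demonstrate that the machinery is correct and calibrated under the
assumed generative structure, not that the biological signature itself is
valid in real tumors; real analyses must supply curated GMTs.

## Numerical choices and degenerate inputs

* Empirical p-values use the add-one estimator, never 0; reported p-values
  are floored at the smallest positive double, and the "< 2.22e-16"
  convention is applied in report formatting only.
* Status ties break upward (observed = null median ⇒ upregulated); a q-value
  exactly at the FDR threshold is non-ALT (strict `<`).
* Sets with no measured member are skipped with a warning (error only when
  nothing remains); a set equal to the whole universe is an error.
* Genes constant in both groups are skipped in differential expression;
  zero-variance genes are dropped before clustering and z-scoring.
* Exact rank-sum enumeration switches on when both groups are ≤ 10.
* The log-rank chi-square approximation is used at 1 df; its finite-sample
  size is visibly inflated below ~25 events per group (the calibration
  checks run at 50 per group).

## Scale of the shipped checks

Test-suite and acceptance problem sizes are chosen as the smallest at which
the checked properties are stable: oracle equivalence on ≤50×10 matrices,
null calibration on 200×2,000 cohorts at 2,000 permutations across 5 seeds,
label recovery on full 497×5,000 cohorts, type-I simulations at 1,000
replicates, power and C-index designs at 250/group with hazard ratio 2 (the
C-index check uses a continuous risk score with hazard ratio 2 per score SD,
since a two-point risk caps Harrell's C at ≈0.58 regardless of
implementation). The whole suite runs in about a minute.

## Known limitations

* The permutation unit is the gene set (competitive null); sample-label
  permutation nulls are not implemented.
* No probe collapsing, alias resolution or ortholog mapping — symbols match
  case-sensitively after whitespace stripping.
* No Cox modeling or multivariable adjustment; the C-index is a property of
  the signature score directly, not of a fitted model.
* FDR is computed across samples within a set; alternative families (across
  sets, joint) are not offered.
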