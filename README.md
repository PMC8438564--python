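# tmmscope

Transcriptome-based classification of tumor telomere-maintenance mechanisms
(TMM), with the survival, differential-expression and correlation analyses
that typically follow.

Cancers keep their telomeres either by reactivating telomerase or through the
recombination-based **alternative lengthening of telomeres (ALT)** pathway.
`tmmscope` infers which route a bulk tumor transcriptome is using: it scores
six TMM sub-pathways per sample — two telomerase-arm sets (`Tel_TERT`,
`Tel_TERC_DKC1`; 38 genes) and four ALT-arm sets (`ALT_HR`, `ALT_CHR`,
`ALT_PML`, `ALT_ins`; 59 genes) — and calls a sample **ALT-like** when its
chromatin-decompaction (`ALT_CHR`) enrichment is upregulated at FDR < 0.5
against a permutation background. The package targets cohort analyses of the
gastric-cancer kind (a few hundred samples across molecular subtypes such as
stem-like, gastric, inflammatory, intestinal and mixed-stromal), but nothing
in it is tissue-specific. It is a library first (with a thin `tmmscope` CLI),
and ships a synthetic-cohort generator so every stage is testable without any
download.

## The statistic

For one sample, genes are ranked by expression (ascending average ranks
$r_g \in [1, G]$). The raw enrichment score of a gene set $Sc$ with $k$
measured members is the sum over all list positions $i$ (descending rank
order) of the difference of two ECDFs:

$$ES(Sc) \;=\; \sum_{i=1}^{G}\Big[ P_{\text{in}}(i) - P_{\text{out}}(i) \Big],
\qquad
P_{\text{in}}(i)=\frac{\sum_{g \in Sc,\; \text{pos}(g)\le i} r_g^{\alpha}}
                       {\sum_{g \in Sc} r_g^{\alpha}},\quad
P_{\text{out}}(i)=\frac{\#\{g \notin Sc: \text{pos}(g)\le i\}}{G-k}$$

with weight exponent $\alpha = 0.25$ by default. Tied genes contribute the
average over all orderings of their tie block, which collapses to using the
average rank itself as the position weight — so scores are tie-order-free and
a fully tied sample scores 0 for every set. Scores are range-normalized
across the whole matrix for comparability between sets.

Calibration draws `n_perm` uniform random gene sets of the same size (the
standard competitive null), yielding per-sample add-one empirical p-values
$p = (1 + \#\{ES_{\text{null}} \ge ES_{\text{obs}}\})/(1 + n_{\text{perm}})$;
"upregulated" means at or above the per-sample null median. Benjamini–
Hochberg across samples gives q-values, and
`label = ALT_like iff upregulated and q < 0.5`. Downstream: Welch t / rank-sum
group comparisons with BH, Pearson anchor-gene panels, Kaplan–Meier +
log-rank survival contrasts and Harrell's concordance index for signature
risk scores.

## Worked example

```python
from tmmscope import generate_cohort
cohort = generate_cohort(seed=7)            # 497 samples x 5,000 genes
```

then score, calibrate and classify (full scripts under `examples/`):

```text
$ python examples/02_score_and_classify.py
per-sample calls (head):
sample_id  chr_score   p     q        status tel_axis alt_axis    label
    S0001     -0.457 1.0 1.000 downregulated TEL_high  ALT_low  non_ALT
    S0002     -0.307 1.0 1.000 downregulated TEL_high  ALT_low  non_ALT
    S0003      0.450 0.0 0.001   upregulated  TEL_low ALT_high ALT_like

ALT-like: 266   non-ALT: 231
agreement with latent truth: 100.0%
stem-like samples called ALT-like: 92.1% (planted 92.3%)
```

Each sample gets its chromatin score, empirical p, BH q, the two TMM axes
(telomerase-axis and ALT-axis status — every sample carries both subtype
assignments) and the final label. On this synthetic cohort the classifier
recovers the planted labels perfectly and reproduces the planted stem-like
ALT-like fraction. The survival example shows the planted prognosis gap:

```text
$ python examples/03_survival_analysis.py
ALT_like  n=266  median survival ~ 17.8 months
non_ALT   n=231  median survival ~ 32.9 months
log-rank: chi2 = 21.9, p = 2.84e-06 (ALT-like prognosis is worse by construction)
ALT-signature risk C-index: 0.545 (0.5 = uninformative)
```

and `examples/04_correlation_panels.py` recovers the planted NR2F2–ZEB1
(r ≈ 0.61) and NR2F2–YAP1 (r ≈ 0.54) log-expression correlations with
BH-adjusted significance encoded as −log10(q) (> 1.3 ⇔ q < 0.05).

The same pipeline runs from the shell on your own files:

```bash
tmmscope simulate --out sim --seed 7
tmmscope all --expression sim/cohort_expression.tsv --gmt sim/cohort_sets.gmt \
             --clinical sim/cohort_clinical.tsv --outdir results --seed 7
```

Inputs are plain text: genes-in-rows TSV or GCT 1.2 expression, GMT gene
sets (the description field carries the sub-pathway tag), and a tab-delimited
clinical table (`sample_id  subtype  time  event`). The shipped default TMM
collection is a structural placeholder (correct 6/38/59/97 layout, synthetic
symbols); substitute your curated GMT for real analyses.

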