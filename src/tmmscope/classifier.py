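"""TMM classification: permutation background, empirical p-values, ALT-like calls.

A sample is called ``ALT_like`` when its chromatin-decompaction (ALT_CHR)
enrichment score is "upregulated" — at or above the median of a matched-size
random-gene-set background for that sample — and its Benjamini–Hochberg
q-value (BH across samples, within the set) falls strictly below the FDR
threshold (default 0.5, deliberately permissive but faithful to the published
decision rule).  Every sample additionally carries a telomerase-axis and an
ALT-axis status, the "two telomere maintenance subtypes" of the pipeline.

The background resamples uniform random gene sets of the same size as the
observed set from the measured gene universe — the standard competitive null
for per-sample set scores.  The number of permutations is a configuration
knob (default 2,000; arbitrarily large backgrounds are supported, just slow).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from statsmodels.stats.multitest import multipletests

from .enrichment import EnrichmentScoreMatrix, SsgseaEngine
from .expression import ExpressionMatrix
from .gene_sets import TEL_SUB_PATHWAYS

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistribution",
    "permutation_null",
    "empirical_p",
    "bh_adjust",
    "classify",
    "cluster_samples",
    "linkage_to_newick",
]

ALT_CHR = "ALT_CHR"


@dataclass
class NullDistribution:
    """Per-sample background scores of random gene sets of one fixed size.

    ``scores`` has shape (n_perm, n_samples): row i holds the scores of the
    i-th random set in every sample context.  Regenerating with the same seed
    reproduces the scores exactly.
    """

    set_name: str
    set_size: int
    n_perm: int
    seed: int
    samples: list[str] = field(repr=False)
    scores: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.scores.shape != (self.n_perm, len(self.samples)):
            raise ValueError(
                f"null scores shape {self.scores.shape} != ({self.n_perm}, {len(self.samples)})"
            )


def permutation_null(
    m: ExpressionMatrix,
    set_size: int,
    n_perm: int,
    seed: int,
    weight_exponent: float = 0.25,
    set_name: str = "",
    engine: SsgseaEngine | None = None,
) -> NullDistribution:
    """Score ``n_perm`` uniform random gene sets of ``set_size`` per sample.

    Pass a prebuilt ``engine`` to amortize the rank/sort precomputation across
    several nulls on the same matrix (the engine's weight exponent then wins).
    """
    G = m.shape[0]
    if not (1 <= set_size < G):
        raise ValueError(f"set_size must be in [1, {G - 1}], got {set_size}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable background")
    if engine is None:
        engine = SsgseaEngine(m, weight_exponent=weight_exponent)
    rng = np.random.default_rng(seed)
    idx_matrix = np.empty((n_perm, set_size), dtype=np.int64)
    for i in range(n_perm):
        idx_matrix[i] = rng.choice(G, size=set_size, replace=False)
    scores = engine.score_index_matrix(idx_matrix)
    return NullDistribution(
        set_name=set_name or f"random_k{set_size}",
        set_size=set_size,
        n_perm=n_perm,
        seed=seed,
        samples=list(m.samples),
        scores=scores,
    )


def empirical_p(observed: float, null_scores: np.ndarray, side: str = "upper"):
    """Add-one empirical tail p-value plus direction status against a null.

    Returns ``(p, status)`` where ``status`` is ``"upregulated"`` when the
    observed score is at or above the null median (``>=`` by convention) and
    ``"downregulated"`` otherwise, and ``p = (1 + #{as-or-more extreme on
    ``side``}) / (1 + n)`` — never 0, at most 1.
    """
    null_scores = np.asarray(null_scores, dtype=float).ravel()
    if null_scores.size == 0:
        raise ValueError("empty null distribution")
    status = "upregulated" if observed >= np.median(null_scores) else "downregulated"
    if side == "upper":
        extreme = int((null_scores >= observed).sum())
    elif side == "lower":
        extreme = int((null_scores <= observed).sum())
    else:
        raise ValueError(f"side must be 'upper' or 'lower', got {side!r}")
    p = (1 + extreme) / (1 + null_scores.size)
    return p, status


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg q-values (step-up FDR adjustment)."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def classify(
    scores: EnrichmentScoreMatrix,
    nulls: Mapping[str, NullDistribution],
    fdr_threshold: float = 0.5,
) -> pd.DataFrame:
    """Assign ALT-like / non-ALT labels from chromatin-decompaction enrichment.

    Calibration runs on raw scores (the nulls are raw-score backgrounds);
    the reported ``chr_score`` is the normalized score for display.  The
    telomerase axis, when telomerase-arm scores and nulls are available, takes
    the per-sample max over Tel_TERT / Tel_TERC_DKC1 against the element-wise
    max of their backgrounds; otherwise it is reported as ``NA``.

    Returns a calls table: sample_id, chr_score, p, q, status, tel_axis,
    alt_axis, label.
    """
    if not (0 < fdr_threshold <= 1):
        raise ValueError("fdr_threshold must be in (0, 1]")
    if ALT_CHR not in scores.set_names:
        raise ValueError(f"score matrix lacks required set {ALT_CHR!r}")
    if ALT_CHR not in nulls:
        raise ValueError(f"null distributions lack required set {ALT_CHR!r}")
    if fdr_threshold >= 0.25:
        logger.info(
            "classifying with permissive FDR threshold %.2f (published default 0.5)",
            fdr_threshold,
        )
    samples = scores.samples
    null_chr = nulls[ALT_CHR]
    if null_chr.samples != samples:
        raise ValueError("ALT_CHR null was computed on different samples than the scores")

    obs = scores.raw.loc[ALT_CHR].to_numpy()
    bg = null_chr.scores
    n_perm = bg.shape[0]
    p = (1 + (bg >= obs[None, :]).sum(axis=0)) / (1 + n_perm)
    med = np.median(bg, axis=0)
    up = obs >= med
    q = bh_adjust(p)
    label = np.where(up & (q < fdr_threshold), "ALT_like", "non_ALT")
    alt_axis = np.where(up, "ALT_high", "ALT_low")

    tel_sets = [s for s in TEL_SUB_PATHWAYS if s in scores.set_names and s in nulls]
    if tel_sets:
        tel_obs = scores.raw.loc[tel_sets].to_numpy().max(axis=0)
        tel_bg = np.maximum.reduce([nulls[s].scores for s in tel_sets])
        tel_axis = np.where(tel_obs >= np.median(tel_bg, axis=0), "TEL_high", "TEL_low")
    else:
        logger.warning("telomerase-arm scores or nulls unavailable; tel_axis reported as NA")
        tel_axis = np.full(len(samples), "NA", dtype=object)

    calls = pd.DataFrame(
        {
            "sample_id": samples,
            "chr_score": scores.normalized.loc[ALT_CHR].to_numpy(),
            "p": p,
            "q": q,
            "status": np.where(up, "upregulated", "downregulated"),
            "tel_axis": tel_axis,
            "alt_axis": alt_axis,
            "label": label,
        }
    )
    counts = calls["label"].value_counts()
    logger.info(
        "classified %d samples: %d ALT_like / %d non_ALT (FDR < %g)",
        len(calls), counts.get("ALT_like", 0), counts.get("non_ALT", 0), fdr_threshold,
    )
    return calls


def cluster_samples(m: ExpressionMatrix, log_offset: float = 1.0):
    """Average-linkage hierarchical clustering of samples.

    Expression is log10(x + offset)-transformed, genes with zero variance
    across samples are dropped, and the sample-pair distance is one minus the
    Pearson correlation.  Returns ``(linkage_matrix, leaf_sample_ids)``;
    tie-breaks are deterministic in the input sample order (sample id order of
    the matrix).
    """
    if m.shape[1] < 2:
        raise ValueError("clustering needs at least 2 samples")
    x = np.log10(m.values + log_offset)
    keep = x.std(axis=1) > 0
    x = x[keep]
    if x.shape[0] < 2:
        raise ValueError("fewer than 2 genes with non-zero variance")
    corr = np.corrcoef(x, rowvar=False)
    dist = 1.0 - corr
    iu = np.triu_indices(len(m.samples), k=1)
    condensed = np.maximum(dist[iu], 0.0)  # clip tiny negative rounding
    linkage = sch.linkage(condensed, method="average")
    leaves = [m.samples[i] for i in sch.leaves_list(linkage)]
    return linkage, leaves


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a SciPy linkage matrix as a Newick string (skbio backend)."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(linkage, labels)
    import io

    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()
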