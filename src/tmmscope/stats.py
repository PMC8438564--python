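"""Group-wise statistics downstream of TMM classification.

Differential expression (Welch t by default), pathway-score comparisons
(Mann–Whitney rank-sum, exact for small groups), anchor-gene correlation
panels and the full pairwise correlation grid with -log10(q) encoding.
All multiple-testing correction is Benjamini–Hochberg.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats as ss

from .classifier import bh_adjust
from .enrichment import EnrichmentScoreMatrix
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "differential_expression",
    "compare_scores",
    "correlate_with_anchor",
    "correlation_heatmap_table",
    "format_p",
]

_P_FLOOR = np.finfo(float).tiny
_EPS_FLOOR = 2.0 ** -52  # double-precision floor used in report formatting


def format_p(p: float) -> str:
    """Report-style p formatting, mirroring the '< 2.22e-16' convention."""
    if p < _EPS_FLOOR:
        return "< 2.22e-16"
    return f"{p:.3g}"


def _floor_p(p) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=float), _P_FLOOR, 1.0)


def _group_masks(labels: Sequence, samples: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    if labels.shape[0] != len(samples):
        raise ValueError("labels length does not match number of samples")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(uniq)}")
    # group A by label value (True for booleans, first in sort order otherwise)
    # so direction is a property of the labels, not of the sample ordering
    group_a = True if labels.dtype == bool else uniq[0]
    mask_a = labels == group_a
    return mask_a, ~mask_a


def differential_expression(
    m: ExpressionMatrix,
    labels: Sequence,
    test: str = "student_t",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene two-group comparison with BH correction across tested genes.

    ``labels`` aligns with ``m.samples`` and must take exactly two values;
    group A is the first label encountered and ``direction`` reports which
    group has the higher mean.  The t-test is the Welch (unequal-variance)
    variant unless ``equal_var=True``.  Genes constant in both groups are
    skipped with a warning.
    """
    if test not in ("student_t", "wilcoxon"):
        raise ValueError(f"unknown test {test!r}")
    mask_a, mask_b = _group_masks(labels, m.samples)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    x = m.values[:, mask_a]
    y = m.values[:, mask_b]
    constant = (x.std(axis=1) == 0) & (y.std(axis=1) == 0)
    if constant.any():
        logger.warning("%d genes constant in both groups skipped", int(constant.sum()))
    keep = ~constant
    x, y = x[keep], y[keep]
    genes = np.asarray(m.genes, dtype=object)[keep]
    if test == "student_t":
        stat, p = ss.ttest_ind(x, y, axis=1, equal_var=equal_var)
    else:
        res = ss.mannwhitneyu(x, y, axis=1, alternative="two-sided")
        stat, p = res.statistic, res.pvalue
    p = _floor_p(p)
    direction = np.where(x.mean(axis=1) >= y.mean(axis=1), "up_in_A", "up_in_B")
    return pd.DataFrame(
        {
            "feature": genes,
            "stat": stat,
            "p": p,
            "q": bh_adjust(p),
            "direction": direction,
            "test": test,
        }
    )


def compare_scores(
    scores: EnrichmentScoreMatrix,
    labels: Sequence,
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """Per-gene-set two-group comparison of enrichment scores.

    The rank-sum test uses exact enumeration when both groups have <= 10
    samples and the normal approximation with continuity correction
    otherwise.  ``test="student_t"`` switches to Welch t.
    """
    if test not in ("wilcoxon", "student_t"):
        raise ValueError(f"unknown test {test!r}")
    mask_a, mask_b = _group_masks(labels, scores.samples)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    rows = []
    table = scores.normalized
    for name in scores.set_names:
        x = table.loc[name].to_numpy()[mask_a]
        y = table.loc[name].to_numpy()[mask_b]
        if test == "wilcoxon":
            method = "exact" if (len(x) <= 10 and len(y) <= 10) else "asymptotic"
            res = ss.mannwhitneyu(x, y, alternative="two-sided", method=method)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            stat, p = ss.ttest_ind(x, y, equal_var=False)
        rows.append(
            {
                "feature": name,
                "stat": stat,
                "p": float(_floor_p(p)),
                "direction": "up_in_A" if x.mean() >= y.mean() else "up_in_B",
                "test": test,
            }
        )
    out = pd.DataFrame(rows)
    out.insert(3, "q", bh_adjust(out["p"].to_numpy()))
    return out


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r, p = ss.pearsonr(x, y)
    return float(r), float(p)


def correlate_with_anchor(
    m: ExpressionMatrix,
    anchor: str,
    panel: Iterable[str],
) -> pd.DataFrame:
    """Pearson correlation of each panel gene with one anchor gene.

    Two-sided p from the t transform of r, BH across the panel.  Panel genes
    absent from the matrix are skipped with a warning; an absent anchor is an
    error.
    """
    if anchor not in m.df.index:
        raise ValueError(f"anchor gene {anchor!r} not in expression matrix")
    panel = list(panel)
    missing = [g for g in panel if g not in m.df.index]
    if missing:
        logger.warning("panel genes absent from matrix skipped: %s", missing)
    panel = [g for g in panel if g in m.df.index]
    if not panel:
        raise ValueError("no panel gene is measured in the expression matrix")
    ax = m.df.loc[anchor].to_numpy()
    rows = []
    for g in panel:
        r, p = _pearson_with_p(ax, m.df.loc[g].to_numpy())
        rows.append({"gene_a": anchor, "gene_b": g, "r": r, "p": float(_floor_p(p))})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["neg_log10_q"] = -np.log10(_floor_p(out["q"].to_numpy()))
    return out


def correlation_heatmap_table(
    m: ExpressionMatrix,
    genes_a: Iterable[str],
    genes_b: Iterable[str],
) -> pd.DataFrame:
    """All pairwise Pearson correlations between two gene panels.

    BH is applied over the full pair grid and significance is encoded as
    ``neg_log10_q = -log10(q)`` (so q = 0.05 maps to ~1.3).  Returns a long
    table; pivot on (gene_a, gene_b) for a heatmap-shaped matrix.
    """
    genes_a = [g for g in genes_a if g in m.df.index]
    genes_b = [g for g in genes_b if g in m.df.index]
    if not genes_a or not genes_b:
        raise ValueError("empty intersection between a gene panel and the expression matrix")
    rows = []
    for ga in genes_a:
        xa = m.df.loc[ga].to_numpy()
        for gb in genes_b:
            r, p = _pearson_with_p(xa, m.df.loc[gb].to_numpy())
            rows.append({"gene_a": ga, "gene_b": gb, "r": r, "p": float(_floor_p(p))})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["neg_log10_q"] = -np.log10(_floor_p(out["q"].to_numpy()))
    return out
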