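"""Single-sample gene-set enrichment (ssGSEA) scoring.

For one sample, genes are ranked by expression (ascending, average ranks for
ties) and then walked in descending-rank order.  The raw enrichment score of a
gene set is the sum over all list positions of the difference between two
empirical CDFs:

* the in-set ECDF, in which each member gene contributes its rank raised to a
  weight exponent ``alpha`` (default 0.25), normalized by the in-set total, and
* the out-of-set ECDF, which steps uniformly by ``1/(G - k)`` (``G`` genes
  measured, ``k`` of them in the set).

Summing the running difference over every position is algebraically identical
to weighting each gene's step by the number of list positions at or after it
— which, for tie-free data, is exactly the gene's rank.  The engine therefore
scores a set in O(k) per sample straight from the rank matrix, with no
per-permutation sorting.  Tied genes share their average rank, which equals
averaging the positional walk over every ordering of the tie block: scores
are tie-order-free and reproducible across platforms, and a fully tied sample
scores 0 for every set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .gene_sets import GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "rank_transform",
    "ssgsea_score",
    "SsgseaEngine",
    "EnrichmentScoreMatrix",
    "enrichment_matrix",
]


def rank_transform(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample ascending ranks (1..G), ties receiving average ranks."""
    return m.df.rank(axis=0, method="average")


class SsgseaEngine:
    """Precomputed scoring engine for one expression matrix.

    Precomputes per-sample average ranks and rank weights ``rank**alpha``;
    any gene set — observed or permuted — then scores in O(k) per sample.
    A gene's contribution weight is its (average) rank, i.e. the number of
    positions at or after it in the descending walk, tie blocks averaged.
    """

    def __init__(self, m: ExpressionMatrix, weight_exponent: float = 0.25):
        if weight_exponent < 0:
            raise ValueError("weight_exponent must be >= 0")
        self.weight_exponent = float(weight_exponent)
        self.genes = m.genes
        self.samples = m.samples
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        ranks = rank_transform(m).to_numpy()
        G, S = ranks.shape
        self.n_genes = G
        self._weights = ranks ** self.weight_exponent
        self._tail = ranks  # positions at/after each gene, tie-averaged
        self._total_tail = G * (G + 1) / 2.0

    def member_indices(self, genes: Iterable[str]) -> np.ndarray:
        """Row indices of the given symbols that are measured in the matrix."""
        idx = [self._gene_index[g] for g in genes if g in self._gene_index]
        return np.asarray(sorted(set(idx)), dtype=np.int64)

    def score_indices(self, idx: np.ndarray) -> np.ndarray:
        """Raw enrichment score per sample for the gene rows ``idx``."""
        G = self.n_genes
        k = len(idx)
        if k == 0:
            raise ValueError("set not represented in the expression matrix")
        if k >= G:
            raise ValueError("set equals universe: no out-of-set genes to compare against")
        w = self._weights[idx, :]
        tail = self._tail[idx, :]
        in_part = (w * tail).sum(axis=0) / w.sum(axis=0)
        out_part = (self._total_tail - tail.sum(axis=0)) / (G - k)
        return in_part - out_part

    def score_index_matrix(self, idx_matrix: np.ndarray, chunk: int = 256) -> np.ndarray:
        """Score many equal-size index sets at once -> (n_sets, n_samples)."""
        idx_matrix = np.asarray(idx_matrix, dtype=np.int64)
        n_sets, k = idx_matrix.shape
        G = self.n_genes
        if not (1 <= k < G):
            raise ValueError(f"set size must be in [1, {G - 1}], got {k}")
        out = np.empty((n_sets, len(self.samples)))
        for start in range(0, n_sets, chunk):
            sl = idx_matrix[start:start + chunk]
            w = self._weights[sl, :]          # (c, k, S)
            tail = self._tail[sl, :]
            in_part = (w * tail).sum(axis=1) / w.sum(axis=1)
            out_part = (self._total_tail - tail.sum(axis=1)) / (G - k)
            out[start:start + len(sl)] = in_part - out_part
        return out

    def score_set(self, gene_set: GeneSet | Iterable[str]) -> np.ndarray:
        genes = gene_set.genes if isinstance(gene_set, GeneSet) else tuple(gene_set)
        return self.score_indices(self.member_indices(genes))


def ssgsea_score(
    sample_ranks: pd.Series,
    gene_set: GeneSet | Iterable[str],
    weight_exponent: float = 0.25,
) -> float:
    """Raw enrichment score of one gene set in one pre-ranked sample.

    ``sample_ranks`` maps gene symbols to their within-sample ranks (as from
    :func:`rank_transform`).  Convenience wrapper over the same arithmetic the
    matrix engine uses.
    """
    genes = gene_set.genes if isinstance(gene_set, GeneSet) else tuple(gene_set)
    ranks = sample_ranks.to_numpy(dtype=float)
    symbols = np.asarray(sample_ranks.index, dtype=object)
    G = len(ranks)
    member = np.isin(symbols, np.asarray(list(genes), dtype=object))
    k = int(member.sum())
    if k == 0:
        raise ValueError("set not represented in the expression matrix")
    if k >= G:
        raise ValueError("set equals universe: no out-of-set genes to compare against")
    w = ranks ** weight_exponent
    in_part = (w[member] * ranks[member]).sum() / w[member].sum()
    out_part = ranks[~member].sum() / (G - k)
    return float(in_part - out_part)


@dataclass
class EnrichmentScoreMatrix:
    """Gene-sets x samples enrichment scores plus scoring metadata.

    ``raw`` holds the running-sum scores; ``normalized`` divides the whole
    matrix by its global score range when ``normalization == "range"`` (the
    usual single-sample-enrichment convention, making scores comparable across
    sets), and equals ``raw`` under ``normalization == "none"``.
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame
    weight_exponent: float
    normalization: str

    @property
    def set_names(self) -> list[str]:
        return self.raw.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.raw.columns.tolist()

    def write_tsv(self, path, which: str = "normalized", header_comment: str | None = None) -> None:
        table = self.normalized if which == "normalized" else self.raw
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            table.to_csv(fh, sep="\t", index_label="gene_set")


def enrichment_matrix(
    m: ExpressionMatrix,
    collection: GeneSetCollection,
    weight_exponent: float = 0.25,
    normalization: str = "range",
) -> EnrichmentScoreMatrix:
    """Score every gene set in ``collection`` against every sample of ``m``.

    Sets with no measured member are skipped with a warning; an error is
    raised only if nothing remains.
    """
    if normalization not in ("range", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    engine = SsgseaEngine(m, weight_exponent=weight_exponent)
    rows = {}
    for gs in collection:
        idx = engine.member_indices(gs.genes)
        if len(idx) == 0:
            logger.warning("gene set %s has no measured members; skipped", gs.name)
            continue
        if len(idx) >= engine.n_genes:
            logger.warning("gene set %s covers the whole gene universe; skipped", gs.name)
            continue
        rows[gs.name] = engine.score_indices(idx)
    if not rows:
        raise ValueError("no gene set overlaps the expression matrix")
    raw = pd.DataFrame.from_dict(rows, orient="index", columns=m.samples)
    if normalization == "range":
        span = raw.to_numpy().max() - raw.to_numpy().min()
        normalized = raw / span if span > 0 else raw.copy()
    else:
        normalized = raw.copy()
    return EnrichmentScoreMatrix(
        raw=raw,
        normalized=normalized,
        weight_exponent=weight_exponent,
        normalization=normalization,
    )
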