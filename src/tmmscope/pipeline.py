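"""End-to-end pipeline: score -> calibrate -> classify -> downstream tables.

Every output table starts with a comment header carrying the package version,
the seed and the configuration hash, so a re-run with an unchanged
configuration is byte-for-byte reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from . import __version__
from .classifier import (
    ALT_CHR,
    classify,
    cluster_samples,
    linkage_to_newick,
    permutation_null,
)
from .enrichment import SsgseaEngine, enrichment_matrix
from .expression import ExpressionMatrix
from .gene_sets import TEL_SUB_PATHWAYS, GeneSet, read_gmt
from .stats import compare_scores, differential_expression
from .survival import harrell_cindex, km_estimate, logrank_test, read_clinical, signature_risk

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run (flat YAML-compatible)."""

    expression: str
    gmt: str
    outdir: str
    clinical: str | None = None
    weight_exponent: float = 0.25
    normalization: str = "range"
    n_perm: int = 2000
    fdr_threshold: float = 0.5
    log10_offset: float = 1.0
    de_q_threshold: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        # outdir is excluded: where results land must not change what they are
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _header(cfg: PipelineConfig) -> str:
    return f"tmmscope {__version__} seed={cfg.seed} config={cfg.config_hash()}"


def _write_table(df: pd.DataFrame, path: str, cfg: PipelineConfig, index_label=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_header(cfg)}\n")
        df.to_csv(fh, sep="\t", index=index_label is not None, index_label=index_label)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return a manifest (also written to outdir).

    Stages: enrichment scores, permutation calibration + classification,
    hierarchical clustering, differential expression, per-set score
    comparisons, and — when a clinical table is configured — KM tables,
    log-rank test and signature C-indexes.  A stage that cannot run for lack
    of input (no clinical table, a single-label classification) is skipped
    with a warning; genuine errors propagate with the stage name.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    outputs: dict[str, str] = {}
    warnings_log: list[str] = []

    def _out(name: str) -> str:
        path = os.path.join(cfg.outdir, name)
        outputs[name] = path
        return path

    # --- load inputs -------------------------------------------------------
    try:
        expr = ExpressionMatrix.read_tsv(cfg.expression)
        collection = read_gmt(cfg.gmt)
    except Exception as e:
        raise RuntimeError(f"stage load_inputs: {e}") from e

    # --- enrichment --------------------------------------------------------
    try:
        scores = enrichment_matrix(
            expr, collection,
            weight_exponent=cfg.weight_exponent,
            normalization=cfg.normalization,
        )
        scores.write_tsv(_out("scores.tsv"), header_comment=_header(cfg))
    except Exception as e:
        raise RuntimeError(f"stage enrichment: {e}") from e

    # --- calibration + classification -------------------------------------
    try:
        engine = SsgseaEngine(expr, weight_exponent=cfg.weight_exponent)
        nulls = {}
        rng = np.random.default_rng(cfg.seed)
        for name in (ALT_CHR, *TEL_SUB_PATHWAYS):
            if name not in collection:
                continue
            k = len(engine.member_indices(collection[name].genes))
            if k == 0:
                continue
            nulls[name] = permutation_null(
                expr, set_size=k, n_perm=cfg.n_perm,
                seed=int(rng.integers(2 ** 31)), set_name=name, engine=engine,
            )
        calls = classify(scores, nulls, fdr_threshold=cfg.fdr_threshold)
        _write_table(calls, _out("calls.tsv"), cfg)
    except Exception as e:
        raise RuntimeError(f"stage classify: {e}") from e

    # --- clustering --------------------------------------------------------
    try:
        linkage, leaves = cluster_samples(expr, log_offset=cfg.log10_offset)
        newick = linkage_to_newick(linkage, expr.samples)
        with open(_out("dendrogram.nwk"), "w") as fh:
            fh.write(newick + "\n")
        with open(_out("leaf_order.txt"), "w") as fh:
            fh.write(f"# {_header(cfg)}\n")
            fh.write("\n".join(leaves) + "\n")
    except Exception as e:
        raise RuntimeError(f"stage clustering: {e}") from e

    # --- group statistics --------------------------------------------------
    labels = calls["label"].to_numpy()
    two_groups = len(pd.unique(labels)) == 2
    if two_groups:
        try:
            tmm_genes = sorted(collection.universe & set(expr.genes))
            de = differential_expression(
                ExpressionMatrix(expr.df.loc[tmm_genes]),
                labels == "ALT_like",
            )
            de["significant"] = de["q"] < cfg.de_q_threshold
            _write_table(de, _out("differential_expression.tsv"), cfg)
            comp = compare_scores(scores, labels == "ALT_like", test="wilcoxon")
            _write_table(comp, _out("score_comparisons.tsv"), cfg)
        except Exception as e:
            raise RuntimeError(f"stage group_stats: {e}") from e
    else:
        msg = "classification produced a single label; group statistics skipped"
        logger.warning(msg)
        warnings_log.append(msg)

    # --- survival ----------------------------------------------------------
    if cfg.clinical is None:
        msg = "no clinical table configured; survival stage skipped"
        logger.warning(msg)
        warnings_log.append(msg)
    else:
        try:
            clinical = read_clinical(cfg.clinical).aligned_to(expr.samples)
            times = clinical["time"].to_numpy(dtype=float)
            events = clinical["event"].to_numpy(dtype=int)
            rows = []
            if two_groups:
                chi2, p = logrank_test(times, events, labels)
                rows.append({"analysis": "logrank_alt_vs_nonalt", "statistic": chi2, "p": p})
                for grp in ("ALT_like", "non_ALT"):
                    mask = labels == grp
                    km = km_estimate(times[mask], events[mask])
                    _write_table(
                        km.reset_index(), _out(f"km_{grp.lower()}.tsv"), cfg
                    )
            else:
                msg = "single classification label; log-rank/KM-by-group skipped"
                logger.warning(msg)
                warnings_log.append(msg)
            # signature risk C-indexes on the two TMM arms and their union
            arm_sets = {
                "ALT_arm": [g for gs in collection.by_arm("ALT") for g in gs.genes],
                "TEL_arm": [g for gs in collection.by_arm("TEL") for g in gs.genes],
            }
            arm_sets["all_TMM"] = arm_sets["ALT_arm"] + arm_sets["TEL_arm"]
            cindex_rows = []
            for name, genes in arm_sets.items():
                genes = [g for g in genes if g in expr.df.index]
                if not genes:
                    continue
                risk = signature_risk(expr, GeneSet(name=name, genes=tuple(genes)))
                cindex_rows.append(
                    {
                        "signature": name,
                        "n_genes": len(genes),
                        "c_index": harrell_cindex(risk.to_numpy(), times, events),
                    }
                )
            if rows:
                _write_table(pd.DataFrame(rows), _out("survival_tests.tsv"), cfg)
            if cindex_rows:
                _write_table(pd.DataFrame(cindex_rows), _out("cindex.tsv"), cfg)
        except Exception as e:
            raise RuntimeError(f"stage survival: {e}") from e

    # --- manifest ----------------------------------------------------------
    import platform

    manifest = {
        "tmmscope_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "outputs": sorted(outputs),
        "warnings": warnings_log,
    }
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs["manifest.json"] = os.path.join(cfg.outdir, "manifest.json")
    return manifest
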