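"""Synthetic gastric-cancer-like cohorts with planted TMM structure.

The generator emulates the statistical skeleton the pipeline assumes in a
~497-sample cohort spread over five molecular subtypes: a 97-gene TMM
collection (38 telomerase-arm + 59 ALT-arm genes across six sub-pathways),
chromatin-decompaction enrichment concentrated in latent ALT-like samples
(92.3% of stem-like samples by default, with subtype-specific rates for the
rest), a survival disadvantage for ALT-like samples, and named anchor-gene
correlations (e.g. NR2F2–ZEB1 at Pearson r = 0.61).

Baseline expression is log-normal (meanlog 3, sdlog 1) — a generic bulk-
expression stand-in; the scoring statistic is rank-based, so the marginal
shape matters less than the planted structure.  Signals are planted on the
log scale: latent ALT-like samples shift ALT-arm genes up by
``chr_effect_sd`` log-SD units and telomerase-arm genes down by
``tel_effect_sd``; latent non-ALT samples carry the opposite signs (chromatin
status is a bimodal up/down phenotype).  Anchor correlations are planted as
Gaussian correlations of the log-expression values — the scale on which
expression correlations are conventionally computed and reported (Pearson r
of the raw lognormal values is badly outlier-inflated and would not be a
stable target).  Everything is reproducible from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .expression import ExpressionMatrix
from .gene_sets import GeneSet, GeneSetCollection
from .survival import SUBTYPES, ClinicalTable

__all__ = [
    "CohortConfig",
    "SimulatedCohort",
    "generate_cohort",
    "generate_null_cohort",
    "DEFAULT_SUBTYPE_PROPORTIONS",
    "DEFAULT_ALT_RATES",
    "DEFAULT_TMM_STRUCTURE",
]

# Overall subtype composition (counts 117/90/93/91/106 of 497) chosen jointly
# with the per-subtype ALT-like rates so the implied ALT-like total is ~255.
DEFAULT_SUBTYPE_PROPORTIONS = {
    "stem_like": 117 / 497,
    "gastric": 90 / 497,
    "inflammatory": 93 / 497,
    "intestinal": 91 / 497,
    "mixed_stromal": 106 / 497,
}

# Probability that a sample of each subtype is latently ALT-like.
DEFAULT_ALT_RATES = {
    "stem_like": 0.923,
    "gastric": 0.6292,
    "inflammatory": 0.20,
    "intestinal": 0.2941,
    "mixed_stromal": 0.4242,
}

# Six TMM sub-pathways: 38 telomerase-arm + 59 ALT-arm genes = 97.
DEFAULT_TMM_STRUCTURE = {
    "Tel_TERT": 19,
    "Tel_TERC_DKC1": 19,
    "ALT_HR": 15,
    "ALT_CHR": 15,
    "ALT_PML": 15,
    "ALT_ins": 14,
}

# Literal anchor symbols kept human-readable; all other genes are G%04d.
ANCHOR_GENES = ("NR2F2", "ZEB1", "YAP1", "ZNF827", "EGR1", "NR3C1")


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort; defaults are the emulated study shape."""

    n_samples: int = 497
    n_genes: int = 5000
    subtype_proportions: dict = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_PROPORTIONS))
    alt_rates: dict = field(default_factory=lambda: dict(DEFAULT_ALT_RATES))
    tmm_structure: dict = field(default_factory=lambda: dict(DEFAULT_TMM_STRUCTURE))
    chr_effect_sd: float = 2.0     # log-scale shift of ALT-arm genes, +/- by latent label
    tel_effect_sd: float = 1.0     # log-scale shift of telomerase-arm genes, opposite sign
    anchor_correlations: list = field(
        default_factory=lambda: [("NR2F2", "ZEB1", 0.61), ("NR2F2", "YAP1", 0.54)]
    )
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    median_survival_months: float = 36.0
    hazard_ratio_alt: float = 2.0
    censor_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        props = self.subtype_proportions
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        if set(props) != set(SUBTYPES):
            raise ValueError(f"subtype proportions must cover exactly {SUBTYPES}")
        for k, v in self.alt_rates.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"alt rate for {k} outside [0, 1]: {v}")
        for a, b, rho in self.anchor_correlations:
            if not (-1.0 < rho < 1.0):
                raise ValueError(f"anchor correlation {a}-{b} outside (-1, 1): {rho}")
        n_tmm = sum(self.tmm_structure.values())
        if self.n_genes < n_tmm + len(ANCHOR_GENES):
            raise ValueError(
                f"n_genes={self.n_genes} too small for {n_tmm} TMM genes + anchors"
            )
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must be in [0, 1)")
        if self.hazard_ratio_alt <= 0 or self.median_survival_months <= 0:
            raise ValueError("hazard parameters must be positive")

    @property
    def stemlike_alt_rate(self) -> float:
        return self.alt_rates["stem_like"]


@dataclass
class SimulatedCohort:
    """Generated inputs plus the latent truth behind them."""

    expression: ExpressionMatrix
    gene_sets: GeneSetCollection
    clinical: ClinicalTable
    truth: pd.DataFrame
    config: CohortConfig

    def write(self, outdir, stem: str = "cohort") -> dict[str, str]:
        """Write expression TSV, GMT, clinical TSV and truth TSV to a directory."""
        import os

        from .gene_sets import write_gmt

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "expression": os.path.join(outdir, f"{stem}_expression.tsv"),
            "gmt": os.path.join(outdir, f"{stem}_sets.gmt"),
            "clinical": os.path.join(outdir, f"{stem}_clinical.tsv"),
            "truth": os.path.join(outdir, f"{stem}_truth.tsv"),
        }
        note = f"tmmscope simulated cohort seed={self.config.seed}"
        self.expression.write_tsv(paths["expression"], header_comment=note)
        write_gmt(self.gene_sets, paths["gmt"])
        self.clinical.write_tsv(paths["clinical"], header_comment=note)
        with open(paths["truth"], "w") as fh:
            fh.write(f"# {note}\n")
            self.truth.to_csv(fh, sep="\t", index=False)
        return paths


def _censoring_rate_for(lam_c: float, hazards: np.ndarray) -> float:
    # P(censor before event) for exponential event/censoring competition
    return float(np.mean(lam_c / (hazards + lam_c)))


def _solve_censoring_rate(target: float, hazards: np.ndarray) -> float:
    lo, hi = 1e-12, 1e6
    f = lambda lc: _censoring_rate_for(lc, hazards) - target
    return brentq(f, lo * hazards.mean(), hi * hazards.mean())


def generate_cohort(cfg: CohortConfig | None = None, **overrides) -> SimulatedCohort:
    """Generate a full synthetic cohort (expression, gene sets, clinical, truth).

    Keyword overrides are applied on top of ``cfg`` (or the defaults), e.g.
    ``generate_cohort(seed=7, chr_effect_sd=3.0)``.
    """
    cfg = replace(cfg or CohortConfig(), **overrides)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, g = cfg.n_samples, cfg.n_genes

    # --- gene universe and TMM membership --------------------------------
    gene_names = [f"G{i:04d}" for i in range(1, g + 1)]
    sets = []
    start = 0
    for sub_name, size in cfg.tmm_structure.items():
        members = tuple(gene_names[start:start + size])
        sets.append(GeneSet.from_tag(sub_name, members, sub_name))
        start += size
    n_tmm = start
    # anchors live outside the TMM sets so planted correlations stay clean
    anchor_rows = {}
    for j, symbol in enumerate(ANCHOR_GENES):
        gene_names[n_tmm + j] = symbol
        anchor_rows[symbol] = n_tmm + j
    collection = GeneSetCollection(sets)

    arm_rows: dict[str, list[int]] = {"TEL": [], "ALT": [], "OTHER": []}
    offset = 0
    for gs in sets:
        arm_rows[gs.arm].extend(range(offset, offset + len(gs)))
        offset += len(gs)
    tel_idx = np.asarray(arm_rows["TEL"], dtype=np.int64)
    alt_idx = np.asarray(arm_rows["ALT"], dtype=np.int64)

    # --- subtype and latent TMM labels ------------------------------------
    subtype_names = list(cfg.subtype_proportions)
    probs = np.array([cfg.subtype_proportions[s] for s in subtype_names])
    subtypes = rng.choice(subtype_names, size=n, p=probs)
    rates = np.array([cfg.alt_rates[s] for s in subtypes])
    is_alt = rng.random(n) < rates

    # --- log-scale expression with planted shifts --------------------------
    z = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=(g, n))
    sign = np.where(is_alt, 1.0, -1.0)
    z[np.ix_(alt_idx, np.arange(n))] += cfg.chr_effect_sd * cfg.baseline_log_sd * sign
    z[np.ix_(tel_idx, np.arange(n))] -= cfg.tel_effect_sd * cfg.baseline_log_sd * sign
    # mild ALT-side upregulation of the EGR1/NR3C1 flavor anchors
    for symbol in ("EGR1", "NR3C1"):
        z[anchor_rows[symbol], is_alt] += 0.5 * cfg.baseline_log_sd

    # --- anchor correlations planted on the log-expression scale -----------
    mu, sd = cfg.baseline_log_mean, cfg.baseline_log_sd
    for gene_a, gene_b, rho in cfg.anchor_correlations:
        za = (z[anchor_rows[gene_a]] - mu) / sd
        eps = rng.standard_normal(n)
        z[anchor_rows[gene_b]] = mu + sd * (rho * za + np.sqrt(1 - rho ** 2) * eps)

    expr = ExpressionMatrix(
        pd.DataFrame(
            np.exp(z),
            index=gene_names,
            columns=[f"S{i:04d}" for i in range(1, n + 1)],
        )
    )

    # --- survival ----------------------------------------------------------
    lam0 = np.log(2) / cfg.median_survival_months
    hazards = lam0 * np.where(is_alt, cfg.hazard_ratio_alt, 1.0)
    event_times = rng.exponential(1.0 / hazards)
    if cfg.censor_rate > 0:
        lam_c = _solve_censoring_rate(cfg.censor_rate, hazards)
        censor_times = rng.exponential(1.0 / lam_c, size=n)
        observed = np.minimum(event_times, censor_times)
        events = (event_times <= censor_times).astype(int)
    else:
        observed, events = event_times, np.ones(n, dtype=int)

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": expr.samples,
                "subtype": subtypes,
                "time": observed,
                "event": events,
            }
        )
    )
    truth = pd.DataFrame(
        {
            "sample_id": expr.samples,
            "subtype": subtypes,
            "is_alt": is_alt.astype(int),
            "hazard": hazards,
            "event_time_uncensored": event_times,
        }
    )
    return SimulatedCohort(
        expression=expr, gene_sets=collection, clinical=clinical, truth=truth, config=cfg
    )


def generate_null_cohort(
    n_samples: int,
    n_genes: int,
    seed: int,
    log_mean: float = 3.0,
    log_sd: float = 1.0,
) -> ExpressionMatrix:
    """An i.i.d. log-normal matrix with no structure (type-I-error harness)."""
    rng = np.random.default_rng(seed)
    values = rng.lognormal(log_mean, log_sd, size=(n_genes, n_samples))
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"G{i:04d}" for i in range(1, n_genes + 1)],
            columns=[f"S{i:04d}" for i in range(1, n_samples + 1)],
        )
    )
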