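"""Gene-set collections for TMM scoring: GMT IO, validation, arm/sub-pathway tags.

The telomere-maintenance collection used by the classifier has a fixed
structure: two telomerase-arm sub-pathways (Tel_TERT, Tel_TERC_DKC1; 38 genes
in total) and four ALT-arm sub-pathways (ALT_HR, ALT_CHR, ALT_PML, ALT_ins;
59 genes in total), 97 genes overall.  The shipped default collection has that
structure with placeholder symbols matching the synthetic-cohort generator;
real analyses substitute their own GMT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "ValidationReport",
    "read_gmt",
    "write_gmt",
    "validate_tmm_collection",
    "default_tmm_collection",
    "TEL_SUB_PATHWAYS",
    "ALT_SUB_PATHWAYS",
    "TMM_SUB_PATHWAYS",
]

TEL_SUB_PATHWAYS = ("Tel_TERT", "Tel_TERC_DKC1")
ALT_SUB_PATHWAYS = ("ALT_HR", "ALT_CHR", "ALT_PML", "ALT_ins")
TMM_SUB_PATHWAYS = TEL_SUB_PATHWAYS + ALT_SUB_PATHWAYS

_ARM_BY_SUB_PATHWAY = {name: "TEL" for name in TEL_SUB_PATHWAYS}
_ARM_BY_SUB_PATHWAY.update({name: "ALT" for name in ALT_SUB_PATHWAYS})

# Expected sizes of a tmm-default collection (arm -> total genes).
_TMM_ARM_TOTALS = {"TEL": 38, "ALT": 59}


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered set of unique gene symbols with a pathway-arm tag.

    ``arm`` is ``TEL`` or ``ALT`` only for the six reserved TMM sub-pathway
    tags; every other collection (EMT, metabolic, signaling signatures...)
    carries ``OTHER``.
    """

    name: str
    genes: tuple[str, ...]
    arm: str = "OTHER"
    sub_pathway: str = ""

    def __post_init__(self):
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if len(self.genes) < 1:
            raise ValueError(f"gene set {self.name!r} is empty")
        cleaned = tuple(g.strip() for g in self.genes)
        if any(not g for g in cleaned):
            raise ValueError(f"gene set {self.name!r} contains empty gene symbols")
        if len(set(cleaned)) != len(cleaned):
            raise ValueError(f"gene set {self.name!r} contains duplicate symbols")
        object.__setattr__(self, "genes", cleaned)
        if self.arm not in ("TEL", "ALT", "OTHER"):
            raise ValueError(f"unknown arm {self.arm!r}")
        expected = _ARM_BY_SUB_PATHWAY.get(self.sub_pathway)
        if self.arm in ("TEL", "ALT") and expected != self.arm:
            raise ValueError(
                f"arm {self.arm} is reserved for sub-pathways "
                f"{[k for k, v in _ARM_BY_SUB_PATHWAY.items() if v == self.arm]}, "
                f"got sub_pathway={self.sub_pathway!r}"
            )

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_tag(cls, name: str, genes: Iterable[str], tag: str = "") -> "GeneSet":
        """Build a set, inferring arm/sub-pathway when ``tag`` is a reserved name."""
        arm = _ARM_BY_SUB_PATHWAY.get(tag, "OTHER")
        sub = tag if tag in _ARM_BY_SUB_PATHWAY else (tag or "")
        return cls(name=name, genes=tuple(genes), arm=arm, sub_pathway=sub)


class GeneSetCollection:
    """An ordered mapping of unique set names to :class:`GeneSet`."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.name in self._sets:
                raise ValueError(f"duplicate gene set name: {gs.name!r}")
            self._sets[gs.name] = gs
        if not self._sets:
            raise ValueError("collection must contain at least one gene set")

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for gs in self:
            out.update(gs.genes)
        return out

    def by_arm(self, arm: str) -> list[GeneSet]:
        return [gs for gs in self if gs.arm == arm]

    def is_tmm_default(self) -> bool:
        """True iff the collection has exactly the six reserved sub-pathways
        partitioning 97 genes as 38 telomerase-arm + 59 ALT-arm."""
        if sorted(self.names) != sorted(TMM_SUB_PATHWAYS):
            return False
        for arm, total in _TMM_ARM_TOTALS.items():
            genes: list[str] = []
            for gs in self.by_arm(arm):
                genes.extend(gs.genes)
            if len(genes) != total or len(set(genes)) != total:
                return False
        return True


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name<TAB>description<TAB>gene1<TAB>gene2...).

    The description field doubles as the arm/sub-pathway tag when it equals
    one of the six reserved TMM names; anything else yields arm ``OTHER``.
    ``#`` comment lines and blank lines are ignored.  Duplicate symbols within
    a line are collapsed (first occurrence kept) with a logged warning.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) <= 2:
                raise ValueError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            name, tag, *genes = (f.strip() for f in fields)
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                logger.warning(
                    "%s: line %d (%s): %d duplicate gene symbols collapsed",
                    path, lineno, name, len(genes) - len(deduped),
                )
            sets.append(GeneSet.from_tag(name, deduped, tag))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection back to GMT; the description field carries the
    sub-pathway tag (or ``na`` when untagged)."""
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            tag = gs.sub_pathway or "na"
            fh.write("\t".join([gs.name, tag, *gs.genes]) + "\n")


@dataclass
class ValidationReport:
    """Per-set coverage of a collection against a measured gene universe."""

    per_set: pd.DataFrame = field(repr=False)
    coverage_floor: float = 0.5
    is_tmm_default: bool = False

    @property
    def flagged(self) -> list[str]:
        return self.per_set.index[self.per_set["flagged"]].tolist()

    @property
    def ok(self) -> bool:
        return not self.per_set["flagged"].any()


def validate_tmm_collection(
    collection: GeneSetCollection,
    expr_genes: Iterable[str],
    coverage_floor: float = 0.5,
) -> ValidationReport:
    """Report, per set: size, members present in ``expr_genes``, coverage.

    A set is flagged when its coverage is strictly below ``coverage_floor``.
    Report-only: never raises on low coverage.
    """
    present = set(expr_genes)
    rows = {}
    for gs in collection:
        n_present = sum(1 for g in gs.genes if g in present)
        coverage = n_present / len(gs)
        rows[gs.name] = {
            "arm": gs.arm,
            "size": len(gs),
            "n_present": n_present,
            "coverage": coverage,
            "flagged": coverage < coverage_floor,
        }
    per_set = pd.DataFrame.from_dict(rows, orient="index")
    report = ValidationReport(
        per_set=per_set,
        coverage_floor=coverage_floor,
        is_tmm_default=collection.is_tmm_default(),
    )
    for name in report.flagged:
        logger.warning(
            "gene set %s covers only %.0f%% of measured genes (floor %.0f%%)",
            name, 100 * per_set.loc[name, "coverage"], 100 * coverage_floor,
        )
    return report


def default_tmm_collection() -> GeneSetCollection:
    """The shipped placeholder TMM collection (correct 6/38/59/97 structure,
    synthetic symbols G0001..G0097 matching :mod:`tmmscope.simulate`)."""
    ref = resources.files("tmmscope").joinpath("data/tmm_default.gmt")
    with resources.as_file(ref) as path:
        return read_gmt(path)
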