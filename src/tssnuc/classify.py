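"""Classification of genes by expression level, expression breadth, and
promoter chromatin state.

Genes are partitioned along three axes:

* RPKM class (S2 cells): Silent (RPKM = 0), Modest (1 <= RPKM <= 25),
  High (RPKM > 25).  RPKM strictly between 0 and 1 falls in a gap of the
  published class bounds; by default it is binned as Modest, configurable
  to Unclassified.
* BoE class: breadth of expression is the number of tissues whose RPKM
  strictly exceeds a threshold (default 3).  Tissue-specific (BoE <= 6),
  ModestBoE (6 < BoE <= 24), Constitutive (BoE > 24).
* Chromatin class: Active if the promoter window (default TSS-relative
  offsets [-300, +200), strand-aware) is entirely covered by domains whose
  states belong to the Active group, NonActive if entirely covered by
  inactive-group domains (mixtures of different inactive states allowed),
  Unclassified otherwise.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .model import ChromatinDomain, Gene, StateMapping

RPKM_CLASSES = ("Silent", "Modest", "High")
BOE_CLASSES = ("TissueSpecific", "ModestBoE", "Constitutive")
CHROMATIN_CLASSES = ("Active", "NonActive")
UNCLASSIFIED = "Unclassified"


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds and conventions for the three classification axes."""

    boe_rpkm_threshold: float = 3.0
    rpkm_modest_low: float = 1.0
    rpkm_modest_high: float = 25.0
    boe_tissue_specific_max: int = 6
    boe_modest_max: int = 24
    window: tuple[int, int] = (-300, 200)
    gap_policy: str = "modest"  # genes with 0 < RPKM < rpkm_modest_low

    def __post_init__(self) -> None:
        if self.window[0] >= self.window[1]:
            raise ValueError("window start must be < window end")
        if self.boe_rpkm_threshold < 0:
            raise ValueError("boe_rpkm_threshold must be non-negative")
        if not (0 < self.rpkm_modest_low <= self.rpkm_modest_high):
            raise ValueError("RPKM class bounds must be strictly increasing")
        if not (0 <= self.boe_tissue_specific_max < self.boe_modest_max):
            raise ValueError("BoE class bounds must be strictly increasing")
        if self.gap_policy not in ("modest", "unclassified"):
            raise ValueError("gap_policy must be 'modest' or 'unclassified'")


def classify_rpkm(rpkm: float, config: ClassificationConfig | None = None) -> str:
    """Assign the RPKM expression-level class for one gene."""
    config = config or ClassificationConfig()
    if rpkm < 0:
        raise ValueError(f"RPKM must be non-negative, got {rpkm}")
    if rpkm == 0:
        return "Silent"
    if rpkm < config.rpkm_modest_low:
        return "Modest" if config.gap_policy == "modest" else UNCLASSIFIED
    if rpkm <= config.rpkm_modest_high:
        return "Modest"
    return "High"


def compute_boe(rpkm_tissues: Sequence[float], threshold: float = 3.0) -> int:
    """Breadth of expression: tissues whose RPKM strictly exceeds ``threshold``."""
    if len(rpkm_tissues) == 0:
        raise ValueError("tissue RPKM vector must be non-empty")
    return int(np.sum(np.asarray(rpkm_tissues, dtype=float) > threshold))


def classify_boe(boe: int, config: ClassificationConfig | None = None) -> str:
    """Assign the breadth-of-expression class for one gene."""
    config = config or ClassificationConfig()
    if boe < 0:
        raise ValueError(f"BoE must be non-negative, got {boe}")
    if boe <= config.boe_tissue_specific_max:
        return "TissueSpecific"
    if boe <= config.boe_modest_max:
        return "ModestBoE"
    return "Constitutive"


class DomainIndex:
    """Per-chromosome sorted index over normalized chromatin-state domains."""

    def __init__(self, domains: Sequence[ChromatinDomain]):
        self._by_chrom: dict[str, tuple[list[int], list[int], list[str]]] = {}
        by_chrom: dict[str, list[ChromatinDomain]] = {}
        for d in domains:
            by_chrom.setdefault(d.chrom, []).append(d)
        for chrom, ds in by_chrom.items():
            ds = sorted(ds, key=lambda d: d.start)
            self._by_chrom[chrom] = (
                [d.start for d in ds],
                [d.end for d in ds],
                [d.state for d in ds],
            )

    def covering_states(self, chrom: str, start: int, end: int) -> set[str] | None:
        """States of domains that jointly cover [start, end) without a gap.

        Returns ``None`` if the chromosome is absent or any base of the
        interval is not covered.
        """
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, states = entry
        i = bisect.bisect_right(starts, start) - 1
        if i < 0 or ends[i] <= start:
            return None
        found: set[str] = set()
        pos = start
        while pos < end:
            if i >= len(starts) or starts[i] > pos:
                return None  # gap in coverage
            found.add(states[i])
            pos = ends[i]
            i += 1
        return found


def promoter_interval(gene: Gene, window: tuple[int, int]) -> tuple[int, int]:
    """Strand-aware genomic half-open interval of TSS-relative offsets.

    For a + strand gene the offset ``o`` maps to base ``tss + o``; for a
    - strand gene it maps to ``tss - o``, so the window is reflected
    around the TSS.
    """
    lo, hi = window
    if gene.strand == "+":
        return gene.tss + lo, gene.tss + hi
    return gene.tss - hi + 1, gene.tss - lo + 1


def assign_chromatin_class(
    gene: Gene,
    domains: DomainIndex | Sequence[ChromatinDomain],
    mapping: StateMapping,
    window: tuple[int, int] = (-300, 200),
) -> str:
    """Classify one gene's promoter window as Active / NonActive / Unclassified.

    The window must be *entirely* covered by Active-group domains (Active)
    or entirely by inactive-group domains (NonActive); partial coverage,
    mixed groups, missing chromosomes, or windows reaching negative
    coordinates yield Unclassified.
    """
    index = domains if isinstance(domains, DomainIndex) else DomainIndex(domains)
    start, end = promoter_interval(gene, window)
    if start < 0:
        return UNCLASSIFIED
    states = index.covering_states(gene.chrom, start, end)
    if states is None:
        return UNCLASSIFIED
    if states <= mapping.active_states:
        return "Active"
    if states <= mapping.inactive_states:
        return "NonActive"
    return UNCLASSIFIED


@dataclass
class ClassificationResult:
    """Per-gene classes plus cross-tabulations and summary fractions."""

    table: pd.DataFrame
    crosstabs: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict[str, float] = field(default_factory=dict)


def build_classification(
    genes: Sequence[Gene],
    domains: Sequence[ChromatinDomain] | DomainIndex,
    mapping: StateMapping,
    config: ClassificationConfig | None = None,
) -> ClassificationResult:
    """Classify every gene on the three axes and cross-tabulate the result.

    Returns a table with one row per gene (order preserved) and, per
    chromatin class, a 3x3 contingency table of RPKM class x BoE class,
    together with the headline fractions of Active genes with any
    expression (RPKM > 0 or BoE above the tissue-specific bound) and of
    NonActive genes with the same property.
    """
    config = config or ClassificationConfig()
    index = domains if isinstance(domains, DomainIndex) else DomainIndex(domains)
    records = []
    for g in genes:
        boe = compute_boe(g.rpkm_tissues, config.boe_rpkm_threshold) if g.rpkm_tissues else 0
        if boe > len(g.rpkm_tissues):
            raise ValueError("BoE exceeds tissue count")
        records.append(
            {
                "gene_id": g.gene_id,
                "rpkm_s2": g.rpkm_s2,
                "boe": boe,
                "rpkm_class": classify_rpkm(g.rpkm_s2, config),
                "boe_class": classify_boe(boe, config),
                "chromatin_class": assign_chromatin_class(g, index, mapping, config.window),
            }
        )
    table = pd.DataFrame(
        records,
        columns=["gene_id", "rpkm_s2", "boe", "rpkm_class", "boe_class", "chromatin_class"],
    )
    crosstabs: dict[str, pd.DataFrame] = {}
    summary: dict[str, float] = {"n_genes": float(len(table))}
    for cc in CHROMATIN_CLASSES:
        sub = table[table["chromatin_class"] == cc]
        ct = pd.crosstab(sub["rpkm_class"], sub["boe_class"]) if len(sub) else pd.DataFrame()
        ct = ct.reindex(index=RPKM_CLASSES, columns=BOE_CLASSES, fill_value=0)
        crosstabs[cc] = ct.astype(int)
        summary[f"n_{cc.lower()}"] = float(len(sub))
        if len(sub):
            expressed = (sub["rpkm_s2"] > 0) | (sub["boe"] > config.boe_tissue_specific_max)
            summary[f"frac_{cc.lower()}_expressed"] = float(expressed.mean())
    return ClassificationResult(table=table, crosstabs=crosstabs, summary=summary)
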