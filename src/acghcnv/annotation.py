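"""Rarity classification against a reference CNV database and gene content.

Coverage of a query region is the percentage of the *query* covered by the
union of intersecting reference records, so stacked records never push it
past 100.  Classes follow the usual survey convention: 0% coverage is
"novel", anything below 50% is "rare", and 50% or more is "common".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .cnv_calling import CnvRegion

__all__ = [
    "ReferenceDb",
    "GeneAnnotation",
    "RarityAnnotation",
    "CLASS_NOVEL",
    "CLASS_RARE",
    "CLASS_COMMON",
    "dgv_coverage",
    "classify_rarity",
    "genes_in_region",
    "verify_symbols",
    "annotate_regions",
]

logger = logging.getLogger(__name__)

CLASS_NOVEL = "novel"
CLASS_RARE = "rare"
CLASS_COMMON = "common"
RARE_COVERAGE_CUTOFF = 50.0


class _IntervalIndex:
    """Per-chromosome interval tree over (start, end, payload) records."""

    def __init__(self, records: Iterable[tuple[str, int, int, object]]) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for chrom, start, end, payload in records:
            if end <= start:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end, payload)
            self._n += 1

    def __len__(self) -> int:
        return self._n

    def query(self, chrom: str, start: int, end: int) -> list[tuple[int, int, object]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end, iv.data) for iv in tree.overlap(start, end))


class ReferenceDb(_IntervalIndex):
    """Known-CNV interval database (a DGV-style BED: chrom, start, end, id)."""

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferenceDb":
        return cls(
            (str(r.chrom), int(r.start), int(r.end), str(r.name))
            for r in df.itertuples()
        )


class GeneAnnotation(_IntervalIndex):
    """Gene spans with symbols (BED: chrom, start, end, symbol)."""

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneAnnotation":
        return cls(
            (str(r.chrom), int(r.start), int(r.end), str(r.name))
            for r in df.itertuples()
        )


@dataclass(frozen=True)
class RarityAnnotation:
    coverage_pct: float
    rarity_class: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage_pct <= 100.0:
            raise ValueError("coverage must lie in [0, 100]")


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    cur_start = cur_end = None
    for s, e in sorted(intervals):
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def dgv_coverage(region: CnvRegion, reference_db: ReferenceDb) -> float:
    """Percent of the region covered by the union of reference records."""
    size = region.end - region.start
    if size <= 0:
        raise ValueError("region end must exceed start")
    clipped = [
        (max(s, region.start), min(e, region.end))
        for s, e, _ in reference_db.query(region.chrom, region.start, region.end)
    ]
    clipped = [(s, e) for s, e in clipped if e > s]
    if not clipped:
        return 0.0
    return 100.0 * _union_length(clipped) / size


def classify_rarity(coverage_percent: float) -> str:
    """0 -> novel; (0, 50) -> rare; [50, 100] -> common."""
    if not 0.0 <= coverage_percent <= 100.0:
        raise ValueError("coverage must lie in [0, 100]")
    if coverage_percent == 0.0:
        return CLASS_NOVEL
    if coverage_percent < RARE_COVERAGE_CUTOFF:
        return CLASS_RARE
    return CLASS_COMMON


def genes_in_region(
    region: CnvRegion,
    gene_annotation: GeneAnnotation,
    containment_only: bool = False,
) -> list[str]:
    """Gene symbols whose span intersects the region (position order).

    By default any overlap counts, including genes straddling a boundary;
    ``containment_only=True`` keeps only genes fully inside the region.
    """
    hits = gene_annotation.query(region.chrom, region.start, region.end)
    if containment_only:
        hits = [(s, e, sym) for s, e, sym in hits if s >= region.start and e <= region.end]
    return [str(sym) for _, _, sym in hits]


def verify_symbols(symbols: Sequence[str], valid_symbol_list: Iterable[str]) -> list[str]:
    """Drop symbols absent from the valid list (non-gene entities); logs count."""
    valid = set(valid_symbol_list)
    kept = [s for s in symbols if s in valid]
    removed = len(symbols) - len(kept)
    if removed:
        logger.info("removed %d unverified symbol(s)", removed)
    return kept


def annotate_regions(
    regions: Sequence[CnvRegion],
    reference_db: ReferenceDb,
    gene_annotation: GeneAnnotation | None = None,
    valid_symbols: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Tabulate regions with DGV coverage, rarity class and verified genes.

    Output columns mirror the survey-table layout: label, frequency, coverage,
    start, end, size (kb), gene count and gene symbols.
    """
    valid = list(valid_symbols) if valid_symbols is not None else None
    rows = []
    for r in regions:
        cov = dgv_coverage(r, reference_db)
        genes: list[str] = []
        if gene_annotation is not None:
            genes = genes_in_region(r, gene_annotation)
            if valid is not None:
                genes = verify_symbols(genes, valid)
        rows.append(
            (
                r.label,
                r.chrom,
                r.frequency_pct,
                round(cov, 2),
                classify_rarity(cov),
                r.start,
                r.end,
                r.size_kb,
                r.status,
                len(genes),
                ",".join(genes),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "chrom",
            "frequency_pct",
            "dgv_coverage_pct",
            "rarity_class",
            "start",
            "end",
            "size_kb",
            "status",
            "n_genes",
            "genes",
        ],
    )
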