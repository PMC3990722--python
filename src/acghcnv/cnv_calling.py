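"""Per-sample CNV calling from segments and cohort-level region aggregation.

Calling applies the study thresholds: a segment is a duplication when its
mean log2 ratio is strictly above ``+0.3``, a deletion when strictly below
``-0.6``, and in either case must contain at least 5 consecutive probes.
Sample-level calls are then clustered across the cohort by reciprocal
overlap into regions carrying a sample frequency (printed to 1 decimal), a
size in kb (2 decimals, ``end - start`` arithmetic) and a gain/loss status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .genome import GenomeModel
from .segmentation import Segment

__all__ = [
    "CnvCall",
    "CnvRegion",
    "DUP_THRESHOLD",
    "DEL_THRESHOLD",
    "MIN_PROBES",
    "call_segments",
    "exclude_sex_chromosomes",
    "aggregate_regions",
    "region_size_kb",
    "filter_by_frequency",
    "calls_to_frame",
    "calls_from_frame",
    "regions_to_frame",
]

logger = logging.getLogger(__name__)

DUP_THRESHOLD = 0.3
DEL_THRESHOLD = -0.6
MIN_PROBES = 5

STATUS_DUP = "duplication"
STATUS_DEL = "deletion"
REGION_AMP = "Amplification"
REGION_DEL = "Deletion"
REGION_BOTH = "Amplification & Deletion"


@dataclass(frozen=True)
class CnvCall:
    sample: str
    chrom: str
    start: int
    end: int
    status: str  # "duplication" | "deletion"
    num_probes: int
    mean_log2: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("call end must exceed start")
        if self.status not in (STATUS_DUP, STATUS_DEL):
            raise ValueError(f"unknown call status {self.status!r}")

    @property
    def size_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CnvRegion:
    """Cohort-level merged CNV region with carrier frequency and status."""

    chrom: str
    start: int
    end: int
    carriers: tuple[str, ...]
    cohort_size: int
    status: str
    label: str = ""
    member_calls: tuple[int, ...] = field(default=(), repr=False)

    @property
    def carrier_count(self) -> int:
        return len(self.carriers)

    @property
    def frequency_pct(self) -> float:
        return round(100.0 * self.carrier_count / self.cohort_size, 1)

    @property
    def size_kb(self) -> float:
        return region_size_kb(self.start, self.end)


def region_size_kb(start: int, end: int) -> float:
    """Interval size in kb, rounded to 2 decimals (0-based, end-exclusive)."""
    if start >= end:
        raise ValueError("start must be below end")
    return round((end - start) / 1000.0, 2)


def call_segments(
    segments: Sequence[Segment],
    dup_threshold: float = DUP_THRESHOLD,
    del_threshold: float = DEL_THRESHOLD,
    min_probes: int = MIN_PROBES,
) -> list[CnvCall]:
    """Convert one sample's segments into CNV calls (strict thresholds)."""
    calls = []
    for seg in segments:
        if seg.num_probes < min_probes:
            continue
        if seg.mean_log2 > dup_threshold:
            status = STATUS_DUP
        elif seg.mean_log2 < del_threshold:
            status = STATUS_DEL
        else:
            continue
        calls.append(
            CnvCall(
                sample=seg.sample,
                chrom=seg.chrom,
                start=seg.start,
                end=seg.end,
                status=status,
                num_probes=seg.num_probes,
                mean_log2=seg.mean_log2,
            )
        )
    return calls


def exclude_sex_chromosomes(
    calls: Sequence[CnvCall], genome_model: GenomeModel
) -> list[CnvCall]:
    """Keep autosomal calls only; the number removed is logged."""
    kept = [c for c in calls if genome_model.is_autosome(c.chrom)]
    removed = len(calls) - len(kept)
    if removed:
        logger.info("excluded %d call(s) on sex chromosomes", removed)
    return kept


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def aggregate_regions(
    calls: Sequence[CnvCall],
    cohort_sample_ids: Sequence[str],
    reciprocal_overlap: float = 0.5,
) -> list[CnvRegion]:
    """Cluster per-sample calls into cohort regions by reciprocal overlap.

    Two calls on the same chromosome join the same cluster when their
    reciprocal overlap is at least ``reciprocal_overlap`` (transitively, i.e.
    clusters are connected components).  Region bounds are the union of the
    member calls; the status is "Amplification & Deletion" when both gains
    and losses contributed.  Frequencies are relative to ``cohort_sample_ids``.
    """
    cohort = list(dict.fromkeys(cohort_sample_ids))
    if not cohort:
        raise ValueError("cohort must contain at least one sample")
    calls = list(calls)
    uf = _UnionFind(len(calls))
    by_chrom: dict[str, list[int]] = {}
    for idx, c in enumerate(calls):
        by_chrom.setdefault(c.chrom, []).append(idx)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda k: calls[k].start)
        for a_pos, i in enumerate(idxs):
            for j in idxs[a_pos + 1 :]:
                if calls[j].start >= calls[i].end:
                    break
                ro = _reciprocal_overlap(
                    calls[i].start, calls[i].end, calls[j].start, calls[j].end
                )
                if ro >= reciprocal_overlap:
                    uf.union(i, j)
    clusters: dict[int, list[int]] = {}
    for idx in range(len(calls)):
        clusters.setdefault(uf.find(idx), []).append(idx)
    regions = []
    for members in clusters.values():
        mc = [calls[k] for k in members]
        start = min(c.start for c in mc)
        end = max(c.end for c in mc)
        has_dup = any(c.status == STATUS_DUP for c in mc)
        has_del = any(c.status == STATUS_DEL for c in mc)
        status = REGION_BOTH if (has_dup and has_del) else (REGION_AMP if has_dup else REGION_DEL)
        carriers = tuple(sorted({c.sample for c in mc}))
        unknown = [s for s in carriers if s not in cohort]
        if unknown:
            raise ValueError(f"carriers not in cohort: {unknown}")
        regions.append(
            CnvRegion(
                chrom=mc[0].chrom,
                start=start,
                end=end,
                carriers=carriers,
                cohort_size=len(cohort),
                status=status,
                label=f"{mc[0].chrom}:{start}-{end}",
                member_calls=tuple(sorted(members)),
            )
        )
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return regions


def filter_by_frequency(
    regions: Sequence[CnvRegion],
    min_percent: float = 10.0,
    strict: bool = False,
) -> list[CnvRegion]:
    """Keep regions at or above a sample-frequency threshold (in percent).

    The default is inclusive (``>=``); pass ``strict=True`` for ``>``.
    """
    if strict:
        return [r for r in regions if r.frequency_pct > min_percent]
    return [r for r in regions if r.frequency_pct >= min_percent]


def calls_to_frame(calls: Iterable[CnvCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.chrom, c.start, c.end, c.sample, c.status, c.num_probes, c.mean_log2)
            for c in calls
        ],
        columns=["chrom", "start", "end", "sample", "status", "num_probes", "mean_log2"],
    )


def calls_from_frame(df: pd.DataFrame) -> list[CnvCall]:
    return [
        CnvCall(
            sample=str(r.sample),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            status=str(r.status),
            num_probes=int(r.num_probes),
            mean_log2=float(r.mean_log2),
        )
        for r in df.itertuples()
    ]


def regions_to_frame(regions: Iterable[CnvRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.label,
                r.chrom,
                r.start,
                r.end,
                r.size_kb,
                r.carrier_count,
                r.cohort_size,
                r.frequency_pct,
                r.status,
                ",".join(r.carriers),
            )
            for r in regions
        ],
        columns=[
            "label",
            "chrom",
            "start",
            "end",
            "size_kb",
            "carriers",
            "cohort_size",
            "frequency_pct",
            "status",
            "carrier_ids",
        ],
    )


def regions_from_frame(df: pd.DataFrame) -> list[CnvRegion]:
    return [
        CnvRegion(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            carriers=tuple(str(r.carrier_ids).split(",")) if str(r.carrier_ids) else (),
            cohort_size=int(r.cohort_size),
            status=str(r.status),
            label=str(r.label),
        )
        for r in df.itertuples()
    ]
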