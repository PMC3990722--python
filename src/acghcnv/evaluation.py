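"""Recovery scoring of pipeline output against planted simulator truth.

Couples the synthetic generator to the analysis stages: run segmentation and
calling over a simulated cohort, then compare per-sample calls with the
planted (sample, region) truth rows by reciprocal overlap and direction.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .cnv_calling import CnvCall, call_segments, exclude_sex_chromosomes
from .segmentation import Segment, SegmentationParams, segment_cohort
from .synthetic_data import SimulatedCohort

__all__ = [
    "pipeline_calls",
    "truth_expected_calls",
    "recovery_counts",
    "f1_score",
    "rarity_outcomes",
]


def pipeline_calls(
    cohort: SimulatedCohort,
    params: SegmentationParams,
    autosomal_only: bool = True,
) -> list[CnvCall]:
    """Segment a simulated cohort and call CNVs with the default thresholds."""
    seg = segment_cohort(cohort.probes, params, cohort.probe_design.probe_length)
    segments = [
        Segment(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            num_probes=int(r.num_probes),
            mean_log2=float(r.seg_mean),
            sample=str(r.sample),
        )
        for r in seg.itertuples()
    ]
    calls = call_segments(segments)
    if autosomal_only:
        calls = exclude_sex_chromosomes(calls, cohort.genome)
    return calls


def truth_expected_calls(
    cohort: SimulatedCohort,
    min_probes: int = 5,
    autosomal_only: bool = True,
) -> pd.DataFrame:
    """Truth rows a correct pipeline should recover as calls.

    Keeps (sample, region) rows covered by at least ``min_probes`` probes of
    the design and, by default, drops sex-chromosome rows to match the
    autosomal analysis.
    """
    rows = cohort.truth.rows
    if autosomal_only:
        autosomes = set(cohort.genome.autosome_names)
        rows = rows[rows["chrom"].isin(autosomes)]
    keep = []
    for r in rows.itertuples():
        pos = cohort.probe_design.starts[r.chrom]
        n_cov = int(
            np.searchsorted(pos, r.end, side="left")
            - np.searchsorted(pos, r.start, side="left")
        )
        if n_cov >= min_probes:
            keep.append(True)
        else:
            keep.append(False)
    return rows.loc[keep].reset_index(drop=True)


def _matches(call: CnvCall, row, reciprocal: float) -> bool:
    if call.sample != row.sample or call.chrom != row.chrom:
        return False
    inter = min(call.end, row.end) - max(call.start, row.start)
    if inter <= 0:
        return False
    if (call.status == "duplication") != (row.copy_number > 2):
        return False
    return (
        inter / (call.end - call.start) >= reciprocal
        and inter / (row.end - row.start) >= reciprocal
    )


def recovery_counts(
    calls: Sequence[CnvCall],
    truth_rows: pd.DataFrame,
    reciprocal: float = 0.5,
) -> tuple[int, int, int]:
    """(true positives, false positives, false negatives) at the call level."""
    matched_calls: set[int] = set()
    tp = fn = 0
    for row in truth_rows.itertuples():
        hit = False
        for k, call in enumerate(calls):
            if _matches(call, row, reciprocal):
                hit = True
                matched_calls.add(k)
        if hit:
            tp += 1
        else:
            fn += 1
    fp = len(calls) - len(matched_calls)
    return tp, fp, fn


def f1_score(tp: int, fp: int, fn: int) -> float:
    if tp == 0:
        return 0.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


def rarity_outcomes(
    cohort: SimulatedCohort,
    calls: Sequence[CnvCall],
) -> dict[str, tuple[str, str]]:
    """Expected vs observed rarity class per recovered planted autosomal region.

    Calls are aggregated into cohort regions; each planted region is matched
    to the aggregated region covering at least half of it, whose coverage
    against the cohort's engineered reference database is then classified.
    """
    from .annotation import ReferenceDb, classify_rarity, dgv_coverage
    from .cnv_calling import aggregate_regions

    regions = aggregate_regions(calls, list(cohort.truth.samples))
    db = ReferenceDb.from_frame(cohort.reference_db)
    outcomes: dict[str, tuple[str, str]] = {}
    carried = set(cohort.truth.rows["region"])
    for planted in cohort.spec.regions:
        if not cohort.genome.is_autosome(planted.chrom) or planted.name not in carried:
            continue
        expected = classify_rarity(planted.db_coverage_pct)
        for region in regions:
            if region.chrom != planted.chrom:
                continue
            inter = min(region.end, planted.end) - max(region.start, planted.start)
            if inter > 0 and inter / (planted.end - planted.start) >= 0.5:
                outcomes[planted.name] = (
                    expected,
                    classify_rarity(dgv_coverage(region, db)),
                )
                break
    return outcomes
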