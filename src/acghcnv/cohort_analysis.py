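"""Cohort-level statistics, group comparison and qPCR interpretation.

Covers the descriptive summary of an autosomal call set (counts, size
distribution, genome fraction, gain:loss ratio), partitioning of regions
between two patient groups (unique vs shared), a 2x2 chi-square carrier
association test, and interpretation of TaqMan ddCt copy-number assays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cnv_calling import (
    STATUS_DUP,
    STATUS_DEL,
    CnvCall,
    CnvRegion,
    aggregate_regions,
)
from .genome import GenomeModel

__all__ = [
    "CohortSummary",
    "GroupPartition",
    "AssociationResult",
    "cohort_summary",
    "partition_regions",
    "chisq_association",
    "qpcr_copy_number",
    "classify_copy_number",
    "truncate2",
]


def truncate2(x: float) -> float:
    """Truncate (not round) to 2 decimals, the convention used for printed means."""
    return math.floor(x * 100.0) / 100.0


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive statistics of a cohort call set.

    Sizes are stored at full precision in kb; ``mean_per_individual`` is the
    exact ratio (use :func:`truncate2` for the printed form).
    """

    n_calls: int
    n_samples: int
    mean_per_individual: float
    size_min_kb: float
    size_max_kb: float
    size_mean_kb: float
    size_median_kb: float
    total_span_mb: float
    pct_genome: float
    n_gains: int
    n_losses: int
    gain_loss_ratio: Optional[float]  # None when there are no losses
    freq_threshold_pct: float
    n_above_threshold: int
    pct_above_threshold: float

    def to_dict(self) -> dict:
        return {
            "n_calls": self.n_calls,
            "n_samples": self.n_samples,
            "mean_per_individual": truncate2(self.mean_per_individual),
            "size_min_kb": round(self.size_min_kb, 2),
            "size_max_kb": round(self.size_max_kb, 2),
            "size_mean_kb": round(self.size_mean_kb, 2),
            "size_median_kb": round(self.size_median_kb, 2),
            "total_span_mb": round(self.total_span_mb, 2),
            "pct_genome": round(self.pct_genome, 2),
            "n_gains": self.n_gains,
            "n_losses": self.n_losses,
            "gain_loss_ratio": None
            if self.gain_loss_ratio is None
            else round(self.gain_loss_ratio, 1),
            "freq_threshold_pct": self.freq_threshold_pct,
            "n_above_threshold": self.n_above_threshold,
            "pct_above_threshold": round(self.pct_above_threshold, 1),
        }


def cohort_summary(
    calls: Sequence[CnvCall],
    genome_model: GenomeModel,
    freq_threshold: float = 10.0,
    sample_ids: Optional[Sequence[str]] = None,
) -> CohortSummary:
    """Summarise an (autosomal) call set for one cohort.

    ``sample_ids`` fixes the cohort size; when omitted, the distinct samples
    present in the calls are used.  The total span is the sum of call sizes
    (a sample-level measure, so recurrent regions count once per carrier) and
    the genome fraction uses the genome model's total length as denominator.
    The frequency filter counts calls whose cohort region exceeds
    ``freq_threshold`` percent carrier frequency (strict, matching the
    ">10%" convention).
    """
    samples = list(dict.fromkeys(sample_ids)) if sample_ids is not None else sorted(
        {c.sample for c in calls}
    )
    if not samples:
        raise ValueError("cohort must contain at least one sample")
    n = len(calls)
    sizes_kb = np.array([c.size_bp / 1000.0 for c in calls], dtype=float)
    n_gains = sum(c.status == STATUS_DUP for c in calls)
    n_losses = sum(c.status == STATUS_DEL for c in calls)
    if n:
        regions = aggregate_regions(calls, samples)
        freq_by_call: dict[int, float] = {}
        for r in regions:
            for k in r.member_calls:
                freq_by_call[k] = r.frequency_pct
        n_above = sum(freq_by_call[k] > freq_threshold for k in range(n))
    else:
        n_above = 0
    return CohortSummary(
        n_calls=n,
        n_samples=len(samples),
        mean_per_individual=n / len(samples),
        size_min_kb=float(sizes_kb.min()) if n else 0.0,
        size_max_kb=float(sizes_kb.max()) if n else 0.0,
        size_mean_kb=float(sizes_kb.mean()) if n else 0.0,
        size_median_kb=float(np.median(sizes_kb)) if n else 0.0,
        total_span_mb=float(sizes_kb.sum() / 1000.0),
        pct_genome=100.0 * float(sizes_kb.sum()) * 1000.0 / genome_model.total_length,
        n_gains=n_gains,
        n_losses=n_losses,
        gain_loss_ratio=(n_gains / n_losses) if n_losses else None,
        freq_threshold_pct=freq_threshold,
        n_above_threshold=n_above,
        pct_above_threshold=100.0 * n_above / n if n else 0.0,
    )


@dataclass(frozen=True)
class GroupPartition:
    """Regions unique to each group and shared between groups.

    ``shared_a``/``shared_b`` hold the shared loci as seen from each group's
    own region list, so every input region lands in exactly one of the four
    tuples.
    """

    unique_a: tuple[CnvRegion, ...]
    shared_a: tuple[CnvRegion, ...]
    shared_b: tuple[CnvRegion, ...]
    unique_b: tuple[CnvRegion, ...]

    @property
    def counts(self) -> tuple[int, int, int]:
        """(unique to A, shared as counted in A, unique to B)."""
        return len(self.unique_a), len(self.shared_a), len(self.unique_b)


def _overlaps(a: CnvRegion, b: CnvRegion, reciprocal: float) -> bool:
    if a.chrom != b.chrom:
        return False
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return False
    if reciprocal <= 0:
        return True
    return (
        inter / (a.end - a.start) >= reciprocal
        and inter / (b.end - b.start) >= reciprocal
    )


def partition_regions(
    regions_a: Sequence[CnvRegion],
    regions_b: Sequence[CnvRegion],
    reciprocal: float = 0.0,
) -> GroupPartition:
    """Split two region sets into unique/shared by interval overlap.

    A region is shared when it overlaps any region of the other group; the
    default rule is any overlap (``reciprocal=0``), with an optional
    reciprocal-overlap fraction for stricter matching.
    """
    shared_a = tuple(r for r in regions_a if any(_overlaps(r, s, reciprocal) for s in regions_b))
    shared_b = tuple(r for r in regions_b if any(_overlaps(r, s, reciprocal) for s in regions_a))
    unique_a = tuple(r for r in regions_a if r not in shared_a)
    unique_b = tuple(r for r in regions_b if r not in shared_b)
    return GroupPartition(unique_a, shared_a, shared_b, unique_b)


@dataclass(frozen=True)
class AssociationResult:
    table: tuple[tuple[int, int], tuple[int, int]]  # [[carriers, non], [carriers, non]]
    statistic: float
    dof: int
    pvalue: float
    method: str


def chisq_association(
    carriers_case: int,
    n_case: int,
    carriers_control: int,
    n_control: int,
    correction: bool = False,
    exact: bool = False,
) -> AssociationResult:
    """Carrier-frequency association between two groups on a 2x2 table.

    Pearson chi-square with 1 df and no continuity correction by default
    (``correction=True`` applies Yates); ``exact=True`` switches to Fisher's
    exact test, appropriate when expected cell counts are small.  The result
    is symmetric in group order.
    """
    if not (0 <= carriers_case <= n_case and 0 <= carriers_control <= n_control):
        raise ValueError("carrier counts must lie within cohort sizes")
    if n_case == 0 or n_control == 0:
        raise ValueError("both cohorts must be non-empty")
    table = np.array(
        [
            [carriers_case, n_case - carriers_case],
            [carriers_control, n_control - carriers_control],
        ]
    )
    if exact:
        res = stats.fisher_exact(table, alternative="two-sided")
        return AssociationResult(
            table=tuple(map(tuple, table.tolist())),
            statistic=float("nan"),
            dof=1,
            pvalue=float(res.pvalue),
            method="fisher_exact",
        )
    if table.sum(axis=0).min() == 0:
        # a margin of zeros: no variation in carrier status
        return AssociationResult(
            table=tuple(map(tuple, table.tolist())),
            statistic=0.0,
            dof=1,
            pvalue=1.0,
            method="pearson_chi2",
        )
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=correction)
    return AssociationResult(
        table=tuple(map(tuple, table.tolist())),
        statistic=float(chi2),
        dof=int(dof),
        pvalue=float(p),
        method="pearson_chi2" + ("_yates" if correction else ""),
    )


def qpcr_copy_number(
    ct_target_replicates: Sequence[float],
    ct_reference_replicates: Sequence[float],
    calibrator_delta_ct: float,
) -> tuple[float, float]:
    """Copy number from duplex TaqMan Ct values: ``2 * 2**(-ddCt)``.

    ``dCt = mean(target Ct) - mean(reference Ct)`` for the test sample;
    ``ddCt = dCt - calibrator_dCt`` against a diploid calibrator.  Returns
    ``(estimate, standard_error)``, the latter propagated from the replicate
    scatter of both assays.
    """
    t = np.asarray(ct_target_replicates, dtype=float)
    r = np.asarray(ct_reference_replicates, dtype=float)
    if t.size < 1 or r.size < 1:
        raise ValueError("need at least one replicate per assay")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
        raise ValueError("Ct values must be finite")
    ddct = (t.mean() - r.mean()) - calibrator_delta_ct
    cn = 2.0 * 2.0 ** (-ddct)
    se_d = math.sqrt(
        (t.var(ddof=1) / t.size if t.size > 1 else 0.0)
        + (r.var(ddof=1) / r.size if r.size > 1 else 0.0)
    )
    se_cn = cn * math.log(2.0) * se_d
    return float(cn), float(se_cn)


def classify_copy_number(
    cn_estimate: float,
    loss_below: float = 1.5,
    gain_at: float = 2.5,
) -> str:
    """Band a copy-number estimate into loss / wildtype / gain.

    The default bands operationalise the validation convention that a value
    around 2 is wild type, around 1 a single-copy loss, and 3 or above a
    gain: the cuts sit midway at 1.5 and 2.5.
    """
    if cn_estimate < 0:
        raise ValueError("copy number must be non-negative")
    if cn_estimate < loss_below:
        return "loss"
    if cn_estimate < gain_at:
        return "wildtype"
    return "gain"
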