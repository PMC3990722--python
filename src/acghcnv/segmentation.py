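"""Circular binary segmentation (CBS) of log2-ratio probe tracks.

The change-point statistic is the classic CBS one: treat the probe sequence of
one chromosome as a circle, and for every arc compare the probes inside the
arc with the probes outside it using a two-sample t statistic (pooled
variance).  The arc maximising ``|T|`` proposes up to two change-points; the
proposal is accepted when a permutation test on the same statistic gives
``p <= alpha``, and segmentation recurses into the resulting pieces.  An
optional MAD-based pruning step merges adjacent segments whose means differ by
less than a configurable multiple of the robust probe noise.

The exact post-processing of the vendor pipeline this emulates is unpublished;
everything here (permutation count, alpha, minimum arc width, pruning
threshold, arc-length cap) is an explicit parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ProbeTrack",
    "Segment",
    "SegmentationParams",
    "ArcSplit",
    "circular_max_t",
    "permutation_pvalue",
    "cbs_segment",
    "prune_segments",
    "robust_track_sd",
    "segment_track",
    "segment_cohort",
]

_REL_TIE_TOL = 1e-9  # relative tolerance grouping numerically tied arcs


@dataclass(frozen=True)
class ProbeTrack:
    """Ordered probes of one chromosome for one sample."""

    chrom: str
    positions: np.ndarray  # probe start coordinates, strictly increasing
    ratios: np.ndarray     # log2(test/reference) per probe
    sample: str
    probe_length: int = 60

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        rat = np.asarray(self.ratios, dtype=float)
        if pos.shape != rat.shape:
            raise ValueError("positions and ratios must have equal length")
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValueError("probe positions must be strictly increasing")
        if np.any(~np.isfinite(rat)):
            raise ValueError("ratios must be finite (filter missing values first)")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "ratios", rat)

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class Segment:
    """A contiguous probe run with constant estimated mean log2 ratio."""

    chrom: str
    start: int       # genomic start = start of first probe
    end: int         # genomic end = start of last probe + probe length
    num_probes: int
    mean_log2: float
    sample: str = ""

    def __post_init__(self) -> None:
        if self.num_probes < 1:
            raise ValueError("segment must contain at least one probe")
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")


@dataclass(frozen=True)
class SegmentationParams:
    """Tuning knobs of the CBS stand-in.

    alpha:       significance level for accepting a split (default 0.01).
    n_perm:      permutations per test (default 1000, minimum 100).
    min_probes:  minimum probes on each side of a split (default 2).
    prune_sd:    merge adjacent segments whose means differ by less than this
                 many robust (MAD-based) track standard deviations.
    max_arc:     optional cap on the arc length searched, in probes; ``None``
                 searches all arcs.  A cap bounds the work per permutation at
                 O(n * max_arc) and only sacrifices sensitivity to events
                 longer than the cap.
    seed:        mandatory seed for the permutation stream.
    """

    alpha: float = 0.01
    n_perm: int = 1000
    min_probes: int = 2
    prune_sd: float = 1.0
    max_arc: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        if self.min_probes < 2:
            raise ValueError("min_probes must be at least 2")
        if self.prune_sd < 0:
            raise ValueError("prune_sd must be non-negative")


@dataclass(frozen=True)
class ArcSplit:
    """Best circular arc: probes ``i..j-1`` versus the rest, with statistic T."""

    i: int
    j: int
    t: float


def _arc_t2_matrix(x: np.ndarray, min_side: int, max_arc: Optional[int]):
    """Squared t statistic for every circular arc, as a (w, n) matrix.

    Entry ``[d-1, i]`` is the arc of length ``d`` starting at probe ``i``
    (wrapping allowed).  Arc lengths run ``min_side..w`` with
    ``w = min(max_arc, n // 2)``; longer arcs are redundant because an arc
    and its complement give the same ``|T|``.
    """
    n = x.size
    w = n // 2
    if max_arc is not None:
        w = min(w, int(max_arc))
    w = max(w, 1)
    x = x - x.mean()  # centering leaves T unchanged but avoids cancellation
    ext = np.concatenate([x, x[:w]])
    p = np.concatenate([[0.0], np.cumsum(ext)])
    q = np.concatenate([[0.0], np.cumsum(ext * ext)])
    s_tot = p[n]
    q_tot = q[n]
    if q_tot <= 0.0:
        return np.zeros((w, n)), w
    # rows are lag-d shifted prefix sums; row-major orientation keeps the
    # inner ufunc loops long and contiguous
    pv = sliding_window_view(p, n)[: w + 1]
    qv = sliding_window_view(q, n)[: w + 1]
    s = pv[1:] - pv[0]
    qs = qv[1:] - qv[0]
    d = np.arange(1.0, w + 1.0)[:, None]
    m = n - d
    diff = s / d - (s_tot - s) / m
    ss = (qs - s * s / d) + (q_tot - qs) - (s_tot - s) ** 2 / m
    np.maximum(ss, 0.0, out=ss)
    denom = ss / (n - 2) * (1.0 / d + 1.0 / m)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = diff * diff / denom
    t2[~np.isfinite(t2)] = 0.0
    # zero pooled variance: infinite contrast if the means genuinely differ
    zero_var = ss <= 1e-12 * q_tot
    if zero_var.any():
        big = diff * diff > 1e-12 * q_tot
        t2[zero_var & big] = np.inf
        t2[zero_var & ~big] = 0.0
    if min_side > 1:
        t2[: min_side - 1, :] = -np.inf
    return t2, w


def _canonical_cuts(i: int, d: int, n: int) -> tuple[int, int]:
    """Map an arc (start ``i``, length ``d``, circular) to linear cut points.

    A split whose second cut sits at the sequence end is the same circular
    split as cutting at 0 and at the first cut; the ``(0, i)`` form is the
    lexicographically smaller representative.
    """
    if i + d < n:
        return i, i + d
    if i + d == n:
        return (0, i) if i > 0 else (0, n)
    return i + d - n, i


def _arc_t_scalar(x: np.ndarray, i: int, j: int) -> float:
    """Signed two-sample t for the linear slice x[i:j] against the rest."""
    n = x.size
    x = x - x.mean()
    inside = x[i:j]
    outside = np.concatenate([x[:i], x[j:]])
    k, m = inside.size, outside.size
    mi, mo = float(np.mean(inside)), float(np.mean(outside))
    ss = float(np.sum((inside - mi) ** 2) + np.sum((outside - mo) ** 2))
    scale = float(np.sum(x * x))
    if ss <= 1e-12 * scale:
        return math.copysign(math.inf, mi - mo) if (mi - mo) ** 2 > 1e-12 * scale else 0.0
    return (mi - mo) / math.sqrt(ss / (n - 2) * (1.0 / k + 1.0 / m))


def circular_max_t(
    ratios: Sequence[float],
    min_side: int = 1,
    max_arc: Optional[int] = None,
) -> Optional[ArcSplit]:
    """Best circular-arc split of a sequence, or ``None`` for < 4 values.

    Returns the arc ``i..j-1`` (0-based, end-exclusive, in linear coordinates)
    whose two-sample t statistic against its complement is maximal in absolute
    value.  Numerical ties are broken by smallest ``i``, then smallest ``j``.
    """
    x = np.asarray(ratios, dtype=float)
    n = x.size
    if n < 4 or n < 2 * min_side:
        return None
    t2, w = _arc_t2_matrix(x, min_side, max_arc)
    best = float(np.max(t2))
    if best <= 0.0:
        # flat sequence: no contrast anywhere
        return ArcSplit(0, min(max(min_side, 1), n - 1), 0.0)
    if math.isinf(best):
        cand = np.argwhere(np.isinf(t2))
    else:
        cand = np.argwhere(t2 >= best * (1.0 - _REL_TIE_TOL))
    cuts = sorted({_canonical_cuts(int(i), int(dm1) + 1, n) for dm1, i in cand})
    scored = [(abs(_arc_t_scalar(x, a, b)), a, b) for a, b in cuts]
    top = max(t for t, _, _ in scored)
    tol = 0.0 if math.isinf(top) else top * _REL_TIE_TOL
    tied = [(a, b) for t, a, b in scored if t >= top - tol]
    a, b = min(tied)
    return ArcSplit(a, b, _arc_t_scalar(x, a, b))


def _perm_max_t2(x, rng, min_side, max_arc) -> float:
    """Max squared arc t of one permutation, via the centered shortcut.

    For mean-centered data the two-sample t of an arc with sum ``s`` and
    length ``d`` reduces to ``t2 = a (n-2) / (q - a)`` with
    ``a = s^2 n / (d (n-d))`` and ``q`` the total sum of squares, which is
    monotone in ``a``; the permutation max therefore only needs window sums.
    """
    y = rng.permutation(x)
    n = y.size
    w = n // 2
    if max_arc is not None:
        w = min(w, int(max_arc))
    w = max(w, 1)
    y = y - y.mean()
    q_tot = float(np.dot(y, y))
    if q_tot <= 0.0:
        return 0.0
    ext = np.concatenate([y, y[:w]])
    p = np.concatenate([[0.0], np.cumsum(ext)])
    s = sliding_window_view(p, n)[1 : w + 1] - p[:n]
    np.square(s, out=s)
    row_max = s.max(axis=1)
    d = np.arange(1.0, w + 1.0)
    a = row_max * (n / (d * (n - d)))
    if min_side > 1:
        a = a[min_side - 1 :]
    a_max = float(a.max())
    denom = q_tot - a_max
    if denom <= 0.0:
        return math.inf
    return a_max * (n - 2) / denom


def permutation_pvalue(
    ratios: Sequence[float],
    t_obs: float,
    n_perm: int,
    seed: int,
    min_side: int = 1,
    max_arc: Optional[int] = None,
) -> float:
    """Permutation p-value of an observed max-|T| arc statistic.

    ``p = (1 + #{permutations with max |T| >= |t_obs|}) / (n_perm + 1)``.
    Deterministic for a fixed seed.
    """
    x = np.asarray(ratios, dtype=float)
    rng = np.random.default_rng(seed)
    t2_obs = t_obs * t_obs
    count = sum(
        _perm_max_t2(x, rng, min_side, max_arc) >= t2_obs for _ in range(n_perm)
    )
    return (1 + count) / (n_perm + 1)


def _split_accepted(x: np.ndarray, t_obs: float, params: SegmentationParams, rng) -> bool:
    """Early-stopped permutation test; decision equals the full-n_perm one.

    Stops as soon as the exceedance count can no longer cross, or can no
    longer stay under, the alpha boundary.  Truncation only shortens the
    permutation stream, so the accept/reject outcome is identical to running
    all ``n_perm`` permutations.
    """
    n_perm, alpha = params.n_perm, params.alpha
    # reject the split once (1 + count) / (n_perm + 1) > alpha is guaranteed
    max_count = math.floor(alpha * (n_perm + 1)) - 1  # largest count with p <= alpha
    if max_count < 0:
        return False
    t2_obs = t_obs * t_obs
    count = 0
    for done in range(1, n_perm + 1):
        if _perm_max_t2(x, rng, params.min_probes, params.max_arc) >= t2_obs:
            count += 1
            if count > max_count:
                return False
        remaining = n_perm - done
        if count + remaining <= max_count:
            return True
    return count <= max_count


def cbs_segment(track: ProbeTrack, params: SegmentationParams) -> list[Segment]:
    """Recursively split a track until no further change-point is accepted.

    Segment means are the arithmetic means of member probes, so the
    probe-weighted mean of segment means equals the global track mean.
    """
    n = len(track)
    if n == 0:
        return []
    x = track.ratios
    rng = np.random.default_rng(params.seed)
    bounds: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        m = hi - lo
        if m < max(4, 2 * params.min_probes):
            bounds.append((lo, hi))
            return
        arc = circular_max_t(x[lo:hi], min_side=params.min_probes, max_arc=params.max_arc)
        if arc is None or arc.t == 0.0:
            bounds.append((lo, hi))
            return
        if not _split_accepted(x[lo:hi], arc.t, params, rng):
            bounds.append((lo, hi))
            return
        pieces = [(lo, lo + arc.i), (lo + arc.i, lo + arc.j), (lo + arc.j, hi)]
        pieces = [(a, b) for a, b in pieces if b > a]
        if len(pieces) == 1:
            bounds.append((lo, hi))
            return
        for a, b in pieces:
            recurse(a, b)

    recurse(0, n)
    bounds.sort()
    return [
        Segment(
            chrom=track.chrom,
            start=int(track.positions[lo]),
            end=int(track.positions[hi - 1]) + track.probe_length,
            num_probes=hi - lo,
            mean_log2=float(np.mean(x[lo:hi])),
            sample=track.sample,
        )
        for lo, hi in bounds
    ]


def robust_track_sd(ratios: Sequence[float]) -> float:
    """Robust probe noise scale: scaled MAD of successive differences.

    Successive differencing removes segment-level mean structure, so the
    estimate is driven by probe noise even on tracks containing CNVs.
    """
    x = np.asarray(ratios, dtype=float)
    if x.size < 2:
        return 0.0
    d = np.diff(x)
    return float(np.median(np.abs(d)) * 1.4826 / math.sqrt(2.0))


def prune_segments(
    segments: Sequence[Segment],
    threshold_sd: float,
    robust_sd: float | None = None,
) -> list[Segment]:
    """Merge adjacent segments whose means differ by less than the threshold.

    ``threshold_sd`` is expressed in units of the robust track standard
    deviation (``robust_sd``; see :func:`robust_track_sd`).  Merging is
    repeated until stable, so the operation is idempotent.  A threshold of 0
    returns the input unchanged.
    """
    segs = list(segments)
    if threshold_sd <= 0 or len(segs) < 2:
        return segs
    if robust_sd is None:
        # fall back to a probe-weighted spread of segment means
        means = np.array([s.mean_log2 for s in segs])
        weights = np.array([s.num_probes for s in segs], dtype=float)
        mu = float(np.average(means, weights=weights))
        robust_sd = float(np.sqrt(np.average((means - mu) ** 2, weights=weights)))
    cut = threshold_sd * robust_sd
    changed = True
    while changed and len(segs) > 1:
        changed = False
        diffs = [abs(segs[k + 1].mean_log2 - segs[k].mean_log2) for k in range(len(segs) - 1)]
        k = int(np.argmin(diffs))
        if diffs[k] < cut:
            a, b = segs[k], segs[k + 1]
            merged = Segment(
                chrom=a.chrom,
                start=a.start,
                end=b.end,
                num_probes=a.num_probes + b.num_probes,
                mean_log2=(a.mean_log2 * a.num_probes + b.mean_log2 * b.num_probes)
                / (a.num_probes + b.num_probes),
                sample=a.sample,
            )
            segs[k : k + 2] = [merged]
            changed = True
    return segs


def segment_track(track: ProbeTrack, params: SegmentationParams) -> list[Segment]:
    """CBS segmentation followed by MAD-based pruning (the full per-track pipeline)."""
    segs = cbs_segment(track, params)
    if params.prune_sd > 0 and len(segs) > 1:
        segs = prune_segments(segs, params.prune_sd, robust_track_sd(track.ratios))
    return segs


def segment_cohort(probe_df, params: SegmentationParams, probe_length: int = 60):
    """Segment every sample x chromosome track of a probe matrix.

    Returns a SEG-style DataFrame (``sample, chrom, start, end, num_probes,
    seg_mean``).  Each track gets its own deterministic permutation seed
    derived from ``params.seed``.
    """
    import pandas as pd

    from .io import sample_columns

    rows = []
    samples = sample_columns(probe_df)
    chroms = list(dict.fromkeys(probe_df["chrom"]))
    for ci, chrom in enumerate(chroms):
        sub = probe_df[probe_df["chrom"] == chrom]
        positions = sub["start"].to_numpy()
        for si, sample in enumerate(samples):
            child_seed = int(
                np.random.SeedSequence([params.seed, ci, si]).generate_state(1)[0] % (2**31)
            )
            track = ProbeTrack(
                chrom=chrom,
                positions=positions,
                ratios=sub[sample].to_numpy(dtype=float),
                sample=sample,
                probe_length=probe_length,
            )
            for seg in segment_track(track, replace(params, seed=child_seed)):
                rows.append(
                    (seg.sample, seg.chrom, seg.start, seg.end, seg.num_probes, seg.mean_log2)
                )
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "num_probes", "seg_mean"]
    )
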