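"""Biological-feature statistics at TAD boundaries and within TADs.

Structural proteins (CTCF, cohesin subunits RAD21/SMC3) accumulate at TAD
boundaries; this module quantifies that with the structural protein profile
(SPP: mean peak counts in 5-kb intervals within +/- 500 kb of a boundary),
a boundary-vs-flank fold change, and the fraction of boundaries tagged by at
least one peak.  Within TADs, repressive H3K27me3 and transcription-coupled
H3K36me3 tend to be mutually exclusive; the log10 signal ratio (LR) over
fixed-size intervals, tested against a shuffle null with Benjamini-Hochberg
FDR, quantifies how many TADs carry a significant mark bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .core import PeakSet, SignalTrack, TadPartition, ValidationError

__all__ = [
    "intersect_peaks",
    "spp",
    "SppResult",
    "boundary_fold_change",
    "FoldChangeResult",
    "tagged_fraction",
    "shared_boundary_enrichment",
    "SharedEnrichmentResult",
    "histone_lr_significance",
    "LrResult",
]

WINDOW_BP = 500_000  # half-window around a boundary for the SPP
INTERVAL_BP = 5_000  # SPP interval size
PEAK_HALF_BP = 10_000  # half-width of the boundary "peak" region
FLANK_BP = 100_000  # width of each distal flank region
FLANK_OFFSET_BP = 400_000  # distance from boundary to the inner flank edge


def intersect_peaks(a: PeakSet, b: PeakSet, label: str = "") -> PeakSet:
    """Regions covered by a peak in both sets (plumbing for combining
    replicate experiments before enrichment analyses)."""
    if a.chrom != b.chrom:
        raise ValidationError("peak sets are on different chromosomes")
    out = []
    i = j = 0
    pa, pb = a.peaks, b.peaks
    while i < len(pa) and j < len(pb):
        s = max(pa[i, 0], pb[j, 0])
        e = min(pa[i, 1], pb[j, 1])
        if e >= s:
            out.append((int(s), int(e)))
        if pa[i, 1] <= pb[j, 1]:
            i += 1
        else:
            j += 1
    return PeakSet(
        chrom=a.chrom,
        peaks=np.array(out, dtype=np.int64).reshape(-1, 2),
        label=label or f"{a.label}&{b.label}",
    )


def _boundary_positions(boundaries, chrom_length_bp=None):
    """Accept a TadPartition or an array of bp positions; return positions
    plus the usable chromosome length."""
    if isinstance(boundaries, TadPartition):
        pos = boundaries.boundary_positions_bp()
        length = chrom_length_bp or boundaries.span_end_bp
    else:
        pos = np.asarray(boundaries, dtype=np.int64).ravel()
        length = chrom_length_bp
    return pos, length


def _usable(pos: np.ndarray, length, window: int):
    keep = pos >= window
    if length is not None:
        keep &= pos + window <= length
    return pos[keep], int(len(pos) - keep.sum())


@dataclass
class SppResult:
    """Per-boundary peak-count profiles around boundaries."""

    positions_bp: np.ndarray  # boundaries actually profiled
    profiles: np.ndarray  # (n_boundaries, n_intervals) peak counts
    n_dropped: int  # boundaries too close to a chromosome end
    interval_bp: int = INTERVAL_BP
    window_bp: int = WINDOW_BP

    @property
    def mean_profile(self) -> np.ndarray:
        """Aggregate profile: mean peak count per interval across boundaries."""
        return self.profiles.mean(axis=0) if len(self.profiles) else np.zeros(0)


def spp(
    boundaries,
    peaks: PeakSet,
    chrom_length_bp: int | None = None,
    window_bp: int = WINDOW_BP,
    interval_bp: int = INTERVAL_BP,
) -> SppResult:
    """Structural protein profile: peak-midpoint counts per ``interval_bp``
    interval across the +/- ``window_bp`` window around each boundary.

    Boundaries closer than ``window_bp`` to either chromosome end are
    dropped (their windows would be truncated) and counted in ``n_dropped``.
    """
    pos, length = _boundary_positions(boundaries, chrom_length_bp)
    pos, n_dropped = _usable(pos, length, window_bp)
    n_int = 2 * window_bp // interval_bp
    if len(pos) == 0:
        return SppResult(
            positions_bp=pos,
            profiles=np.zeros((0, n_int)),
            n_dropped=n_dropped,
            interval_bp=interval_bp,
            window_bp=window_bp,
        )
    mids = np.sort(peaks.midpoints()) if peaks.n_peaks else np.empty(0, dtype=np.int64)
    # interval k of boundary b covers (b - window + k*iv, b - window + (k+1)*iv]
    grid = pos[:, None] - window_bp + interval_bp * np.arange(n_int + 1)[None, :]
    cum = np.searchsorted(mids, grid, side="right")
    profiles = np.diff(cum, axis=1).astype(float)
    return SppResult(
        positions_bp=pos,
        profiles=profiles,
        n_dropped=n_dropped,
        interval_bp=interval_bp,
        window_bp=window_bp,
    )


@dataclass
class FoldChangeResult:
    """Boundary-vs-flank enrichment of peak density.

    ``fold_change`` is the headline aggregate statistic: mean SPP in the
    +/-10-kb boundary region over mean SPP in the two distal 100-kb flanks,
    minus 1 (averaged across boundaries before taking the ratio).
    ``per_boundary`` holds the ratio-then-average variant, NaN where a
    boundary's flanks hold no peaks.
    """

    fold_change: float
    per_boundary: np.ndarray
    n_boundaries: int
    n_excluded_zero_flank: int
    n_dropped: int

    @property
    def mean_per_boundary(self) -> float:
        valid = self.per_boundary[np.isfinite(self.per_boundary)]
        return float(valid.mean()) if valid.size else float("nan")


def boundary_fold_change(
    boundaries,
    peaks: PeakSet,
    chrom_length_bp: int | None = None,
) -> FoldChangeResult:
    """Fold change of peak density at boundaries versus distal flanks.

    The "peak" region spans +/-10 kb around the boundary; the flanks span
    100 kb each, 400 kb away on both sides.  The fold change is the density
    ratio minus 1, so 0 means no enrichment.  Boundaries whose flanks carry
    zero peaks are excluded from the per-boundary average and counted; when
    every flank is empty the aggregate is NaN.
    """
    pos, length = _boundary_positions(boundaries, chrom_length_bp)
    pos, n_dropped = _usable(pos, length, WINDOW_BP)
    if len(pos) == 0:
        return FoldChangeResult(
            fold_change=float("nan"),
            per_boundary=np.empty(0),
            n_boundaries=0,
            n_excluded_zero_flank=0,
            n_dropped=n_dropped,
        )
    mids = np.sort(peaks.midpoints()) if peaks.n_peaks else np.empty(0, dtype=np.int64)

    def count(lo, hi):  # peaks with midpoint in (lo, hi]
        return (
            np.searchsorted(mids, hi, side="right")
            - np.searchsorted(mids, lo, side="right")
        ).astype(float)

    peak_counts = count(pos - PEAK_HALF_BP, pos + PEAK_HALF_BP)
    flank_counts = count(pos - WINDOW_BP, pos - FLANK_OFFSET_BP) + count(
        pos + FLANK_OFFSET_BP, pos + WINDOW_BP
    )
    peak_len = 2.0 * PEAK_HALF_BP
    flank_len = 2.0 * FLANK_BP
    with np.errstate(divide="ignore", invalid="ignore"):
        per_boundary = np.where(
            flank_counts > 0,
            (peak_counts / peak_len) / (flank_counts / flank_len) - 1.0,
            np.nan,
        )
    total_flank = flank_counts.sum()
    if total_flank > 0:
        aggregate = float(
            (peak_counts.sum() / (len(pos) * peak_len))
            / (total_flank / (len(pos) * flank_len))
            - 1.0
        )
    else:
        aggregate = float("nan")
    return FoldChangeResult(
        fold_change=aggregate,
        per_boundary=per_boundary,
        n_boundaries=len(pos),
        n_excluded_zero_flank=int((flank_counts == 0).sum()),
        n_dropped=n_dropped,
    )


def tagged_fraction(
    boundaries, peaks: PeakSet, bin_size_bp: int | None = None
) -> float:
    """Fraction of boundaries with at least one peak overlapping the boundary
    bin or one of the two adjacent bins (+/- one bin around the junction)."""
    if isinstance(boundaries, TadPartition):
        if bin_size_bp is None:
            bin_size_bp = boundaries.bin_size_bp
        pos = boundaries.boundary_positions_bp()
    else:
        if bin_size_bp is None:
            raise ValidationError("bin_size_bp is required for raw positions")
        pos = np.asarray(boundaries, dtype=np.int64).ravel()
    if len(pos) == 0:
        return float("nan")
    if peaks.n_peaks == 0:
        return 0.0
    starts = peaks.peaks[:, 0]
    ends_cummax = np.maximum.accumulate(peaks.peaks[:, 1])
    lo = np.maximum(pos - bin_size_bp + 1, 1)
    hi = pos + bin_size_bp
    idx = np.searchsorted(starts, hi, side="right")
    hit = (idx > 0) & (ends_cummax[np.clip(idx - 1, 0, None)] >= lo)
    return float(hit.mean())


@dataclass
class SharedEnrichmentResult:
    """Peak fold change for consensus ("shared") versus private boundaries."""

    min_callers: int
    radius_bins: int
    shared: FoldChangeResult
    not_shared: FoldChangeResult
    n_shared: int
    n_not_shared: int


def shared_boundary_enrichment(
    partitions,
    peaks: PeakSet,
    min_callers: int,
    radius_bins: int = 2,
    chrom_length_bp: int | None = None,
) -> SharedEnrichmentResult:
    """Split consolidated boundary clusters by the number of supporting
    callers and compare peak fold changes between the classes.

    A unique boundary is "shared" when at least ``min_callers`` distinct
    callers contribute a boundary to its cluster (single-linkage within
    ``radius_bins``), "not shared" otherwise.  Fold changes use the cluster
    representative positions.
    """
    from .concordance import shared_boundaries  # local import avoids a cycle

    sb = shared_boundaries(partitions, radius_bins)
    bin_size = partitions[0].bin_size_bp
    counts = sb.counts()
    pos = np.round(sb.cluster_positions()).astype(np.int64) * bin_size
    if chrom_length_bp is None:
        chrom_length_bp = max(p.span_end_bp for p in partitions)
    shared_mask = counts >= min_callers
    fc_shared = boundary_fold_change(pos[shared_mask], peaks, chrom_length_bp)
    fc_private = boundary_fold_change(pos[~shared_mask], peaks, chrom_length_bp)
    return SharedEnrichmentResult(
        min_callers=int(min_callers),
        radius_bins=int(radius_bins),
        shared=fc_shared,
        not_shared=fc_private,
        n_shared=int(shared_mask.sum()),
        n_not_shared=int((~shared_mask).sum()),
    )


@dataclass
class LrResult:
    """Within-TAD histone-mark log-ratio significance."""

    interval_size_bp: int
    interval_starts: np.ndarray
    lr: np.ndarray  # per-interval log10 ratio
    tad_mean_lr: np.ndarray  # observed mean LR per TAD (NaN: no interval)
    pvalues: np.ndarray
    qvalues: np.ndarray
    mu: float  # chromosome-wide mean LR
    fdr: float
    pseudocounts: tuple[float, float]
    n_shuffles: int
    null: str

    @property
    def fraction_significant(self) -> float:
        valid = np.isfinite(self.qvalues)
        if not valid.any():
            return float("nan")
        return float((self.qvalues[valid] < self.fdr).mean())


def histone_lr_significance(
    tads: TadPartition,
    sig27: SignalTrack,
    sig36: SignalTrack,
    n_shuffles: int = 10,
    seed: int | None = None,
    fdr: float = 0.1,
    pseudocount: float | None = None,
    null: str = "pooled",
    alternative: str = "two-sided",
    plus_one: bool = True,
    gap_policy: str = "error",
) -> LrResult:
    """Test each TAD for a biased H3K27me3/H3K36me3 balance.

    The chromosome is cut into intervals of 10% of the mean TAD size
    (rounded down to a bin multiple, at least one bin); per interval
    ``LR = log10((mean sig27 + eps27) / (mean sig36 + eps36))`` with
    pseudocounts defaulting to 1% of each track's global mean.  The observed
    statistic is the mean LR over the intervals whose midpoints fall inside
    the TAD.  Interval LR values are permuted ``n_shuffles`` times across
    interval positions; the empirical p-value compares the observed deviation
    from the chromosome-wide mean against the randomized within-TAD averages
    — pooled across all TADs and shuffles by default (``null="pooled"``), or
    against each TAD's own shuffle values (``null="per_tad"``).  p-values are
    BH-adjusted across TADs.
    """
    if tads.n_domains == 0:
        raise ValidationError("partition has no TADs")
    if null not in ("pooled", "per_tad"):
        raise ValidationError("null must be 'pooled' or 'per_tad'")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValidationError("alternative must be two-sided, greater or less")
    bin_bp = tads.bin_size_bp
    isz = max(bin_bp, int(tads.mean_size_bp() * 0.1) // bin_bp * bin_bp)
    span = max(tads.span_end_bp, sig27.span_end_bp, sig36.span_end_bp)
    n_int = span // isz
    if n_int < 2:
        raise ValidationError("chromosome span too short for LR intervals")
    starts = 1 + isz * np.arange(n_int, dtype=np.int64)
    intervals = np.column_stack([starts, starts + isz - 1])
    m27 = sig27.mean_over(intervals, gap_policy)
    m36 = sig36.mean_over(intervals, gap_policy)
    eps27 = pseudocount if pseudocount is not None else 0.01 * sig27.global_mean()
    eps36 = pseudocount if pseudocount is not None else 0.01 * sig36.global_mean()
    if eps27 <= 0 or eps36 <= 0:
        raise ValidationError("pseudocounts must be positive (empty track?)")
    lr = np.log10((m27 + eps27) / (m36 + eps36))
    mids = starts + isz // 2
    # membership by interval midpoint: contiguous slice per TAD
    lo = np.searchsorted(mids, tads.starts, side="left")
    hi = np.searchsorted(mids, tads.ends, side="right")
    n_tads = tads.n_domains
    sizes = (hi - lo).astype(float)
    cum = np.concatenate([[0.0], np.cumsum(lr)])
    with np.errstate(invalid="ignore", divide="ignore"):
        obs = np.where(sizes > 0, (cum[hi] - cum[lo]) / sizes, np.nan)
    mu = float(lr.mean())
    rng = np.random.default_rng(seed)
    shuffled = np.empty((n_shuffles, n_tads))
    for k in range(n_shuffles):
        perm = lr[rng.permutation(n_int)]
        cumk = np.concatenate([[0.0], np.cumsum(perm)])
        with np.errstate(invalid="ignore", divide="ignore"):
            shuffled[k] = np.where(sizes > 0, (cumk[hi] - cumk[lo]) / sizes, np.nan)

    def _dev(x):
        if alternative == "two-sided":
            return np.abs(x - mu)
        if alternative == "greater":
            return x - mu
        return mu - x

    d_obs = _dev(obs)
    d_null = _dev(shuffled)
    add = 1.0 if plus_one else 0.0
    pvals = np.full(n_tads, np.nan)
    valid = np.isfinite(d_obs)
    if null == "pooled":
        pool = np.sort(d_null[np.isfinite(d_null)])
        denom = len(pool) + add
        ge = len(pool) - np.searchsorted(pool, d_obs[valid], side="left")
        pvals[valid] = (ge + add) / denom
    else:
        for t in np.nonzero(valid)[0]:
            col = d_null[:, t]
            col = col[np.isfinite(col)]
            pvals[t] = ((col >= d_obs[t]).sum() + add) / (len(col) + add)
    if not plus_one:
        pvals[valid] = np.maximum(pvals[valid], np.finfo(float).tiny)
    qvals = np.full(n_tads, np.nan)
    if valid.any():
        qvals[valid] = multipletests(pvals[valid], method="fdr_bh")[1]
    return LrResult(
        interval_size_bp=isz,
        interval_starts=starts,
        lr=lr,
        tad_mean_lr=obs,
        pvalues=pvals,
        qvalues=qvals,
        mu=mu,
        fdr=fdr,
        pseudocounts=(float(eps27), float(eps36)),
        n_shuffles=int(n_shuffles),
        null=null,
    )
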