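"""Partition-vs-partition statistics.

The central metric is the Measure of Concordance (MoC) between two domain
partitions P and Q of the same chromosome, with base pairs as the clustered
elements and TADs plus inter-TAD gaps as the clusters:

    MoC(P, Q) = 1                                      if N_P = N_Q = 1
              = (1 / (sqrt(N_P * N_Q) - 1)) *
                (sum_ij ||F_ij||^2 / (||P_i|| * ||Q_j||) - 1)   otherwise

where ``||F_ij||`` is the overlap (bp) between clusters P_i and Q_j.  MoC is
symmetric and ranges from 0 (no concordance) to 1 (identical partitions).

Conservation statistics complement MoC: a boundary of one partition is
conserved in another when a boundary of the latter lies within a tolerance
radius (in bins); a TAD is conserved when both its boundaries match the two
ends of one single TAD on the other side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TadPartition, ValidationError

__all__ = [
    "moc",
    "moc_detail",
    "ConcordancePair",
    "conserved_boundaries",
    "conserved_tads",
    "cross_resolution_conserved",
    "ConservationResult",
    "shared_boundaries",
    "SharedBoundaries",
    "conservation_ratio",
    "size_summary",
    "SizeSummary",
]


def _check_same_chrom(p: TadPartition, q: TadPartition):
    if p.chrom != q.chrom:
        raise ValidationError(
            f"partitions are on different chromosomes: {p.chrom!r} vs {q.chrom!r}"
        )


def _check_same_bin(p: TadPartition, q: TadPartition):
    if p.bin_size_bp != q.bin_size_bp:
        raise ValidationError(
            f"bin sizes differ ({p.bin_size_bp} vs {q.bin_size_bp}); "
            "use cross_resolution_conserved for mixed resolutions"
        )


@dataclass
class ConcordancePair:
    """MoC computation with its full overlap table."""

    moc: float
    clusters_a: np.ndarray
    clusters_b: np.ndarray
    overlaps: list = field(default_factory=list)  # (i, j, overlap_bp)


def _overlap_sum(A: np.ndarray, B: np.ndarray, record=None) -> float:
    """Two-pointer sweep over sorted non-overlapping cluster lists,
    accumulating ||F_ij||^2 / (||A_i|| * ||B_j||)."""
    total = 0.0
    i = j = 0
    while i < len(A) and j < len(B):
        s = max(A[i, 0], B[j, 0])
        e = min(A[i, 1], B[j, 1])
        if e >= s:
            ov = float(e - s + 1)
            la = float(A[i, 1] - A[i, 0] + 1)
            lb = float(B[j, 1] - B[j, 0] + 1)
            total += ov * ov / (la * lb)
            if record is not None:
                record.append((i, j, int(ov)))
        if A[i, 1] <= B[j, 1]:
            i += 1
        else:
            j += 1
    return total


def moc_detail(
    p: TadPartition, q: TadPartition, gaps_as_clusters: bool = True
) -> ConcordancePair:
    """MoC between two partitions, returning the overlap table as well.

    With ``gaps_as_clusters`` (the default) inter-TAD regions count as
    clusters and the two partitions are harmonized to the union span, the
    shorter side gaining a terminal gap cluster.
    """
    _check_same_chrom(p, q)
    if gaps_as_clusters:
        span = max(p.span_end_bp, q.span_end_bp)
        A = p.clusters(span)
        B = q.clusters(span)
    else:
        A, B = p.domains, q.domains
    na, nb = len(A), len(B)
    rec: list = []
    if na == 0 or nb == 0:
        raise ValidationError("cannot compute MoC against an empty cluster list")
    if na == 1 and nb == 1:
        return ConcordancePair(moc=1.0, clusters_a=A, clusters_b=B, overlaps=rec)
    total = _overlap_sum(A, B, rec)
    value = (total - 1.0) / (np.sqrt(na * nb) - 1.0)
    # MoC is mathematically bounded in [0, 1]; values within accumulated
    # rounding error of the bounds (e.g. the telescoping single-cluster
    # case, exactly 0) are snapped onto them
    value = min(1.0, max(0.0, value))
    if value < 1e-12:
        value = 0.0
    elif 1.0 - value < 1e-12:
        value = 1.0
    return ConcordancePair(moc=float(value), clusters_a=A, clusters_b=B, overlaps=rec)


def moc(p: TadPartition, q: TadPartition, gaps_as_clusters: bool = True) -> float:
    """Measure of Concordance between two TAD partitions (in [0, 1])."""
    return moc_detail(p, q, gaps_as_clusters).moc


@dataclass
class ConservationResult:
    """Outcome of a boundary- or TAD-conservation comparison."""

    kind: str  # "boundary" | "tad" | "cross_resolution"
    radius_bins: int
    items_a: np.ndarray
    items_b: np.ndarray
    conserved_a: np.ndarray  # bool per item of a
    conserved_b: np.ndarray

    @property
    def fraction_a(self) -> float:
        return float(self.conserved_a.mean()) if len(self.conserved_a) else float("nan")

    @property
    def fraction_b(self) -> float:
        return float(self.conserved_b.mean()) if len(self.conserved_b) else float("nan")

    @property
    def n_conserved_a(self) -> int:
        return int(self.conserved_a.sum())

    @property
    def n_conserved_b(self) -> int:
        return int(self.conserved_b.sum())


def _edges_within(sources: np.ndarray, targets: np.ndarray, radius: int) -> np.ndarray:
    """For each source edge, is some target edge within ``radius`` bins?"""
    if len(sources) == 0:
        return np.zeros(0, dtype=bool)
    if len(targets) == 0:
        return np.zeros(len(sources), dtype=bool)
    pos = np.searchsorted(targets, sources)
    left = np.clip(pos - 1, 0, len(targets) - 1)
    right = np.clip(pos, 0, len(targets) - 1)
    dist = np.minimum(
        np.abs(sources - targets[left]), np.abs(sources - targets[right])
    )
    return dist <= radius


def conserved_boundaries(
    p: TadPartition, q: TadPartition, radius_bins: int
) -> ConservationResult:
    """Boundary conservation at a tolerance radius (same bin size required).

    A boundary of ``p`` is conserved when some boundary of ``q`` lies within
    ``radius_bins`` bins; fractions are reported for both sides (the counts
    are asymmetric for radius > 0)."""
    _check_same_chrom(p, q)
    _check_same_bin(p, q)
    if radius_bins < 0:
        raise ValidationError("radius_bins must be >= 0")
    ep, eq = p.boundaries(), q.boundaries()
    return ConservationResult(
        kind="boundary",
        radius_bins=int(radius_bins),
        items_a=ep,
        items_b=eq,
        conserved_a=_edges_within(ep, eq, radius_bins),
        conserved_b=_edges_within(eq, ep, radius_bins),
    )


def _tads_conserved_in(p: TadPartition, q: TadPartition, radius: int) -> np.ndarray:
    """True per p-TAD when one single q-TAD matches both its boundaries
    within ``radius`` bins."""
    ps, pe = p.start_edges, p.end_edges
    qs, qe = q.start_edges, q.end_edges
    out = np.zeros(p.n_domains, dtype=bool)
    for k in range(p.n_domains):
        lo = np.searchsorted(qs, ps[k] - radius, side="left")
        hi = np.searchsorted(qs, ps[k] + radius, side="right")
        if hi > lo:
            out[k] = bool((np.abs(qe[lo:hi] - pe[k]) <= radius).any())
    return out


def conserved_tads(
    p: TadPartition, q: TadPartition, radius_bins: int
) -> ConservationResult:
    """TAD conservation: a TAD is conserved when its start and end both match
    the start and end of a single TAD on the other side, within the radius."""
    _check_same_chrom(p, q)
    _check_same_bin(p, q)
    if radius_bins < 0:
        raise ValidationError("radius_bins must be >= 0")
    return ConservationResult(
        kind="tad",
        radius_bins=int(radius_bins),
        items_a=p.domains,
        items_b=q.domains,
        conserved_a=_tads_conserved_in(p, q, radius_bins),
        conserved_b=_tads_conserved_in(q, p, radius_bins),
    )


def cross_resolution_conserved(
    coarse: TadPartition, fine: TadPartition
) -> ConservationResult:
    """Conservation of coarse-resolution boundaries against a finer matrix.

    A boundary found at the bigger bin size is conserved when at least one
    fine boundary falls inside the genomic interval of its boundary bin
    (interval edges included).  ``fraction_a`` is the headline number: the
    fraction of coarse boundaries confirmed at the finer resolution.
    """
    _check_same_chrom(coarse, fine)
    factor, rem = divmod(coarse.bin_size_bp, fine.bin_size_bp)
    if rem or factor < 1:
        raise ValidationError(
            f"coarse bin size {coarse.bin_size_bp} must be a multiple of "
            f"fine bin size {fine.bin_size_bp}"
        )
    records = sorted(set(coarse.boundary_records()))
    fine_pos = fine.boundaries() * fine.bin_size_bp  # bp junction positions
    Bc = coarse.bin_size_bp
    conserved = np.zeros(len(records), dtype=bool)
    for idx, (bin_idx, _kind) in enumerate(records):
        lo_bp, hi_bp = bin_idx * Bc, (bin_idx + 1) * Bc
        i = np.searchsorted(fine_pos, lo_bp, side="left")
        conserved[idx] = i < len(fine_pos) and fine_pos[i] <= hi_bp
    return ConservationResult(
        kind="cross_resolution",
        radius_bins=0,
        items_a=np.array([r[0] for r in records], dtype=np.int64),
        items_b=fine_pos,
        conserved_a=conserved,
        conserved_b=np.zeros(0, dtype=bool),
    )


@dataclass
class SharedBoundaries:
    """Consolidated boundary clusters across multiple callers."""

    radius_bins: int
    linkage: str
    edges: np.ndarray  # all boundary edges, sorted
    callers: np.ndarray  # caller index per edge
    cluster_ids: np.ndarray  # cluster index per edge
    n_callers_total: int

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_ids[-1]) + 1 if len(self.cluster_ids) else 0

    def counts(self) -> np.ndarray:
        """Distinct callers represented in each cluster."""
        out = np.zeros(self.n_clusters, dtype=np.int64)
        for cid in range(self.n_clusters):
            sel = self.cluster_ids == cid
            out[cid] = len(np.unique(self.callers[sel]))
        return out

    def cluster_positions(self) -> np.ndarray:
        """Representative (mean) edge per cluster, in bin units."""
        out = np.zeros(self.n_clusters)
        for cid in range(self.n_clusters):
            out[cid] = self.edges[self.cluster_ids == cid].mean()
        return out

    def histogram(self) -> pd.Series:
        """Number of unique boundary clusters found by k callers, k=1..N."""
        counts = self.counts()
        idx = np.arange(1, self.n_callers_total + 1)
        return pd.Series(
            [(counts == k).sum() for k in idx], index=idx, name="n_boundaries"
        )

    def per_edge_counts(self) -> np.ndarray:
        """Caller count of the cluster each edge belongs to."""
        counts = self.counts()
        return counts[self.cluster_ids]


def shared_boundaries(
    partitions, radius_bins: int, linkage: str = "single"
) -> SharedBoundaries:
    """Consolidate the boundaries of several callers into clusters and count
    how many distinct callers support each unique boundary.

    ``linkage="single"`` links edges whose consecutive gap is within the
    radius; ``"complete"`` caps the cluster diameter at the radius instead.
    """
    partitions = list(partitions)
    if len(partitions) < 2:
        raise ValidationError("shared_boundaries needs at least 2 partitions")
    chrom = partitions[0].chrom
    bin_size = partitions[0].bin_size_bp
    for p in partitions[1:]:
        if p.chrom != chrom:
            raise ValidationError("all partitions must share one chromosome")
        if p.bin_size_bp != bin_size:
            raise ValidationError("all partitions must share one bin size")
    if linkage not in ("single", "complete"):
        raise ValidationError("linkage must be 'single' or 'complete'")
    edges_all, callers_all = [], []
    for ci, p in enumerate(partitions):
        e = p.boundaries()
        edges_all.append(e)
        callers_all.append(np.full(len(e), ci, dtype=np.int64))
    edges = np.concatenate(edges_all)
    callers = np.concatenate(callers_all)
    order = np.argsort(edges, kind="stable")
    edges, callers = edges[order], callers[order]
    cluster_ids = np.zeros(len(edges), dtype=np.int64)
    cid = 0
    anchor = edges[0] if len(edges) else 0
    for k in range(1, len(edges)):
        if linkage == "single":
            new = edges[k] - edges[k - 1] > radius_bins
        else:
            new = edges[k] - anchor > radius_bins
        if new:
            cid += 1
            anchor = edges[k]
        cluster_ids[k] = cid
    return SharedBoundaries(
        radius_bins=int(radius_bins),
        linkage=linkage,
        edges=edges,
        callers=callers,
        cluster_ids=cluster_ids,
        n_callers_total=len(partitions),
    )


def conservation_ratio(p: TadPartition, q: TadPartition, radius_bins: int) -> float:
    """Conserved TADs over the maximum possible number of conserved TADs,
    i.e. min(N_P, N_Q).  Uses the p-side conserved count."""
    res = conserved_tads(p, q, radius_bins)
    denom = min(p.n_domains, q.n_domains)
    if denom == 0:
        return float("nan")
    return res.n_conserved_a / denom


@dataclass
class SizeSummary:
    """Mean TAD size per resolution plus linear-fit slopes."""

    table: pd.DataFrame
    slope_bp: float  # d(mean size in bp) / d(bin size in bp)
    slope_bins: float  # d(mean size in bins) / d(bin size in bp)


def size_summary(partitions_by_bin_size: dict[int, TadPartition]) -> SizeSummary:
    """Summarize how mean TAD size scales with matrix resolution.

    Fits ordinary least squares of mean TAD size against bin size, once with
    size in bp and once in bins; needs at least two resolutions.
    """
    if len(partitions_by_bin_size) < 2:
        raise ValidationError("size_summary needs partitions at >= 2 bin sizes")
    rows = []
    for b in sorted(partitions_by_bin_size):
        p = partitions_by_bin_size[b]
        if p.bin_size_bp != b:
            raise ValidationError(
                f"partition keyed {b} has bin_size_bp {p.bin_size_bp}"
            )
        rows.append(
            {
                "bin_size_bp": b,
                "n_tads": p.n_domains,
                "mean_size_bp": p.mean_size_bp(),
                "mean_size_bins": float(p.sizes_bins.mean()) if p.n_domains else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    x = table["bin_size_bp"].to_numpy(dtype=float)
    slope_bp = float(np.polyfit(x, table["mean_size_bp"].to_numpy(), 1)[0])
    slope_bins = float(np.polyfit(x, table["mean_size_bins"].to_numpy(), 1)[0])
    return SizeSummary(table=table, slope_bp=slope_bp, slope_bins=slope_bins)
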