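"""Core genomic containers shared by every analysis module.

All interval coordinates are 1-based and closed, the convention used by the
uniform three-column TAD output format (``chr1  1  10000`` is the first 10-kb
bin).  BED and bedGraph inputs are converted on read (see
:mod:`tadconcord.genomic_io`).

A *boundary* has two interchangeable representations:

* the **bin index** of a domain's start or end bin (used for per-domain
  boundary records and the cross-resolution conservation rule), and
* the **junction (edge) index** in bin units — the point between bin ``k-1``
  and bin ``k``, at base-pair position ``k * bin_size_bp``.  The junction
  between an end bin ``e`` and the following start bin ``e+1`` is a single
  edge, which is what makes de-duplicated boundary counting well defined.

Distances measured in bins are identical under either representation, so a
tolerance radius of 5 bins means +/- 50 kb on a 10-kb matrix either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "TadConcordError",
    "ValidationError",
    "FormatError",
    "TadPartition",
    "DomainSet",
    "ContactMatrix",
    "PeakSet",
    "SignalTrack",
    "BinCovariates",
]


class TadConcordError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(TadConcordError, ValueError):
    """A container violated one of its invariants."""


class FormatError(TadConcordError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def _as_interval_array(domains) -> np.ndarray:
    arr = np.asarray(domains, dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("domains must be an (n, 2) array of (start, end)")
    return arr


def _nearest_aligned(pos: int, bin_size: int, kind: str) -> int:
    # starts sit at k*bin+1, ends at k*bin
    if kind == "start":
        return int(round((pos - 1) / bin_size)) * bin_size + 1
    return max(bin_size, int(round(pos / bin_size)) * bin_size)


@dataclass
class TadPartition:
    """An ordered, non-overlapping set of TADs on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    domains : array-like of shape (n, 2)
        1-based closed ``(start_bp, end_bp)`` intervals, bin aligned: every
        start is ``k*bin_size_bp + 1`` and every end ``k*bin_size_bp``.
    bin_size_bp : int
        Bin size of the contact matrix the TADs were called on.
    chrom_length_bp : int, optional
        Chromosome length; when absent, span-dependent quantities use the
        last domain end.
    label : str
        Free-text identifier (caller name, normalization, resolution...).
    """

    chrom: str
    domains: np.ndarray
    bin_size_bp: int
    chrom_length_bp: int | None = None
    label: str = ""

    def __post_init__(self):
        self.domains = _as_interval_array(self.domains)
        b = int(self.bin_size_bp)
        if b <= 0:
            raise ValidationError("bin_size_bp must be positive")
        self.bin_size_bp = b
        d = self.domains
        if d.size:
            if (d[:, 0] < 1).any():
                rows = np.nonzero(d[:, 0] < 1)[0]
                raise ValidationError(f"start < 1 in rows {rows.tolist()}")
            if (d[:, 0] > d[:, 1]).any():
                rows = np.nonzero(d[:, 0] > d[:, 1])[0]
                raise ValidationError(f"start > end in rows {rows.tolist()}")
            order = np.argsort(d[:, 0], kind="stable")
            d = d[order]
            bad = np.nonzero(d[1:, 0] <= d[:-1, 1])[0]
            if bad.size:
                r = int(bad[0])
                raise ValidationError(
                    f"overlapping domains: rows {r} and {r + 1} "
                    f"({tuple(d[r])} vs {tuple(d[r + 1])})"
                )
            mis_s = np.nonzero((d[:, 0] - 1) % b != 0)[0]
            if mis_s.size:
                r = int(mis_s[0])
                pos = int(d[r, 0])
                raise ValidationError(
                    f"row {r}: start {pos} is not aligned to {b}-bp bins; "
                    f"nearest aligned start is {_nearest_aligned(pos, b, 'start')}"
                )
            mis_e = np.nonzero(d[:, 1] % b != 0)[0]
            if mis_e.size:
                r = int(mis_e[0])
                pos = int(d[r, 1])
                raise ValidationError(
                    f"row {r}: end {pos} is not aligned to {b}-bp bins; "
                    f"nearest aligned end is {_nearest_aligned(pos, b, 'end')}"
                )
            self.domains = d
        if self.chrom_length_bp is not None:
            L = int(self.chrom_length_bp)
            if L <= 0:
                raise ValidationError("chrom_length_bp must be positive")
            if d.size and d[-1, 1] > L:
                raise ValidationError(
                    f"domain end {int(d[-1, 1])} exceeds chrom_length_bp {L}"
                )
            self.chrom_length_bp = L

    # -- basic accessors -------------------------------------------------
    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def starts(self) -> np.ndarray:
        return self.domains[:, 0]

    @property
    def ends(self) -> np.ndarray:
        return self.domains[:, 1]

    @property
    def sizes_bp(self) -> np.ndarray:
        return self.domains[:, 1] - self.domains[:, 0] + 1

    @property
    def sizes_bins(self) -> np.ndarray:
        return self.sizes_bp // self.bin_size_bp

    @property
    def span_end_bp(self) -> int:
        """Chromosome length when known, otherwise the last domain end."""
        if self.chrom_length_bp is not None:
            return self.chrom_length_bp
        if self.n_domains == 0:
            return 0
        return int(self.domains[-1, 1])

    def mean_size_bp(self) -> float:
        return float(self.sizes_bp.mean()) if self.n_domains else float("nan")

    # -- derived structure ----------------------------------------------
    def gaps(self) -> np.ndarray:
        """Maximal uncovered (inter-TAD) intervals within [1, span_end]."""
        L = self.span_end_bp
        if self.n_domains == 0:
            if L >= 1:
                return np.array([[1, L]], dtype=np.int64)
            return np.empty((0, 2), dtype=np.int64)
        out = []
        prev_end = 0
        for s, e in self.domains:
            if s > prev_end + 1:
                out.append((prev_end + 1, s - 1))
            prev_end = e
        if L > prev_end:
            out.append((prev_end + 1, L))
        return np.array(out, dtype=np.int64).reshape(-1, 2)

    @property
    def start_edges(self) -> np.ndarray:
        """Junction index (bin units) at each domain's left side."""
        return (self.domains[:, 0] - 1) // self.bin_size_bp

    @property
    def end_edges(self) -> np.ndarray:
        """Junction index (bin units) at each domain's right side."""
        return self.domains[:, 1] // self.bin_size_bp

    def boundaries(self, dedupe: bool = True) -> np.ndarray:
        """Boundary junction indices (bin units).

        With ``dedupe`` the junction shared by an end bin ``e`` and the next
        start bin ``e+1`` collapses to a single edge and identical positions
        across domains collapse; without it every domain contributes its two
        records in domain order.
        """
        if self.n_domains == 0:
            return np.empty(0, dtype=np.int64)
        rec = np.empty(2 * self.n_domains, dtype=np.int64)
        rec[0::2] = self.start_edges
        rec[1::2] = self.end_edges
        if dedupe:
            return np.unique(rec)
        return rec

    def boundary_records(self) -> list[tuple[int, str]]:
        """Per-domain boundary records as ``(bin_index, kind)`` tuples."""
        b = self.bin_size_bp
        out = []
        for s, e in self.domains:
            out.append((int((s - 1) // b), "start"))
            out.append((int((e - 1) // b), "end"))
        return out

    def boundary_positions_bp(self, interior_only: bool = False) -> np.ndarray:
        """De-duplicated boundary positions in base pairs (junction points)."""
        edges = self.boundaries(dedupe=True)
        if interior_only and edges.size:
            lo = (self.domains[0, 0] - 1) // self.bin_size_bp
            hi = self.span_end_bp // self.bin_size_bp
            edges = edges[(edges != lo) & (edges != hi)]
        return edges * self.bin_size_bp

    def clusters(self, span_end_bp: int | None = None) -> np.ndarray:
        """Domains plus inter-TAD gaps, tiling [1, span] — the MoC clusters."""
        L = self.span_end_bp if span_end_bp is None else int(span_end_bp)
        if L < 1:
            return np.empty((0, 2), dtype=np.int64)
        out: list[tuple[int, int]] = []
        prev_end = 0
        for s, e in self.domains:
            if s > prev_end + 1:
                out.append((prev_end + 1, int(s) - 1))
            out.append((int(s), int(e)))
            prev_end = int(e)
        if L > prev_end:
            out.append((prev_end + 1, L))
        return np.array(out, dtype=np.int64).reshape(-1, 2)


@dataclass
class DomainSet:
    """Possibly nested or overlapping domains — input to hierarchy extraction."""

    chrom: str
    domains: np.ndarray
    bin_size_bp: int
    label: str = ""

    def __post_init__(self):
        self.domains = _as_interval_array(self.domains)
        if int(self.bin_size_bp) <= 0:
            raise ValidationError("bin_size_bp must be positive")
        self.bin_size_bp = int(self.bin_size_bp)
        d = self.domains
        if d.size:
            if (d[:, 0] < 1).any() or (d[:, 0] > d[:, 1]).any():
                raise ValidationError("domains must satisfy 1 <= start <= end")
            # sort by (start, -length)
            order = np.lexsort((-(d[:, 1] - d[:, 0]), d[:, 0]))
            self.domains = d[order]

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    def duplicate_mask(self) -> np.ndarray:
        """True for rows that repeat an earlier (start, end) pair exactly."""
        d = self.domains
        mask = np.zeros(len(d), dtype=bool)
        if len(d) > 1:
            same = (d[1:] == d[:-1]).all(axis=1)
            mask[1:] = same
        return mask


@dataclass
class ContactMatrix:
    """Symmetric binned intra-chromosomal contacts, stored as a sparse
    upper triangle.

    ``total_reads`` is the sum of stored entries, i.e. off-diagonal contacts
    counted once.
    """

    chrom: str
    bin_size_bp: int
    n_bins: int
    data: sp.spmatrix
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = int(self.n_bins)
        if n <= 0:
            raise ValidationError("n_bins must be positive")
        self.n_bins = n
        self.bin_size_bp = int(self.bin_size_bp)
        coo = sp.coo_matrix(self.data)
        if coo.shape != (n, n):
            raise ValidationError(f"matrix shape {coo.shape} != ({n}, {n})")
        if coo.nnz:
            if (coo.row > coo.col).any():
                raise ValidationError("entries must be upper-triangular (i <= j)")
            if not np.isfinite(coo.data).all():
                raise ValidationError("counts must be finite")
            # raw counts must be non-negative; normalized residuals
            # (e.g. Pearson) may dip below zero
            if not self.normalized and (coo.data < 0).any():
                raise ValidationError("counts must be non-negative")
        self.data = coo.tocsr()

    @property
    def total_reads(self) -> float:
        return float(self.data.sum())

    def full(self) -> sp.csr_matrix:
        """Symmetric matrix with the diagonal counted once."""
        u = self.data
        return u + u.T - sp.diags(u.diagonal().astype(float))

    def marginals(self) -> np.ndarray:
        """Per-bin total contacts (row sum of the symmetric matrix)."""
        return np.asarray(self.full().sum(axis=1)).ravel()

    def to_dense(self) -> np.ndarray:
        return self.full().toarray()


@dataclass
class PeakSet:
    """ChIP-seq peak intervals, 1-based closed internally."""

    chrom: str
    peaks: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.peaks = _as_interval_array(self.peaks)
        p = self.peaks
        if p.size:
            if (p[:, 0] < 1).any() or (p[:, 0] > p[:, 1]).any():
                raise ValidationError("peaks must satisfy 1 <= start <= end")
            self.peaks = p[np.argsort(p[:, 0], kind="stable")]

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def midpoints(self) -> np.ndarray:
        return (self.peaks[:, 0] + self.peaks[:, 1]) // 2


@dataclass
class SignalTrack:
    """Piecewise-constant non-negative signal over sorted, non-overlapping
    1-based closed intervals (e.g. ChIP-seq fold change over control)."""

    chrom: str
    intervals: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.intervals = _as_interval_array(self.intervals)
        self.values = np.asarray(self.values, dtype=float).ravel()
        iv, v = self.intervals, self.values
        if len(iv) != len(v):
            raise ValidationError("intervals and values must have equal length")
        if iv.size:
            if (iv[:, 0] < 1).any() or (iv[:, 0] > iv[:, 1]).any():
                raise ValidationError("intervals must satisfy 1 <= start <= end")
            order = np.argsort(iv[:, 0], kind="stable")
            iv, v = iv[order], v[order]
            if (iv[1:, 0] <= iv[:-1, 1]).any():
                raise ValidationError("track intervals must not overlap")
            if not np.isfinite(v).all() or (v < 0).any():
                raise ValidationError("values must be finite and non-negative")
            self.intervals, self.values = iv, v

    @property
    def span_end_bp(self) -> int:
        return int(self.intervals[-1, 1]) if len(self.intervals) else 0

    def _cum_at(self, x: np.ndarray, per_bp: np.ndarray) -> np.ndarray:
        """Vectorized cumulative sum of ``per_bp`` (one rate per interval,
        applied to each covered bp) over [1, x]."""
        x = np.asarray(x, dtype=np.int64)
        starts, ends = self.intervals[:, 0], self.intervals[:, 1]
        lens = (ends - starts + 1).astype(float)
        cum = np.concatenate([[0.0], np.cumsum(per_bp * lens)])
        k = np.searchsorted(starts, x, side="right") - 1
        kk = np.clip(k, 0, None)
        frac = np.clip(np.minimum(x, ends[kk]) - starts[kk] + 1, 0, None)
        return np.where(k >= 0, cum[kk] + per_bp[kk] * frac, 0.0)

    def mean_over(self, intervals, gap_policy: str = "error") -> np.ndarray:
        """Mean signal over each query ``(start, end)`` interval.

        With ``gap_policy="error"`` any query touching uncovered positions
        raises; ``"zero"`` treats uncovered base pairs as signal 0.
        """
        q = _as_interval_array(intervals)
        if q.size == 0:
            return np.empty(0)
        if len(self.intervals) == 0:
            if gap_policy == "zero":
                return np.zeros(len(q))
            raise ValidationError(
                "track has no coverage; pass gap_policy='zero' to zero-fill "
                "or mask the uncovered intervals"
            )
        ones = np.ones(len(self.values))
        ints = self._cum_at(q[:, 1], self.values) - self._cum_at(q[:, 0] - 1, self.values)
        covs = self._cum_at(q[:, 1], ones) - self._cum_at(q[:, 0] - 1, ones)
        lens = (q[:, 1] - q[:, 0] + 1).astype(float)
        if gap_policy != "zero" and (covs < lens).any():
            i = int(np.nonzero(covs < lens)[0][0])
            raise ValidationError(
                f"query interval {tuple(q[i])} overlaps a track gap; pass "
                "gap_policy='zero' to zero-fill gaps or mask them upstream"
            )
        return ints / lens

    def global_mean(self) -> float:
        """Signal mean over covered base pairs."""
        if len(self.intervals) == 0:
            return 0.0
        lens = (self.intervals[:, 1] - self.intervals[:, 0] + 1).astype(float)
        return float(np.sum(self.values * lens) / np.sum(lens))


@dataclass
class BinCovariates:
    """Per-bin local genomic features used by LGF normalization."""

    mappability: np.ndarray
    gc_content: np.ndarray
    fragment_length: np.ndarray

    def __post_init__(self):
        self.mappability = np.asarray(self.mappability, dtype=float).ravel()
        self.gc_content = np.asarray(self.gc_content, dtype=float).ravel()
        self.fragment_length = np.asarray(self.fragment_length, dtype=float).ravel()
        n = len(self.mappability)
        if len(self.gc_content) != n or len(self.fragment_length) != n:
            raise ValidationError("covariate vectors must have equal length")
        for name, v in self.items():
            if not np.isfinite(v).all():
                raise ValidationError(f"{name} contains non-finite values")
        if ((self.mappability < 0) | (self.mappability > 1)).any():
            raise ValidationError("mappability must lie in [0, 1]")
        if ((self.gc_content < 0) | (self.gc_content > 1)).any():
            raise ValidationError("gc_content must lie in [0, 1]")
        if (self.fragment_length <= 0).any():
            raise ValidationError("fragment_length must be positive")

    def items(self):
        return [
            ("mappability", self.mappability),
            ("gc_content", self.gc_content),
            ("fragment_length", self.fragment_length),
        ]

    @property
    def n_bins(self) -> int:
        return len(self.mappability)
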