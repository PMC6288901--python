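"""Readers and writers for the plain-text formats the toolkit touches.

TAD partitions travel as three-column text (``chrom  start  end``, 1-based
closed, tab or comma separated).  ChIP-seq peaks arrive as BED and signal
tracks as bedGraph — both 0-based half-open on disk and converted to the
internal 1-based closed convention on read.  Sparse contact matrices use a
triplet text format (``i  j  count``) with a single header line carrying the
chromosome, bin size and bin count.  Single-resolution ``.cool`` containers
can be imported through h5py.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import scipy.sparse as sp

from .core import (
    ContactMatrix,
    FormatError,
    PeakSet,
    SignalTrack,
    TadPartition,
)

__all__ = [
    "read_partition",
    "read_partitions",
    "write_partition",
    "read_peaks",
    "write_peaks",
    "read_bedgraph",
    "write_bedgraph",
    "read_triplets",
    "write_triplets",
    "read_cool",
]


def _split_row(line: str):
    line = line.rstrip("\n")
    if "\t" in line:
        return [f.strip() for f in line.split("\t")]
    if "," in line:
        return [f.strip() for f in line.split(",")]
    return line.split()


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _parse_interval_file(path, n_cols: int):
    """Generic chrom/start/end(+extra) parser returning per-chromosome rows."""
    by_chrom: dict[str, list] = {}
    for lineno, line in _data_lines(path):
        fields = _split_row(line)
        if len(fields) < n_cols:
            raise FormatError(
                f"expected at least {n_cols} columns, got {len(fields)}", lineno
            )
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"non-integer coordinate: {exc}", lineno) from None
        extra = fields[3:n_cols] if n_cols > 3 else []
        by_chrom.setdefault(chrom, []).append((lineno, start, end, extra))
    return by_chrom


def read_partitions(
    path, bin_size_bp: int, chrom_length_bp=None, label: str = ""
) -> dict[str, TadPartition]:
    """Read a 3-column TAD file, split into per-chromosome partitions.

    ``chrom_length_bp`` may be a single int (applied to every chromosome)
    or a ``{chrom: length}`` mapping.
    """
    by_chrom = _parse_interval_file(path, 3)
    out = {}
    for chrom, rows in by_chrom.items():
        if isinstance(chrom_length_bp, dict):
            length = chrom_length_bp.get(chrom)
        else:
            length = chrom_length_bp
        doms = np.array([(s, e) for _, s, e, _ in rows], dtype=np.int64)
        out[chrom] = TadPartition(
            chrom=chrom,
            domains=doms,
            bin_size_bp=bin_size_bp,
            chrom_length_bp=length,
            label=label or os.path.basename(str(path)),
        )
    return out


def read_partition(
    path, bin_size_bp: int, chrom_length_bp=None, label: str = ""
) -> TadPartition:
    """Read a single-chromosome TAD partition (error on multi-chromosome files)."""
    parts = read_partitions(path, bin_size_bp, chrom_length_bp, label)
    if len(parts) > 1:
        raise FormatError(
            f"file contains {len(parts)} chromosomes "
            f"({sorted(parts)}); use read_partitions()"
        )
    if not parts:
        return TadPartition(
            chrom="",
            domains=np.empty((0, 2), dtype=np.int64),
            bin_size_bp=bin_size_bp,
            chrom_length_bp=None
            if isinstance(chrom_length_bp, dict)
            else chrom_length_bp,
            label=label or os.path.basename(str(path)),
        )
    return next(iter(parts.values()))


def write_partition(p: TadPartition, path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for s, e in p.domains:
            fh.write(f"{p.chrom}{sep}{s}{sep}{e}\n")


def read_peaks(path, chrom: str | None = None, label: str = "") -> PeakSet:
    """Read a BED file of peaks (0-based half-open), converting to 1-based
    closed.  With ``chrom`` only that chromosome is kept; otherwise the file
    must contain a single chromosome."""
    by_chrom = _parse_interval_file(path, 3)
    if chrom is not None:
        rows = by_chrom.get(chrom, [])
        name = chrom
    else:
        if len(by_chrom) > 1:
            raise FormatError(
                f"BED file spans {len(by_chrom)} chromosomes; pass chrom="
            )
        name = next(iter(by_chrom)) if by_chrom else ""
        rows = by_chrom.get(name, [])
    peaks = []
    for lineno, s, e, _ in rows:
        if e <= s:
            raise FormatError(f"BED end {e} <= start {s}", lineno)
        peaks.append((s + 1, e))
    return PeakSet(
        chrom=name,
        peaks=np.array(peaks, dtype=np.int64).reshape(-1, 2),
        label=label or os.path.basename(str(path)),
    )


def write_peaks(p: PeakSet, path) -> None:
    """Write peaks as BED (converting back to 0-based half-open)."""
    with open(path, "w") as fh:
        for s, e in p.peaks:
            fh.write(f"{p.chrom}\t{s - 1}\t{e}\n")


def read_bedgraph(path, chrom: str | None = None, label: str = "") -> SignalTrack:
    """Read a bedGraph signal track (0-based half-open) to 1-based closed."""
    by_chrom = _parse_interval_file(path, 4)
    if chrom is not None:
        rows = by_chrom.get(chrom, [])
        name = chrom
    else:
        if len(by_chrom) > 1:
            raise FormatError(
                f"bedGraph spans {len(by_chrom)} chromosomes; pass chrom="
            )
        name = next(iter(by_chrom)) if by_chrom else ""
        rows = by_chrom.get(name, [])
    ivs, vals = [], []
    for lineno, s, e, extra in rows:
        if e <= s:
            raise FormatError(f"bedGraph end {e} <= start {s}", lineno)
        try:
            v = float(extra[0])
        except (ValueError, IndexError):
            raise FormatError("missing or non-numeric value column", lineno) from None
        ivs.append((s + 1, e))
        vals.append(v)
    return SignalTrack(
        chrom=name,
        intervals=np.array(ivs, dtype=np.int64).reshape(-1, 2),
        values=np.array(vals, dtype=float),
        label=label or os.path.basename(str(path)),
    )


def write_bedgraph(t: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for (s, e), v in zip(t.intervals, t.values):
            fh.write(f"{t.chrom}\t{s - 1}\t{e}\t{v:g}\n")


_TRIPLET_HEADER = "#tadconcord-triplets"


def write_triplets(m: ContactMatrix, path) -> None:
    coo = sp.coo_matrix(m.data)
    with open(path, "w") as fh:
        fh.write(
            f"{_TRIPLET_HEADER}\tchrom={m.chrom}\tbin_size={m.bin_size_bp}"
            f"\tn_bins={m.n_bins}\tnormalized={int(m.normalized)}\n"
        )
        for i, j, c in zip(coo.row, coo.col, coo.data):
            if float(c) == int(c):
                fh.write(f"{i}\t{j}\t{int(c)}\n")
            else:
                fh.write(f"{i}\t{j}\t{float(c)!r}\n")


def read_triplets(path) -> ContactMatrix:
    """Read a sparse upper-triangle triplet matrix written by
    :func:`write_triplets`."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith(_TRIPLET_HEADER):
            raise FormatError("missing triplet header line", 1)
        fields = dict(
            kv.split("=", 1) for kv in header.split("\t")[1:] if "=" in kv
        )
        try:
            chrom = fields["chrom"]
            bin_size = int(fields["bin_size"])
            n_bins = int(fields["n_bins"])
        except (KeyError, ValueError):
            raise FormatError("header must carry chrom, bin_size, n_bins", 1) from None
        normalized = bool(int(fields.get("normalized", "0")))
        rows, cols, vals = [], [], []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"expected 3 columns, got {len(parts)}", lineno)
            try:
                i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise FormatError(str(exc), lineno) from None
            if c < 0:
                raise FormatError(f"negative count {c}", lineno)
            if i > j:
                i, j = j, i
            rows.append(i)
            cols.append(j)
            vals.append(c)
    data = sp.coo_matrix(
        (vals, (rows, cols)), shape=(n_bins, n_bins)
    )
    return ContactMatrix(
        chrom=chrom,
        bin_size_bp=bin_size,
        n_bins=n_bins,
        data=data,
        normalized=normalized,
    )


def read_cool(path, chrom: str | None = None) -> ContactMatrix:
    """Import one chromosome from a single-resolution .cool container.

    Only the intra-chromosomal upper triangle is kept; counts are read from
    ``pixels/count``.
    """
    with h5py.File(path, "r") as h5:
        chrom_names = [
            c.decode() if isinstance(c, bytes) else str(c)
            for c in h5["chroms/name"][:]
        ]
        if chrom is None:
            if len(chrom_names) > 1:
                raise FormatError(
                    f".cool file has {len(chrom_names)} chromosomes; pass chrom="
                )
            chrom = chrom_names[0]
        if chrom not in chrom_names:
            raise FormatError(f"chromosome {chrom!r} not in {chrom_names}")
        cid = chrom_names.index(chrom)
        bin_chrom = h5["bins/chrom"][:]
        bin_ids = np.nonzero(bin_chrom == cid)[0]
        if bin_ids.size == 0:
            raise FormatError(f"no bins for chromosome {chrom!r}")
        lo, hi = int(bin_ids[0]), int(bin_ids[-1]) + 1
        starts = h5["bins/start"][lo:hi]
        bin_size = int(h5.attrs.get("bin-size", starts[1] - starts[0] if len(starts) > 1 else 0))
        if bin_size <= 0:
            raise FormatError("could not determine bin size from .cool file")
        b1 = h5["pixels/bin1_id"][:]
        b2 = h5["pixels/bin2_id"][:]
        counts = h5["pixels/count"][:]
        keep = (b1 >= lo) & (b1 < hi) & (b2 >= lo) & (b2 < hi)
        n = hi - lo
        data = sp.coo_matrix(
            (counts[keep].astype(float), (b1[keep] - lo, b2[keep] - lo)),
            shape=(n, n),
        )
    return ContactMatrix(chrom=chrom, bin_size_bp=bin_size, n_bins=n, data=data)
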