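"""Hi-C matrix preprocessing: resolution selection, subsampling, and the two
normalization strategies applied before TAD calling.

Resolution follows the map-resolution convention: the smallest bin size such
that at least 80% of bins accumulate at least 1000 contacts.  Normalization
is either ICE (iterative correction: equal-visibility matrix balancing) or
LGF (a HiCNorm-style log-linear Poisson regression on local genomic
features — restriction fragment length, GC content, and mappability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import statsmodels.api as sm

from .core import BinCovariates, ContactMatrix, ValidationError

__all__ = [
    "aggregate_bins",
    "resolution_for",
    "subsample",
    "ice_normalize",
    "lgf_normalize",
    "IceResult",
]


def aggregate_bins(contacts: ContactMatrix, bin_size_bp: int) -> ContactMatrix:
    """Re-bin a contact matrix to a coarser resolution (an exact multiple
    of the current bin size)."""
    factor, rem = divmod(int(bin_size_bp), contacts.bin_size_bp)
    if rem or factor < 1:
        raise ValidationError(
            f"target bin size {bin_size_bp} is not a multiple of "
            f"{contacts.bin_size_bp}"
        )
    if factor == 1:
        return contacts
    n_new = -(-contacts.n_bins // factor)  # ceil
    coo = sp.coo_matrix(contacts.data)
    i, j = coo.row // factor, coo.col // factor
    data = sp.coo_matrix((coo.data, (i, j)), shape=(n_new, n_new))
    data.sum_duplicates()
    return ContactMatrix(
        chrom=contacts.chrom,
        bin_size_bp=int(bin_size_bp),
        n_bins=n_new,
        data=data,
        normalized=contacts.normalized,
        meta=dict(contacts.meta),
    )


def resolution_for(
    contacts: ContactMatrix,
    candidate_bins,
    min_contacts: int = 1000,
    min_fraction: float = 0.8,
    exclude_bins=None,
) -> int | None:
    """Smallest candidate bin size at which >= ``min_fraction`` of bins make
    >= ``min_contacts`` contacts; ``None`` when no candidate qualifies.

    All bins in the chromosome span count toward the denominator, except an
    optional ``exclude_bins`` list of base-resolution bin indices (e.g.
    unmappable regions).
    """
    candidates = sorted(int(b) for b in candidate_bins)
    if not candidates:
        raise ValidationError("candidate_bins must be non-empty")
    excluded = np.asarray(exclude_bins, dtype=np.int64) if exclude_bins is not None else None
    for b in candidates:
        agg = aggregate_bins(contacts, b)
        marg = agg.marginals()
        keep = np.ones(agg.n_bins, dtype=bool)
        if excluded is not None and excluded.size:
            keep[np.unique(excluded * contacts.bin_size_bp // b)] = False
        frac = float((marg[keep] >= min_contacts).mean()) if keep.any() else 0.0
        if frac >= min_fraction:
            return b
    return None


def subsample(contacts: ContactMatrix, fraction: float, seed: int) -> ContactMatrix:
    """Binomially thin each matrix entry, keeping every contact independently
    with probability ``fraction``.  Deterministic given ``seed``."""
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must lie in (0, 1], got {fraction}")
    coo = sp.coo_matrix(contacts.data)
    counts = coo.data
    if counts.size and not np.allclose(counts, np.round(counts)):
        raise ValidationError("subsample requires integer counts")
    if fraction == 1.0:
        return contacts
    rng = np.random.default_rng(seed)
    kept = rng.binomial(counts.astype(np.int64), fraction) if counts.size else counts
    data = sp.coo_matrix((kept, (coo.row, coo.col)), shape=coo.shape)
    data.eliminate_zeros()
    return ContactMatrix(
        chrom=contacts.chrom,
        bin_size_bp=contacts.bin_size_bp,
        n_bins=contacts.n_bins,
        data=data,
        normalized=contacts.normalized,
        meta={**contacts.meta, "subsample_fraction": fraction, "subsample_seed": seed},
    )


@dataclass
class IceResult:
    """Balanced matrix plus the multiplicative bias vector.

    ``normalized.data[i, j] == raw[i, j] / (bias[i] * bias[j])``; masked
    (zero-marginal) bins carry NaN biases.
    """

    normalized: ContactMatrix
    bias: np.ndarray
    n_iter: int
    converged: bool
    masked_bins: np.ndarray


def ice_normalize(
    contacts: ContactMatrix, max_iter: int = 1000, tol: float = 1e-12
) -> IceResult:
    """Iterative correction: repeatedly divide each row by its mean marginal
    until the variance of the log bias update is below ``tol``.

    Bins with zero marginal contacts are masked.  The output is rescaled so
    the total number of (stored) contacts equals the input total.  The
    residual row-sum spread at stop is of the order of the bias-update
    spread, sqrt(tol), so the default leaves the unmasked row sums equal to
    well below one part in 1e4.
    """
    raw_total = contacts.total_reads
    if raw_total <= 0:
        raise ValidationError("cannot ICE-normalize an all-zero matrix")
    W = contacts.full().astype(float)
    marg = np.asarray(W.sum(axis=1)).ravel()
    masked = marg == 0
    active = ~masked
    bias = np.ones(contacts.n_bins)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        marg = np.asarray(W.sum(axis=1)).ravel()
        s = np.ones_like(marg)
        s[active] = marg[active] / marg[active].mean()
        bias *= s
        inv = sp.diags(1.0 / s)
        W = inv @ W @ inv
        if np.var(np.log(s[active])) < tol:
            converged = True
            break
    # preserve the raw total so normalized counts stay on the input scale
    upper = sp.triu(W).tocoo()
    scale = raw_total / upper.data.sum()
    upper.data *= scale
    bias = bias / np.sqrt(scale)
    bias[masked] = np.nan
    norm = ContactMatrix(
        chrom=contacts.chrom,
        bin_size_bp=contacts.bin_size_bp,
        n_bins=contacts.n_bins,
        data=upper,
        normalized=True,
        meta={**contacts.meta, "normalization": "ice", "ice_iterations": it},
    )
    return IceResult(
        normalized=norm,
        bias=bias,
        n_iter=it,
        converged=converged,
        masked_bins=np.nonzero(masked)[0],
    )


def _lgf_design(cov: BinCovariates, active: np.ndarray, on_degenerate: str):
    """Pairwise design over active-bin pairs i < j: log-products of fragment
    length and GC as regressors, log-product of mappability as offset."""
    idx = np.nonzero(active)[0]
    ii, jj = np.triu_indices(len(idx), k=1)
    bi, bj = idx[ii], idx[jj]
    cols, names = [], []
    for name, v in (("fragment_length", cov.fragment_length), ("gc_content", cov.gc_content)):
        x = np.log(v[bi] * v[bj])
        if np.ptp(x) < 1e-12:
            if on_degenerate == "raise":
                raise ValidationError(
                    f"covariate {name!r} has zero variance across bins"
                )
            continue  # intercept absorbs a constant covariate
        cols.append(x)
        names.append(name)
    offset = np.log(cov.mappability[bi] * cov.mappability[bj])
    X = sm.add_constant(
        np.column_stack(cols) if cols else np.empty((len(bi), 0)), has_constant="add"
    )
    return bi, bj, X, names, offset


def lgf_normalize(
    contacts: ContactMatrix,
    covariates: BinCovariates,
    residual: str = "ratio",
    on_degenerate: str = "drop",
):
    """HiCNorm-style local-genomic-feature normalization.

    Fits ``count_ij ~ Poisson(exp(b0 + b_len*log(len_i*len_j) +
    b_gc*log(gc_i*gc_j)) * map_i*map_j)`` over all off-diagonal upper-triangle
    bin pairs and returns the residual matrix: observed/fitted by default
    (``residual="ratio"``) or Pearson residuals (``residual="pearson"``,
    which can be negative and is returned dense).

    Bins with zero mappability are masked.  Constant covariates are dropped
    from the design (``on_degenerate="drop"``) or rejected
    (``on_degenerate="raise"``).
    """
    if residual not in ("ratio", "pearson"):
        raise ValidationError("residual must be 'ratio' or 'pearson'")
    if covariates.n_bins != contacts.n_bins:
        raise ValidationError(
            f"covariates cover {covariates.n_bins} bins, matrix has {contacts.n_bins}"
        )
    if contacts.total_reads <= 0:
        raise ValidationError("cannot LGF-normalize an all-zero matrix")
    active = covariates.mappability > 0
    if active.sum() < 3:
        raise ValidationError("fewer than 3 bins with positive mappability")
    dense = contacts.to_dense()
    bi, bj, X, names, offset = _lgf_design(covariates, active, on_degenerate)
    y = dense[bi, bj]
    if not np.allclose(y, np.round(y)):
        raise ValidationError("LGF normalization requires integer counts")
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    fit = model.fit()
    mu = fit.fittedvalues
    n = contacts.n_bins
    if residual == "ratio":
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(mu > 0, y / mu, 0.0)
        out = sp.coo_matrix((r[r != 0], (bi[r != 0], bj[r != 0])), shape=(n, n))
        data = out
    else:
        r = np.where(mu > 0, (y - mu) / np.sqrt(mu), 0.0)
        full = np.zeros((n, n))
        full[bi, bj] = r
        data = sp.coo_matrix(np.triu(full))
    norm = ContactMatrix(
        chrom=contacts.chrom,
        bin_size_bp=contacts.bin_size_bp,
        n_bins=n,
        data=data,
        normalized=True,
        meta=_lgf_meta(contacts, fit, names, residual),
    )
    return norm, fit.params


def _lgf_meta(contacts, fit, names, residual):
    return {
        **contacts.meta,
        "normalization": "lgf",
        "lgf_residual": residual,
        "lgf_covariates": names,
        "lgf_coefficients": np.asarray(fit.params).tolist(),
    }
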