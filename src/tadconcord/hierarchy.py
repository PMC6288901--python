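"""Nesting-level extraction from nested/overlapping domain sets.

Some callers emit hierarchies: domains nested inside larger domains.  Level
1 (the lowest level) is the set of domains that contain no other domain;
each domain at level i must contain at least one domain present at level
i - 1 (equivalently, a domain's level is the length of the longest
containment chain below it).  Exact duplicates of an already-kept domain are
discarded, as are domains that partially overlap a kept domain (neither
nested nor disjoint — only perfectly laminar structure is levelled), and
levels with fewer than ``min_domains`` domains are flagged out of downstream
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DomainSet, TadPartition, ValidationError

__all__ = ["extract_levels", "HierarchyLevels", "level_summaries"]


@dataclass
class HierarchyLevels:
    """Result of nesting-level extraction."""

    chrom: str
    bin_size_bp: int
    level_domains: list  # level i -> (k, 2) array, index 0 = level 1
    retained: list  # bool per level (>= min_domains)
    discarded: dict = field(default_factory=dict)
    min_domains: int = 10

    @property
    def n_levels(self) -> int:
        return len(self.level_domains)

    @property
    def retained_levels(self) -> list[int]:
        """1-based indices of levels large enough for downstream summaries."""
        return [i + 1 for i, keep in enumerate(self.retained) if keep]

    def as_partition(self, level: int, chrom_length_bp=None) -> TadPartition:
        """Domains of one level as a TadPartition (levels are laminar, so
        same-level domains are disjoint)."""
        if not 1 <= level <= self.n_levels:
            raise ValidationError(f"level {level} out of range 1..{self.n_levels}")
        return TadPartition(
            chrom=self.chrom,
            domains=self.level_domains[level - 1],
            bin_size_bp=self.bin_size_bp,
            chrom_length_bp=chrom_length_bp,
            label=f"level{level}",
        )

    def assigned_domains(self) -> np.ndarray:
        parts = [d for d in self.level_domains if len(d)]
        return (
            np.concatenate(parts, axis=0)
            if parts
            else np.empty((0, 2), dtype=np.int64)
        )


def _contains(outer, inner) -> bool:
    """Containment with equality allowed on at most one endpoint."""
    s1, e1 = outer
    s2, e2 = inner
    return s1 <= s2 and e2 <= e1 and not (s1 == s2 and e1 == e2)


def extract_levels(d: DomainSet, min_domains: int = 10) -> HierarchyLevels:
    """Assign nesting levels to a laminar domain family.

    Exact duplicates keep their first occurrence; domains partially
    overlapping an already-kept domain are discarded; levels are containment
    depths (level 1 = innermost).  Levels with fewer than ``min_domains``
    domains are reported but flagged as not retained.
    """
    doms = d.domains
    empty = np.empty((0, 2), dtype=np.int64)
    if len(doms) == 0:
        return HierarchyLevels(
            chrom=d.chrom,
            bin_size_bp=d.bin_size_bp,
            level_domains=[],
            retained=[],
            discarded={"coincident": empty, "partial_overlap": empty},
            min_domains=min_domains,
        )
    kept: list[tuple[int, int]] = []
    coincident, partial = [], []
    seen = set()
    for s, e in doms:
        key = (int(s), int(e))
        if key in seen:
            coincident.append(key)
            continue
        ok = True
        for ks, ke in kept:
            if e < ks or s > ke:  # disjoint
                continue
            if (ks <= s and e <= ke) or (s <= ks and ke <= e):  # nested
                continue
            ok = False
            break
        if ok:
            kept.append(key)
            seen.add(key)
        else:
            partial.append(key)
    kept_arr = np.array(kept, dtype=np.int64).reshape(-1, 2)
    # containment depth by dynamic programming over domains sorted by length
    n = len(kept_arr)
    lengths = kept_arr[:, 1] - kept_arr[:, 0]
    order = np.argsort(lengths, kind="stable")
    level = np.zeros(n, dtype=np.int64)
    for pos, i in enumerate(order):
        lvl = 1
        for j in order[:pos]:
            if _contains(kept_arr[i], kept_arr[j]):
                lvl = max(lvl, int(level[j]) + 1)
        level[i] = lvl
    n_levels = int(level.max()) if n else 0
    level_domains = []
    for lv in range(1, n_levels + 1):
        sel = kept_arr[level == lv]
        level_domains.append(sel[np.argsort(sel[:, 0])])
    retained = [len(ld) >= min_domains for ld in level_domains]
    return HierarchyLevels(
        chrom=d.chrom,
        bin_size_bp=d.bin_size_bp,
        level_domains=level_domains,
        retained=retained,
        discarded={
            "coincident": np.array(coincident, dtype=np.int64).reshape(-1, 2),
            "partial_overlap": np.array(partial, dtype=np.int64).reshape(-1, 2),
        },
        min_domains=min_domains,
    )


def level_summaries(
    h: HierarchyLevels,
    peaks=None,
    sig27=None,
    sig36=None,
    chrom_length_bp: int | None = None,
    seed: int = 0,
    n_shuffles: int = 10,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Per-level domain counts, mean sizes and (optionally) CTCF fold change
    and LR-significant fraction, for retained levels only."""
    from .feature_enrichment import boundary_fold_change, histone_lr_significance

    rows = []
    for lv in h.retained_levels:
        part = h.as_partition(lv, chrom_length_bp)
        row = {
            "level": lv,
            "n_domains": part.n_domains,
            "mean_size_bp": part.mean_size_bp(),
        }
        if peaks is not None:
            row["fold_change"] = boundary_fold_change(
                part, peaks, chrom_length_bp
            ).fold_change
        if sig27 is not None and sig36 is not None:
            row["lr_fraction_significant"] = histone_lr_significance(
                part, sig27, sig36, n_shuffles=n_shuffles, seed=seed, fdr=fdr
            ).fraction_significant
        rows.append(row)
    return pd.DataFrame(rows)
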