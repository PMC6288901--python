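"""Shared fixtures and random-instance generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from tadconcord import TadPartition


def random_partition(
    rng: np.random.Generator,
    n_bins: int = 100,
    bin_size_bp: int = 10_000,
    max_domains: int = 12,
    gap_prob: float = 0.2,
    chrom: str = "chrT",
) -> TadPartition:
    """Random bin-aligned partition, possibly with inter-TAD gaps."""
    n_dom = int(rng.integers(1, max_domains + 1))
    n_edges = min(n_dom, n_bins)
    interior = np.sort(
        rng.choice(np.arange(1, n_bins), size=max(0, n_edges - 1), replace=False)
    )
    edges = np.concatenate([[0], interior, [n_bins]])
    domains = []
    for s, e in zip(edges[:-1], edges[1:]):
        if rng.random() < gap_prob:  # leave this stretch as an inter-TAD gap
            continue
        domains.append((int(s) * bin_size_bp + 1, int(e) * bin_size_bp))
    if not domains:  # guarantee at least one domain
        domains = [(int(edges[0]) * bin_size_bp + 1, int(edges[1]) * bin_size_bp)]
    return TadPartition(
        chrom=chrom,
        domains=np.array(domains, dtype=np.int64),
        bin_size_bp=bin_size_bp,
        chrom_length_bp=n_bins * bin_size_bp,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
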