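# tadconcord

Tools for evaluating and comparing **topologically associating domain (TAD)
callers** on Hi-C data: concordance metrics between domain partitions,
biological-feature enrichment statistics at boundaries and within domains,
hierarchy-level extraction, and the Hi-C preprocessing steps that come
before TAD calling (map-resolution selection, read subsampling, ICE and
local-genomic-feature normalization).  A seeded synthetic-data generator
with planted structure makes every analysis testable end to end without any
downloads.

It is written for computational biologists who need to decide which TAD
caller to trust, to quantify how stable a caller's output is across
normalizations, bin sizes and sequencing depths, or to check whether a
partition carries the biological signatures expected of real TADs (CTCF and
cohesin at boundaries, mutually exclusive H3K27me3/H3K36me3 inside domains).

## The core metric

Two TAD partitions *P* and *Q* of the same chromosome are compared with the
**Measure of Concordance (MoC)**, treating base pairs as the clustered
elements and TADs *plus inter-TAD gaps* as the clusters:

```
MoC(P, Q) = 1                                                if N_P = N_Q = 1
          = (Σ_i Σ_j ‖F_ij‖² / (‖P_i‖·‖Q_j‖) − 1) / (√(N_P·N_Q) − 1)  otherwise
```

where `‖P_i‖`, `‖Q_j‖` are cluster sizes in bp and `‖F_ij‖` is the overlap
between clusters `P_i` and `Q_j`.  MoC is symmetric and ranges from 0 (no
concordance) to 1 (identical partitions).

Around it sit the complementary statistics used to benchmark callers:

* **boundary / TAD conservation** within a tolerance radius in bins, plus a
  cross-resolution rule (a coarse boundary is confirmed when a fine-bin
  boundary falls inside its boundary bin);
* **shared boundaries** across many callers (single-linkage consolidation,
  caller-support histograms, conservation ratios, TAD-size scaling);
* **structural-protein enrichment**: peak profiles in 5-kb intervals within
  ±500 kb of boundaries, boundary-vs-flank fold change, tagged fractions,
  shared-vs-private boundary enrichment;
* **histone-mark bias**: per-interval `log10(H3K27me3/H3K36me3)` ratios,
  within-TAD means tested against a shuffle null with Benjamini–Hochberg
  FDR;
* **hierarchy levels**: nesting depth extraction from nested/overlapping
  domain sets with per-level summaries;
* **Hi-C preprocessing**: the 80%-of-bins/1000-contacts map-resolution
  rule, binomial read subsampling, ICE matrix balancing and HiCNorm-style
  Poisson-regression (LGF) normalization.

## Worked example

```python
import tadconcord as tc

cfg = tc.SimulationConfig(chrom_length_bp=30_000_000, bin_size_bp=10_000, seed=7)
sim = tc.simulate_partition(cfg)          # planted truth
truth = sim.partition
rival = tc.perturb_partition(truth, jitter_bins=2, split_prob=0.1, seed=7)

print(truth.n_domains)                                   # 68 TADs, mean 441 kb
print(round(tc.moc(truth, rival), 3))                    # 0.895
print(tc.conserved_boundaries(truth, rival, 2).fraction_a)  # 1.0

peaks = tc.simulate_peaks(cfg, sim)       # CTCF-like, boundary enriched
fc = tc.boundary_fold_change(truth, peaks, cfg.chrom_length_bp)
print(round(fc.fold_change, 2))                          # 2.28
print(round(tc.tagged_fraction(truth, peaks), 3))        # 0.87

t27, t36 = tc.simulate_marks(cfg, sim)    # mutually exclusive mark tracks
lr = tc.histone_lr_significance(truth, t27, t36, seed=7)
print(lr.interval_size_bp, round(lr.fraction_significant, 3))  # 40000 0.471
```

Reading the output: jittering every boundary by up to 2 bins leaves the
partitions highly concordant (MoC 0.895) and every boundary is recovered at
a 2-bin tolerance.  The planted boundary peaks show a 2.28-fold density
excess over distal flanks and tag 87% of boundaries.  With half of the TADs
carrying a dominant mark (the generator default `phi=0.5`), 47% of TADs
reach a significant log-ratio bias at FDR < 0.1.

The same operations are available from the shell:

```bash
tadconcord simulate --out-dir sim --seed 7 --chrom-length 30000000 --bin-size 10000
tadconcord moc sim/tads.txt sim/tads.txt --bin-size 10000
tadconcord enrich-peaks sim/tads.txt sim/peaks.bed --bin-size 10000
tadconcord normalize contacts.txt iced.txt --method ice
```

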