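# Methods

This note documents the statistical procedures implemented in `tadconcord`,
the conventions and defaults they rely on, what the synthetic-data
generator does and does not emulate, and the design decisions taken where a
procedure admits more than one reasonable reading.

## Coordinates and boundaries

All intervals are 1-based and closed internally; a partition at bin size
*b* has starts at `k·b + 1` and ends at `k·b`.  BED and bedGraph inputs
(0-based, half-open) are converted on read and back on write.

A TAD contributes two boundary records, the bin indices of its start and
end bins.  For de-duplicated boundary sets the toolkit works with
**junction (edge) indices**: the point between bins `k−1` and `k`, at
base-pair position `k·b`.  The junction shared by a domain ending at bin
`e` and the next starting at bin `e+1` is then naturally a single boundary,
and identical positions across domains collapse — so two adjacent one-bin
domains yield three unique boundaries (chromosome-side edge, shared
junction, terminal edge).  Distances between boundaries are measured in
bins and are identical under bin- or edge-indexing; a tolerance radius of
5 bins on a 10-kb matrix means ±50 kb.

Chromosome length is optional on every container.  When absent, span-
dependent quantities (gaps, MoC harmonization, window clipping) use the
last domain end.

## Measure of Concordance

`moc(P, Q)` treats base pairs as clustered elements.  Because many callers
leave inter-TAD regions uncalled, gaps are counted as clusters by default
(`gaps_as_clusters=True`); when the two partitions cover different spans,
the union span is used and the deficient side gains a terminal gap cluster,
so both clusterings cover the same element set.  The double sum is
evaluated with a linear two-pointer sweep over the two sorted cluster
lists.

Numerical note: the sum accumulates rounding of order machine epsilon, so
the result is clamped to [0, 1] and snapped to a bound when within 1e-12 —
the formula-forced values (1 for identical partitions, 0 for one cluster
versus many, where the inner sum telescopes to 1) are therefore returned
exactly.  When exactly one side has a single cluster the general branch
applies (not the `N_P = N_Q = 1` special case) and yields 0.

## Conservation statistics

*Same resolution.*  A boundary of `P` is conserved in `Q` when some
boundary of `Q` lies within `radius_bins` bins.  Fractions are reported for
both directions; the counts are asymmetric for radius > 0.  A TAD is
conserved when its start and end both match, within the radius, the start
and end of **one single** TAD on the other side — a TAD whose two
boundaries match two different TADs is not conserved.  (If several TADs
each match both boundaries at a radius > 0, the TAD counts as conserved;
the requirement is that one TAD accounts for both ends.)

*Cross resolution.*  A boundary found at the bigger bin size is conserved
when at least one fine-resolution boundary falls inside the genomic
interval of its boundary bin, interval edges included.  Start and end
records keep their own boundary bins, so the rule is side-aware.

*Shared boundaries.*  Boundaries of all callers are consolidated by
single-linkage clustering: consecutive sorted edges link when their gap is
at most the radius (complete linkage, capping the cluster diameter, is
available as an option).  Each cluster reports the number of distinct
supporting callers; the per-caller split into "shared" (≥ *k* callers) and
"not shared" classes reuses these clusters with their mean positions as
representatives.

*Conservation ratio.*  Conserved TADs of `P` (with respect to `Q`) divided
by `min(N_P, N_Q)`, the maximum attainable number of conserved TADs.  The
p-side count makes the ratio mildly asymmetric at radius > 0.

## Structural-protein enrichment

The structural protein profile (SPP) counts peak **midpoints** per 5-kb
interval across a ±500-kb window centred on each boundary (midpoint
assignment avoids double counting a peak spanning two intervals).
Boundaries closer than 500 kb to either chromosome end are dropped and
counted, since truncated windows would bias the flanks.

The boundary fold change is the peak density in the ±10-kb region around
the junction over the density in two 100-kb flanks located 400 kb away,
minus 1 (so 0 = no enrichment).  The headline statistic aggregates counts
across boundaries before taking the ratio ("average-then-ratio"), which is
robust when individual flanks are sparse; the per-boundary
ratio-then-average variant is returned alongside, with NaN for boundaries
whose flanks hold no peaks (these are counted and excluded).  The fold
change is invariant to uniform rescaling of peak density.

A boundary is "tagged" when at least one peak overlaps the ±1-bin region
around the junction (±10 kb at 10-kb bins).

## Histone-mark log-ratio test

For a partition with mean TAD size *m*, the chromosome is cut into
intervals of `floor(0.1·m / b)·b` bp (at least one bin).  Per interval,
`LR = log10((mean s27 + ε27)/(mean s36 + ε36))`; the pseudocounts default
to 1% of each track's global mean (configurable).  A TAD's observed
statistic is the mean LR over the intervals whose midpoints fall inside it.

The null is built by permuting the interval LR values across interval
positions (10 shuffles by default) and recomputing the within-TAD means.
The empirical p-value is two-sided around the chromosome-wide mean LR
(significant = high *or* low) with a +1 correction:

* `null="pooled"` (default): a TAD's observed deviation is compared
  against the single pooled distribution of all randomized within-TAD
  means (all TADs × all shuffles).  With *n* TADs this yields a p-value
  granularity of 1/(10·n+1), which is what makes intermediate significant
  fractions observable at FDR 0.1 with only 10 shuffles.
* `null="per_tad"`: each TAD is compared against its own 10 shuffle
  values, minimum p = 1/11.  With Benjamini–Hochberg at 0.1 this variant
  is effectively all-or-nothing (the smallest achievable q is
  `(1/11)·n/m` over the m TADs at minimum p) and is provided for
  completeness.

p-values are BH-adjusted across TADs and the reported headline number is
the fraction of TADs with q < 0.1.  Tracks must cover every interval; gaps
raise an error that names the `gap_policy="zero"` zero-fill alternative,
so the choice is always explicit.

## Hierarchy levels

Level 1 is the set of domains containing no other domain; a domain's level
is the length of the longest containment chain below it (equivalently:
each level-i domain contains at least one level-(i−1) domain; a domain
containing domains from several lower levels lands one above the deepest).
Containment allows equality on at most one endpoint; exact duplicates keep
their first occurrence and later copies are discarded.  Domains that
partially overlap an already-kept domain (neither nested nor disjoint) are
never assigned a level — only perfectly laminar structure is levelled —
and are reported in `discarded`, so assigned + discarded always equals the
input.  Levels with fewer than `min_domains` (default 10) domains are
reported but flagged out of downstream summaries.

## Hi-C preprocessing

*Map resolution.*  The smallest candidate bin size at which ≥ 80% of bins
make ≥ 1000 contacts.  "Bins" means all bins in the chromosome span at
that bin size (an exclusion list is accepted for, e.g., unmappable
regions), and a bin's contacts are its full row sum with the diagonal
counted once.  Qualification is monotone in bin size because aggregation
only adds marginals.

*Subsampling.*  Binomial thinning of binned counts: each contact is kept
independently with probability `fraction`, which matches subsampling the
read list before binning in distribution, entry by entry.  Deterministic
under the seed.

*ICE.*  Iterative correction assuming equal bin visibility: each round
divides the matrix by the outer product of the normalized marginals and
multiplies the bias vector accordingly; zero-marginal bins are masked.
The stopping statistic is the variance of the log bias update; the default
tolerance 1e-12 leaves the unmasked row sums equal to well below one part
in 1e4 even on slowly converging zero-diagonal matrices (the residual
row-sum spread at stop is of the order of the update spread, √tol).  The
output is rescaled to preserve the raw contact total, and
`normalized(i,j)·bias_i·bias_j = raw(i,j)` holds exactly.

*LGF.*  A log-linear Poisson regression of off-diagonal pair counts on
`log(len_i·len_j)` and `log(gc_i·gc_j)` with `log(map_i·map_j)` as offset,
fitted by IRLS (statsmodels GLM).  The normalized matrix holds the
residuals as observed/fitted ratios by default; Pearson residuals
`(y−μ)/√μ` are available and recorded in the output metadata.  Covariates
with zero variance are dropped from the design (the intercept absorbs
them), so identical covariates reduce to an intercept-only fit and the
output is proportional to the input; a strict mode rejects them instead.
Bins with zero mappability are masked.

## Synthetic data

The generator plants exactly the structure the analyses assume, at the
scales of deeply sequenced human Hi-C:

* **Partitions** tile the chromosome with log-normal domain sizes (default
  mean 500 kb, σ_log 0.5, clipped to 100 kb–5 Mb, 10-kb bins).  Laminar
  hierarchies are built top-down, each parent split into ≥ 2 children so
  every parent strictly contains its children; means scale ×3 per level.
* **Contacts**: expected count ∝ `(1+|i−j|)^(−α) · γ^k` with α = 1,
  γ = 2 and k the number of planted domains (across levels) containing
  both bins, scaled to the configured depth and drawn Poisson.
* **Peaks**: a uniform Poisson background (default 1 peak per 50 kb,
  300-bp peaks) plus extra peaks at ρ× the background rate within ±1 bin
  of each interior boundary (default ρ = 3).
* **Marks**: a fraction φ of TADs (default 0.5) gets a dominant mark
  chosen 50/50 (means 4.0 vs 0.25; balanced TADs sit at 1.0) with
  log-normal per-bin noise (σ = 0.3).

All generators are deterministic under their seed.  What the generator
does **not** emulate: restriction-fragment structure, trans contacts,
unmappable regions, copy-number variation, peak-width variation, replicate
structure, or correlated noise along the genome.  Passing tests therefore
demonstrate correctness of the statistical machinery on idealized inputs
with known truth, not robustness to every artefact of real Hi-C or
ChIP-seq data.

## Test and verification scales

The statistical test-bed uses problem sizes chosen to give each check real
power while keeping the suite fast: boundary-enrichment calibration uses
1000 boundaries spaced 2 Mb apart (so the ±400–500-kb flanks of one
boundary never touch a neighbouring boundary's planted peaks) with a
2e-4/bp background; the planted-recovery case uses ρ = 2, i.e. a total
boundary rate of 3× background and an expected fold change of 2.  FDR
calibration runs 100 null replicates (20-Mb chromosome, 50-kb bins,
~40 TADs each) and the power check 10 replicates at φ = 1.  ICE balancing
is exercised on random positive matrices up to n = 200, and all
conservation and hierarchy operations are validated against quadratic
brute-force oracles on randomly generated instances.

## Known limitations

* MoC compares single chromosomes; genome-wide summaries are left to the
  caller (compute per chromosome and aggregate).
* The LGF fit materializes all upper-triangle bin pairs; for very large
  matrices (n ≫ 2000 bins) memory grows quadratically.
* `conserved_tads` counts a TAD as conserved when one partner TAD matches
  both ends within the radius; at large radii several partners may
  qualify and the rule does not disambiguate further.
* Hierarchy extraction discards partially overlapping domains rather than
  attempting a best-effort laminar repair.
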