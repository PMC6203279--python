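# Methods

This note records the models implemented in `tf3dnet`, the conventions and
numerical choices behind them, what the synthetic data generator does and
does not emulate, and the design decisions taken where the published
procedure left room.

## Coordinates and containers

All intervals are 0-based half-open (BED convention). Peak centers are
`floor((start + end) / 2)`; narrowPeak summit offsets are ignored. Strand
is preserved through I/O but ignored by every co-localization computation.
Contact maps are stored densely and symmetrically per chromosome
(normalized float64, raw int64) with a boolean per-bin validity mask;
structures as an `(n_models, n_particles, 3)` array over an ordered
particle table.

## CCL scores from population Hi-C

For a query locus *i* and partner sites *j* on the same chromosome,
`CCL_i = Σ_j ln(Obs_ij / Exp_ij)`. The expected profile is the empirical
mean of the normalized contact over all unmasked bin pairs at each
separation, zeros included.

Filter cascade and conventions (defaults follow the published thresholds;
all are `CCLConfig` fields):

* **Coverage.** Bins with total raw reads strictly below ⅓ of the
  per-chromosome median (over bins with any reads) are masked everywhere,
  including the expected profile.
* **Diagonal exclusion.** Pairs separated by ≤ 25 kb in bin units (five
  5-kb bins either side of the diagonal) are never consumed.
* **Adaptive merging.** Bin size grows to 25 kb for loci strictly more
  than 100 kb apart and 55 kb beyond 1 Mb. Merged windows are centered on
  each locus's base bin; `Obs` and raw counts are sums over the window
  cross-product, and `Exp` is the sum of base-bin expected values over the
  same separation offsets, so `Obs/Exp` is exactly 1 on a flat map at any
  merge level. Windows that leave the chromosome or touch a masked bin
  invalidate the pair.
* **Read support.** A pair is consumed only when the merged window holds
  strictly more than 20 raw reads. The published text does not say whether
  this applies per base bin-pair or per merged window; the merged window
  is the default (`raw_filter_scope`), with the per-base variant
  available.
* **Degenerate ratios.** Pairs with zero observed or zero expected
  contact contribute nothing and are tallied in a skipped-pair diagnostic
  rather than producing −∞.
* **Log base.** Natural log for homotypic, heterotypic and integrated
  scores alike (the printed equations mix `log_e` and a bare `log`).
* **Query loci.** Homotypic scores are computed at all putative sites by
  default; a config switch restricts to ChIP-identified sites, since the
  published description supports either reading.

The implementation precomputes a dense per-bin-pair `ln(Obs/Exp)` table
via separable sliding-window sums (no summed-area-table cancellation), so
scoring and permutation tests reduce to indexed sums; unit tests verify
exact (1e-12) agreement with per-pair brute-force enumeration.

Rank normalization uses mid-rank fractional ranks `(rank − 0.5)/n`
(average rank for ties) and quantile groups `floor(rank × n_groups)`
clipped to the last group; 100 distinct scores give exactly 10 per decile.

## Permutation nulls, CE and pair calling

For direction A→B, the null permutes the pooled positions of all TFs
except B within each stratum (chromosome by default, sub-compartment ×
chromosome optionally), preserving each TF's per-stratum site count; B
stays fixed. Because a site's score depends only on its contact-map bin,
permutations reduce to relabelling pooled bin indices; all directions
sharing a fixed partner are drawn from one joint pooled permutation (the
exact same null, much cheaper).

Empirical p-values use the smoothed estimator `(1 + b)/(1 + n_perm)`.
These p-values are *discrete* — the statistic is the count of sites above
a pooled-null quantile — and therefore conservative between their atoms;
calibration runs show the fraction of p ≤ 0.05 under the null is ≈ 0.04.
For each of the top 20/10/5% cutoffs, Benjamini–Hochberg correction runs
across all directions separately per fraction; a direction passes (by
default) if any fraction reaches the FDR, and a pair is significant only
when both directions pass. The combination rule over the three fractions
is not specified in the published text; `combine ∈ {any, all,
fraction=0.10}`.

`CE_{A,B}` is a signed KL divergence between observed and pooled-null CCL
histograms on unit-width bins (`k = floor(score)`), natural log, zero
observed mass contributing zero. When an observed bin has no null mass,
every null bin receives one pseudo-observation before normalization (the
divergence is otherwise undefined). The sign is +1 when the observed
median ≥ the null median. Clustering uses
`d(A,B) = exp(−(CE_AB + CE_BA)/2)` (or squared-Euclidean on matrix rows)
under Ward or average linkage. The adaptive cut scans the midpoints
between merge heights and keeps the labelling with the best silhouette
among those whose clusters all reach the minimum size (3); a fixed-k cut
(k = 2) is the fallback. This is a deliberately simple stand-in for the
dynamic-tree algorithm, justified by the reported robustness of the
grouping across clustering variants.

Pair ranking uses the percentage increase of high-CCL sites,
`%Δ = 100 (obs − mean_null)/mean_null`, summed over both directions, ties
broken by the smaller empirical p; a zero null mean ranks first with an
infinite sentinel. Sub-compartment analyses exclude TFs with fewer than
300 ChIP sites in either required stratum (A1/A2 by default; 0 disables).

## Single-cell structure analyses

**Radius.** The deposited coordinate unit is arbitrary, so the particle
radius is estimated per structure as half the median 3D distance between
sequentially adjacent intra-chromosome particles of the first model. This
convention is ours; it matches the generator's constant step of 2 radii
exactly.

**QC.** Models are superposed onto the first model by Kabsch
least-squares; the per-particle RMSD over models (relative to the
reference) must be < 1 radius. A single displacement of 2 radii in one of
ten models gives RMSD ≈ 2/√10 minus an O(1/n_particles) share absorbed by
the refit. Single-model structures pass everything with a warning.

**Consistent proximity.** A particle pair is proximal only if within the
threshold (1.5, 2 or 3 radii) in *every* model, both particles pass QC,
and same-chromosome pairs are more than three particles (300 kb) apart.
`cis`/`trans` modes restrict to intra-/inter-chromosome pairs; trans
analyses should use the 3-radius threshold (smaller ones starve the
counts).

**SDE.** `r_i = Σ_j n_j / d_ij³` over admissible partners, computed per
model and averaged (averaging stabilizes single-model noise; the
published text does not state the aggregation). `n_j` is the weighted
100-kb linear site density. The null circularly rotates the track by an
independent random offset per chromosome, separately within the A and B
compartment classes, 100 times; `SDE_i = log2(r_i⁰ / r_i)` as printed.
The printed orientation conflicts with the prose description of SDE as an
enrichment of the observed density; both are exposed
(`orientation ∈ {as_printed, enrichment}`, default as printed). Z-scores
standardize on the quartile of particles with the lowest sequential
density, whose SDE values behave most like a plain normal.

**PE.** Sites map to the particle containing their center (integer
counts; fractional weights are used only inside `n_j` for SDE).
`PE = log2(Obs/Exp)`: the log base is unstated for PE and chosen to match
the explicitly base-2 SDE. The null relabels sites within chromosome ×
compartment × crowding stratum (crowding = number of sites of any TF
consistently proximal to the site's particle, five equal-sized rank
groups per compartment, remainders spread from the lowest group; 10 or 20
groups are configurable and give nearly identical controls). Homotypic
(diagonal) entries count unordered within-set pairs. In the PE matrix,
pairs with zero observed or expected counts are floored at the smallest
finite enrichment so clustering stays defined.

## Site-level operations

Putative sites are motif matches with p ≤ 1e-4 whose center lies in a
DHS; peaks map to their best (lowest-p, leftmost on ties) overlapping
motif. Genomic-marker categorization follows the published rules exactly
(promoters within 2 kb upstream of a TSS with H3K4me3+H3K27ac, strong
when H3K36me3 overlaps TSS ± 1 kb by ≥ 300 bp; enhancers from chromatin
state + H3K4me1, active/inactive by H3K27ac/H3K27me3), with ambiguous
mark combinations and methylated regions excluded at highest precedence;
"upstream" is strand-aware when the TSS table carries strand, else the
left side. Linear density spreads each site's unit mass over 100-kb
regions by sliding-window overlap, conserving site counts for interior
sites. Conservation between cell lines requires a partner peak
overlapping the query center with centers < 300 bp apart, nearest center
winning.

Occupancy is bound/putative per group, with errors from 1000 resamples
each dropping a random third of sites (validated against the closed-form
hypergeometric SD). Tercile contrasts use a G-test with Williams'
correction `q = 1 + (N/r₁ + N/r₂ − 1)(N/c₁ + N/c₂ − 1)/(6N·df)` or
chi-square with Yates' correction, BH-adjusted across TFs, skipping TFs
with < 300 sites per tercile. SignalValue comparisons pair sites with
identical sequence keys and identical mark/DHS/methylation (and
optionally sub-compartment) context, retain all cross-group pairings,
difference per-TF fractional-rank SignalValues, test with Wilcoxon
signed-rank, and build the control by pooling both members of every pair
and re-pairing at random (expected delta zero by construction). The
sequence key is an opaque per-site identifier, so the module needs no
genome FASTA; synthetic data supplies it directly.

## Synthetic data: what it emulates, and what it does not

Contact maps: normalized score `c · max(s,1)^(−α)` (α = 1, scale 200)
with log-normal multiplicative noise (σ = 0.3) and Poisson raw counts —
heavy-tailed but with none of the TAD/loop/compartment block structure of
real maps. Planted pairs multiply bin pairs holding bound sites of the
two TFs by a factor f (max over qualifying pairs). Site sets place one
site per 5-kb bin with a controllable A-compartment bias against
alternating 1-Mb A/B blocks; occupancy is Bernoulli per site.

Structures: per-chromosome random walks with constant step 2 radii
(uniformly random directions; no excluded volume), ten models from
Gaussian coordinate jitter of 0.3 radii (comfortably inside the 1-radius
QC threshold), and alternating A/B blocks. TFs connected by planted
contact pairs share a spatial cluster *on every chromosome*: one anchor
per (group, chromosome), placed by a farthest-point rule so groups occupy
separated neighborhoods, with sites drawn from the particles nearest the
anchor (`cluster_tightness` = 1 means exactly the n nearest; an explicit
sphere radius errors when too small). Per-chromosome anchoring matters:
the PE null permutes within chromosomes, so a single cross-chromosome
cluster would sit in near-pure strata and be invisible to it — as it
would be in real data, where TF hubs recur genome-wide. By default half
of a clustered TF's sites are planted (`cluster_fraction` = 0.5), keeping
crowding strata mixed.

Occupancy inputs: one putative site per 300-bp DHS, log-uniform motif
p-values in [1e-8, 1e-4], Bernoulli binding (or a supplied per-site
propensity to plant occupancy–score correlation), and mark/TSS/state
tracks laid out to realize the promoter/enhancer categories in roughly
fixed proportions.

Everything is driven by per-product generators spawned from the spec
seed; identical specs give bit-identical outputs.

Passing tests on these inputs demonstrate the estimators and nulls behave
correctly under known signal and no signal; they do not demonstrate
robustness to Hi-C normalization artifacts, TAD structure, copy-number
variation, or mapping bias, none of which the generator models.

## Validation experiments and problem sizes

The bundled experiments (`tf3dnet.experiments`) use desk-scale stand-ins
chosen once: null calibration with 10 TFs × 500 sites (one site per
80 kb, a realistic ChIP-seq density) over eight 5-Mb chromosomes, 200
permutations, 50 replicates; planted-group recovery with two 8-TF groups
(enrichment 3, 150 sites per TF) over four 5-Mb chromosomes; structural
planted pairs with two pair components plus four background TFs over two
300-particle chromosomes. Under the null the caller flags essentially no
pairs at FDR 0.05, and P(p ≤ 0.05) ≈ 0.04: the permutation p-values are
valid but discrete (count statistics), hence conservative between atoms —
a two-sided KS test against the continuous uniform will detect that
discreteness at large sample sizes even though the test is exactly
calibrated in the direction that matters.

## Known limitations

* Trans (inter-chromosomal) CCL is out of scope; only cis contacts are
  scored. Structure analyses do support trans proximity.
* The dynamic-tree cut is a silhouette-based height scan, not the full
  hybrid algorithm.
* No boundary correction near the modelled nuclear surface is applied to
  the structural enrichments (consistent with the published analysis).
* The contact-map dialect is plain TSV; `.hic`/`.cool` readers would be
  an adapter layer, not core.
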