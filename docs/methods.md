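# Methods

This note documents the models, defaults and design choices behind
`spherotad`: what each stage assumes, what the synthetic generator does and
does not emulate, and where a genuinely open design decision was settled.

## Contact-matrix model and normalization

A `ContactMatrix` is one chromosome's dense symmetric cis map at a fixed
bin size with a per-bin validity mask and a state tag (`raw` → `balanced` →
`oe`). Balancing is ICE (iterative proportional fitting): bins with fewer
than `min_nnz` (default 10) nonzero cells are masked, then the matrix is
rescaled until unmasked row sums agree to `tol` (default 1e-5, max 200
iterations); non-convergence returns a flagged partial result. The
expected-by-distance vector is the mean over unmasked cells at each
separation; dividing it out gives the O/E map, whose per-diagonal mean is 1
by construction. The pipeline is cis-only and in-memory — it targets
single-chromosome, desk-scale analyses, not genome-wide out-of-core
processing.

## Compartments

The per-bin compartment score is the first eigenvector of the Pearson
correlation matrix of O/E columns (computed over unmasked bins), scaled so
its L2 norm equals `score_scale` (default 100). The A/B label is the sign;
bins with |score| below `min_abs` are unassigned. `min_abs` defaults to
**10% of the track's RMS magnitude** rather than a fixed number: a
unit-norm eigenvector's per-bin magnitude scales as 1/√n, so any absolute
threshold would mean different stringency at different bin counts.

The eigenvector's sign is arbitrary, so tracks must be oriented before any
comparison. The reference condition is oriented against gene-TSS density
smoothed to ~1 Mb (compartment scale — raw per-bin counts are too noisy to
fix a sign reliably); the second condition is oriented by correlation with
the first oriented track. Cross-condition orientation is the robust choice
because genuine compartment changes are sparse, whereas an activity
reference can legitimately anti-correlate with one condition when large
gene-dense regions flip compartment.

A transition bin has |score| ≥ `min_abs` in both conditions and opposite
labels; maximal same-direction runs are merged into A→B / B→A regions.
Merged-run semantics were chosen (over per-bin counting) so that one
contiguous flipped region is one event. The compartment bin size is
configurable; 100 kb is the default. Per-gene scores use the TSS bin;
metagene profiles rescale each gene body to a fixed number of positions
(area-weighted) with genomic-bin flanks, strand-oriented, and the
between-condition test is a paired two-tailed t-test on per-gene mean body
scores (paired because the same genes are scored in both conditions; Welch
is available).

## TAD calling

Insulation at bin *i* is the mean of the balanced matrix over the square
`[i−w, i) × (i, i+w]` (default *w* = 5 bins = 500 kb at 100 kb),
reported as log2 of its ratio to the chromosome-wide mean of the statistic;
undefined within *w* of the ends or where the square is >50% masked.
Boundaries are local minima whose strength — the mean of the nearest
flanking local maxima minus the minimum — reaches `delta_thresh`. The
default is **0.2**: on matrices at realistic sequencing depth, true
boundary strengths are ≥0.9 while the smooth curvature of the insulation
profile inside large domains produces spurious minima with strengths around
0.10–0.14, so 0.2 separates the two populations with a wide margin on both
sides. The boundary set is invariant under positive scaling of the matrix
(the log-ratio normalizes it away). Domains tile the chromosome between
consecutive boundaries, chromosome ends acting as implicit boundaries;
domains shorter than `min_tad_bins` (default 3) are merged by dropping the
weaker delimiter (ties toward the lower index, deterministically).

## TAD change classification

TADs of the two conditions are joined by an edge when their overlap covers
≥ `min_overlap_frac` (default 0.5) of the smaller; connected components of
this bipartite graph are the change events, so every TAD belongs to exactly
one event. Per component: 1-to-1 with both boundaries within
`tolerance_bins` (default 1) → conserved; 1-to-1 with a boundary displaced
beyond tolerance → shifted; m-to-1 whose single TAD spans the m (ends
within tolerance) → fused; 1-to-m transpose → split; anything else →
complex. The taxonomy is exactly dual: fused(A,B) events are split(B,A)
events. Boundary conservation is the fraction of internal reference
boundaries with a partner within tolerance (chromosome ends excluded — they
exist by construction).

A moved internal boundary produces **two** 1-to-1 shifted events (each
flanking TAD witnesses it); recovery scoring therefore lets several called
events match one planted shift, and precision counts a called event as
correct if it contains a planted signature boundary.

## Aggregate contact analysis

Point-anchored aggregates average (2f+1)² O/E submatrices centered on each
anchor's diagonal pixel (f = 20 bins default), skipping anchors near ends
or >50%-NaN windows; the center score is the central 3×3 mean. Rescaled
domain aggregates take a window `expand_factor` (default 3) times the
domain, block-average it to `k_pixels`² (default 90², area-weighted — this
conserves mean signal, unlike interpolation), and average across domains;
the corner score is the mean of a 5×5-pixel box at the domain's
(start, end) corner where corner loops sit.

The between-condition test computes per-anchor score pairs and applies a
paired sign-flip permutation (default 1000 permutations, two-sided,
+1-corrected) — distribution-free, because O/E submatrix scores are
heavy-tailed. For the corner statistic, each anchor's corner box is
normalized by background boxes sliding along the same diagonal of its
window (the same genomic separation). This distance-matched normalization
is essential: any condition difference that perturbs the expected-by-
distance curve (domain fusions, widespread loop loss) shifts raw O/E corner
values at *every* domain, and a paired test over many anchors will detect
that global bias; normalizing at matched distance cancels it exactly while
leaving the focal loop signal intact.

## Peak/gene integration

Overlap accounting uses the ≥1 bp rule; shared percentages are truncated
(not rounded) to two decimals, matching how such fractions are printed.
Count-mode accepts already-tabulated totals. Overlap significance offers a
hypergeometric model (universe discretized at the median peak width, tail p
on intersecting bins, enrichment or depletion tail chosen by the fold) and
a placement-permutation model. Peak density per TAD change class is peaks
per Mb per event interval, compared across classes by two-sided
Mann–Whitney. TSS metagenes use a peak-overlap indicator per window
(strand-oriented; minus-strand profiles reversed). Enhancer-associated
peaks are those overlapping the acetylation set; their distance (peak
midpoint to nearest TSS, absolute) is compared between a gene set and a
size-matched seeded sample of unregulated genes by one-sided Mann–Whitney.

Super-enhancers follow the ROSE conventions: peaks stitched within 12.5 kb
(optional ±2.5 kb TSS exclusion), stitched regions ranked ascending by
total signal, both axes rescaled to [0, 1], and the cutoff set where the
curve's slope first reaches 1; regions above it are super-enhancers, genes
are assigned within 50 kb. The cutoff index is invariant under uniform
scaling of signals.

DE summarization classifies up (log2FC ≥ +t, padj < p) and down
(log2FC ≤ −t, padj < p). The qPCR comparative-Ct fold is
`2^(Ct_ref − Ct_ip)`; the sign convention is fixed so that a lower IP Ct
(more template) gives fold > 1 — the exponent order sometimes printed the
other way around would make enrichment fall as IP signal rises.

## Synthetic data: what it emulates

The generator draws Poisson counts with mean

```
λ(i,j) = depth · (1+|i−j|)^(−α) · c^(s_i·s_j) · t^[same TAD] · ℓ^[loop pixel]
```

with defaults α = 1, c = 1.6, t = 2, ℓ = 3 and depth = 1000 expected
counts per bin pair at zero distance (row sums ≈ 7600 — comparable to a
deep Hi-C library at 100 kb, and chosen so the window-5 insulation
statistic has per-bin noise ≪ the boundary-strength threshold). The default
genome is one 200-Mb chromosome at 100 kb (2000 bins), TADs of 8–30 bins.

Structural choices that make planted events well-posed:

- Compartment segments are groups of 2–3 consecutive TADs with strictly
  alternating sign, so compartment borders coincide with TAD boundaries (as
  in real genomes). This prevents compartment contrast from mimicking TAD
  boundaries, leaves interior boundaries available as fusion/shift targets
  (those targets exclude compartment borders, whose insulation dip would
  survive the boundary's removal), and guarantees two same-direction flips
  are never adjacent, so each planted flip stays one distinct region.
- Fusions remove one interior boundary each, no two sharing a TAD; splits
  bisect an untouched TAD of ≥16 bins; shifts move one boundary by 3 bins
  (beyond the 1-bin matching tolerance plus localization jitter).
- Every domain carries a 2×2 corner-loop block; a configurable set of
  conserved domains loses it in the 3D condition.
- CTCF peaks sit at 2D boundaries plus background; fused boundaries always
  lose their peak in 3D and the rest are lost independently at
  `ctcf_loss_fraction` (default 0.75). PR gains 3D-specific sites, half of
  them inside acetylated enhancer clusters. H3K27ac has shared background
  positions (condition-specific scores) plus high-signal clusters, 80%
  shared between conditions and 60% anchored 5–30 kb from DE-gene TSSs.
- Genes: 1000 total, 150 down / 80 up; down genes are enriched in fused
  intervals (30%), A→B flip regions (15%) and corner-loss domains (25%);
  background placement is 3:1 biased toward the A compartment, which is
  what makes gene density a usable orientation reference.

The dedicated corner-loss study (`corner_loss_config`) plants *only* loop
losses (40 domains, holding 80% of the down genes) and keeps control genes
out of those domains — the desk-scale stand-in for the genome-scale
dilution that makes random-gene controls effectively clean in real data.

What the generator does **not** emulate: read-level noise and mapping
artifacts, trans contacts, replicate-to-replicate biological variability,
copy-number and coverage biases, nested/hierarchical domains, and realistic
peak-width or signal-shape distributions. Passing the planted-recovery
tests therefore demonstrates that the algorithms recover the structures
they model, under Poisson sampling noise at realistic depth — not that they
are robust to every artifact of real Hi-C or ChIP-seq data.

Event densities are deliberately desk-scale: a 2000-bin genome holds ~100
TADs and ~40 compartment segments, so 31 boundary events and 12 flips are a
far larger *fraction* of the genome than the corresponding genome-wide
counts in a real comparison. Consequently fixture-level summary numbers
(eigenvector correlation across conditions ≈ 0.4–0.5 at 1 Mb, boundary
conservation ≈ 75%, DE-gene fractions in fused domains) differ from
genome-scale values by construction; the recovery statistics
(precision/recall per event class, permutation contrasts) are the
validation currency. Fixtures below ~600 bins are used only for stages that
do not involve compartment flips — at 300 bins the scaled flip events would
cover nearly half the genome and cross-condition orientation becomes
ambiguous.

## Determinism and numerical conventions

All generator outputs are pure functions of (config, seed); one explicit
`numpy` Generator per operation, no global RNG state. Pipeline outputs
contain no timestamps, and the report embeds a hash of the
analysis-relevant configuration (output paths excluded), so identical
(config, seed) runs are byte-identical. Ties are broken deterministically
(plateau minima at the lowest index; short-TAD merges drop the weaker, then
lower-index, delimiter). Masked bins propagate as NaN through O/E,
insulation and aggregates and are excluded from all means. Empirical
permutation p-values carry the +1 correction and are therefore never 0.

## Known limitations

Single chromosome per matrix; dense storage (an n-bin matrix costs ~8n²
bytes); no hierarchical TADs, loop calling, or differential-insulation
significance per boundary; the hypergeometric overlap model treats bins as
exchangeable (no GC/mappability matching); super-enhancer calling expects
precomputed peak scores rather than raw coverage.
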