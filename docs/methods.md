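# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data generator, and the known limitations of `chromdar`.

## Coordinates and interval algebra

All intervals are 0-based half-open `[start, end)`; BED files are read and
written in that convention, and SNP tables (1-based on disk, VCF-style) are
converted to 0-based points on read. Overlap always means sharing ≥ 1 base.
Merging with `gap = 0` additionally coalesces *touching* intervals
(`end(a) == start(b)`), matching the adjacency behaviour of the standard
`-d 0` merge tools, so a merged set is pairwise non-touching and idempotent
under re-merging. Design choices that the convention forces:

- **Blacklist subtraction removes whole regions**, never trims them. Trimming
  would silently change region coordinates and counts downstream.
- **Nearest-TSS distance is measured from the region start** (not midpoint or
  summit); ties break toward the smaller coordinate, then the smaller gene id,
  so the assignment is deterministic.
- **Point-to-region distance** is 0 inside the region and otherwise the
  distance to the nearest *included* base (`start` or `end − 1`): a point one
  base past a region is at distance 1, not 0.
- Strand is carried by TSS entries (the TSSE profile is strand-flipped) but
  ignored by all region overlap logic, since ATAC signal is unstranded.

## Consensus regions and QC

Per-sample peaks are concatenated, merged, and filtered to regions supported
by ≥ `min_samples_for_consensus` (default 5) sample peak sets (≥ 1 bp overlap
each), then blacklist overlaps are removed. Counting uses fragments (a read
pair = one fragment): a fragment increments every merged region it touches and
counts once in the FRiP numerator. The FRiP floor (default 0.2) flags rather
than drops samples — failing libraries are a judgement call for the analyst.

Regions with mean log₂-cpm < 0 across all samples (strict inequality; prior
count 0.5) or on dropped chromosomes (default chrY) are removed before
testing. Non-canonical contigs are kept unless a `contig_allowlist` is
configured.

The TSS enrichment score aggregates per-base fragment depth over ±1000 bp
around every TSS (minus-strand profiles flipped), partitions the profile into
100-bp windows, scores each window by its mean depth divided by the mean of
the two terminal windows, and reports the maximum. The aggregate-then-score
order (rather than per-TSS scores averaged) and the unsmoothed maximum are
deliberate: they make the two analytic cases exact (uniform coverage → 1;
a 10× spike confined to the central window → 10).

PCA is computed on region-centered (not variance-scaled) log₂-cpm — the
values are already on a common scale. Per principal component and factor
(treatment, individual, time) a one-way ANOVA F-test and R² are reported.

## Differential accessibility

The engine follows the count-based moderated-t workflow:

1. **TMM** normalization with the canonical trims (0.30 on M, 0.05 on A),
   precision-weighted trimmed mean, reference sample chosen by the
   75th-percentile rule, factors rescaled to geometric mean 1. Matches
   edgeR's `calcNormFactors` to ~1e-14 in cross-check tests.
2. **voom**: `y = log2((count+0.5)/(effective lib+1)·1e6)`; per-region OLS
   residual √sd is lowess-smoothed (span 0.5, 3 robustness iterations)
   against average log₂ count; per-observation weights are the predicted √sd
   at the observation's fitted log₂ count raised to the −4th power, with
   predictions clamped to the trend's range at the extremes and floored at
   1e-6 before inversion.
3. **Consensus intra-donor correlation**: per region, the intraclass
   correlation of √weight-scaled residuals is estimated by the moment (ANOVA
   cross-product) estimator — mean within-donor cross-product over mean
   squared residual — which is exactly unbiased for the variance-component
   ratio under the balanced cell-means design used here. Per-region estimates
   are clipped to (−0.9999, 0.9999) and combined as
   `tanh(trim_mean(atanh(ρ_r), 0.15))`. One pass only (no
   voom/correlation iteration): the iteration policy adds nondeterminism in
   exchange for negligible movement of the consensus, and single-pass
   estimates match limma's `duplicateCorrelation` within ~0.01 in tests.
4. **GLS contrasts**: one design column per treatment × time cell; the donor
   enters only through a block-compound-symmetry correlation (a donor fixed
   effect would absorb the blocking and is confounded with the random-effect
   strategy). Each drug is contrasted against the vehicle at the same
   timepoint. With ρ = 0 the fit reduces exactly to weighted least squares.
5. **Empirical Bayes**: a scaled inverse-χ² prior (d₀, s₀²) is moment-matched
   on log variances (trigamma inversion by Newton iteration; variances
   floored at 1e-10). Posterior variance `(d₀s₀² + df·s²)/(d₀ + df)`;
   moderated t on d₀ + df degrees of freedom; identical variances give the
   d₀ = ∞ branch (full shrinkage, normal reference).
6. **BH per contrast**; DAR ⇔ adjusted p < 0.05 (strict), direction
   opening/closing by the log₂FC sign. The trastuzumab contrast is computed
   identically to every other drug — its emptiness under the null design is a
   tested property, not a special case.

Under the null synthetic design the moderated test's p < 0.05 rate is
calibrated (0.05 ± 0.01 pooled over 20 replicates of 5000 regions) and BH
labels essentially no DARs; under planted 10% effects at |log₂FC| = 1.5,
dispersion 0.1, 4 donors, sensitivity exceeds 0.8 with empirical FDR below
0.10. These are recomputed by the test suite and `scripts/acceptance.py`.

## Enrichment

A region hits a track if some feature interval overlaps it by ≥ 1 bp and by
≥ `min_frac` of the *feature's* length (0 by default; 0.5 is the standard
variant for transposable elements). The 2×2 (DAR/CAR × hit/miss) table is
tested by Pearson chi-square (1 df, no continuity correction — the Fisher
switch covers small counts) unless any cell < 10, in which case Fisher's
exact test is used, two-sided by summing tables with point probability ≤ the
observed (the convention exhaustive enumeration reproduces). Odds ratios with
a zero cell are reported as +∞/0 with a `degenerate` flag; no Haldane
correction is applied by default. Bonferroni correction is applied within
feature-category families (TE classes; CpG/TSS "other features"; cRE
subtypes) separately per contrast; the grouping is configurable because
"across categories" is genuinely ambiguous. DEG-proximity enrichment uses
Fisher's exact test on the linked-region universe at each window (2 kb and
20 kb by default; the 2 kb universe nests inside the 20 kb one).

## SNPs, TADs and permutation overlap

A SNP overlaps a region iff `start ≤ pos < end`. TAD assignment is an
intersection join: SNPs to every containing TAD, regions to every TAD they
touch; (SNP, region) pairs are formed within shared TADs and de-duplicated
across nested TADs. DAR-pair and CAR-pair distance pools are compared by a
two-sided Wilcoxon rank-sum test: exact enumeration when both pools have ≤ 8
members and no ties, otherwise the normal approximation with tie and
continuity corrections. The reported statistic is the rank-sum W of the DAR
pool.

The permutation overlap test re-places each query region uniformly at random
on its own chromosome, preserving length (no gap or blacklist masking —
the simplest documented scheme; the placement is seeded and reproducible) and
reports `p = (1 + #{permuted ≥ observed})/(B + 1)`, so p is always within
`[1/(B+1), 1]`.

## Linkage

Region–gene links take the nearest TSS to the region start and keep the link
iff |distance| ≤ window (inclusive boundary) and the gene is expressed; one
link per region. The drug-response effect size is the per-region median log₂FC
across the configured treatment set at a timepoint (midpoint for even counts).
Cross-phenotype correlation is Spearman by default (the conventional reading
of a reported ρ; Pearson is a config switch), with average ranks for ties and
an exact pairing-permutation p for n ≤ 10. When a region overlaps several
histone regions, the pair keeps the partner with the largest overlap (tie →
lower coordinate) so the per-pair table is deterministic.

## Synthetic data

The generator emulates the repeated-measures drug panel the pipeline is built
for; its defaults are the study conditions, not tuning knobs:

- 4 individuals × 6 treatments (DOX, EPI, DNR, MTX, TRZ, VEH) × 2 timepoints
  (3 h, 24 h) = 48 samples; library sizes uniform in 5×10⁵–2×10⁶ (desk
  scale); negative-binomial counts with dispersion 0.1, so
  `variance = μ + 0.1 μ²`.
- Donor random effects `b ~ N(0, 0.3²)` per (region, donor) on the log₂
  scale — enough to make the blocking matter without dominating treatment
  separation, consistent with donor structure appearing on the second rather
  than first principal component.
- 10% of regions carry planted effects of |log₂FC| = 1.5; 90% of planted
  regions respond to all three anthracyclines (the shared-response structure),
  the rest to one; MTX responds on half; TRZ and VEH never. Effects are equal
  at both timepoints.
- Responsive regions carry a designated feature track at relative risk 3 over
  the 0.10 base rate; SNPs are planted near responsive regions (closer than
  to background regions) with a fraction falling inside regions; expression
  and histone responses of linked genes/regions are κ-scaled copies of the
  regional effect plus Gaussian noise (κ = 0.5 and 0.7, noise sd 0.5 and
  0.4), giving a designed rank correlation between phenotypes.
- Per-sample peak sets jitter region edges by ±50 bp and drop each region
  with probability 0.05; decoy peaks appear in 1–4 samples (below the
  consensus threshold) and dedicated blacklisted peaks always appear but are
  covered by blacklist intervals — so the consensus and blacklist rules are
  exercised non-trivially.
- Everything derives from one integer seed through named `SeedSequence`
  streams; a fixed seed gives byte-identical files.

What the generator does **not** emulate: GC and mappability bias,
fragment-length periodicity, peak-shape heterogeneity, linkage disequilibrium
among SNPs, donor-specific treatment response (the random effect is additive,
not interactive), and time-varying effect sizes. Passing recovery tests
therefore demonstrate the statistical machinery is correct and calibrated
under its assumed generative family — not that those assumptions hold in any
particular real library.

## Problem sizes and numerical notes

The test suite and acceptance script use 2000–5000 regions, 16–48 samples,
and 10–100 simulation replicates per property; brute-force oracle sweeps use
~1000 random instances per interval operation. The GLS fit is fully batched
(einsum over regions), so a 5000-region, 48-sample analysis takes about a
second on one CPU. Ties and degenerate inputs: zero-variance regions floor at
1e-10 before the prior fit; degenerate 2×2 margins give p = 1 with a flag;
empty DAR or CAR sets raise rather than silently return; lowess predictions
are clamped at the trend boundaries (no extrapolation).

## Known limitations

- The chi-square and two-sided Fisher p-values agree closely only where it
  matters (small p); at moderate p they can differ by several percent because
  the exact test sums discrete tables — the Fisher switch at counts < 10 does
  not remove this, it only protects the small-count regime.
- The consensus-correlation moment estimator assumes a balanced design (every
  donor in every cell); severely unbalanced designs would need the REML
  rotation.
- `voom` weights assume the mean–variance trend is shared across regions;
  copy-number-like regions violating it are shrunk like everything else.
- The permutation overlap test's uniform re-placement ignores accessibility
  and mappability structure, so its p-values are optimistic on real genomes;
  use it as a concordance screen, not a calibrated test.
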