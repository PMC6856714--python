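# Methods

## Balanced matrices and expected values

All statistics operate on balanced matrices: raw cis counts `c_ij` times
per-bin weights from classic iterative correction (ICE), applied per
chromosome.  Bins whose fraction of nonzero cis pixels falls below
`min_nnz_frac` (default 0.02) or whose marginal is zero are masked before
iterating; iteration stops when the coefficient of variation of the
balanced marginals drops below `tol` (default 1e-5, max 300 iterations),
and weights are rescaled so the mean balanced marginal is 1.  Masked bins
propagate as NaN into every pixel they touch.  Upstream pair-level
filtering (mapping quality ≥ 30, duplicate removal) is assumed to have
happened before the triplet files were written; it is an input contract,
not re-checked.

The expected value at diagonal offset `d` is the plain per-diagonal mean of
balanced values over pixel pairs whose two bins are both unmasked.  Zero
pixels count toward the mean — in a balanced matrix an absent sparse entry
is an observed zero, not missing data.  No smoothing is applied.

Two desk-scale caveats of per-chromosome ICE on short chromosomes are worth
knowing.  First, bins near chromosome ends have intrinsically smaller decay
mass; forcing equal marginals inflates their weights, so obs/exp is mildly
elevated in the outermost ~10–15% of a short chromosome.  Fixed-size
pileups are unaffected (edge-crossing windows are skipped), and the domain
z-score null samples positions uniformly, so it absorbs the same structure
as its query; but a single-matrix z-score for a domain *at* a chromosome
end should be interpreted cautiously.  Second, any feature that adds mass
to a bin's marginal is partially cancelled by balancing; the simulator is
designed so features carry no net marginal mass (below), which is also the
physically correct model of the assay.

## Pileups

Pileups accumulate the observed balanced values and the expected values of
every eligible window separately and divide the sums
(`Σ obs / Σ exp`), *not* the mean of per-window ratios: deep, short-range
windows should dominate shallow, long-range ones in proportion to their
information content.  Per-pixel valid counts are tracked so masked pixels
in some windows do not unbalance the two sums.  Geometry defaults follow
the window used throughout the analyses here: 100 kb flank at 5 kb
resolution → 41 × 41 pixels spanning 205 kb, centre index (20, 20).

Choices where the procedure was genuinely open:

* **Minimum separation** defaults to `2·flank + resolution` (210 kb at the
  defaults) so windows never touch the main diagonal, whose steep decay
  gradient would otherwise dominate the average.  No maximum by default.
* **Region snapping**: the bin containing the interval midpoint; a midpoint
  on an exact bin boundary goes to the left bin.
* **Edge handling**: windows crossing a chromosome end are skipped entirely
  and counted, never NaN-padded, so every pixel averages the same windows.
* **Orientation**: for two distinct region sets, each cross pair is
  accumulated with rows centred on the first set's anchor, so
  `pileup(A, B)` is exactly the transpose of `pileup(B, A)`.  Within one
  set each unordered pair is taken once and the result is symmetrized
  (averaged with its transpose) by default.
* **Rescaled pileups** resize each region's on-diagonal window
  (`flank_factor` = 1.0 region length on each side) to a 33 × 33 grid by
  area-weighted box resampling that ignores NaN, then average grids across
  regions (regions shorter than 10 kb are skipped).  Rescaled pileups are a
  mean of per-region grids — each region contributes equally regardless of
  depth, which is what a variable-length average is for.

## Local interaction density and quantile summaries

Density windows are 25 kb at 5 kb resolution; eligible pixels are pairs
with `i ≤ j` and `j − i ≥ 2` (exactly 6 per window), so the ligation-noise
dominated first two diagonals never enter.  A window is dropped when the
missing fraction of its eligible pixels reaches 20%; since missing pixels
come from masked bins, one masked bin removes the window.  Windows tile the
chromosome by default (stride = window size) so no pixel enters the
bootstrap twice; a one-bin stride is available by flag.

Windows are joined to a coverage track by overlap-weighted sums
(read-density semantics; fraction-style tracks such as GC use the
overlap-weighted mean) and grouped into quantiles of coverage — 10 groups
by default.  Each group is summarised by its mean density and a
percentile-bootstrap 95% CI (1000 resamples of windows within the group,
seeded).  Cross-condition mode bins a second condition's windows by the
*first* condition's coverage quantile edges, so a 2i map is stratified by
serum occupancy.  When coverage values tie, quantile edges collapse and the
affected lower groups are reported empty with n = 0 rather than raising.

## Loop classification

Anchor points are BEDPE anchor-interval midpoints.  A loop is associated
with a peak set iff both anchor points are within 5,000 bp (inclusive) of a
peak — implemented as "widen peaks by the tolerance, test containment", so
a gap of exactly 5,000 bp associates and 5,001 bp does not.  A missing peak
on either side is no association; an empty peak set yields all-False flags
with a warning.  The two flags partition loops into CTCF_only /
RING1B_only / both / neither, and per-class pileups report the class
centre-pixel values.

## Insulation, compartments, similarity, z-scores

* **Diamond insulation** (100 kb window at 25 kb bins → 16-pixel diamonds)
  is log2-normalized against the chromosome mean of the raw scores
  (configurable to median); a bin is invalid if any constituent bin is
  masked or the diamond leaves the chromosome.  Boundary candidates are
  plain local minima of the normalized score.
* **Compartment eigenvector**: per chromosome, obs/exp over valid bins
  minus 1, leading eigenvector by |eigenvalue| (ties broken by GC
  correlation magnitude), scaled by √|eigenvalue| and sign-oriented so its
  Pearson correlation with the GC track is non-negative.  This is the
  eigendecomposition route rather than PCA of the correlation matrix.
* **Track similarity**: bins invalid in any track are dropped for all;
  Pearson correlations; average-linkage clustering on 1 − r.
* **Domain contact z-score** is this package's own reconstruction of a
  depletion test at chosen loci: the statistic is the mean obs/exp over
  within-domain pixels with |i − j| ≥ 2; the null is the same statistic on
  `n_null` windows of the same bin length placed uniformly over fully
  valid, non-overlapping positions (seeded, without replacement).
  Differential mode scores `log2(condition2 / condition1)` of the domain
  statistic against the null windows' log ratios, which cancels shared
  positional structure.  If the null is degenerate (identical matrices)
  the z-score is defined as 0.

## The synthetic-data generator

The generator is the package's study-conditions stand-in for deposited
sequencing data.  Pixel intensity on a chromosome is

    λ(i,j) = Z · w_i w_j · (|i−j|+1)^(−α) · (1 + κ e_i e_j) · F(i,j)

with log-normal biases `w` (log-sd β = 0.3), deterministic ±1 compartment
blocks `e` (800 kb), and `F = D·L` combining domain enrichment δ with
Gaussian point loops of amplitude φ and width σ = 1 bin.  `Z` scales the
total to N; counts are Poisson (over-dispersion is deliberately out of the
default model).  The decay uses (s+1)^(−α) to avoid the s = 0 singularity.

**Features redistribute contacts rather than create them.**  Every
sequenced fragment end ligates to exactly one partner, so a locus that
engages in strong specific contacts does so at the expense of its diffuse
contacts, and true marginals carry no feature signal.  The generator
enforces this: focal features (occupancy domains, all loops) keep their
full enrichment at feature pixels, while the background pixels of every
touched bin are rescaled by symmetric factors (a short Sinkhorn iteration)
so each bin's total intensity equals its feature-free value exactly.
Tiling fields (TADs; the graded compaction tiles of `graded_spec`)
contribute their mass directly — a quasi-uniform shift that cancels in
obs/exp.  Besides being the physically right model, this makes balancing
recover exactly the planted biases, so planted amplitudes are recoverable
at desk scale; without it, per-chromosome ICE on a 10 Mb chromosome
cancels 20–30% of a feature's enrichment into its weights.  One residual
effect remains: the mass moved out of feature-bin backgrounds deflates the
per-diagonal expected by ~2–3%, so absolute enrichments in a feature-rich
map run a few percent high; the acceptance tolerances comfortably cover
this.

**Default study conditions** (2 chromosomes × 10 Mb at 5 kb, N = 5 × 10⁶
cis counts — every recovery experiment runs in seconds): per chromosome,
tiling CTCF-class TADs (400 kb – 1 Mb, δ = 1.5, boundaries on the 25 kb
grid); 10 polycomb occupancy domains (20–100 kb, δ = 2, non-overlapping);
48 standalone RING1B-bound CGI anchors kept clear of domains and CTCF
sites, with polycomb loops (φ = 3, σ = 1) between *every* anchor pair
260 kb – 1.5 Mb apart — polycomb CGIs interact combinatorially — and 200
CTCF loops (φ = 3) between random pairs of 60 CTCF sites 260 kb – 1.2 Mb
apart.  Feature counts were chosen once so that planted amplitudes are
measurable with small sampling error at this depth while each bin's
feature mass stays well below its contact budget; on shorter chromosomes
the domain width is capped (chromosome length / 60) for the same budget
reason, and a spec whose features exceed a bin's budget is rejected with
an explicit error.  The 2i-like condition multiplies the excess enrichment
(δ − 1, φ − 1) of polycomb-class features by ρ (default 0, full
depletion) and leaves CTCF-class features untouched, so λ at CTCF feature
pixels is identical across conditions for any ρ.  Paired conditions share
the planted genome; `replicate()` changes only the sampling noise (biases
and Poisson draws), which is what distinguishes library replicates from
conditions in the clustering analyses.

**Derived tracks**: occupancy = γ·(planted polycomb intensity) plus
log-normal noise — it emulates a *serum* ChIP read-density track, so it is
not attenuated in the 2i condition (the analysis deliberately bins 2i maps
by serum occupancy); GC = affine map of the compartment vector plus
Gaussian noise, so eigenvector phasing is testable; RING1B peaks cover the
occupancy domains and bound-CGI anchor bins, CTCF peaks the CTCF anchor
bins; CGIs are anchor-centred ±1 kb intervals labelled bound/unbound, with
unbound CGIs sampled away from all planted polycomb signal; loops are the
planted anchor pairs as single-bin BEDPE anchors.

**What the generator does not emulate**: trans contacts, over-dispersed
(negative-binomial) counts, restriction-fragment granularity, copy-number
or mappability structure, nested/hierarchical TADs, compartment strength
varying along the chromosome, and genome-scale chromosome lengths.
Passing recovery tests therefore demonstrates that the estimators are
correct and well calibrated under the model's assumptions at desk scale —
not that real-data estimates are unbiased at these magnitudes.

## Calibration experiments

* **Bootstrap coverage**: 200 repetitions of drawing 400 window densities
  from a log-normal (log-sd 0.3, known mean), summarising with the
  percentile bootstrap (1000 resamples); the fraction of 95% CIs covering
  the true mean is checked against 93–97%.  Percentile bootstrap
  under-covers slightly at finite n, which the sample size keeps inside
  the band.
* **Null z-scores**: 20 feature-free simulated maps (1 × 3 Mb at 5 kb,
  3 × 10⁵ counts, biases only) × 10 domains of 75 kb placed uniformly at
  random, 150 null windows each; the 200 z-scores are checked for mean in
  [−0.2, 0.2] and SD in [0.8, 1.2].  Placing calibration domains from the
  same positional distribution as the null is essential: the ICE edge
  effect described above gives window statistics genuine positional
  structure that both query and null must sample alike.

## Known limitations

* Cis-only throughout; trans entries are counted and dropped at read time.
* The triplet text format is the native interchange; multi-resolution
  container formats are out of scope (aggregation is by integer factors
  from the base resolution).
* Duplicate (i, j) keys in input are an error, not summed — this catches
  malformed exports at the cost of refusing concatenated shards.
* The sliding-window stride, quantile count, rescale grid, flank factor and
  z-score construction are package decisions where the underlying
  procedures are conventionally under-specified; all are configurable.
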