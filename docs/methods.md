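# Methods

This note documents the models, the numerical choices and the limits of
what the synthetic-data tests demonstrate.

## Worm-length morphometry

A larva in a single grayscale image is measured as the geodesic length of
the longest path through the medial skeleton of its silhouette.

*Segmentation.* The default threshold minimizes intraclass variance over
the grayscale histogram (Otsu); a fixed threshold is available for
calibrated setups. Foreground polarity is auto-detected as the minority
class — a worm occupies a small part of the field of view — and can be
forced. A constant image has no object and is an error, never a zero
length.

*Skeleton and path.* The mask is reduced to its largest 8-connected
component (a second component above 5% of the largest's area raises
`multiple_components`), thinned with a topology-preserving algorithm, and
the path maximizing geodesic distance between any two skeleton pixels is
extracted by a two-pass farthest-point search over the weighted pixel
graph (orthogonal steps 1, diagonal steps √2). This prunes side branches
deterministically with no spur-length parameter. A cyclic skeleton (more
edges than a tree allows) raises `self_overlap_suspected`: coiled worms
are flagged, not unfolded, because no unambiguous unfolding exists for a
single threshold mask.

*Length.* `path_length` is the exact chamfer (1, √2) sum and is kept as
the bit-reproducible reference metric; its toy values (10 µm for 11
collinear pixels at 1 µm/px, 10√2 µm diagonally) are exact. For the
default measurement, however, the path coordinates are first smoothed
with a 5-pixel moving average (endpoints pinned) and summed as Euclidean
segments. The raw chamfer length of a thinned skeleton systematically
overestimates a smooth centerline — a digital straight line at angle θ is
overcounted by up to ~8%, and thinning adds pixel-level zigzag — which we
measured as a +4.6% median bias on synthetic larvae; smoothing removes it
(≈0.6% median absolute error on 100 worms of 150–300 µm with varied
curvature and noise) while leaving collinear paths unchanged.
`smooth_window=0` restores the raw chamfer output. Endpoint retraction
(the skeleton of a blunt-ended tube stops roughly one half-width short of
each tip) partially offsets in the other direction and is deliberately
not corrected separately: with the rendered blunt ends it is small, and a
radius-based correction would re-introduce an overshoot.

Unit handling is exact: lengths scale linearly in `px_size_um`, and a 90°
rotation changes the measurement by well under 0.5%.

## Logistic growth and developmental timing

Growth is summarized by L(t) = L_max / (1 + e^{−r(t−t₀)}). Initial values
are L_max ← 1.05 × max length, t₀ ← time of steepest smoothed increase,
r ← 4 × (max slope) / L_max (the slope of a logistic at its midpoint is
r·L_max/4); the fit is trust-region least squares with positivity bounds
on L_max and r. Convergence is reported honestly; a constant trajectory
is a degenerate error because r is unidentifiable. Fits require ≥ 8
points spanning ≥ 10 h. On the default sampling (one point per 3 min over
65 h) noiseless parameters are recovered to better than 1e-4 relative and
5% multiplicative noise leaves median parameter errors well under 1%.

Timings are pure interval arithmetic — ex-utero = hatch − laid, larval =
first egg − hatch, generation = first egg − laid — so additivity holds
exactly on complete records, and missing events propagate to exactly the
intervals that need them.

*Windowed ratio bootstrap.* Development time is tiled into 15 half-open
windows of 4 h 16 min (so the windows partition [0, 64 h] exactly and
every measurement belongs to one window). Within a window, one
measurement is drawn uniformly with replacement from each cohort; a pair
more than 1.5 h apart in real time is rejected and redrawn
(resample-until-accept with a cap of 100·B attempts, keeping exactly
B = 1000 accepted ratios), and the mean with the percentile 95% interval
of the accepted ratios is reported. The sampling unit is a single
(animal, time) measurement, not an animal, matching the per-pair time
constraint; ratio orientation is group_b/group_a (mutant over wild type)
and is stated in the output. A window where either cohort is empty, or
where no pair can meet the time constraint, is reported with
n_accepted = 0 rather than being silently dropped.

## Bootstrap effect sizes

`mean_difference` resamples both groups independently (B = 5000 default,
B ≥ 1000 enforced) and reports mean(test) − mean(control) with a BCa
interval. The BCa levels are *expanded* for small samples: the nominal
normal quantile is replaced by √(n/(n−1)) · t_{α/2, n−1} with
n = min(n_control, n_test), the standard correction for the narrowness
bias of resampling intervals (plain percentile/BCa intervals for means at
n = 20 cover a true difference only ~93% of the time; with expansion,
measured coverage is 94–96% across simulation replications). When the
acceleration is undefined (all jackknife values equal) the percentile
interval is used and labelled as a fallback; when both groups have zero
variance the interval collapses to the point estimate and is flagged
degenerate rather than inventing width. The percentile variant's
endpoints equal plain quantiles of the stored bootstrap distribution, so
it can be verified directly against the returned draws.

## Negative-binomial differential expression

*Size factors.* The pseudoreference for gene i is the geometric mean of
its counts across samples, over genes with no zero count; sample j's
factor is the median over those genes of counts_ij / pseudoref_i,
computed in log space. If no gene is positive everywhere the error tells
the user to filter — silently changing the gene set would change the
estimator.

*Dispersion.* Per-gene method-of-moments dispersion on normalized counts,
α_i = max(0, (s² − µ)/µ²), with the variance pooled within groups
(df-weighted) so group mean differences never inflate dispersion. The
trend α(µ) is a lowess fit of log α on log µ (frac = 0.4) over genes with
positive raw dispersion, evaluated by interpolation with flat
extrapolation; with fewer than 50 usable genes a nonnegative LS fit of
the parametric family a₀ + a₁/µ takes over and the model records which
route was used. Testing uses max(raw, trend) per gene, guarding against
underestimated dispersions at the 3–5 replicates typical of these
designs.

*Test.* An exact conditional two-group test: conditioning on a gene's
total K, the two group sums are modelled as moment-matched NBs with means
q·S_g (q = K/(S_a+S_b), S_g the summed size factors) and dispersions
α·Σs_j²/S_g² — the exact dispersion of a sum of independent NB counts
sharing α. The two-sided p-value is the conditional probability of all
splits of K no more likely than the observed one (ties included with a
1e-8 relative tolerance). This vectorized implementation agrees with a
brute-force enumeration oracle to 1e-10 on totals up to 200, yields
p ≈ 1 for perfectly balanced splits, and produces near-uniform null
p-values (KS distance < 0.05 at 2000 genes, 5 vs 5). A zero-total gene
has p = 1, and zero-count genes are excluded from the multiple-testing
universe before BH.

Fold changes are (mean_test + ε)/(mean_control + ε) on normalized counts
with ε = 0.5, recorded in the output; DE calls require q < 0.01 and fold
change beyond 2 in either direction. On the spiked simulation (5000
genes, 10% DE at 2-fold, 5 vs 5) the realized false discovery proportion
at q < 0.01 averages well under 0.05 with positive recall — dispersion
max()-ing makes the procedure conservative, which we prefer at this n.

*PCA and embedding.* PCA is computed through the SVD of the per-gene
centered matrix (samples as observations); requesting more components
than the rank truncates with a flag. Embedding onto a reference time
course computes eigenvectors and centering from the reference alone;
query samples are centered with the *reference* gene means (centering by
query means is available but not default: with few query samples their
own means absorb the biological signal) and labelled by the nearest
reference sample in the top-k eigenspace. Projecting the reference
reproduces its own scores to machine precision, which pins down the
centering convention.

## Lipidomics

Zero encodes a non-detect throughout. The detection filter keeps lipids
detected in at least ⌊n/2⌋ + 1 samples (integer-safe reading of
"half + 1"); an all-samples rule is selectable, and is the right choice
when left-censoring near the detection limit would otherwise leave
zeros inside the tested groups. Total normalization divides each sample
by its total over retained lipids (columns sum to 1 exactly); t-tests run
on these normalized values, while PCA runs on log₁₀(x + 1e-6) z-scores
(sample sd, ddof = 1 — so a two-sample lipid scores ±1/√2; zero-variance
lipids get z = 0 and a flag). The t-test is two-sided pooled-variance;
zero pooled variance yields p = 1 at equal means and a flagged p = 0
otherwise. FDR is BH step-up by default with a Storey-type pFDR variant
(π₀ estimated at λ = 0.5) behind a flag. Consistency calling takes one
result table per comparison and reports per-lipid significance flags, the
lipids significant in every comparison, the union, and per-class tallies.

## Synthetic data: what it does and does not show

Worm images are parametric sines rendered by exact disk stamping (via a
distance transform), blurred, with an illumination gradient and additive
Gaussian noise; the truth length is quadrature-exact. Real L1 images add
out-of-focus blur, touching debris and coiled postures that the generator
does not emulate — passing tests bound algorithmic bias, not robustness
to every imaging pathology (coils are only flagged). The imaging noise
model is a stand-in, not a claim about real optics.

Count matrices are NB draws with log-normal gene means (log-mean 4, sd
1.5), dispersion trend α(µ) = a₀ + a₁/µ (defaults 0.01 + 1/µ — the
parametric family consistent with a local-regression fit), log-normal
size factors, and spiked ±lfc log2 fold changes; real data add outliers,
batch structure and correlated genes. The reference time course uses
per-gene monotone log-linear trends, so adjacent timepoints correlate
more than distant ones; real embryo series are not monotone for all
genes.

Lipid tables are log-normal with two variance components: per-cell
replicate noise (0.08 log₁₀, ~20% CV — typical for internal-standard
corrected LC-MS biological replicates) and a per-sample global scale
(0.1 log₁₀) emulating extraction/loading variation, which total
normalization removes. Non-detects in `gen_lipid_table` are uniform
per-cell dropouts; the acceptance script's time-course panel instead
censors below a fixed detection limit and gives lysophospholipid classes
1–2 orders lower abundance than storage/membrane classes, because
uniform dropout of an abundant analyte is not how LC-MS non-detection
behaves and a dense high-abundance spike-in would violate the
compositional assumption behind total normalization.

## Problem sizes

Defaults used by the test suite and acceptance script: 100 synthetic
worms for morphometry accuracy; 100 noisy trajectories for logistic
recovery; 200 cohorts × 15 windows (B = 300) for ratio-bootstrap null
coverage; 1000 simulations (B = 1000) for effect-size CI coverage; 2000
genes for the null-uniformity check and 20 × 5000 genes for the spiked-DE
error control; a 100-lipid, 19-sample panel for the lipid time-course
analysis. These sizes give stable estimates of each property while
keeping a full run in the low minutes on one CPU.
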