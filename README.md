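# nemaquant

Quantitative phenotyping and molecular profiling for *Caenorhabditis
elegans*, built for studies that combine image-based morphometry,
long-term growth imaging, bulk RNA-seq and LC-MS lipidomics — for example
when characterizing the developmental phenotype of a mutant such as the
dsRNA-uptake receptor *sid-2*.

The package is aimed at worm labs and bioinformaticians who need the
computational half of such a study as tested, reusable code: every stage
can be exercised on synthetic data with known ground truth, so each
estimator's accuracy is measurable without any raw data download.

## What it computes

**Morphometry** — larval body length from a single grayscale image:
intensity thresholding (Otsu by default), largest-component cleanup,
topology-preserving skeletonization, extraction of the geodesically
longest skeleton path (which prunes side branches), and its length in µm.
`path_length` is the exact chamfer metric (orthogonal steps 1 px,
diagonal √2 px); `measure_worm_length` by default smooths the path
coordinates with a 5-px moving average before summing Euclidean segments,
which removes the pixelation bias of thinned skeletons.

**Growth and development** — per-animal length series L(t) are summarized
by the 3-parameter logistic

    L(t) = L_max / (1 + exp(−r (t − t₀)))

with least-squares fits of (L_max, r, t₀); median growth curves carry
bootstrap CIs of the median; developmental timings decompose as
generation = ex-utero + larval; and cohorts are compared by a windowed
bootstrap of length ratios: 15 half-open windows of 4 h 16 min tiling
[0, 64 h], within each window B = 1000 mutant/wild-type measurement pairs
drawn with replacement (pairs more than 1.5 h apart in real time are
rejected and redrawn), reporting the mean ratio and percentile CI.

**Estimation statistics** — Gardner-Altman-style effect sizes: the
bootstrap mean difference (and percent-of-control) with a BCa confidence
interval (expanded percentile levels for small samples, percentile
fallback when the acceleration is undefined), plus hatch-rate summaries.

**Transcriptome** — from a gene × sample count matrix: median-of-ratios
size factors against a geometric-mean pseudoreference, method-of-moments
NB dispersions with a locally-regressed mean–dispersion trend, an exact
conditional NB test per gene (conditioning on the gene's total count),
Benjamini-Hochberg FDR, DE calls at q < 0.01 and |fold change| > 2, PCA
of log₂(x+1)-centered expression, and projection of query samples onto
the top-10 principal axes of a reference developmental time course with
nearest-reference-timepoint ("pseudotime") labelling.

**Lipidome** — detection filtering (detected in ≥ ⌊n/2⌋+1 samples;
all-samples rule available), per-sample total normalization, log₁₀ +
z-score transform for PCA, pooled-variance two-sample t-tests with BH
FDR, and consistency calling across timepoint comparisons.

**Synthetic data** (`nemaquant.synthio`) — generators for every input
with recorded ground truth: sinuous worm images with quadrature-exact
centerline lengths, logistic growth series, NB count matrices with known
size factors / dispersion trend / spiked fold changes, smooth reference
time courses, and log-normal lipid tables.

## Worked example

```python
import numpy as np
from nemaquant import synthio
from nemaquant.morphometry import WormImage, measure_worm_length

img, truth = synthio.gen_worm_image(210.0, amplitude_um=20.0, seed=11)
m = measure_worm_length(WormImage(img, truth.px_size_um))
print(f"true {truth.centerline_length_um:.1f} um, measured {m.length_um:.1f} um")
```

prints

```
true 210.0 um, measured 208.7 um
```

a 0.6% error on a curved ~L1-scale larva. The same round trip at the
cohort scale (100 worms, 150–300 µm, varied curvature and noise) gives a
median absolute relative error of about 0.6%.

The command line chains stages into reproducible runs (identical config
and seed ⇒ byte-identical CSVs):

```bash
nemaquant simulate --outdir sim/ --n-worms 5 --seed 7
nemaquant measure-length --images sim/ --out lengths.csv
nemaquant growth-fit --lengths sim/growth.csv --out fits.csv
nemaquant rnaseq-de --counts counts.tsv --samples samples.csv --out de.csv
```

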