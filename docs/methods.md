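# Methods

This note documents the models, parameter choices and numerical conventions
behind `cervitex`, and what the synthetic data generator does and does not
emulate.

## Pipeline and protocol

Source micrographs are 512×512 8-bit grayscale images, 45 per class (normal,
benign, malign) per modality (SEM, AFM). Each is cut into four disjoint
256×256 quadrant tiles, indexed row-major (0 top-left … 3 bottom-right) with
0-based (row, col) coordinates; tiling and re-mosaicking are bit-exact
inverses. Non-512×512 inputs are rejected rather than resized, because
resampling changes texture statistics silently.

The train/test split is a seeded uniform stratified draw at the **tile**
level: exactly half the tiles of every (modality, class) stratum train the
classifiers, so the standard protocol gives 270/270 with 90 training tiles
per class. Tile-level splitting means sibling tiles of one source image can
land on both sides; an optional source-level mode (`by_source=True`) avoids
this leakage but changes the counts (45 sources per class cannot be halved
evenly), so it is off by default. The leakage has a measurable effect: at
zero class separation the mean per-class recall of the tile-level protocol
sits slightly above chance (≈34–36 % rather than 33.3 %) because classifiers
can memorize source-specific texture. This is a property of the protocol
itself, not of the classifiers.

## Wavelet decomposition

Sixteen families are supported: db2–db5, bior1.5/1.3/2.8/3.3, coif2–coif5,
sym2–sym5 (this is also the canonical column order of reports). Tiles are
cast to float64 without prior normalization and decomposed with a separable
2-D DWT iterated three times on the approximation branch; the four bands of
the coarsest stage (CA, CD1 horizontal, CD2 vertical, CD3 diagonal) feed the
feature extractor. Boundary handling is periodization, so a 256×256 tile
yields exactly 32×32 sub-bands and orthogonal families conserve energy to
rounding error; the full coefficient tree is retained, making the transform
invertible to < 1e-8 for all 16 families. Levels other than 3 are supported
but not used by the protocol.

## Texture features

Each sub-band is min–max quantized into G = 16 equal-width levels **per
band**, because detail- and approximation-band dynamic ranges differ by
orders of magnitude. A span below 1e-8 (relative to band magnitude) is
treated as constant so that floating-point dust in analytically-zero bands
(e.g. details of a constant tile) does not masquerade as texture.

The co-occurrence matrix pools pair counts at distance 1 over the four
angles 0°/45°/90°/135° into a single matrix, symmetrizes by adding the
transpose, and normalizes to unit sum. Pooling (rather than averaging
features over per-angle matrices) was chosen for rotation robustness and
fewer knobs; both the angle set and symmetry are configurable. The ten
features use standard co-occurrence definitions (see README); entropy is in
bits (the base only rescales weights, it cannot change classification
ranks); `mean` and `standard_deviation` are GLCM marginal statistics by
default so all ten features are functions of one estimated object, with
`stats_source="band"` switching to raw sub-band moments. A degenerate GLCM
with zero marginal spread gets correlation 0 by convention.

## Divergence weighting and classification

Features are discretized into R = 10 equal-frequency bins computed on the
pooled (label-blind) training values; interior quantile edges that coincide
with the data extremes are dropped, so a constant feature degenerates to a
single bin and automatically receives zero weight. Class-conditional bin
histograms are Laplace-smoothed with α = 1; R and α are free parameters of
the method (no canonical values exist) and were fixed once at these
conventional defaults.

Three divergences score feature separability. The default `jsd` form is a
per-bin Bernoulli Kullback–Leibler sum symmetrized as the mean of both
orders; the textbook Jensen–Shannon divergence (mixture form) is available
as `form="standard"`. The default `hd` form is the squared-difference sum
Σ(p−q)², with the textbook squared Hellinger distance Σ(√p−√q)² as the
alternative; `td` is triangular discrimination Σ(p−q)²/(p+q) with 0/0 := 0.
The defaults favour the forms as printed in the protocol this package
implements; both alternatives are switchable per classifier and all
divergences as implemented are symmetric, non-negative, and zero iff the
arguments agree.

The raw weight of feature p is the mean divergence over the three unordered
class pairs of its class-conditional distributions — the only reading that
yields one scalar per feature from three classes. Raw weights are divided by
the pooled marginal bin entropy H(p) = −Σ P log P (natural log; entropy
rather than the sign-flipped sum, which would be negative) and rescaled by a
constant z so they sum to one; the scale of the weight vector only
sharpens or flattens the product-rule scores, so sum-to-one is the canonical
normalization. If every raw weight is zero the classifier falls back to
uniform weights with a warning.

Classification is the weighted product rule in log domain,
score(c) = log P(c) + Σ_i W(i) log P(bin(a_i) | c), with out-of-range
feature values clamped to the edge bins and ties broken in the fixed label
order normal < benign < malign. One classifier is trained per (family,
divergence, modality): 16 × 3 × 2 models.

## Reporting arithmetic

The classification rate of a class is its recall on the test tiles, in
percent. All reported numbers are **truncated toward zero** at two decimals,
not rounded — the convention was verified against the published summary
values (e.g. a three-algorithm mean of 98.296… reports as 98.29). Decimal
arithmetic is used on printed-precision operands so binary floating point
cannot perturb the truncation boundary; full-precision grids are retained
and written to a companion CSV. Row averages are means of the three class
rates; algorithm averages are means over the 16 families; the per-modality
grand average is the mean of the three algorithm averages. Two row cells of
the published AFM table are inconsistent with their own class cells
(hd/sym2, td/bior1.5); `reference_tables.KNOWN_ROW_DISCREPANCIES` records
them, and the published per-algorithm averages reproduce from the published
row cells.

## AFM metrology

Roughness is computed after subtracting the least-squares best-fit plane
(standard tilt correction); Rq is the RMS deviation and Ra the mean absolute
deviation, in nm, with Rq the default. Particles are 8-connected components
of the mask heights > threshold; the default threshold is Otsu's level on
the height histogram, overridable in nm. Volume integrates
(height − threshold) × pixel_size² over particle pixels with nm→µm
conversion, so totals are in µm³ — the ambiguous length-unit "volume"
figures that AFM vendors report are treated as ordering information only and
never reproduced numerically.

## Synthetic generator

Each image is a self-affine Gaussian random field (white noise shaped by a
radial spectral filter f^(−β/2), DC removed) plus soft-edged particle mesas
(tanh radial profile, plateau radius r, edge width r/4) at class-dependent
density, radius and amplitude. In AFM mode the composed surface is rescaled
so its plane-detrended RMS roughness equals the class target exactly; in SEM
mode the same surface is standardized and mapped affinely to 8-bit with a
class gain plus additive Gaussian read noise.

Default class parameters (separation 1):

| class  | β   | target Rq (nm) | particles | radius (px) | amplitude (×RMS) | SEM gain | SEM noise (gray) |
|--------|-----|----------------|-----------|-------------|------------------|----------|------------------|
| normal | 3.4 | 50.23          | 52        | 20          | 8                | 28       | 0.8              |
| benign | 2.4 | 244.654        | 36        | 9           | 8                | 44       | 4.0              |
| malign | 1.5 | 456.145        | 10        | 5           | 24               | 60       | 9.0              |

The roughness targets are the reported class measurements used as generator
parameters, not as claims. Particle density/radius/amplitude were chosen
once so that the Otsu-thresholded **total** particle volume is smallest for
the malign class with normal and benign of the same order, mirroring the
reported ordering (the published per-class "volume" figures cannot be
matched numerically because their unit is a length). Otsu segmentation needs
the particle population to be visible against the background height
histogram; the chosen coverages keep the bump/background split dominant for
every class. Because absolute bump height scales with the class roughness
target, malign images carry few, small, tall particles — their mean
per-particle volume is not ordered the same way as the total.

The `separation` knob shrinks every class parameter linearly toward the
cross-class mean; at 0 the three classes are identically distributed. Each
image's RNG stream derives from a SHA-256 hash of (seed, modality, class,
index), so datasets are reproducible file by file and any subset can be
regenerated independently.

What the generator does **not** emulate: electron-optics artifacts (charging,
edge brightening), AFM tip convolution and line artifacts, cell morphology
(membranes, organelles — the fields are statistically homogeneous), and
inter-patient variability. Passing tests therefore demonstrate that the
pipeline recovers the class contrasts the generator encodes — spectral slope,
roughness scale, particulate content, noise level — not that the published
clinical accuracies would be reproduced on real micrographs.

## Problem sizes used by the test suite and reproduction script

Unit and property tests run on small rasters (16–256 px) and 2–10 images per
class. The reproduction script uses the full 45 images/class protocol for
counting and metrology, 10 images/class (120 tiles per split) for the
48-classifier separability check, and 15 images/class over five seeds for
the zero-separation chance check — sizes at which every quantity it reports
is stable across seeds.

## Known limitations

- The divergence-weighting scheme assumes conditionally independent binned
  features (naive Bayes); strongly correlated wavelet features violate this,
  which is acceptable for ranking classes but makes the scores poorly
  calibrated as probabilities.
- Equal-frequency binning with R = 10 needs ≳ a few dozen training samples
  per class; far smaller training sets silently degrade to coarse bins.
- The tile-level split overstates accuracy whenever sibling tiles correlate;
  use `by_source=True` for leakage-free estimates.
- Otsu's threshold is only meaningful when particles occupy a visible mode
  of the height histogram; supply an explicit threshold for sparse or very
  rough samples.
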