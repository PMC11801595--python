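# cervitex

Wavelet/GLCM texture classification of cervical SEM and AFM micrographs with
divergence-weighted classifiers, plus AFM surface metrology and a seeded
synthetic data generator.

## The problem

Early grading of cervical cell samples can draw on two kinds of microscopy:
scanning electron microscopy (SEM), which images surface texture, and atomic
force microscopy (AFM), which additionally yields quantitative height maps.
Diagnostic classes (normal, benign, malign) differ in surface texture,
roughness and particulate content. This package implements a complete
texture-classification protocol for such micrographs, aimed at researchers in
quantitative microscopy and biomedical image analysis:

1. **Tiling.** Each 512×512 8-bit micrograph is cut into four non-overlapping
   256×256 quadrants. With 45 source images per class per modality this gives
   3 × 4 × 45 = 540 tiles, split half/half (stratified by class) into 270
   training and 270 test tiles.
2. **Wavelet decomposition.** Each tile is decomposed with a level-3
   separable 2-D discrete wavelet transform under one of 16 wavelet families
   (db2–db5, bior1.3/1.5/2.8/3.3, coif2–coif5, sym2–sym5), yielding the
   coarsest-stage approximation CA and details CD1/CD2/CD3 (32×32 each under
   periodization).
3. **Texture features.** Each sub-band is quantized to G = 16 gray levels and
   summarized by a pooled symmetric gray-level co-occurrence matrix (GLCM),
   from which 10 features are computed — homogeneity, contrast, angular
   second moment, entropy, mean, standard deviation, correlation, cluster
   prominence, dissimilarity, cluster shade — a 4×10 feature matrix per tile
   per family.
4. **Divergence-weighted classification.** Features are discretized into
   R = 10 equal-frequency bins; class-conditional bin distributions
   P(bin | c) are estimated with Laplace smoothing. Each feature p gets a
   separability weight: the mean divergence over the three class pairs,

       W_av(p) = mean over class pairs (t,u) of D(P_t, P_u),

   where D is one of Jensen–Shannon (JSD), squared-difference
   Hellinger-style (HD), or triangular (TD) divergence. Weights are
   normalized by the pooled bin entropy H(p) and rescaled to sum to one,
   W(p) = W_av(p) / (z·H(p)). A tile with features a_1..a_40 is classified
   by the weighted naive-Bayes product rule

       ĉ = argmax_c P(c) · ∏_i P(bin(a_i) | c)^W(i)

   (computed in log domain). One classifier is trained per (wavelet family,
   divergence), 48 per modality.
5. **Reporting.** Per-class test recall in percent is assembled into a
   3 algorithms × 16 families × 3 classes grid with per-family row averages,
   per-algorithm 16-family averages and a per-modality grand average, all
   truncated (not rounded) to two decimals.

The package also provides AFM metrology — RMS/mean surface roughness after
plane detrending (nm) and Otsu-thresholded particle volume (µm³) — and a
seeded generator of synthetic three-class SEM-like micrographs and AFM-like
height maps (self-affine Gaussian random fields plus particle mesas) whose
class contrasts follow the reported measurements: roughness
50.23 / 244.654 / 456.145 nm for normal / benign / malign, particle volume
smallest for malign.

## Worked example

```python
from cervitex import afm
from cervitex.synthetic import SyntheticConfig, generate_class_image
from cervitex.pipeline import run_synthetic_experiment

cfg = SyntheticConfig(n_images_per_class=5, seed=7)

hm = generate_class_image(cfg, "malign", "AFM", 0)
print(f"Rq = {afm.surface_roughness(hm):.3f} nm")
stats = afm.particle_volume(hm)
print(f"particles: {stats.count}, volume = {stats.total_volume_um3:.4f} um^3")

rep = run_synthetic_experiment(cfg, "SEM", families=["db2", "sym2"],
                               divergences=["jsd", "hd", "td"])
print(rep.to_frame())
```

prints

```
Rq = 456.145 nm
particles: 10, volume = 0.9709 um^3
               db2   sym2
normal_jsd   100.0  100.0
benign_jsd   100.0  100.0
malign_jsd   100.0  100.0
average_jsd  100.0  100.0
...
```

The malign-class height map reproduces its configured RMS roughness exactly
and its particle volume is the smallest of the three classes; on this small
well-separated synthetic dataset every divergence classifier reaches 100 %
per-class recall (rows are per-class recall in percent; each `average_*` row
is the truncated mean of the three class rows above it).

The same steps are scriptable from the shell:

```bash
cervitex generate --modality SEM --out data/sem --seed 7 --n-per-class 45
cervitex tile --in data/sem/manifest.csv --out data/tiles --manifest tiles.csv
cervitex split --manifest tiles.csv --seed 7
cervitex extract --manifest tiles.csv --families all --out features.csv
cervitex train --features features.csv --divergence jsd --family db2 --out db2_jsd.json
cervitex predict --model db2_jsd.json --features features.csv --out pred.csv
cervitex metrology --in map.tif --pixel-size 0.02 --out metrics.csv
```

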