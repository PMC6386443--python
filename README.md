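# glcminv — gray-level-invariant Haralick texture features

Haralick texture features are scalar descriptors (contrast, correlation,
entropy, energy, …) computed from the gray-level co-occurrence matrix
(GLCM) of an image, and are widely used in medical image analysis and
radiomics. Their Achilles' heel is the quantization step: before the GLCM
is built, image intensities on a range [a, b] are reduced to N discrete
gray-levels, and the resulting feature values depend strongly on N. A
contrast value computed at 32 gray-levels cannot be compared with one
computed at 128, so models built at one quantization do not transfer to
data quantized differently.

`glcminv` implements a modified feature set that removes this dependence.
The classical normalized GLCM

&nbsp;&nbsp;&nbsp;&nbsp;P = X / ΣᵢΣⱼ X(i, j)

is a probability *mass* function over gray-level pairs, and its entries
shrink as N grows. Reinterpreting the same counts as a discretized
probability *density* on the unit square,

&nbsp;&nbsp;&nbsp;&nbsp;P̃ = X / (ΣᵢΣⱼ X(i, j) · Δᵢ Δⱼ),&nbsp;&nbsp;&nbsp;&nbsp;Δᵢ = Δⱼ = 1/N,

keeps the Riemann volume Σ p̃(i, j)/N² = 1 at every quantization. Each
feature is then rewritten as a Riemann sum approximating an integral over
the pair density: indices i, j are mapped to i/N, j/N ∈ (0, 1], and every
sum carries the appropriate cell differential (1/N for marginal sums,
1/N² for joint sums, 1/(2N−1) for the sum-marginal). As N → ∞ these sums
converge to fixed integrals, so the features become asymptotically
invariant to the quantization. Most invariant features are exact
rescalings of the originals (e.g. Contrast/N², N²·Energy,
Entropy − 2 ln N, with Correlation unchanged), so their interpretations
are preserved; the entropy family becomes differential entropy (and can
be negative), and maximum probability becomes the density at the mode.

The package provides:

- quantization, dithering, displacement-vector sets (8/4 offsets in 2D,
  26/13 in 3D), co-occurrence counting with optional ROI masks, and both
  normalizations (`glcminv.glcm`);
- all 20 texture features in both formulations, including the marginal
  statistics, the Q matrix and the maximal correlation coefficient
  (`glcminv.features`);
- synthetic data: GLCMs discretized from bivariate Gaussian densities and
  two-class Gaussian-random-field textures (`glcminv.synthetic`);
- cross-quantization classification experiments with logistic regression
  and forward feature selection (`glcminv.experiments`);
- a CLI (`glcminv features | glcm | synth | benchmark`) reading PNG/TIFF
  (2D) and NIfTI (3D) with CSV/JSON output (`glcminv.cli`).

## Worked example

Compute features from one continuous synthetic texture at three
quantizations (quantization limits taken from the image histogram):

```python
from glcminv import (QuantizationSpec, compute_all,
                     gaussian_random_field, glcm_from_image)

img = gaussian_random_field((128, 128), correlation_length=3.0, seed=42)
lo, hi = float(img.min()), float(img.max())
for variant in ("original", "invariant"):
    print(variant)
    for n in (16, 64, 256):
        spec = QuantizationSpec(n_levels=n, lower=lo, upper=hi)
        f = compute_all(glcm_from_image(img, spec, variant=variant)).values
        print(f"  N={n:3d}  contrast={f['contrast']:.4g}  energy={f['energy']:.4g}  "
              f"entropy={f['entropy']:.4g}  correlation={f['correlation']:.4g}")
```

```
original
  N= 16  contrast=0.5314  energy=0.05507  entropy=3.269  correlation=0.9436
  N= 64  contrast=5.987  energy=0.004211  entropy=5.847  correlation=0.9595
  N=256  contrast=93.32  energy=0.0002783  entropy=8.537  correlation=0.9605
invariant
  N= 16  contrast=0.002076  energy=14.1  entropy=-2.276  correlation=0.9436
  N= 64  contrast=0.001462  energy=17.25  entropy=-2.471  correlation=0.9595
  N=256  contrast=0.001424  energy=18.24  entropy=-2.553  correlation=0.9605
```

The original contrast grows by a factor ~175 and energy shrinks by ~200×
between N = 16 and N = 256 — the same texture, different numbers. The
invariant contrast, energy and entropy settle to a plateau (the residual
drift between N = 64 and 256 is a few percent), and correlation is
identical in both formulations. The invariant entropy is negative because
it is a differential entropy.

The same computation from the shell:

```bash
glcminv synth --n-per-class 1 --shape 128 128 --seed 42 --out demo/
glcminv features demo/sample_0000_class0.tiff --levels 64 --variant invariant --out demo/features.csv
```

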