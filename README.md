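# lmsf — local mean suppression filtering for fluorescence images

Fluorescence microscopy images of tissue mix bright nuclei, dim low-contrast
objects, and a noisy, non-uniform background. Separating foreground from
background reliably — without a trained model, and without destroying faint
objects — is the problem this package addresses. It is aimed at image-analysis
practitioners who need a fast, unsupervised background-identification and
denoising step in front of quantification or instance segmentation.

## The filter

The local mean suppression filter (LMSF) is a pixel-wise nonlinear operator.
For an image I(k, m), let Ī(k, m) be the mean intensity over the
(2n + 1) × (2n + 1) window centered at the pixel, clipped to the image domain
and divided by the number of available pixels (adaptive averaging — no
padding). Then

    Î(k, m) = 0        if I(k, m) / Ī(k, m) < θ
    Î(k, m) = I(k, m)  otherwise

so a pixel is labeled background (zeroed) when it falls strictly below a
fraction θ of its local mean; kept pixels are bit-identical to the input.
The half-window n is bounded by n_max = ⌊min(K, M)/2⌋ − 1.

Background identification combines the filter across a set of scales
N = {n₁ < n₂ < …}: each scale is applied to the *original* image, and a pixel
is background if **any** scale labels it background (the union of per-scale
backgrounds, i.e. the Boolean product of per-scale foregrounds). Small n
catches narrow gaps between crowded nuclei; large n catches wide, gradually
varying background. θ = 0.5 is a good default; 0.5 ≤ θ ≤ 1 (up to ≈1.1 for
very fuzzy foregrounds) is the practical range. A rule of thumb picks N from
the widest background gap: `select_scales(80)` → {5, 10, 20, 40}, optionally
appending n_max for images with an extended background.

Local means use summed-area tables, so runtime is independent of n —
1000 × 1000 images with n up to 499 are processed in well under a second per
scale.

## Worked example

```python
import numpy as np
from lmsf import (PRESETS, gen_nuclei_image, preset_filter_params,
                  cumulative_lmsf, background_f1)

image, truth = gen_nuclei_image(PRESETS["large-background"])
theta, scales = preset_filter_params("large-background", image.shape)
filtered, background = cumulative_lmsf(image, scales, theta)
print("theta", theta, "scales", scales)
print("background fraction", round(background.mean(), 3))
print("background F1 vs truth", round(background_f1(background, truth.background), 3))
```

prints

```
theta 0.5 scales (5, 10, 20, 40, 127)
background fraction 0.837
background F1 vs truth 0.961
```

i.e. on a synthetic 256 × 256 scene of sparse bright and dim nuclei the
multi-scale filter labels 84% of the pixels background and agrees with the
generator's ground-truth background mask at pixelwise F1 ≈ 0.96. `filtered`
is the image with those pixels zeroed and every kept pixel untouched.

The same pipeline is available from a shell:

```bash
lmsf fixtures --preset large-background --out fx/
lmsf background fx/large-background.tif --theta 0.5 --max-gap 80 \
     --large-background --out out/
lmsf coloc stack.tif --theta 0.5,0.95,0.6 --scales 5,10,20,40,80,160,499 --out co/
```

Each run writes the filtered TIFF, an 8-bit mask PNG (foreground white by
default), and a JSON manifest with parameters and output checksums.

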