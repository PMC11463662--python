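# Methods

## The filter and its assumptions

The local mean suppression filter compares each sample or pixel to the mean
of its local neighborhood and zeroes it when the ratio falls *strictly* below
a threshold θ. The model assumption is that fluorescence background is
locally dim relative to its surroundings at *some* spatial scale: narrow
inter-nuclear gaps are dim relative to small neighborhoods that include the
adjacent bright nuclei, while wide empty regions are dim relative to large
neighborhoods that reach the nearest foreground. Intensities are assumed
non-negative (fluorescence counts); negative inputs are rejected rather than
clipped, since the ratio test is meaningless for signed data.

The 1-D analog form of the filter (continuous-time local mean over a window
of half-length T) is realized only by dense sampling followed by the digital
filter with n ≈ T/Δt; no symbolic integration is performed.

### Adaptive averaging

Local means near the borders divide the clipped-window sum by the count of
available samples (n + 1 values at an end point, n + 2 at the next, …). No
padding of any kind is used, which avoids edge artifacts that constant or
reflective padding would introduce. The same rule applies in 2-D with
rectangular clipped windows. This makes the mean well defined for any
half-window n ≥ 1 — even windows larger than the image, which degenerate to
the global mean. The bare mean operators therefore accept any n ≥ 1, while
the filter entry points enforce n ≤ n_max = ⌊min(K, M)/2⌋ − 1, the largest
scale at which a window can still distinguish local from global structure.

### Cumulative multi-scale response

Each scale in N is applied to the original image (never to a progressively
zeroed intermediate), and the cumulative background is the pixelwise union of
the per-scale backgrounds — equivalently the Boolean product of the
per-scale foreground indicators. Union is associative and commutative, so the
result is independent of scale order, and adding a scale can only grow the
background. Pixels kept as foreground carry their exact input value; the
filter never smooths.

## Parameters

- **θ (threshold)** — dimensionless ratio cutoff; default 0.5. Lowering θ
  risks labeling true background as foreground, raising it the opposite. The
  practical range is 0.5–1.0, with values up to ≈1.1 useful when foreground
  and background intensities overlap heavily ("fuzzy" foreground). The
  comparison is strict, so a constant image with θ = 1 is entirely
  foreground (ratio exactly 1).
- **n (half-window)** — pixels; the averaging window is (2n+1)². Small n
  resolves narrow gaps, large n wide gradual background. Bounded by n_max.
- **N (scale set)** — `select_scales` derives N from the widest
  background-gap width g: max(N) = ⌊g/2⌋, then repeated integer halving down
  to `min_scale` (default 5). For images with an extended background,
  n_max is appended so the widest window captures long-range variation;
  halving values above n_max are dropped. Scale sets are deduplicated and
  sorted, and scales above n_max raise an error rather than being silently
  clamped, keeping runs reproducible.

Documented per-regime presets: θ = 0.5 with gap-derived scales plus n_max for
large-background images; θ = 0.5 with N = {5, 10, 20, 40} for dense
large-foreground images (also the denoising default); θ ≈ 0.95 with the
extended scale family for fuzzy foregrounds; per-channel θ of 0.5 / 0.95 /
0.6 for nuclei / nuclear-membrane / cell-membrane channels in the
co-localization use case.

## Numerical choices

- Local means use summed-area tables with clipped-window pixel counts, so
  per-pixel cost is independent of n. Integer images accumulate exactly in
  int64 (no overflow up to 16-bit intensities on any realistic image size);
  floating-point images accumulate in float64.
- The ratio test is evaluated as `value · count < θ · window_sum`, avoiding
  a division. For integer inputs this makes strictness exact; for float
  inputs it holds at float64 precision. A zero window sum implies every
  pixel in the window is zero (non-negative data), so the pixel itself is
  zero and is labeled background outright, avoiding 0/0.
- Zero pixels are always background for θ > 0 (ratio 0), including the
  all-zero-window degenerate case above.
- Kept pixels are returned bit-identical in the input dtype.
- The fast means are validated against a naive per-pixel clipped-window
  oracle (≤ 1e−9 relative) and cross-checked against an independent
  scipy.ndimage route (uniform filtering of the zero-padded image and of a
  ones image, whose quotient reproduces the clipped-window mean).

## Synthetic scenes: what they emulate and what they do not

`synth` generates nuclei-like scenes: Gaussian-profile blobs (bright and
dim, optionally clustered) over a dim background with a linear gradient and
additive zero-truncated Gaussian noise. Blob sigma is set so the profile
falls to `support_fraction` (default 10%) of its peak exactly at the drawn
radius; ground-truth foreground is the union of those disks, background its
complement. Smooth Gaussian edges mimic the gradual foreground-to-background
transitions that make real fluorescence images hard to threshold globally.

Three frozen presets mirror the practical regimes: `large-background`
(sparse nuclei, ~10% foreground), `large-foreground` (clustered nuclei, ~40%
foreground, narrow gaps), and `fuzzy-foreground` (peaks only ~4–7× the
background offset, noise sd 2). Preset scene parameters and the documented
filter settings were chosen once to represent each regime and frozen; the
recovery check asserts pixelwise background F1 ≥ 0.90 on them (measured
0.96 / 0.95 / 0.91).

Not emulated: PSF convolution, Poisson shot noise, camera gain/offset
structure, autofluorescence texture, and tissue-scale intensity
heterogeneity. Passing the recovery check therefore shows that the
multi-scale union logic and parameter heuristics behave as designed on
controlled scenes with known truth — not that any particular F1 will be
attained on real tissue images.

## Design choices where the design was open

- **Per-scale masks on the original image.** The alternative — sequentially
  re-filtering the progressively zeroed image — was not implemented: zeroed
  pixels would drag down local means at later scales and erode foreground
  edges, and it would make the result depend on scale order. The union of
  independent per-scale backgrounds is order-invariant and matches the
  qualitative behavior the method is built on (small scales contribute
  narrow gaps, large scales wide regions).
- **Class-map bit encoding.** Channel 0 is the least significant bit, so a
  pixel foreground in channels 0 and 2 of a 3-channel stack has label 5.
  Any fixed encoding would do; this one makes labels directly readable in
  binary and is recorded in the written legend JSON.
- **Mask polarity.** Written mask PNGs default to foreground = 255 /
  background = 0 (the common display convention); a flag flips the written
  file only, never the in-memory mask.
- **Gamma display** normalizes by the image maximum, not the dtype maximum,
  so integer and float inputs display identically; it is display-only and
  never fed back into filtering.
- **No registration.** Multi-channel inputs must be pre-registered; a shape
  mismatch is an error, not a resampling trigger.

## Problem sizes

The test suite runs on synthetic inputs only: random images up to 32 × 32
for oracle equivalence (with every admissible n), 256 × 256 preset scenes
for the recovery checks, and ~19k-sample sine-squared signals for the
1-D cutoff experiments. These sizes exercise every code path, including
n = n_max, while keeping the full suite under half a minute.

## Known limitations

- A bright isolated speck in a wide empty region survives every scale (its
  ratio is high at all window sizes); the method by design preserves it, so
  hot pixels should be removed upstream if they are artifacts.
- Background whose intensity exceeds θ × (local mean) at every scale — e.g.
  a uniformly lit field with no foreground anywhere in the image — is kept
  as foreground; the method assumes some foreground exists to pull local
  means up.
- θ is global per channel; spatially varying contrast within one channel may
  need the fuzzy-foreground treatment (sweeping θ) rather than a single run.
- Integer exactness of the strict comparison does not extend to float inputs
  whose window sums are inexact in float64; discrepancies are confined to
  ratios within ~1e−15 of θ.
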