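# Methods

## Problem setting

Medical segmentation masks are typically background-dominated (extreme class
imbalance) and separate tissues whose intensity distributions overlap
heavily (weak boundaries).  Pixel-wise losses — cross-entropy, Dice, focal —
average over the whole grid, so the easy far-from-boundary pixels dominate
both the loss value and its gradient, and the decision boundary drifts
toward the majority class exactly where it matters least.

This package implements a boundary-aware alternative: a **narrow-band
active-contour (NB-AC) loss** that restricts a Chan–Vese-style region energy
to a fixed-width band around the ground-truth boundary, together with the
two-branch encoder–decoder architecture that supplies the contour and band
maps it needs, baselines to compare against, overlap metrics, and a phantom
generator that reproduces the two data pathologies synthetically.

## The narrow band

For a binary mask `y`, the band is built discretely in two steps:

1. **Edge extraction (χ).**  A fixed smoothed central-difference stencil
   (the Sobel kernel normalized so a unit-slope ramp responds with exactly
   1): the derivative along each spatial axis is the central difference
   `(F[i+1] − F[i−1]) / 2` smoothed with `[1/4, 1/2, 1/4]` along the other
   axes, with replicate padding; the edge map is the root sum of squares.
   The smoothing term matters: pure axis-aligned central differences are
   blind to purely diagonal transitions at mask corners, while the smoothed
   stencil is strictly positive on every pixel whose 3×3 neighbourhood mixes
   both mask values.
2. **Band dilation (ζ).**  A grayscale dilation (moving-window maximum) with
   a B×B window (B×B×B in 3D), replicate-padded.  The window is square and
   therefore separable; `B = 1` is the identity.

The composition `ζ(χ(y))` is the ground-truth narrow band `F_ζχy`.  Its
binarization (`> 0`) splits by the mask value into an **inner band** (inside
`y`) and an **outer band** (outside), which partition the band exactly.

`B` defaults to 5 in 2D and 3 in 3D and is configurable; it trades
boundary-localization (small B) against gradient coverage (large B).  Both
χ and ζ are fixed, non-learnable operators by default, which keeps every
oracle test exact and training deterministic.  A learnable variant of χ
(a 3×3 convolution initialized to the same stencil) is available behind
`BackboneConfig(trainable_edge_kernel=True)`; it zero-pads as convolution
layers do, so it matches the fixed gate only away from the image frame.

## Losses

All trainable losses normalize every term by its domain's pixel count so
magnitudes are comparable across image sizes and the band terms do not
drown the length term on large grids.  (The classic Chan–Vese energy kept
as an evaluation-only reference uses unnormalized sums, matching its usual
statement.)  Probabilities are clamped to `[1e-7, 1 − 1e-7]` before
logarithms; soft Dice adds `1e-6` to numerator and denominator.

**Region loss (first branch).**  Categorical cross-entropy of the softmax
probabilities against the one-hot mask, averaged over pixels.

**NB-AC band loss (second branch).**  For one class with prediction `p`,
contour map `F_LC` and band map `F_LN`:

```
L2 = μ · mean|F_LC|  +  E_in  +  E_out
```

Three band-energy semantics are provided because the band's descriptor
domain can be defined in more than one defensible way:

- `two_sided` (default): `E_in = λ_in · mean over (band ∧ y=1) of
  (p − b_in)²` and symmetrically for the outer sub-band, with `b_in`/`b_out`
  the plain sub-band means of `p`.  This matches the picture of a
  homogeneity criterion on each side of the evolving curve and is the
  default.
- `band_vs_complement`: descriptors and energies weighted by the grayscale
  band `F_ζχy` and its complement (`b_in = Σ p·F / Σ F`, etc.).  With these
  weights the identity `ΣF · b_in + Σ(1−F) · b_out = Σp` holds exactly.
- `gated_domain`: energies of the gated prediction `p · F_LN` against the
  weighted descriptors, integrated over the whole grid.

The descriptors are treated as per-step constants (detached) by default,
the standard practice for Chan–Vese-style losses where the region means are
re-estimated each iteration; a flag enables full differentiation.  For the
mean-based modes the distinction is immaterial at the optimum (the
derivative through a mean of residuals that sum to zero vanishes), but for
the gated-domain mode it is not.

Band weights default to `μ = λ_in = λ_out = 1` (no published values exist);
the two branch losses combine as `0.5·L1 + 0.5·L2`, the published setting.

Multi-class handling: the band loss is computed per foreground class against
that class's one-hot band and averaged; classes whose mask is constant in a
patch are skipped with a warning rather than contributing a spurious 0/0.

**Baselines.**  Binary cross-entropy, soft Dice (per foreground class,
averaged), and focal loss.  The focal loss is implemented with the leading
minus sign so it is non-negative and reduces exactly to cross-entropy at
`γ = 0, α = 1`, consistent with its original formulation.  The
offset-curve (OsC) loss combines the region loss, a band energy gated by the
smooth Heaviside `H_ε(x) = ½(1 + (2/π)·arctan(x/ε))` of the prediction's
signed-distance level set, and the total variation of that level set over
the band.  The signed distance of a thresholded prediction is not
differentiable, so the level set (and hence the gate and the smoothness
term) is treated as a per-step constant; when the thresholded prediction is
constant the ground-truth level set substitutes.  `ε` defaults to 1 (no
published value).

**Signed distance.**  Exact Euclidean distance transform on each side of
the mask, positive inside, negative outside.  Distances are measured pixel
centre to pixel centre (no half-pixel boundary offset), which keeps the
brute-force nearest-opposite-pixel oracle exact.

## Architecture

The first branch is a standard encoder–decoder.  U-Net levels follow the
two-convolutions-plus-norm-plus-activation recipe with 2× max-pooling down
and 2× bilinear up-sampling plus skip concatenation up; batch normalization
and ReLU in 2D, instance normalization and leaky ReLU in 3D.  The FCN
variant taps stages 1, 3 and the final stage, projects each tap to the base
width, bilinearly up-samples to input resolution and sums — the exact stage
indices of the published "conv1, conv3, conv7" wiring are underdetermined,
so the taps clamp to the configured depth.

The second branch consumes the final decoder feature map `F_H`, applies one
residual block (two convolutions with identity skip; count configurable),
projects to one channel per class with a 1×1 convolution, and passes the
result through the transitional gate to produce `F_LC = χ(·)` and
`F_LN = ζ(F_LC)`.  The published description does not fix the number,
width or placement of the second-branch blocks; one full-resolution block
before the gate is the minimal faithful realization.  Because the gate is
differentiable, the band loss back-propagates through the second branch
into the shared encoder.

Training uses Adam with learning rate 1e-2 and weight decay 1e-4 (2D
defaults; 2e-4 is the published 3D learning rate), all config-exposed.

## Automatic differentiation

The package carries its own reverse-mode automatic-differentiation core
(`nbac.autodiff`, `nbac.nn`): a tape of numpy arrays with broadcast-aware
arithmetic, reductions, gathers, N-d convolution, pooling, bilinear
up-sampling and normalization layers, plus Adam.  Design points worth
noting:

- `sqrt` uses a zero subgradient at 0 so edge maps of locally constant
  fields have finite (zero) gradients;
- elementwise `maximum` splits the gradient equally on ties, and max-pooling
  distributes over tied window maxima;
- probability clamps pass no gradient outside the clamped interval;
- convolution accumulates offset-by-offset (one small channel contraction
  per kernel tap) rather than through an im2col buffer, which is what makes
  CPU training of the desk-scale models practical.

Gradient checks against central finite differences (with descriptors
pinned, matching the detached semantics) agree to better than 1e-4 relative
error.

## Phantom generator

The generator emulates the two target pathologies without reproducing any
real dataset's statistics:

- **Class imbalance**: target class proportions are realized by quantile
  thresholding of a smooth random field (blobs), quantile-sliced deformed
  radius fields (nested rings), or incrementally grown random-walk tubes of
  1–3 px radius (vessels).  Quantile assignment makes blob/ring proportions
  exact up to pixel rounding; vessels are grown until their measured area
  reaches the target and re-drawn (bounded retries) if any class misses its
  target by more than 20 % relative.
- **Weak boundaries**: per-class intensities are Gaussian,
  `clip(μ_c + σ_c·N(0,1))`, with adjacent means spaced `contrast_gap` apart
  (default 0.1 on a [0, 1] scale, i.e. means two noise standard deviations
  apart at the default σ = 0.05 — heavily overlapping histograms).
  Shrinking the gap provably shrinks the Bhattacharyya separation of
  adjacent-class histograms, which is the tested monotone knob.  An optional
  low-frequency multiplicative bias field emulates intensity inhomogeneity.

Identical seed and config give bit-identical phantoms; datasets written to
disk (PNG pairs in 2D, NIfTI in 3D) carry a JSON manifest with per-item
seeds, realized proportions and the config hash.

What the phantoms do **not** model: anisotropic voxel spacing, partial
voluming, acquisition artifacts, anatomically plausible shape priors, or
multi-modal channels.  Passing the smoke-training check therefore shows the
losses, gates and optimizer interact correctly end to end at desk scale —
not that the published clinical-dataset scores are reproduced.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on one CPU.  Oracle
suites use ≥ 50 random instances up to 16×16 (agreement within 1e-6);
gradient checks use 8×8 instances.  The smoke-training experiment — the
deliberately scaled-down analogue of a published loss-comparison table —
trains a depth-2, base-width-8 two-branch U-Net with the NB-AC loss for 150
steps (batch 8) on 64 three-class 64×64 weak-boundary phantoms
(`contrast_gap` 0.1, noise 0.05) and evaluates foreground macro-Dice on 16
held-out phantoms; the median over three seeds exceeds 0.85, typically
reaching ≈ 0.95.  The comparison harness runs {CE, Dice, focal, NB-AC}
under identical seeds and emits a per-loss/per-seed table with medians.

Other conventions: empty-class metrics score 1 when both masks are empty
and 0 when exactly one is; macro averages exclude the background class by
default; the validation split of on-disk datasets is a deterministic 80/20
by item index; training patches are whole 64×64 phantoms (no cropping
needed at this scale); a NaN loss aborts with a diagnostic dump of the
offending batch; gradient-norm clipping exists but is off by default.

## Known limitations

- The numpy autodiff core is single-threaded and eager; it is sized for
  desk-scale experiments, not for the published patch counts or volumes.
- The 3D path shares all loss and operator code with 2D but has only been
  exercised at small volume sizes.
- Band width `B` and the Eq.-level band weights have no published values;
  the defaults here are package choices, documented above.
- The `gated_domain` band mode and the default `two_sided` mode are
  genuinely different functionals; which one the original experiments used
  cannot be determined, which is exactly why all three are exposed.
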