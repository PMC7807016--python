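# Methods

## Problem and model

Cone-beam CT (CBCT) acquired on linac-mounted flat-panel systems guides
patient positioning in radiotherapy, but scatter, noise and reconstruction
artefacts blur the images and corrupt CT values badly enough (hundreds of
HU in soft tissue) that they cannot support dose calculation. This package
implements a bidirectional adversarial translation model that maps chest
CBCT slices toward fan-beam CT (FBCT) appearance.

Two generators are trained jointly, `G_CF: CBCT -> FBCT` and
`G_FC: FBCT -> CBCT`, against two patch critics `D_F` and `D_C`. The
critics minimise the Wasserstein objective with a gradient penalty
enforcing a 1-Lipschitz constraint:

    L_D = E[D(G(x))] - E[D(real)] + lambda * E[(||grad D(m)||_2 - 1)^2]

with the penalty evaluated at per-sample convex mixtures
`m = eps*real + (1-eps)*fake`, `eps ~ U[0,1]`. The generators minimise

    L_G = l_adv*L_adv + l_cyc*L_cycle + l_gen*L_generated
          + l_id*L_identity + l_sob*L_sobel

where

- `L_adv = -E[D_F(G_CF(x))] - E[D_C(G_FC(y))]`;
- `L_cycle` is the L2 norm of the round-trip residual image
  (`x - G_FC(G_CF(x))` and the mirrored direction), averaged over the batch;
- `L_generated` is the paired mean absolute residual `|y - G_CF(x)|` plus
  the mirrored direction — it requires aligned pairs and is disabled for
  unpaired data;
- `L_identity` is, by default, the *re-application* consistency
  `||G_CF(x) - G_CF(G_CF(x))||_2` (+ mirrored): a generator applied to its
  own output should change nothing. A config switch selects the classic
  cross-domain variant `||G_CF(y) - y||` instead. The re-application form
  is the default because it regularises the generator as an idempotent map
  onto its target domain, which is the property the training actually
  exploits when fakes are fed back through the cycle;
- `L_sobel` filters both translation residuals with the two orthogonal 3x3
  Sobel kernels (edge-replicate padding, so a constant residual scores
  exactly zero) and takes the mean absolute response — an edge-preservation
  term.

Norm conventions are fixed package-wide: the quadratic (L2) terms are the
per-image RMS of the residual, averaged over the batch, and the L1 terms
are per-pixel means. The pixel normalisation of the L2 terms is load
bearing: the gradient of an unnormalised image norm has constant magnitude
however small the residual, so with equal weights the cycle/identity pull
toward the identity map would outweigh the mean-scaled L1 term by a factor
of sqrt(n_pixels) and training would freeze at the identity — a failure
mode we observed directly before fixing the convention. A small eps
(1e-12) under each square root keeps the gradient finite at an exactly
zero residual.

### Weight schedule

Training proceeds in three phases keyed on the epoch: a pure adversarial
warm-up (all auxiliary weights zero, adversarial weight fixed at 1), a
cycle-consistency phase with (cycle, identity, generated, sobel) =
(5, 5, 1, 0), and the full objective (10, 10, 10, 1e-4). The tiny Sobel
weight matters: the Sobel response scales with the 8x kernel gain, and a
larger weight lets edge error dominate the total. Default phase
breakpoints are epochs 10 and 20 of a 200-epoch run (5% / 10%); the
scaled-down profile keeps those fractions (epochs 1 and 2 of 19) rather
than the absolute epoch counts, otherwise a short run would never leave
the warm-up. The gradient-penalty coefficient is 10, the usual choice for
this objective, and configurable.

### Architectures

Generators are residual encoder-decoders in the deblurring-GAN lineage:
7x7 stride-1 convolution, two stride-2 *inception* downsampling blocks,
N residual blocks (convolution + instance norm + Swish, additive skip),
two x2 transposed-convolution blocks, 7x7 output convolution, sigmoid
into [0, 1]. The inception block runs four parallel convolutions with
kernels 1/5/9/13, each branch scaled by kernel_size/28 (the weight sum)
before channel concatenation, so large receptive fields dominate without
inflating activation scale. One architectural note: a first *stride-2*
convolution plus two stride-2 inception blocks would downsample x8 while
two transposed convolutions only restore x4; the first convolution is
therefore stride 1, which closes the shapes and matches the deblurring
lineage the generator comes from. Residual blocks use the single
convolution literally listed for them; a two-convolution variant is
available behind a config flag.

Critics are patch discriminators: four stride-2 convolutions (channels
64-128-256-512 in the full profile), LeakyReLU(0.2), instance norm from
stage 2 (never batch statistics — the per-sample gradient penalty forbids
them), and a final 1-channel convolution with no pooling or dense head, so
one instance scores any input at least its receptive-field size and its
parameter count is independent of image size.

Weights initialise from N(0, 0.02^2) under explicit seeds; sigmoid output
activation matches the normalized data range.

### Optimisation

Adam with learning rate 1e-4, beta1 = 0.5 (the customary GAN setting;
only Adam and the learning rate are inherent to the regimen), batch 8 in
the full profile. The learning rate is constant for the first 20 epochs,
then cosine-annealed to zero at the final epoch. One critic update per
generator update by default (configurable; 5 is the conservative
Wasserstein setting, 1 keeps CPU runs fast and is sufficient at this
problem size). Critic and generator updates alternate; the party not
being updated is frozen (its parameters excluded from gradient tracking).

## Numerical engine

No GPU framework is assumed: the networks run on a small reverse-mode
autodiff engine written on numpy (float32, BLAS matmuls via im2col with
numba-compiled patch gathers). Every vjp is expressed in traced
primitives, so gradients are themselves differentiable graphs; the
convolution keeps this property through the conv/dx/dw triality (each
backward op is a primitive whose own vjps are the other two). That makes
the gradient-penalty parameter gradient — a second derivative through the
critic — exact, which the test suite verifies against float64 finite
differences. Two deliberate exceptions are exact to first order only and
are never on a second-derivative path: the fused Swish derivative
(generators only) and the sign/mask constants of |x| and LeakyReLU
(a.e.-correct). A terminal backward pass severs the graph's parent links
so op/closure reference cycles free by reference counting; without this,
long training runs drown the Python cycle collector.

## Preprocessing

CT values are windowed to [-950, 500] HU and scaled linearly to [0, 1]
(clipping outside the window); the window spans lung air to trabecular
bone at the W=1450/L=-225 display setting typical for this anatomy. Body
masks threshold at CT > -1000, keep the largest connected component and
fill its convex hull; non-body pixels are set to -1000 HU (air) before
normalization — the fill value is a package choice. Anatomy cropping
takes a 264x336 window centred on the mask centroid, clamped in-bounds
(centroid centring is a package choice; only the target size is inherent).
Augmentation draws one crop offset, one rotation in +-20 degrees and one
flip decision per axis, and applies them identically to both images of a
pair; rotation is bilinear with background fill. Crop precedes rotation
(cheaper interpolation; the opposite order would be equally defensible).
Registration of real CBCT/FBCT pairs is out of scope: synthetic pairs are
aligned by construction, and real-data users must supply pre-registered
pairs.

## Synthetic phantom data

Patient data are replaced by parametric ellipse phantoms of a thorax
slice: body (fat ring), muscle band, two lungs, mediastinum, breast,
sternum, spine, painted back-to-front with per-pixel Gaussian texture.
Mean CT values and texture SDs default to the FBCT reference values for
the seven evaluation tissues (right lung -775+-123, left lung -806+-34,
breast -80+-20, mediastinum 48+-6, muscle 66+-9, sternum 245+-15, spine
304+-19 HU); each structure's mask is exactly the set of pixels it owns
after painting, so ROI statistics are self-grounding.

The CBCT degradation applies, in a fixed contract order: per-tissue
CT-value bias inside each mask (defaults are the CBCT-minus-FBCT
reference differences, e.g. breast -256 HU, spine -221 HU), a smooth
additive shading field (sum of three low-frequency oriented cosines —
a first-order stand-in for scatter's slowly varying CT-value error, not
projection physics), isotropic Gaussian blur (default 1.5 px), and white
noise (default 20 HU). Zero parameters give the identity. Per-pair
anatomical jitter perturbs axes by +-5% and centres by +-3 px; a draw
violating the geometric invariants (structures inside the body, lungs
disjoint from bone) is redrawn deterministically.

What the phantom does **not** emulate: streak/ring artefacts, beam
hardening, truncation, respiratory deformation, or inter-slice context.
Passing tests show the method removes blur/noise/bias-type artefacts on
aligned 2-D data; they do not certify performance on real patient CBCT.

## Desk-scale benchmark

The end-to-end exercise (`cycledeblur.benchmark`) simulates 80 aligned
64x64 pairs (64 train / 16 held out) with the signature breast bias
(-256 HU), 1.5 px blur and 20 HU noise — the bias-only degradation
isolates the tissue whose recovery is measured — and trains the small
profile (16 base channels, 3 residual blocks, batch 4, 19 epochs x 16
iterations ~= 300 generator iterations, proportional schedule breakpoints
at epochs 1 and 2, learning rate 2e-3, no rotation augmentation). Problem
sizes were chosen so the whole run fits in minutes on one CPU core; the
learning rate is calibrated to the profile's step budget (see the
schedule note above). Measured on the held-out pairs: whole-image MAE
against FBCT before vs after translation, breast CT-value error before
vs after, and PSNR/SSIM. The claims checked are directional (translation
beats the raw input; at least half the breast bias removed), not the
patient-study effect sizes, which require the original cohort and the
full training budget.

One mechanism worth knowing when reading desk-scale numbers: strict cycle
consistency discourages denoising, because a deterministic inverse
generator cannot re-create an exact noise instance, so removing noise
raises the cycle term by the noise RMS. The MAE improvement at this scale
therefore comes from deblurring and CT-value correction (both invertible,
hence cycle-compatible) while the noise floor largely remains.

## Known limitations

- 2-D slices only; no 3-D context or multi-slice consistency.
- The engine is CPU-bound; the full 200-epoch profile at clinical
  resolution is out of reach without a GPU framework.
- Global-statistics SSIM (per the defining formulas used here) reads
  higher than windowed SSIM implementations; values are not comparable
  across conventions.
- The phantom's artefact model is statistical, not physical; conclusions
  transfer to real CBCT only qualitatively.
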