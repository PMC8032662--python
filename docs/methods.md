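# Methods

## Problem and approach

Chronic brain infarcts are heterogeneous in contrast, morphology and
location, which makes supervised detectors brittle: any training set
under-represents some lesion appearance. `mranomaly` instead learns what
*normal-appearing* brain tissue looks like and flags whatever deviates
from it. The unit of analysis is a two-channel, in-plane 15×15-voxel
patch extracted from co-registered volumes (channel 1 T1-like, channel 2
FLAIR-like). Patches are purely two-dimensional because the targeted
acquisitions are strongly anisotropic (≈0.9×0.9 mm in-plane, 4 mm
slices); a through-plane patch would mix very different length scales.

## Preprocessing

Per channel, intensities are linearly mapped so that the 5th percentile
of voxels *inside the brain mask* becomes 0 and the 95th becomes 1
(linear-interpolation percentiles). The map is applied to the whole
channel and values are deliberately **not clipped**: lesions are
intensity outliers by nature and clipping would erase exactly the
contrast the detector needs. Percentiles are computed per volume and per
channel. Bias-field correction (e.g. N4) is an external preprocessing
step; the package accepts already-corrected volumes and only offers a
subprocess hook.

## Network

The generator is an encoder–decoder–encoder:

* encoder `G_E`: two blocks of [conv 5×5, stride 2, pad 1 → batch norm →
  leaky ReLU (slope 0.2)], then a linear conv 3×3 (stride 1, pad 0) to a
  `latent_dim`×1×1 bottleneck `z`. Spatial trace 15 → 7 → 3 → 1.
* decoder `G_D`: the exact mirror with transposed convolutions
  (1 → 3 → 7 → 15); the output layer is linear — no squashing — because
  normalized intensities can legitimately exceed [0, 1].
* second encoder `G_E2`: architecturally identical to `G_E` but with its
  own parameters, mapping the reconstruction x̂ to ẑ. Sharing weights
  would collapse the encoding loss into a reconstruction proxy.

Batch normalization is omitted after the latent-producing convolution
and after the decoder output: normalizing `z` or x̂ would fight the
encoding and reconstruction losses directly.

The discriminator reuses the encoder topology up to the second block;
the flattened activations of that block are the feature vector f(·) used
for feature matching, followed by one conv 3×3 to a scalar real/fake
logit. Channel widths default to (32, 64) and are configuration, not
contract — the spatial trace only admits two strided blocks before the
3×3 latent convolution on a 15×15 patch.

All layers are implemented in NumPy inside `mranomaly.nn` (strided
convolution and its adjoint via im2col/col2im, batch normalization,
leaky ReLU, Adam), with explicit backpropagation. Forward oracles
(scipy.signal correlation) and finite-difference gradient checks cover
every layer and the composite three-term loss.

## Training

Generator loss per minibatch, with weights (70, 10, 1):

    L = 70·mean|x − x̂|  +  10·mean(z − ẑ)²  +  1·mean(f(x) − f(x̂))²

The discriminator minimizes binary cross-entropy against *soft* labels:
real targets ~ U[0.8, 1], fake targets ~ U[0, 0.2], which keeps its
gradients alive early in training. The pairing (real image ↔ soft-real
label) is the default; a `label_swap` switch implements the opposite
reading. Updates alternate discriminator-then-generator, one step each
per minibatch of 64, Adam with learning rate 10⁻³ and moment
coefficients (0.5, 0.999) — the usual GAN choice for the first moment.

Horizontal and vertical flips (each with probability 0.5, both channels
together) are redrawn every epoch. After each epoch the *weighted*
generator loss — all three terms — is evaluated on a training-validation
patch set from held-out subjects, in evaluation mode and without
augmentation, so early stopping is deterministic given the weights.
Training stops once that loss has not set a new minimum for 10
consecutive epochs (hard cap `max_epochs`, default 500), and the weights
of the best epoch are restored.

## Anomaly scoring

After training, the per-element **median** and **median absolute
deviation** (MAD) of the latent difference d = z − ẑ are computed over
the (unaugmented) training patches with the deployed best-epoch weights.
MAD values are floored at ε = 10⁻⁶ so scores stay finite for degenerate
elements. At inference, each latent element scores

    score_i = |d_i − median_i| / MAD_i ,

i.e. the deviation from the median in MAD units. The conventional 0.6745
consistency factor (which rescales MAD to a normal σ) is **off** by
default — the statistic is used as a unitless rank-like quantity and the
flagging threshold was defined on the unscaled ratio — but available via
`use_consistency_constant`. The patch anomaly score is the Nth
percentile (default N = 50) of the elementwise scores.

Volumes are scored on a dense stride-4 grid over every slice (patch
center inside the brain mask, patch fully inside the slice). Voxel-level
maps take the **maximum** score over all covering patches, so a voxel
exceeds the threshold exactly when some covering patch does. Grid points
with score **strictly greater than 3** are grouped into connected
components on the (slice, row/4, col/4) lattice with 6-connectivity —
one stride step in one in-plane axis, or the same in-plane position on
an adjacent slice, since a finding can continue on the next thick slice.
Components consisting of a single isolated flagged patch are discarded
as spurious; survivors are the *suspected anomalies*.

## Evaluation

A lesion counts as detected when at least one of its annotated voxels
lies inside the voxel footprint (union of member patches) of a retained
suspected anomaly; the one-voxel rule is the weakest defensible overlap
criterion and is configurable (`min_overlap_voxels`). One suspected
anomaly may detect several lesions and vice versa; lesions are what is
counted. Sensitivity and the detected-volume fraction are pooled over
lesions across volumes; the suspected-anomaly rate is total components
over volumes. Volumes with no annotations contribute only to the
false-positive rate. The latent-size / percentile sweep re-aggregates
cached elementwise scores (inference is percentile-independent), which
is verified against full re-inference in the tests. The nearest-neighbor
analysis of missed lesions searches in the generator's own latent space
z (Euclidean distance, ties to the lowest training index); a raw-pixel
mode exists for comparison.

## Phantom generator

The synthetic cohort emulates: two channels with partially shared smooth
structure (a Gaussian-filtered random bias field, half of its variance
common to both channels), additive white noise, an ellipsoidal per-slice
brain mask, and the anisotropic 0.9×0.9×4.0 mm voxel grid. Lesions are
additive-contrast discs (spanning adjacent slices when their radius
exceeds the slice thickness): core contrast −25 in channel 1 and −20 in
channel 2, a +25 hyperintense rim in channel 2 (rim thickness 1.8 mm),
radii 3–6 mm, 2–4 lesions per test volume, against noise σ = 5 and field
amplitude 8 (all in raw intensity units before normalization). These
defaults put the lesion core at 5σ and 4σ of the noise — clearly
outlying but not trivially separable from the bias-field variation.

The phantom does **not** simulate MR physics, partial-volume effects,
cortical folding, cerebrospinal-fluid boundaries, white matter
hyperintensity morphology, or motion artefacts. Passing the phantom
study therefore demonstrates that the statistical machinery — training
on normal tissue, latent calibration, modified Z-scoring, filtering,
matching — recovers high-contrast outliers end to end; it does not
certify performance on clinical images, where boundary false positives
and small low-contrast lesions dominate the error budget.

## Desk-scale study conditions

The packaged end-to-end study (`mranomaly.experiments.run_phantom_study`,
also what `scripts/acceptance.py` runs) uses 16 training + 4
training-validation lesion-free phantoms and 10 lesioned test phantoms
of 18×80×80 voxels, 20,000 training and 2,000 training-validation
patches, a latent size of 32 with channel widths (8, 16), at most 15
epochs, percentile 50 and threshold 3. These sizes are the package's own
choice of a configuration that trains in minutes on one CPU while
leaving the method's behaviour intact; capacity and patch counts scale
down, the statistic and thresholds do not.

## Numerical and design notes

* Percentile definition everywhere: linear interpolation (the common
  default), recorded in configuration.
* Sampling is uniform over the pooled set of valid (volume, center)
  placements, with replacement; a placement is valid when the patch
  center is masked and the patch fits in the slice. Center-in-mask (not
  patch-in-mask) keeps boundary tissue represented in training.
* Dense grids anchor at in-plane offset 0; no sub-stride phase
  randomization, so inference is deterministic.
* The latent-difference statistic is calibrated after training with the
  best-epoch weights — statistics must match the deployed model.
* All randomness flows from named integer seeds; identical seeds give
  bit-identical patch sets, training records and score maps on the same
  platform.
* Checkpoints are single `.npz` archives holding all parameters, the
  model configuration and the latent calibration.

## Known limitations

* Small low-contrast lesions (≲1 ml clinically) are the known weak spot
  of a 15×15 single-slice patch detector; the phantom study uses ≥3 mm
  radii and does not probe this regime.
* Footprints of suspected anomalies are unions of 15×15 patch tiles,
  not segmentations; reported component volumes overestimate lesion
  volumes accordingly.
* Training is single-threaded NumPy; it is sized for patch counts in
  the tens of thousands, not the million-patch regime of a full cohort
  (the code accepts such sizes, but expect hours, not minutes).
* Classification of suspected anomalies into clinical categories is out
  of scope; the pipeline only localizes.
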