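# mranomaly

Unsupervised detection of chronic brain infarcts — and other focal
abnormalities — on co-registered two-channel brain MR volumes (e.g.
T1-weighted + T2-FLAIR). Instead of learning lesions from annotations,
an adversarial autoencoder learns the appearance of *normal* brain
tissue from 15×15-voxel image patches; at inference, patches the model
cannot represent well stand out in its latent space and are flagged as
suspected anomalies. The package is aimed at researchers in medical
image analysis who want a lesion-agnostic screening pass over volumetric
brain MRI.

## Method

A generator encodes a two-channel patch x into a latent vector z,
reconstructs x̂ from z, and re-encodes x̂ into ẑ with a second,
independently parameterized encoder (spatial trace 15 → 7 → 3 → 1 and
back). It is trained adversarially on normal-appearing brain patches
with the weighted loss

    L = 70·‖x − x̂‖₁ + 10·‖z − ẑ‖₂² + 1·‖f(x) − f(x̂)‖₂²   (elementwise means)

where f(·) are discriminator features; the discriminator itself is
trained with soft labels (real ~ U[0.8, 1], fake ~ U[0, 0.2]). Early
stopping selects the epoch with the lowest generator loss on a held-out
training-validation set.

Anomaly scoring is a robust outlier statistic on the latent difference
d = z − ẑ. With per-element median mᵢ and median absolute deviation
MADᵢ calibrated over the training patches, each element scores the
modified Z-score |dᵢ − mᵢ| / MADᵢ, and a patch's anomaly score is the
Nth percentile (default N = 50) of these values. Volumes are scored on a
dense stride-4 patch grid; grid points with score > 3 are grouped into
connected components, single isolated patches are discarded as spurious,
and the survivors — *suspected anomalies* — are matched against lesion
annotations by voxel overlap to report sensitivity, suspected anomalies
per image, and the detected fraction of total lesion volume.

The neural network (strided convolutions, transposed convolutions,
batch normalization, Adam, backpropagation) is implemented in NumPy in
`mranomaly.nn`; a synthetic phantom module generates two-channel brains
with insertable lesions (hypointense core in channel 1, hyperintense rim
in channel 2) so the whole pipeline trains and evaluates at desk scale.
See `docs/methods.md` for the full model description and design notes.

## Worked example

The command-line interface drives the whole pipeline on NIfTI volumes;
`simulate` creates a phantom cohort to try it without data:

```bash
mranomaly simulate --seed 7 --out cohort --n-train 4 --n-trainval 2 --n-test 3
# wrote 4+2 normal and 3 lesioned phantoms to cohort

mranomaly train --seed 7 --data cohort --out run/model.npz \
    --n-patches 6000 --latent-dim 32 --max-epochs 6
# trained 6 epochs, best epoch 5 (trainval loss 15.1846); checkpoint: run/model.npz

mranomaly evaluate --data cohort --checkpoint run/model.npz --out run/eval
# {
#   "n_volumes": 3,
#   "n_lesions": 8,
#   "n_detected": 8,
#   "sensitivity": 1.0,
#   "volume_fraction": 1.0,
#   "n_suspected": 7,
#   "suspected_per_image": 2.3333333333333335
# }
```

All 8 inserted lesions were recovered (sensitivity 1.0, 100 % of the
lesion volume) at the cost of 2.3 suspected anomalies per image — the
false findings a reader would have to dismiss. `mranomaly score` writes
a per-voxel anomaly map (NIfTI) and a suspected-anomaly table (CSV) for
a single volume; `mranomaly sweep` produces the operating points of the
free-response curve over latent sizes and percentiles.

The same pipeline is available as a scikit-learn estimator:

```python
from mranomaly import GanomalyPatchDetector
det = GanomalyPatchDetector(latent_dim=32, channel_widths=(8, 16), random_state=0)
det.fit(train_patches)              # (n, 2, 15, 15) normal-tissue patches
scores = det.anomaly_scores(X)      # per-patch modified-Z percentile
smap = det.score_volume(volume)     # dense-grid AnomalyScoreMap
```

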