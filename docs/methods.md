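# Methods

`tomopick` localizes particles in cryo-electron tomograms by regressing a
smooth centroid heatmap rather than segmenting particle volumes. This note
describes the model, the numerical choices behind each stage, what the
synthetic phantoms do and do not emulate, and the known limitations.

## Centroid labels

For a particle of radius R (half the longest axis for non-spherical
particles), the training target at distance r from the centroid is

    I(r) = [exp(-r² / 2σ₁²) + exp(-r² / 2σ₂²)] / 2,   r ≤ R;   I(r) = 0, r > R

a sum of two isotropic Gaussians normalized to peak at 1. The sigmas derive
from diameter fractions f₁ = 0.95 and f₂ = 0.5 under the convention that a
Gaussian's width is ±3σ, giving σᵢ = fᵢ·D/6, i.e. σ₁ ≈ 0.32 R and
σ₂ ≈ 0.17 R. The wide component carries positional uncertainty; the narrow
one sharpens the peak so that maxima survive downstream smoothing. Compared
with binary masks, the taper encodes "probably near the centre" instead of a
hard boundary.

Choices worth knowing:

- **Combination of overlapping particles is voxel-wise maximum**, not sum.
  A sum would exceed 1 wherever particles crowd (densely packed specimens
  are exactly the regime this method targets) and would merge peaks.
- **Normalization is peak = 1** (division by the r = 0 value). The
  downstream confidence threshold (typically 0.3) presumes a [0, 1] scale.
- **Sub-voxel centroids are not snapped**: the profile is evaluated at the
  exact continuous distance, so the nearest voxel may hold a value slightly
  below 1. Phantom ground truth is placed on the grid, where the peak is
  exactly 1.
- Truncation keeps r ≤ R and zeroes r > R, so the label support is the
  union of radius-R balls around the centroids.

## Preprocessing

Tomograms are rescaled so the particle diameter spans a fixed number of
voxels, `target_particle_px` (default 10); the scale factor is
`target_particle_px / (diameter / voxel_size)` and the voxel size is divided
by it. Resampling is trilinear; when downscaling, a Gaussian anti-alias
pre-filter with σ = sqrt((1/s)² − 1)/2 is applied first (the
variance-matching choice: one output voxel then carries the variance of the
input neighbourhood it replaces, which also keeps integrated intensity
stable to within a few percent through a down/up round trip).

Intensities are normalized to `(x − median) / IQR`. The median/IQR pair is
the standard robust location/scale statistic and makes tomograms from
different reconstruction pipelines comparable; constant volumes are
rejected rather than silently passed through. No percentile clipping is
applied before normalization.

Training volumes are cut into overlapping 64³ cubes with stride 32. Per
axis the window origins are 0, 32, 64, … plus one final origin clamped to
`dim − 64` whenever the strided grid stops short of the boundary — full
coverage without interior zero padding (only volumes smaller than one cube
are padded, and the padding is recorded). Cubes containing at least one
positive label voxel are all kept; an equal number of negative cubes is
sampled uniformly without replacement (seeded). When negatives are scarce,
all of them are kept.

## Loss

The training loss is

    L = mean( w(y) ⊙ H_δ(ŷ − y) ) + λ · L_grad

where H_δ is the Huber loss (δ = 1 by default) and w(y) the
inverse-class-frequency weight: with |P| positive and |N| negative voxels
and T = |P| + |N|, positives get T/(2|P|) and negatives T/(2|N|). The weight
volume has mean 1 (loss scale independent of chunk content) and puts equal
total weight on each class; if a chunk has only one class the weights fall
back to 1. The gradient term L_grad applies the Huber loss to the per-axis
discrete second derivatives ([1, −2, 1] stencil, replicate borders, three
channels averaged) of prediction and target, sharpening sensitivity to the
edges of the Gaussian peaks; λ defaults to 1 and a first-derivative variant
sits behind `grad_order=1`. Second derivatives were chosen over first
because the operator named for this term is the second-order derivative; the
flag preserves the alternative reading.

Because training runs on plain NumPy, the analytic gradient of L with
respect to the prediction is implemented alongside (Huber derivative
`clip(r, −δ, δ)`; stencil adjoints with explicit border accumulation) and is
verified against central finite differences in the test suite.

## Backbone and training

The backbone contract is minimal — a trainable map from a cube to a
same-shape scalar field with named parameters and a save/load round trip —
so any volumetric architecture can be plugged in where its framework is
available. The built-in default, `ResUNet3D`, is a deliberately small
three-level encoder–decoder (~16k parameters, two average-pool
downsamplings, concatenation skips, leaky-ReLU, linear 1×1 head plus a
zero-initialized 1×1 global residual) written directly in NumPy with
hand-derived backpropagation. Convolutions are im2col GEMMs; the input
gradient is computed as a GEMM against the flipped-kernel matrix rather
than a scatter, which matters on one CPU. The receptive field (~±27 voxels)
comfortably covers a 10-voxel particle.

The default schedule follows common practice for this task: AdamW
(decoupled weight decay 1e-10), initial learning rate 4e-4, batches of ten
cubes, at most 150 epochs, learning rate halved after 6 epochs without
validation improvement, early stopping after 36 such epochs, 20% of the
cube pairs held out for validation. "Improvement" means the validation loss
drops below the running best by more than 1e-6, evaluated once per epoch;
the returned checkpoint is the best-validation one, not the last.
Validation (not training) loss gates both schedulers. Fine-tuning resumes
from a checkpoint with the same loop (conventionally 20 epochs at lr 5e-5).

One caveat that the defaults inherit: they are calibrated for large
backbones trained over many thousands of optimizer steps. The built-in
backbone trained for tens of epochs on a handful of tomograms sees only a
few hundred AdamW steps, and at lr 4e-4 it stalls near the trivial
"predict zero" solution. The synthetic-recovery experiment shipped with the
package therefore trains it with smaller batches (more steps per epoch at
identical wall time, since samples are processed individually) and a higher
learning rate; the exact values are in `tomopick/experiments.py` and were
chosen from single-chunk fitting probes, not from the evaluation outcome.

## Inference and extraction

Whole tomograms are tiled with the same clamped-origin chunk grid used in
training; each cube is predicted independently and overlaps are fused by
unweighted per-voxel averaging (weights sum to 1 everywhere, so constants
are reproduced exactly). A cosine-window weighting is available for seam
suppression. The fused map is clamped to [0, 1], fixing the meaning of
confidence thresholds regardless of the backbone's output range.

Peaks are voxels attaining the maximum of their centered cubic
neighbourhood of side 2·⌊min_distance/2⌋+1 (clipped at borders), processed
in decreasing confidence with greedy Chebyshev-distance suppression at
min_distance, then filtered by threshold (inclusive ≥, so a threshold of
1.0 can retain saturated peaks). Plateau ties resolve to the
lexicographically smallest (z, y, x) index, making extraction fully
deterministic. min_distance defaults to the particle diameter in rescaled
pixels. For crowded fields that default is conservative: spheres in contact
have center separation equal to the diameter in *Euclidean* terms, which
along a diagonal is only ~diameter/√3 in Chebyshev terms, so suppression at
the diameter removes genuinely distinct neighbours. The phantom-recovery
experiment accordingly extracts with min_distance equal to the particle
radius. Extraction can be gated by a binary mask (a point is kept if its
nearest voxel is inside), and coordinates can be mapped back to the
original pixel grid by dividing by the preprocessing scale.

## Metrics

Predictions are assigned to ground truth one-to-one by minimizing total
Euclidean distance (`scipy.optimize.linear_sum_assignment`; the optimum is
identical to the Jonker–Volgenant solver's). Matched pairs within half the
particle diameter are true positives; everything else on the prediction
side is a false positive and unmatched ground truth a false negative, so
tp + fp = |pred| and tp + fn = |gt| always hold. Precision, recall and F1
follow, with explicit zero-denominator conventions (no predictions →
precision 0; no ground truth → recall 1 if tp > 0 else 0; P + R = 0 →
F1 = 0). Localization error is the RMSE over true-positive pair distances
divided by the particle diameter, reported as missing (not 0) when there
are no true positives; the mean is over true positives only, with the
min(|gt|, |pred|) denominator variant available behind a flag.

The operating point is chosen by sweeping percentiles 2–98 in steps of 8
(13 rows) of the pooled prediction confidences, recomputing the metrics at
each cutoff and flagging the F1-maximal row (lowest percentile on ties) —
F1_max. Cutoffs are observed confidence values (`np.percentile` with
`method="lower"`), so the lowest percentile always retains every
prediction; interpolated cutoffs would drop the weakest prediction even for
a perfect predictor.

## Synthetic phantoms

Phantoms are uniform solid spheres (dark on a light background, the cryo
density convention) at integer-grid centers with pairwise separation ≥
2·radius (touching allowed, overlap not), additive Gaussian noise, and an
optional anisotropic Gaussian blur (σ_z ≥ σ_xy) standing in for
missing-wedge elongation. SNR is defined as contrast²/noise-variance and is
calibrated exactly by construction; the suite verifies the realized ratio
within 10%. Defaults: 96³ voxels at a nominal 10 Å/px, 15 particles of
radius 5 px (diameter 10 px — no rescaling needed), SNR 0.5.

What the phantoms do *not* emulate: projected molecular densities, CTF
modulation, reconstruction artefacts, true Fourier-wedge missing
information, intensity gradients, or crowded heterogeneous backgrounds
(membranes, filaments). Real cryo-ET data sits at SNR below 0.1 with
structured rather than white noise. Passing the synthetic recovery test
therefore demonstrates that the pipeline — labels, loss, training loop,
stitching, extraction, scoring — is internally consistent and can recover
known centroids from heavy white noise with a small model; it does not by
itself establish detection performance on experimental tomograms, which
depends on backbone capacity and training data.

## Degenerate inputs and tie-breaks

- Constant volumes: rejected by `robust_normalize` (zero IQR) with guidance.
- Zero particles: labels render all-zero; training refuses chunk sets with
  no positive cube.
- Empty coordinate files parse to an empty set with a warning, not an error.
- Peak plateaus: lexicographic (z, y, x) winner; assignment ties: the
  solver's deterministic optimum.
- All internal volumes are float32; metrics and loss accumulate in float64.

## Known limitations

- The built-in backbone is sized for CPU smoke-scale training; realistic
  detection on experimental data calls for a larger plugged-in architecture.
- One particle size per model: multi-scale mixtures are out of scope.
- Filamentous assemblies have no centroid in the useful sense and are not
  handled.
- Centroids are voxel-resolution; no sub-voxel peak refinement is applied.
- Binary IMOD model files are not parsed; export point text instead.
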