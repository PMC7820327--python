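# Methods

This note records the models, parameter choices and numerical conventions
behind `uwfdr`, and what the synthetic-data experiments do and do not show.

## Coordinate and scale conventions

All code uses 0-based `(row, col)` coordinates with row 0 at the top and
pixel centers at integer positions; angles are degrees measured from the
+col axis toward +row (clockwise on screen). Pixel-unit constants of the
detection pipeline (merge distance 150, macula search band 500 × 30,
candidate crop 614, red-refinement radius 307, disc exclusion 250) are
defined at the native UWF raster of 3072 × 3900 and rescaled by
`sqrt(H·W / (3072·3900))` for other sizes. Area thresholds are fractions of
the image area (defaults 10⁻⁴ to 10⁻²).

## Landmark detection

The green channel is multiplied by a centered Gaussian with
`s = sigma_frac · min(H, W)`; the default `sigma_frac = 0.35` keeps the
whole retinal field near full weight while pulling frame corners to
essentially zero, which removes bright skin/eyelid structures before
thresholding. The threshold is τ = μ − σ with μ, σ pooled over reference
optic-disc regions. Two conventions had to be fixed:

* **Population SD** (divide by n): the statistics describe a pooled pixel
  population, not a sample estimate.
* The reference statistics are computed **on the Gaussian-weighted green
  channel** — the same domain the threshold is applied in — so that the
  center-weighting attenuation of discs at varying eccentricity is part of
  μ and σ. Computing them on raw intensities makes τ systematically too
  high for discs far from the frame center.

Components are 8-connected; merging of nearby components is done by
union-find over centroid distances, repeated against merged centroids until
a fixpoint, which makes the result independent of component discovery order.
Red-channel refinement takes the centroid of raw red pixels > 50 inside a
circular neighbourhood (no Gaussian weighting — the weighting exists only to
suppress border structures during thresholding). Candidate centers fuse as
0.75·green + 0.25·red.

In heuristic-only mode (no trained segmenter) the disc boundary is
re-estimated by Otsu thresholding of the raw green channel inside the
candidate neighbourhood before moment-based ellipse fitting. The thresholded
blob from the weighted map is asymmetric for off-center discs (the
center-facing side survives the threshold more easily), which biases its
centroid; the local Otsu blob is symmetric and recovers the center to
sub-pixel accuracy on synthetic data.

Ellipse fitting uses second-order central moments (the moment-equivalent
ellipse: semi-axes `2·sqrt(eigenvalues)` of the pixel covariance). Masks
with fewer than 5 foreground pixels are rejected as degenerate.

The macula is the extremal pixel of the CMYK key channel
K = 1 − max(R,G,B)/255 inside the search band. Under this standard
convention the dark macula has the *largest* K, so the default polarity is
"largest K"; the polarity is configurable for data using an inverted K
convention. The band is searched on both sides of the disc (laterality is
unknown before the macula is found; the detected side then determines
laterality), with ties broken toward the smallest row, then column.

## Disc segmentation (U-Net)

Encoder: residual blocks (conv-BN-ReLU-conv-BN with identity or projected
shortcut) with stride-2 downsampling, width and depth parameterized; the
full-scale configuration is 512 px input, base width 64, four stages
(ResNet-18-like), the test configuration 128 px, base width 8, three stages.
Decoder: nearest-neighbour ×2 upsampling, skip concatenation, 3 × 3
convolution + ReLU per level, and a 1 × 1 output convolution; nearest
upsampling was chosen over transposed convolution for its artifact-free
gradient and simplicity. Preprocessing is CLAHE followed by bicubic resize
and [0, 1] scaling; CLAHE uses scikit-image's `equalize_adapthist` with
`clip_limit = 0.02` and an 8 × 8 tile grid (the clip limit is in
scikit-image's normalized convention, corresponding to the common OpenCV-style
clip of ~2).

Training minimizes soft dice loss, `1 − (2Σpt + ε)/(Σp + Σt + ε)` with
ε = 10⁻⁶ (guards the empty-mask 0/0 case), using Adam at learning rate 10⁻⁴
for 30 epochs, batch size 2. Among multiple candidate patches the one with
the highest mean predicted foreground probability wins (ties → lowest
index); predicted masks binarize at 0.5. Model weights plus batch-norm
running statistics are stored as an `.npz` archive with a JSON manifest of
the configuration and seed.

## Field geometry

Left-eye images are mirrored (col → W−1−col) so the disc is always right of
the macula; the image is then rotated about the disc center by the angle
that brings the macula onto the disc row (bicubic resampling, zero fill).
The disc center is a fixed point; the transform record is invertible and
round-trips points to within 0.5 px.

The crop windows are parameterized in units of the disc–macula distance D,
the only scale the two landmarks provide. Field 1 (disc-centered) and
Field 2 (macula-centered) are circles of radius 0.5·D — each central field
spans one disc–macula distance — and the F1–F2 window is their bounding box
expanded symmetrically to the 448:640 aspect ratio. The 7SF window is
centered on the macula and spans 4·D horizontally (rows follow from the
896:1024 aspect), approximating the ~90° seven-field region relative to the
two ~30° central fields; both factors are configurable, and the defaults are
an interpretation rather than a measured standard. Crops resize to
896 × 1024 (7SF) and 448 × 640 (F1–F2); a reduced-scale experiment may
request a smaller raster of the same window directly.

An advisory occlusion flag marks crops whose central row band contains more
than 20% near-black pixels (max channel < 30), automating the manual
exclusion of eyelash/eyelid-contaminated fields; it is off in the library
and on in the evaluation pipeline.

## Classification

Residual network with global average pooling and a two-logit softmax head
(the two-logit form matches the per-class weight formulation). Class
weights are N/count(c) with N the minority-class training count, so the
minority weight is exactly 1. Optimization is SGD with momentum 0.9 at
learning rate 10⁻³, decayed ×0.1 every 7 epochs, 25 epochs. Inputs are
scaled to [0, 1] per channel; no augmentation. Batch size defaults to 4 in
the reduced configuration — small batches give the short 25-epoch schedule
enough update steps on the few-hundred-image synthetic sets; full-scale runs
would use larger batches. Crops whose size is an exact multiple of the model
input are downsampled by block averaging (exact anti-aliasing), otherwise by
bicubic resize.

CAM for class c is Σₖ w₍c,k₎·Fₖ over the final convolutional feature maps,
bilinearly upsampled to the input size; it is exact (not gradient-based)
because the head is GAP + linear.

## Evaluation protocol

Ten runs of ten-fold stratified CV by default (scalable); each run draws its
own shuffling seed from the plan seed. Within each training set a
stratified 1/10 hold-out is reserved for validation. The operating
threshold scans midpoints between consecutive sorted unique scores (plus
sentinels beyond both extremes) and picks the one minimizing
|sensitivity − specificity|, tie-breaking by larger sensitivity+specificity,
then lower threshold. AUC is the rank (Mann–Whitney) statistic with ties
counted ½. The paired t-test pairs per-(run, fold) metric values across
variants — the finest paired unit; per-run aggregation is available by
pooling the table — and uses sample (n−1) SD, as does RSD = 100·sd/mean.
Images whose mean score is zero are excluded from the RSD average and
counted. Images failing landmark detection or crop extraction for either
variant are excluded from both variants and logged with the reason, so the
compared sets are identical.

## Synthetic data

The generator emulates the geometry and photometric ordering of UWF scans:
near-black background, reddish retinal field with smooth low-amplitude
texture, a bright soft-edged elliptical disc (Gaussian edge blur σ = 3 px,
so ellipse fitting sees realistic boundaries), a multiplicative dark macular
dip, dark curvilinear vessel arcs radiating from the disc, optional eyelash
strokes crossing the superior border or an eyelid band, and Gaussian pixel
noise (default sd 2). The default canvas is 768 × 975 — quarter scale of the
native raster — with full-scale generation available. DR images add
"lesion" blobs: bright exudate-like and dark hemorrhage-like Gaussian dots
(default 25 per image, radius 6–11 px at quarter scale, contrast 70), placed
anywhere in the retina or confined to an annulus of 1.15–1.55 D around the
macula that excludes the central-fields box — the peripheral configuration
used to test whether the wider 7SF crop captures signal the central fields
miss.

What this does *not* show: the synthetic classes are separable by simple
local contrast, so classifier accuracy on synthetic data says nothing about
clinical DR detection performance; the images lack scanning-laser color
profiles, projection distortion of the UWF optics, media opacities and
vessel pathology. The synthetic experiments validate the *geometry and
protocol machinery* — landmark recovery, alignment, crop nesting, paired
statistics — not diagnostic accuracy.

## Problem sizes of the shipped experiments

The test suite and acceptance script run: landmark recovery on 50 clean
quarter-scale images (reference statistics from 50 more), U-Net training on
20 pairs at 128 px for the full 30 epochs, and the paired field comparison
on 200 images (100 DR / 100 healthy, peripheral lesions) with 3 runs ×
5-fold CV and the reduced classifier at 32 px inputs. These sizes keep a
full run on one CPU in the ten-minute range while leaving every protocol
element (stratification, pairing, repeated runs) intact.

## Known limitations

* The 7SF window extent is an interpretation parameterized in D; no
  per-field (F3–F7) masks or montage stitching.
* The heuristic disc detector assumes the disc is the brightest coherent
  retinal structure; dense bright artifacts inside the retinal field could
  produce false candidates (mitigated, not eliminated, by the U-Net stage).
* Batch normalization makes tiny-batch training noisier at the smallest
  dataset sizes; seeds are fixed throughout so runs are reproducible.
* The numpy engine is CPU-only and desk-scale; full-resolution training
  (512 px segmentation, 896 × 1024 classification) is supported by the
  architecture parameterization but not practical without a GPU framework.
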