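# Methods

## The recognition problem

Each frame of a frontal, head-fixed macaque face video carries one
harmonized AU class per facial region. The upper and lower face are
coded and classified independently: lower-face actions have little
influence on upper-face motion (and vice versa), and the underlying
musculature is controlled by distinct motor territories. The classifier
targets are the three dominant classes per region (upper: `UpperNone`,
`AU1+2`, `AU43_5`; lower: `AU25+26`, `AU25+26+16`, `AU25+26+18i`).
Everything else maps to the non-target sentinels `OtherUpper` /
`OtherLower` (kept for behavioral reporting, excluded from training and
testing), and frames with no lower-face coding map to `LowerNone`.
Harmonization rules: `AU43` and `AU45` merge into `AU43_5` (they differ
only in movement duration); `AU12` is removed before matching (too
infrequent in the training corpus to learn); upper-face frames combining
a brow raise with an eye closure cannot be expressed in the
three-class taxonomy and fall into `OtherUpper` (logged).

## Alignment

Seven landmarks — four eye corners, two mouth corners, the mouth
center — are annotated once per video on the mean of its neutral frames
(neutral = no coded action in either region). A single affine transform
per video maps them to reference positions fixed as fractions of the
frame size (left-eye corners at 0.42 w/0.3 h and 0.48 w/0.3 h,
right-eye corners at 0.52 w/0.3 h and 0.58 w/0.3 h, mouth corners at
0.44 w/0.55 h and 0.56 w/0.55 h, mouth center at 0.5 w/0.5 h) and is
applied identically to all frames. Seven correspondences over-determine
the six affine parameters, so the transform is the ordinary
least-squares minimizer; it is exact to machine precision when the
correspondences are affine-consistent, and the estimation refuses
collinear landmark configurations. Coordinates are 0-based,
x = column / y = row, origin top-left, continuous coordinates at pixel
centers. Warping uses inverse-mapped bilinear resampling with zero fill
outside the source image; bilinear + zero fill is a deliberate default
(the alignment literature offers no single convention), kept fixed so
that warped outputs are bit-reproducible.

## δ-images and databases

Aligned frames are cropped to rectangular per-region ROIs supplied by
config (for synthetic data, the generator ships ROIs matching its face
template: the upper ROI is the top 42% of rows). Per video, the
"optimal" neutral frame is the neutral frame with the smallest L2
distance to the video's mean-neutral image — a stable automated proxy
for an expert's choice, with a manual per-video override honored. The
δ-image is the signed difference frame − optimal neutral, which cancels
per-video texture and illumination. δ-images are flattened row-major
into an images × pixels database with per-row provenance (video, frame,
subject, class). Pixel values stay on the native 0–255 float scale
throughout; no [0, 1] rescale is applied because the eigenvalue
elimination threshold downstream is scale-dependent.

## Eigenfaces

Training rows are zero-meaned and eigendecomposed. When n < p (images
fewer than pixels — the usual case) the n × n Gram ("snapshot") matrix
is used; its nonzero spectrum equals that of the p × p covariance, and
the symmetric eigendecomposition is deterministic, unlike iterative
truncated solvers. The covariance uses the unbiased 1/(n − 1)
normalization; this choice only shifts the absolute eigenvalue scale,
and the elimination threshold (default 1e−6, applied on native-scale
data) is exposed as config for that reason. Eigenvectors are
unit-normalized; each component's largest-magnitude element is made
positive (eigenvector sign is arbitrary; fixing it makes serialized
models comparable). Explained-variance ratios are computed over the
retained components, so `pcExplVar` selection is reproducible
regardless of how many near-zero eigenvalues were dropped. The
dimensionality N is the smallest leading-component count whose
cumulative ratio reaches `pcExplVar` percent (grid default 50–95% in
5-point steps, configurable to 1-point resolution).

Zero-meaning plus unit normalization makes squared Euclidean distance
in image space an affine function of image correlation
(‖u − v‖² = 2(1 − corr) for unit-norm, zero-mean vectors), so
nearest-neighbor matching in the eigenspace approximates template
correlation — the rationale for the KNN classifier.

## Classification

KNN stores the training weights verbatim and votes among the k nearest
neighbors under the configured metric (Euclidean, or cosine distance
1 − cos). Tie rules are fixed for determinism: neighbor ties at the
k-th radius are resolved by smallest training-row index (stable sort);
vote ties by the smallest summed distance among the tied classes, then
by the fixed class order of the region. The SVM alternative is a
linear-kernel one-vs-one machine (regularization constant 1.0) on
features standardized by the training mean/SD; its hyperparameters are
deliberately plain since nothing beyond "multiclass SVM" is specified
for the original experiments.

## Balancing, validation designs, grid search

Class frequencies are extremely skewed (in the motivating corpus the
upper-face classes count roughly 1213 / 19 500 / 150 000 frames), so
training sets are balanced by random undersampling: every class is cut
to the smallest class's count, drawn without replacement from a seeded
generator; the draw is a pure function of (seed, set index), and 3–10
independent balanced sets are kept. Test sets are never undersampled.

Three designs, with inclusion thresholds that guarantee training and
test sufficiency per class:

* within-subject: leave one video of a subject out; kept only if every
  class has ≥ 20 training and ≥ 5 test frames;
* across-subject: leave one subject out; thresholds 150 / 50 (scaled
  proportionally for desk-scale synthetic runs, see below);
* holdout: repeated stratified validation/test splits (default 100
  splits, 80/20) for per-subject tuning on a new population; per-class
  test counts use largest-remainder rounding so the global 20% is hit
  exactly where divisible (ties toward the larger class, then class
  order).

The grid search fits eigenfaces per (balanced set × partition) on the
balanced rows restricted to the partition's training pool, then scores
every (k, pcExplVar, metric) on the partition's test rows by average
TPR; the configuration score is the mean over partitions, and ties
break toward smaller k, smaller pcExplVar, Euclidean before cosine,
smaller set index. Reports aggregate video-level results per subject
first (unweighted), then across subjects with a standard error, which
keeps subjects with many videos from dominating. A true class absent
from a test set has undefined TPR; it is reported as NaN and excluded
from the mean with a logged warning (the inclusion thresholds normally
prevent this).

## Synthetic data: what it emulates, and what it does not

The generator renders schematic frontal faces (smooth face blob, eyes,
brows, nose, mouth) at a configurable size (default 800 × 700, matching
typical face-camera frames) and deforms them per class: `AU1+2` raises
the brows, `AU43_5` shrinks the eye aperture toward zero, `AU25+26`
opens the mouth, `+16` pushes a lower-lip band downward, `+18i` pulls
the mouth corners inward and adds protrusion shading. Deformation
magnitudes are pixel displacements (defaults proportional to frame
height, ≈ 12–30 px at 700 rows). Subjects get deterministic appearance
offsets (base intensity, feature gain and scale); each video gets one
camera-pose offset (defaults ± 5° rotation, ± 5% scale, ± 10 px
translation) so alignment has real work; labels arrive in contiguous
episodes (geometric length, mean 6 frames, AU episodes ≥ 3 frames, a
3-frame neutral lead per video so a neutral reference always exists);
optional additive Gaussian intensity noise (default SD 2 on the 0–255
scale). Default class frequencies are skewed the way real coded corpora
are (upper 0.77 / 0.17 / 0.06). In the canonical geometry the landmarks
sit exactly at the reference positions and each region's features are
confined to its ROI rows, enabling exact region-locality and alignment
recovery tests.

What passing tests on this data do **not** show: robustness to
non-affine head motion, occlusion, fur texture, illumination drift,
coder disagreement, or video-codec artifacts — none of which the
renderer models. The synthetic results certify the pipeline's
machinery, not field performance.

Because label episodes are temporally clustered, per-class frame counts
fluctuate more than i.i.d. draws (variance inflated roughly by the mean
episode length); frequency tests use correspondingly inflated bounds.
At zero deformation **and** zero noise every δ-image is exactly zero
and the eigen decomposition is degenerate by construction, so the
chance-level control runs at zero deformation with noise SD 6 — images
that carry intensity structure but no class signal.

## Behavioral and neural statistics

AU frequencies and pairwise co-occurrence (cell = frames with both AUs
÷ frames of the rarer AU) summarize coded or classified streams.
Facial-configuration proportions per block period (enter/exit, shutter
open, shutter closed) feed a Pearson χ² test of homogeneity (no
continuity correction; expected counts from the margins). Peri-AU-onset
firing is binned in 300 ms windows anchored at the onset (bins kept
only while fully inside the ± 0.7 s analysis window) and z-scored
against a pre-block baseline binned at the same width:
z = (FR − mean_baseline)/SD_baseline. AU onset = first frame of an
episode after at least one non-AU frame. The epoch convention for the
"hundreds of ms around onset" analysis is configurable (window and bin
width are parameters) since more than one reading is defensible.

## Problem sizes used in the shipped checks

The end-to-end checks run at desk scale as the package's own choice of
test conditions: 64 × 56-pixel frames, 4 subjects × 3 videos × 60
frames, 10 px deformations, zero noise, pose jitter on, across-subject
thresholds scaled to 60/20 (the full-scale 150/50 thresholds presuppose
corpus-sized videos), grid over k ∈ {1, 3} × pcExplVar ∈ {80, 95}. The
chance-level control uses 20 seeds at 32 × 28 pixels with zero
deformation and noise SD 6. The published-count balancing check uses
metadata-only databases with the exact class counts 1213/19 500/150 000
and 310/15 000/15 000.

## Known limitations

* Landmarks are annotated manually (files are read; no detector).
* One affine per video assumes the head is fixed within a video.
* The optimal-neutral criterion (L2 to the mean neutral) is a proxy;
  the manual override exists precisely because an expert may disagree.
* The KNN tie rules and SVM settings are this package's conventions —
  deterministic, but conventions nonetheless.
* No incremental PCA: refitting is O(n²p) per balanced set × partition.
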