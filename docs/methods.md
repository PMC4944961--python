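# Methods

This note documents the models and procedures implemented in kennelscope,
the choices made where the design was genuinely open, and what the
synthetic validation does and does not establish.

## Problem setting

A single quadruped (the motivating case is a shelter dog) lives in a
rectangular pen, here 3 × 3 m, observed by a single depth sensor mounted
side-on at 1.5 m height. The sensor delivers per-frame depth maps
(millimetres, 0 = invalid) at 10 fps. From this stream the package infers,
per frame, the animal's location in the pen, a seven-part skeleton (head,
torso, tail, four legs) with a posture label (stand, sit, lie, plus
locomotion split from stand by speed), and from those, behavioural reports
and an unsupervised clustering of recurring movement patterns.

## Scene model and segmentation

The pen geometry is a set of planes in the sensor frame — exactly one
floor plus walls — together with an orthonormal metric frame on the floor
giving pen coordinates. Planes can be constructed from three user-picked
points (`io.plane_from_points`); the synthetic generator derives them from
the camera pose.

Foreground extraction back-projects every valid pixel to 3D and removes
points within a threshold of any plane. Defaults: threshold 5 cm (above
typical sensor noise, below leg clearance), minimum blob 200 pixels,
8-connectivity. Segmentation is hysteresis-style: pixels clearing only
40 % of the threshold are kept when connected to the fully-cleared
component. Without this the animal's feet — necessarily close to the
floor — are eaten by the plane removal; with it, noiseless renders recover
the true silhouette at IoU ≥ 0.95. The largest connected component is the
blob; its 3D mean is the barycentre.

Trajectories re-project barycentres through a ground-plane homography
(image → pen floor, fit from floor-point correspondences generated by the
calibrated scene; corner reprojection must close within 1 cm). Two
systematic corrections are applied before the homography: the barycentre
is pushed 0.07 m away from the sensor along its viewing ray (the visible
surface of a body lies about one mean body radius in front of its
centroid; 0.07 m is the hemisphere-averaged offset measured on the
synthetic model), then dropped along the floor normal to remove body-height
parallax. Out-of-pen projections are clamped to the pen bounds and
flagged, keeping trajectories gap-free for alignment.

## Skeleton model

A skeleton is seven labelled line segments in metres, stored
(attachment, tip). Omitted parts (folded legs in sit/lie) use a
zero-length sentinel so every posture has a total representation. The
16-value solution vector holds, per part, the in-plane orientation angle
and projected length — the minimal parametrisation of a segment anchored
by the constraint system — plus the two components of the barycentre
motion vector. Encoding and decoding round-trip exactly on the candidate
grid.

The appearance plane is the upright image plane (sensor x, up), where the
blob's points are rasterised into a 3 cm occupancy grid smoothed with a
Gaussian (σ = 0.8 cells).

### Junction graph

For pose comparison each skeleton is summarised by a graph over the six
torso junctions (head, four leg attachments, tail) ordered along the torso
axis, with edges between torso-adjacent junctions. The edge weight is
exp(−Δθ) with Δθ the unsigned angle between the non-torso segments
incident at the two junctions; the exponential maps angles into (0, 1],
guaranteeing positive degrees for the normalized Laplacian
L = I − D^(−1/2) W D^(−1/2). Zero-length (omitted) segments fall back to
the torso direction so the graph is defined for all postures. The
descriptor is the matrix of the first k (default 3) non-trivial
eigenvectors of L, with the trivial smallest-eigenvalue component
discarded and signs fixed so each vector's largest-magnitude entry is
positive (determinism). Because only angles between segments enter, the
descriptor is invariant to rigid rotation and uniform scaling of the
animal — the property that makes pose comparison independent of the
individual's size and shape.

## Structured body-part labelling

The labeller is a linear structured model F(x, y) = w·φ(x, y) over a
discretised candidate space of skeletons.

**Candidates.** Torso segments pass through the blob barycentre at
discretised orientations (default 24) and lengths (default 5, spanning
0.45–0.85 of the blob's bounding-box diagonal); head and tail attach at
the torso ends over 8 relative angles within ±60°; legs point downward
with a splay parameter (6 configurations) and fixed length ratios. Posture
classes restrict the space: *sit* admits only pitched torsos
(rear-low/front-high arcs) and enumerates front legs only; *lie* admits
near-horizontal torsos and no legs. The per-class arcs are wider than the
world-frame pitch of the canonical poses because the projection of a
receding horizontal body axis acquires apparent pitch up to the camera
tilt (~25°).

**Features.** Per segment, occupancy is sampled at 5 points along the
segment and along two parallel lines offset ±6 cm ("ribbon" samples, 15
values) — the ribbon makes the descriptor sensitive to local thickness,
which is what separates a raised head from a thin tail. Each part block
adds a length ratio; the torso block adds a motion-alignment term
cos(θ_torso − θ_motion)·min(|m|/0.05, 1), which orients the torso so the
head end leads when the animal moves. The raw motion components pass
through. Total dimension 115.

**Training.** Online passive-aggressive max-margin updates with margin
rescaling: the loss of a candidate is its mean endpoint distance to the
(grid-snapped) ground truth, normalised by the GT torso length. Updates
are clipped at C (default 1.0) and the returned weight vector is the
average of all iterates, which is markedly more stable than the last
iterate. Epoch order is seeded; training is deterministic given
`random_state`.

**Inference.** Score and loss both decompose over parts given the torso,
so the exact (loss-augmented) argmax factorises: per torso candidate, the
best head, tail and leg configurations are selected independently, and the
best torso wins. Ties resolve to the lowest candidate index. The
brute-force enumeration over the full product grid is retained as an
independent oracle and the factorised argmax is audited against it in the
tests; they agree exactly.

## Posture classification

One structured model per posture (stand, sit, lie), each trained only on
its own class under its own constraint set; the classifier reports the
posture whose calibrated score is highest (tie order stand > sit > lie),
together with that model's skeleton.

The three raw scores are not on a common scale, and no amount of
within-class margin training can fix that: a feature that is constant
across candidates of one frame cancels out of every update, so
cross-class offsets are unlearnable in principle. Calibration is therefore
a separate layer fit on the training frames. Three modes are provided:
fixed per-model offsets from configuration, per-model mean-centering, and
(default) a multinomial logistic map over the three structured scores plus
six floor-relative blob geometry covariates — barycentre height, top
height, 20th-percentile height, vertical and horizontal extent, and the
fraction of points within 12 cm of the floor. These covariates carry the
physically decisive posture signal (a standing animal's mass is elevated
on thin legs; a lying animal's mass rests on the floor) that the
2D-projected appearance scores cannot fully resolve; inputs are z-scored
before the logistic fit. The residual ambiguity then concentrates exactly
where it belongs: between sit and lie, whose geometry overlaps
continuously through crouched intermediate poses.

Locomotion is split from stand afterwards: frames labelled stand become
locomotion when the barycentre speed over a centred 0.5 s window exceeds
0.1 m/s; sit and lie are never relabelled.

## Ethogram

Durations are frame counts times the frame period; a bout is a maximal
run of one label (an optional minimum-bout filter exists, off by default);
the interval table tiles the clip (default 300 s intervals) with a
possibly short last interval. Unknown-posture frames are reported as
"unscored" but count toward total time. Activity is time with
instantaneous speed above 0.1 m/s plus path length; grid occupancy credits
each frame period to the 3 × 3 cell containing the position, cells being
half-open [lo, hi) row-major from the pen origin, with the outer boundary
credited to the last cell. All tables export to dot-decimal CSV and
round-trip.

## Pattern clustering

A clip is cut into contiguous non-overlapping windows (default 5 s; a
trailing remainder shorter than half a window is dropped, but a clip
shorter than one window yields one window). Window symbols are either
ground coordinates or skeleton-graph descriptors — action analysis
deliberately ignores pen position, describing only how the skeleton moves.

Symbol similarity: trajectories use c = exp(−‖p−q‖/scale) with scale 1 m
(the pen is 3 m, so 1 m separates within-pen patterns well); actions use
|det(Baᵀ Bb)| over the k-column Laplacian eigenbases, clipped to [0, 1]
against round-off, which is 1 for identical spectral subspaces and 0 for
orthogonal ones.

Alignment is Needleman-Wunsch with the piecewise symbol score 2c for
c ≥ 0.5, 2(c − 0.5) for c < 0.5, and 0 for gaps — that is, +2 for a
perfect match, −1 for a complete mismatch, 0 for a gap. The zero gap
penalty is the point of using global alignment rather than time warping:
two renditions of the same behaviour at different speeds align through
gaps at no cost and still score highly. Row and column 0 of the score
table hold cumulative gap scores (all zero under the default scheme);
traceback ties resolve diagonal > up > left (score-neutral, for
determinism). The DP score is verified against exhaustive enumeration of
all global alignments on short windows.

Pairwise alignment scores form a similarity matrix; K-medoids (PAM-style
greedy swap from a seeded initialisation, objective monotone by
construction) partitions the windows after the monotone-decreasing
transform D = max(S) − S (chosen over a per-row transform to keep D
symmetric; any monotone decreasing transform preserves medoid structure).
Within each cluster, windows are reported in order of distance to the
medoid, medoid first. Cluster count is a user decision, not automated.

## Evaluation metrics

PCP: a part is correct when both predicted endpoints lie within
α × (GT part length) of the matching GT endpoints (α = 0.5, the
human-pose convention); endpoint correspondence picks the pairing with
the smaller summed distance; zero-length GT parts are excluded.
Frame-level PCP averages parts within a frame, then over frames; a pooled
parts average is also exposed (identical when all frames evaluate the
same part set). Confusion matrices are predictions × ground truth with
column-normalised percentages. Agreement between automated and manual
per-clip durations uses Spearman's rho per behaviour label, with an exact
permutation p-value for ≤ 8 clips and the t-approximation beyond.

## Synthetic recordings

The generator replaces the depth sensor: capsule limbs are z-buffered into
320 × 240 depth maps (pinhole camera, f ≈ 285 px, one lap of Gaussian
depth noise with 5 mm std by default) from scripted motion. Default body:
torso 0.60 m at 0.42 m shoulder height, head/tail 0.25 m, torso radius
0.11 m. Postures are template poses; locomotion swings the legs with gait
phase; an interpolation parameter morphs sit into lie continuously to
produce the ambiguous crouches seen in real animals. Path primitives
(stay, line with bounce, circle, perimeter circuit) compose into scripts;
four canonical pen behaviours — perimeter circling, half-pen circling,
side pacing, corner standing — serve as planted patterns, with speeds set
so one 5 s window covers roughly one full rendition, making windows of
the same pattern mutually alignable regardless of phase.

What the generator does *not* emulate: fur and long-coat occlusion,
self-occlusion beyond the capsule silhouette, sensor artefacts other than
additive Gaussian noise (no edge dropout, no sunlight washout), multiple
animals, and non-planar clutter in the pen. Passing tests therefore
demonstrate the correctness and internal consistency of the algorithms
under the stated geometry, not field accuracy on real kennel recordings.

## Study protocols and problem sizes

- **Learning curve**: training pools of 385 annotated frames (half
  stationary standing, half walking with true motion vectors, per-frame
  body proportions randomised ±25 %), nested prefixes 67/128/228/385,
  single averaged online pass with C = 0.05, 5 seeds, one fixed held-out
  set of 150 frames. The single pass makes "more data = more updates along
  one trajectory" the operative mechanism; with multi-epoch training this
  45–115-parameter model saturates at the smallest rung and the curve is
  flat. Held-out PCP rises monotonically (≈ 0.70 → 0.73 at seed 0);
  factorised inference is audited against brute-force enumeration on a
  subset of frames.
- **Confusion structure**: 3 seeds, 70 training frames per posture, 40
  clean test frames per posture plus 80 ambiguous crouches with
  interpolation in [0.35, 0.65]. Pooled over seeds, ≥ 95 % of
  misclassifications are sit↔lie and stand accuracy stays ≥ 95 %.
- **Pattern recovery**: 10 windows in composition 3/2/3/2 over the four
  pen behaviours, 4 clusters, 5 seeds; adjusted Rand index 1.0 at zero
  jitter and ≥ 0.8 at 10 cm positional jitter.

## Numerical conventions

Angles live in (−π, π] with −π mapped to π; eigenvector signs are fixed by
the largest-magnitude entry; argmax ties resolve to the lowest candidate
index; K-medoids initialisation and all data generation are seeded.
Degenerate inputs (empty blobs, missing torso, constant rank vectors,
zero-length windows) raise typed errors or return documented sentinels
rather than propagating NaNs.

## Known limitations

The appearance model is a 2D projection: poses aligned with the optical
axis are foreshortened and head/tail disambiguation at rest relies on
weak thickness cues (the motion vector resolves it when the animal
moves). Predicted skeletons carry a single depth per frame (the blob's
mean), so PCP against truly 3D ground truth degrades for poses deep along
the axis. Posture calibration is fit on the training distribution; a
sensor at a very different height or a much larger/smaller animal needs
recalibration. The .oni container of the original acquisition stack is
not parsed; recordings must be converted to the PNG-directory container
or supplied through a custom `FrameSource` adapter.
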