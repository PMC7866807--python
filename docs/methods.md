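# Methods

## Problem setting

A seated subject holds both feet off the ground, soles toward a rig of
three cameras: thermal (384 × 288 px), colour and depth (1280 × 720 px),
at a stand-off of roughly 80 cm. After registration every pixel carries
five channels (R, G, B, depth in mm, IR counts). The task is to isolate
the foot soles — the region whose temperatures matter clinically — in the
presence of background structure that can be skin-coloured (hands, face)
or warm (radiators, other body parts) but almost never lies *on the foot
plane*. That geometric fact drives the whole pipeline.

## Registration

IR images lack the contrast and features that intensity- or
feature-based registration needs, so the RGB-D rasters are brought onto
the thermal grid by a parametric transform: per-axis scale factors that
match the two fields of view, a translation, and a crop to 384 × 288.
A target pixel samples the source at `x_s = (x_t − shift)/scale`; colour
is interpolated bilinearly, depth by nearest neighbour so silhouette
edges never blend two surfaces into a depth that exists on neither.
Out-of-source pixels become black / depth 0 (0 is reserved for "no
measurement" throughout). A helper derives the scale factors from two
pinhole camera models (`tan(fov_target/2)/tan(fov_source/2)` per axis)
for users who know their intrinsics; measured parameters can be given
directly in the YAML config. Depth-dependent parallax between the
non-coaxial cameras is deliberately not modelled — the subject is a
single near-planar surface at a fixed stand-off, where a planar
approximation is adequate and anything richer would require a per-rig
extrinsic calibration.

## Skin thresholding

Skin detection is purely per-pixel: one bound rule in each of RGB, HSV
and full-range BT.601 YCbCr, combined by conjunction (configurable to
disjunction or majority). The default bounds are the widely used
combined rule — R > 95, G > 40, B > 20, R > G, R > B, |R−G| > 15;
H ∈ [0°, 50°], S ∈ [0.23, 0.68]; Y > 80, Cb ∈ [85, 135], Cr ∈ [135, 180]
— kept entirely in configuration, since different lighting or skin-tone
distributions will need different bounds. An alpha channel is ignored.
No morphology is applied by default (`clean_mask` exists but is off),
because spatial tidy-up is the depth stage's job.

## Depth refinement

Any candidate mask — the skin mask, or an external CNN prediction — is
refined in four steps:

1. **Deprojection.** Valid-depth mask pixels go through the pinhole
   model `x = (c−cx)z/fx`, `y = (r−cy)z/fy`; zero-depth pixels are
   recorded separately as undeprojectable.
2. **Statistical outlier filter.** Per point, the mean Euclidean
   distance to its k = 20 nearest neighbours (exact kd-tree search; the
   clouds are ≤ ~50 k points); points above the global mean + 2 std of
   those means are discarded. This targets stray depth samples at mask
   edges, where the depth pixel straddles the silhouette. On a finite
   uniform grid this rule necessarily trims the boundary ring — the
   per-point means are only equal in truly equidistant configurations —
   which is acceptable here: boundary attrition of a few pixels is
   exactly the intended behaviour on real masks. A tiny relative slack
   (1e−9) on the cutoff keeps zero-variance configurations intact under
   floating-point rounding.
3. **RANSAC plane.** 500 iterations; each draws 3 distinct points
   (near-collinear triples skipped by a scale-aware cross-product test),
   counts points within the distance threshold, and the candidate with
   most inliers wins (ties → first encountered). The winning inlier set
   is refitted by total least squares (smallest principal direction), and
   the returned inlier set is recomputed against the refitted plane so
   plane and set are mutually consistent. The plane is canonicalised to
   `d ≥ 0`. All randomness flows from one integer seed.
4. **Mask refinement.** Keep mask pixels with `|n·x − d| ≤ τ`.
   Undeprojectable pixels follow a policy: `drop` (default — the
   refinement operates purely on the cloud), `keep`, or
   `fill-by-neighbor-vote` (re-added when >4 of the 8 refined neighbours
   are foreground, useful for toes at grazing angles where depth drops
   out). The output is always a subset of the input mask. Pixels removed
   by the statistical filter stay removed — that filter's purpose is to
   discard noisy edge points.

### The distance threshold

τ defaults to AUTO: `c·σ̂` with c = 2, where σ̂ estimates the depth
spread *at the foot surface*. The candidate mask may be contaminated by
skin-coloured background at a very different depth; a plain sample
standard deviation then explodes (≈150 mm on the default scenes instead
of ≈4 mm), the RANSAC band swallows both depth clusters, and refinement
can do more harm than good. σ̂ is therefore a robust estimator: values
outside the Tukey fences (quartile ± 1.5 IQR) are rejected and the
sample std of the remainder is divided by 0.9711 (the normal-consistency
constant for a ±2.7σ truncation). Pure quantile estimators (MAD, IQR)
were rejected because integer-millimetre depth quantises them — at
σ = 4 mm the MAD can only land on whole millimetres, an ~11 % bias. The
fenced estimator tolerates up to 25 % contamination per tail, well above
the distractor fractions that plausibly pass a skin threshold. With
c = 2 roughly 5 % of genuinely on-plane pixels fall outside the band by
construction; c is configurable where higher recall matters.

## STAPLE fusion

Binary STAPLE treats the true segmentation and each rater's sensitivity
p_j and specificity q_j as joint unknowns, estimated by EM (equations in
the module docstring). Implementation choices:

- the foreground prior γ defaults to the mean foreground fraction over
  raters (config-overridable); a spatially varying prior is out of scope;
- initialisation p₀ = q₀ = 0.99999, the classical recommendation;
- convergence on the performance parameters (max-abs change < 1e−7,
  ≤ 200 sweeps), with a final E-step so the posterior matches the
  converged parameters; estimates clamped to [1e−6, 1−1e−6];
- E-step products in log space; pixels are grouped by identical
  rater-decision pattern, so a sweep costs O(2^R) pattern evaluations —
  the 384 × 288 × 5-rater fusions in the tests run in milliseconds;
- the observed-data log-likelihood Σ log(a_i + b_i) is recorded every
  sweep; the test suite asserts it never decreases;
- left and right feet, delineated separately in practice, can be fused
  independently and OR-combined (`fuse_sides`);
- rating automatic approaches against each other is the same
  computation (`rate_segmentations`), each algorithm playing rater.

A stack that is entirely foreground or entirely background is rejected
as degenerate (the prior is empirically undefined there).

## Metrics, loss, statistics

Overlap metrics follow the standard confusion-count definitions; the
library returns fractions, the reporting layer formats percentages
(mean ± std, two decimals, per timepoint T0/T5). Conventions: two empty
masks score DICE = IoU = 1; ratio metrics with a zero denominator raise
an explicit undefined-metric error rather than returning 0.

The training loss is `α·BCE + (1−α)·(1 − softDICE)` with smoothing
s = 1 and probability clamping at 1e−7. The Dice term enters as a
*loss*: a formulation in which better overlap increases the objective
cannot be minimised meaningfully, so the similarity-coefficient reading
is provided only behind `dice_term="similarity"` for comparison.

Wilcoxon matched-pairs testing discards zero differences, uses the
exact null distribution for n ≤ 25 without ties and the normal
approximation with tie and continuity correction otherwise (delegated
to scipy). The Hochberg step-up adjustment is implemented directly
(adjusted p_(k) = min over j ≥ k of (m−j+1)·p_(j), clipped to 1) and is
cross-checked against statsmodels in the tests.

## Synthetic scenes: what they do and do not show

Each scene renders two stylised feet (elliptical sole + five toe discs,
randomised position/rotation/scale) at 800 ± 4 mm with 1.5 mm sensor
noise, a background plane at 1300 mm, skin-toned RGB (224, 180, 150 with
per-scene jitter and per-pixel noise of std 5), IR counts ~600 above
background with a smooth gradient, and distractors at background depth:
by default two skin-coloured and one warm-only, radii 10–18 px — about
what a hand or forearm subtends at 1.3 m with these optics. Distractors
are rejected-sampled to stay clear of the feet, so the ground truth is
exactly the rendered silhouette. Simulated raters optionally perturb the
boundary morphologically, then flip each foreground pixel off with
probability 1−p and each background pixel on with probability 1−q.

What passing on these scenes demonstrates: the algebra and geometry of
every stage (exactness against brute-force oracles), parameter recovery
under the models' own assumptions, and the end-to-end claim that depth
refinement removes off-plane skin-coloured structure without sacrificing
the feet. What it does not demonstrate: robustness to real illumination,
diverse skin tones (the threshold bounds are known to be
population-sensitive), arched or deformed soles that violate the
single-plane model, registration parallax, or depth sensor artefacts
beyond i.i.d. noise and dropouts. Numbers measured here (e.g. mean SPD
DICE ≈ 0.97 over 50 default scenes) characterise the synthetic
conditions, not clinical data.

## Problem sizes

The test suite and the acceptance script run at desk scale: full-size
(384 × 288) rasters wherever the operation is cheap (scene generation,
SPD, STAPLE fusion), 50 scenes for the refinement-benefit experiment,
5 000-point clouds for plane recovery, 200 random 64 × 64 mask pairs for
metric exactness, and 8 × 8 instances for the plain-arithmetic EM
cross-check. Everything is seeded; repeated runs are bit-identical.

## Known limitations

- One plane is fitted for both feet jointly; a per-foot fit via
  connected-component splitting is possible but not the default, and
  genuinely non-planar soles (high arches imaged obliquely) will lose
  pixels at the 2σ band.
- The skin model is a fixed threshold rule, not adaptive; the defaults
  encode a light-skin operating point.
- The statistical filter's boundary attrition is indiscriminate: on very
  thin structures (toes a few pixels wide) it can erode genuine surface.
- CNN training and inference (the U-Net/SegNet halves of the original
  workflow) are out of scope; the refinement stage accepts their
  predictions as external candidate masks.
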