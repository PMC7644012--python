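# Methods

## Model

`doubleyolk` implements a Mamdani-type fuzzy inference system over two
egg indicators: the weight WI in grams and the dimensionless geometric
indicator GI = major-axis length / minor-axis length (≥ 1).

**Membership functions.** Each indicator carries three piecewise-linear
fuzzy sets generated from one strictly increasing anchor triple
(l, m, h): *low* = shoulder (degree 1 for x ≤ l, linear to 0 at m),
*medium* = triangle (0 at l, 1 at m, 0 at h), *high* = shoulder (0 at m,
1 from h on). The shoulders cover the whole real line, so every input
fuzzifies to valid degrees and at most two of the three are nonzero.
The printed triangle definition assigns 1 only exactly at the peak; the
linear ramps attain 1 there anyway, so the continuous form is
value-identical and is what we evaluate. Degenerate (non-increasing)
anchors are rejected rather than special-cased: no useful configuration
contains them.

**Inference.** Rule strengths are the pairwise minima of the GI and WI
degrees, in row-major order R1…R9 (GI category major). The rule grid maps
(GI, WI) categories to SY/DY; the default grid is the one shown in the
README. Per output class the strengths are aggregated by root-sum-square
(RSS). The output membership is modelled as two *singletons* at centers 0
(SY) and 1 (DY): drawn output sets are triangles in some presentations,
but the centroid arithmetic uses only the two center values, and the
singleton form reproduces the reference worked example exactly
(0.612 / 0.50 → 0.449). The centroid (center-of-gravity) defuzzification

    t = (F_SY·c_SY + F_DY·c_DY) / (F_SY + F_DY),  c_SY = 0, c_DY = 1,

is therefore the DY mass fraction. An egg is labeled DY iff t ≥ 0.5; the
tie goes to DY so the premium class is the closed set (the threshold is
configurable). If no rule fires — impossible with shoulder sets, possible
with a user-supplied grid — the result is flagged `degenerate` and
defaults to t = 0 (SY) instead of raising, so batch runs never die on one
odd egg.

**A non-obvious property: the truth surface is not globally monotone.**
One might expect t to be non-decreasing in weight and in ratio, since the
rule grid is monotone row- and column-wise. It is not, and this is a
structural property of min-firing plus RSS, not a bug: when an input's
membership splits across two adjacent categories whose rules conclude the
*same* class, the min operator caps both strengths and
√(a² + b²) < a + b loses aggregate mass relative to the unsplit case.
Concretely (case3 preset): at 83 g, WI = (0, 0.2, 0.8); at ratio 1.30
only R2 (0.2, SY) and R3 (0.8, DY) fire and t = 0.800, while at ratio
1.35 the GI mass splits (0.5, 0.5, 0), R3 = R6 = 0.5, and
t = √0.5 / (√0.08 + √0.5) ≈ 0.714 — a *more elongated* egg scores
*lower*. The dips are local (≲ 0.09) and rarely cross the 0.5 boundary.
Monotonicity does hold along any grid on which the other input sits
wholly in a single category; the test suite asserts exactly that, plus
the frozen counterexample above.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| GI anchors (case3) | 1.30, 1.40, 1.50 | — | flock ratios span ≈1.30–1.50; >1.50 is almost surely DY |
| WI anchors (case3) | 65, 75, 85 | g | production preset: lowest SY-error among the 20-case sweep family |
| WI anchors (worked_example) | 66, 74, 82 | g | 66 g ≈ upper bound of clearly-low weights, 82 g ≈ onset of clearly-large eggs |
| decision threshold | 0.5 | — | midpoint of the two output centers; ties to DY |
| output centers | 0, 1 | — | truth value readable directly as DY propensity |

The two WI presets coexist deliberately: the worked-example arithmetic is
defined (and tested) under (66, 74, 82), while (65, 75, 85) is the
configuration recommended for deployment. No automatic anchor optimizer
is provided; choosing anchors is an evaluation exercise (`sweep`), not a
fitting step.

## K-means baseline

Lloyd's algorithm, k = 2, on raw (grams, ratio) coordinates. Distance is
*unscaled* Euclidean by default — the gram axis then dominates the
dimensionless ratio axis by two orders of magnitude, making the split
nearly a weight threshold. That is intentional: it is the baseline whose
failure on the overlap zone motivates the fuzzy approach
(`scaling="standardize"` is available but off by default). Convergence is
declared on *exact* centroid repetition, with a max_iter = 100 guard; the
per-iteration centroid trace is kept so the stopping behavior is
inspectable. A cluster that empties keeps its previous centroid and the
result is flagged. Initialization defaults to two data-plausible extremes
(57.64 g, 1.2599) / (97.78 g, 1.5065) for reproducibility; a seeded
uniform init over the data's bounding box is available. The lighter-
centroid cluster is read as SY (tie on weight broken by ratio; fully
identical centroids raise).

## Error accounting

All error figures are percentages of **all** eggs graded, not per-class
recalls: SY-error = 100·(true SY graded DY)/n, DY-error = 100·(true DY
graded SY)/n, total = their sum (= overall misclassification rate). The
commercially primary figure is the SY-error — DY buyers must not receive
SY eggs — with total error secondary. Text output rounds to 2 d.p.; full
precision is kept internally.

## Synthetic population

The generator emulates a commercial flock with 180 SY / 99 DY eggs
(stratified, so counts are exact and reproducible), default seed 1105.
Class means are fixed at (69.61 g, 1.3494) for SY and (84.92 g, 1.4202)
for DY. The class shapes are deliberately asymmetric, because the overlap
structure is the whole point:

* **SY**: weight is skew-normal (shape 4, SD 7.0 g) — a right tail of
  large SY eggs reaches into the 78–85 g zone;
* **DY**: a two-mode mixture — 35% "small DY" eggs at (78.5 g, 1.41),
  SD (4.0 g, 0.045), which mingle with those large SY eggs, and 65%
  "large DY" eggs (SD 4.5 g, 0.045) whose mode is derived so the class
  mean lands exactly on the configured value;
* within every component, weight and ratio correlate at 0.3 (heavier
  eggs run slightly longer), via a conditional draw that preserves the
  marginal means/SDs;
* weights truncate at 40 g and ratios at 1.01 (no physically impossible
  eggs); each egg also gets consistent major/minor axes in mm from a
  weight-dependent width (≈ 44 mm at 60 g).

The skew and mixture parameters were calibrated once against the
reference behavior of the unscaled K-means baseline on such a flock —
an error signature dominated by SY errors (≈ 11% SY / ≈ 4% DY of all
eggs) — and then frozen. With symmetric Gaussian classes that signature
is unobtainable (a two-means weight threshold is then near-optimal and
*beats* the fuzzy classifier), i.e. symmetric clusters do not represent
the population this tool exists for. What passing tests on this
population show is that the classifier behaves as designed *on data with
this overlap structure*; they cannot certify error rates on any real
flock, whose dispersions, tail weights and DY sub-population are not
anchored to published measurements. Dispersion values here are modelling
choices, not measured quantities.

## Image geometry

`extract_geometry` follows the classic chain: luminance grayscale →
Canny edges (thresholds default to automatic values — Otsu on the Sobel
gradient magnitude, low = high/2 — overridable) → contour extraction →
minimum-area rotated enclosing rectangle (rotating calipers over the
convex hull, via shapely); the rectangle's side lengths are the axes and
their quotient the GI, which needs no pixel-to-mm calibration. The
boundary handed to the rectangle step is traced with sub-pixel
marching-squares contours at the Otsu iso-level of the smoothed image
(largest contour wins; others are logged): binary edge pixels quantize
the boundary by ~1 px, and because the enclosing rectangle's area is
nearly flat in rotation for an ellipse (it grows ∝ sin² 2φ), that
quantization lets the minimum-area rectangle tilt several degrees and
bias the ratio by 2–3%. Sub-pixel contours keep the ratio error well
under 1% across rotations; the rectangle's *angle* still wanders a few
degrees — inherent to the flat minimum, and irrelevant to the ratio.
The synthetic renderer draws an egg-colored ellipse (optional linear
ovoid taper ≤ 0.3, optional Gaussian pixel noise, seeded) on a green
background with ground-truth axes stored, so accuracy is testable
end-to-end. Conventions: pixel units, origin top-left; angles in degrees
CCW from horizontal.

## Problem sizes

Defaults keep every computation interactive: populations of 279 eggs
(10,000 for distributional checks), oracle comparisons on 1,000 random
inputs, rendered test images of ≈ 320×240 px, sweeps of 20
configurations. The full test suite runs in a few seconds.

## Known limitations

* Anchors are chosen by evaluation, not optimization; no optimizer ships.
* The truth surface's local non-monotonicity (above) is inherent to
  min + RSS aggregation; applications needing a monotone score should
  aggregate differently (out of scope here).
* The synthetic flock fixes nothing about real flocks beyond its class
  means, counts and the qualitative overlap structure; error percentages
  measured on it do not transfer.
* The geometry module assumes one egg on a contrasting background,
  externally lit; candled or multi-egg scenes are out of scope.
* Hen age, breed and lay-order effects on DY incidence are not modelled.
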