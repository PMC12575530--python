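# Methods

This note documents the models, algorithms and defaults behind `pancad`, the
choices made where the design was genuinely open, and what the synthetic
phantoms can and cannot tell you about real CT data.

## The detection model

Two per-case scores feed a disjunction rule:

* **Mass channel** — the maximum of a voxelwise tumor-likelihood volume in
  [0, 1]. The package treats this volume as input; producing it (typically a
  3-D CNN over the pancreatic-phase CT) is outside scope. The maximum is a
  deliberately simple summary: it asks only "did anything anywhere look like
  tumor, and how strongly".
* **Duct channel (D/P ratio)** — a geometric indirect indicator. A tumor
  obstructing the main pancreatic duct (MPD) dilates it upstream, i.e.
  tail-ward of the lesion, while the drained parenchyma atrophies; both
  effects push up the ratio of duct to parenchyma cross-sectional area. The
  per-case score is the 90th percentile of that ratio over all centerline
  stations: high enough to respond to a dilated *segment* (which spans many
  stations), robust to a few aberrant sections, and insensitive to where
  along the organ the dilation sits.

A case is positive iff either score strictly exceeds its threshold.
"Strictly" is a choice — the verbal rule "above the threshold" does not
decide boundary equality — and is configurable; with strict comparison the
duct threshold can be set to the maximum control score and still yield
exactly 100% calibration specificity.

### Threshold calibration

On a labelled threshold-setting set, the mass cutoff is the largest value
keeping the fraction of cancers strictly above it at ≥ 80% (realized as the
midpoint between the adjacent distinct observed scores, which makes the
cutoff stable to float jitter); the duct cutoff is the smallest value
holding control specificity at 100%, i.e. the largest control score. The
asymmetric targets reflect the channels' roles: the mass channel is the
sensitive front line, the duct channel must not erode combined specificity
beyond what the mass channel already costs. Calibrated cutoffs are
data-dependent by construction; numerical values from one cohort (including
any published ones) do not transfer to another.

## Geometry pipeline

### Centerline

Union of parenchyma and duct masks (the duct bridges parenchymal gaps at the
neck) → largest connected component → 3-D skeletonization
(`skimage.morphology.skeletonize`) → graph over skeleton voxels
(26-connectivity, edges weighted by physical distance) → geodesic diameter
(longest shortest path over endpoint pairs, ties broken by smallest linear
voxel index, so the result is deterministic) → end extension → moving-average
smoothing (window 5 stations) → arclength resampling at 1 mm →
central-difference unit tangents.

The end-extension step exists because skeletonization of a tubular mask
retracts by roughly one organ radius at each end; the geodesic path is
therefore prolonged along its end tangents until it exits the mask. On
straight test cylinders this recovers the full axis length to within a
voxel. Skeleton-graph geodesics were chosen over distance-transform ridge
tracing for determinism and simplicity; the module boundary would admit
either.

Head/tail orientation is not decidable from a binary mask and is supplied as
configuration: an explicit head coordinate or an anatomical direction vector
(head = endpoint with the larger projection). The phantom generator lays the
organ head→tail along +x, so the pipeline default vector is (−1, 0, 0).

### Cross-sections and the D/P profile

At every station a square plane orthogonal to the tangent (half-width 40 mm,
covering the pancreatic caliber with margin) is sampled by nearest-neighbour
lookup at the native in-plane pitch (the smallest voxel spacing);
out-of-volume samples are background. The in-plane basis is the tangent
crossed with its least-aligned coordinate axis, then orthonormalized —
deterministic and smooth along the path.

The ratio's denominator is the parenchyma mask **excluding** the duct lumen:
segmentation labels are mutually exclusive, so this is what the masks
naturally measure. The alternative convention duct/(parenchyma + duct)
differs by < 5% at physiological ratios and sits behind a config switch.
Stations with parenchyma area < 20 mm² are flagged invalid and excluded from
every summary: the ratio diverges as the denominator vanishes at the organ
tips. The percentile uses the linear-interpolation quantile definition
(position q/100·(n−1) in the sorted valid ratios) — quantile conventions
differ across ecosystems, so the choice is fixed and tested.

### Jump localization

"The location where the D/P ratio increases sharply from head to tail" is
formalized as: median-smooth the valid-station ratio sequence (window 5),
take the station maximizing the forward difference (next − current) scanning
head→tail, and accept it if that difference reaches `min_jump` = 0.01
(about a quarter of the step a mild 1.5× dilation produces at baseline
anatomy); ties go to the most head-ward station, a flat profile yields no
location. Median smoothing suppresses single-station spikes without
smearing a genuine step by more than half the window.

### Segments

Arclength-fraction breakpoints head [0, 0.40), body [0.40, 0.70),
tail [0.70, 1] — approximating the anatomical proportions of head, body and
tail along the organ axis. The uncinate process is a sub-region of the head
that arclength cannot distinguish; it exists only as an explicit truth
label, and localization concordance treats "head (uncinate process)" as
matching a predicted "head" at its default granularity. Undetected cancers
are excluded from the concordance denominator by default (no predicted
location exists to compare); a switch counts them as discordant instead.

## Evaluation statistics

* **Proportions** (sensitivity, specificity, PPV, NPV): Wald 95% intervals
  p̂ ± 1.96·√(p̂(1−p̂)/n), clipped to [0, 1]; zero-denominator metrics are
  flagged undefined, never reported as 0. Wald is the package default
  because it is the convention of the diagnostic-accuracy reports this
  engine is meant to reproduce; Wilson and Clopper–Pearson are available
  behind a flag for small-sample work.
* **Exact McNemar** for paired sensitivities: p = min(1, 2·P(X ≤ min(b, c))),
  X ~ Binomial(b + c, ½) over the discordant pairs; p = 1 when b = c.
* **Fisher exact R×2** by complete enumeration of tables with the observed
  margins, summing the conditional multivariate-hypergeometric probability
  of every table no more probable than the observed one. Probabilities are
  compared as exact integer numerators over the common denominator
  C(N, c₁), so the test is bit-reproducible with no floating-point
  tolerance; enumeration is instantaneous at the 4×2/n≈100 scale this
  package meets. Reduces to the textbook 2×2 test.
* **ROC**: threshold sweep over distinct scores under strict `>`, trapezoidal
  AUC, ties grouped.
* **Decision curves** for binary tests: NB(pt) = TP/N − (FP/N)·pt/(1−pt),
  with treat-all and treat-none references. Note that with *binary* verdicts
  the curves of two tests can cross even when one dominates the headline
  rates; a claim that one model's net benefit is higher over a whole
  threshold range need not follow from its confusion table and should be
  checked with `NetBenefitCurve.crossing`. Applying this formula to
  published confusion counts of the combined rule versus the duct channel
  alone shows exactly such a crossing near pt ≈ 0.27 — a reminder that DCA
  on binary tests is not settled by sensitivity/specificity orderings.
* Bonferroni-adjusted stratified comparisons use α = 0.05/k with k the
  number of metric families compared (k = 4 → α = 0.0125).

Rounding for display: one decimal for percentages, three for p-values;
internal values are never rounded.

## The phantom generator

Each case is a curved, tapering tube of parenchyma (cubic spline through
four control points, ~110 mm long, radius 11→8 mm head→tail) with a coaxial
duct (radius 1.6→2.0 mm), rasterized on a 1 mm grid by exact point-to-segment
projection (so boundary voxels are not lost to curve-sampling jitter) and
truncated at flat end planes. Cancer cases multiply the duct radius by a
dilation factor (cohort default range 1.3–2.5) and the parenchyma radius by
an atrophy factor (0.75–0.95) tail-ward of the tumor fraction s₀, and add a
Gaussian heatmap blob (σ = tumor radius/2) at the tumor center; tumor
diameters are drawn from 7–20 mm, matching the small-PDAC (≤ 2 cm, T1)
definition with a typical median of 16 mm. Controls carry only distractor
blobs (1–3 per case, amplitude 0.05–0.5) and voxel noise (σ = 0.02), so a
minority of cancers — those whose blob amplitude, drawn from 0.2–0.95, falls
inside the distractor range — are mass-invisible and detectable only through
the duct channel, which is the clinical scenario motivating the indirect
indicator. Segmentation error is emulated by independent boundary-voxel
flips at a rate of `surface_noise_sd / voxel_spacing` (default 0.05).

Masks are exclusive (duct voxels removed from the parenchyma mask) and the
duct always lies inside the parenchyma envelope. Every spec also yields an
**analytic D/P profile** — r(s)²/(R(s)² − r(s)²) with no voxelization —
used as the oracle the measurement pipeline is tested against. Everything is
deterministic given the spec seed; cohorts are bit-reproducible.

What the phantoms do **not** model: CT intensities and contrast phases,
duct-branch anatomy, fatty infiltration of the parenchyma, tumors carved out
of the parenchyma mask (the tumor exists in the truth record and heatmap
only), the uncinate process's geometry, and inter-observer segmentation
style. Passing phantom tests therefore validates the geometry, calibration
and statistics of the pipeline — not clinical performance, which depends on
upstream segmentation and heatmap quality.

## Problem sizes and numerical choices

Default grids are 128×80×48 voxels at 1 mm (cohort cases) and up to
256×100×100 at 0.5 mm for the convergence checks; test and acceptance
cohorts use 12 threshold-setting plus 28–40 evaluation cases, sizes at which
the full pipeline runs in a few minutes on one CPU while leaving the
rank-order and recovery properties clearly measurable. Voxelization puts a
~3% floor on cross-sectional-area accuracy at 1 mm for a 2 mm-radius duct;
the geometry tests assert the analytic ratio within 10% at 1 mm and 5% at
0.5 mm. Degenerate inputs fail loudly and specifically: empty masks,
single-voxel skeletons, planes with no evaluable parenchyma, one-class
calibration sets and unattainable sensitivity targets all raise with
diagnostic messages rather than returning silent zeros.

## Known limitations

* The centerline is a single curve; multi-branch duct trees are out of scope.
* Orientation needs external information (a direction vector or head point);
  there is no automatic anatomical head detector.
* The heatmap maximum ignores spatial extent; `component_voxel_count` is
  reported but unused by the classifier.
* Calibration quantile behaviour with very small threshold-setting sets is
  coarse (a 6-case set moves the mass cutoff in 1/6-sensitivity steps), so
  per-channel test rates on small synthetic cohorts scatter widely around
  their targets even though the disjunction identities always hold.
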