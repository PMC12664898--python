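# Methods

## Scope and model

`clickmap3d` quantifies regional proliferation from 3D fluorescence volumes
of click-labelled (EdU⁺) nuclei.  The pipeline is point-based: nuclei are
reduced to centroids early, and every later stage (normalization, region
lookup, statistics) operates on point sets rather than volumes.  This keeps
whole-brain analysis tractable and makes each stage auditable — the number
of points entering and leaving every stage is logged, because points are
legitimately lost at the noise filter and at the atlas boundary.

Coordinates are physical micrometres.  A grid with spacing *s* places voxel
*i* over the half-open interval [*i·s*, (*i*+1)·*s*); the origin sits at the
most left-anterior-superior voxel, and a point maps to voxel
⌊point / s⌋.  Axes are abstract (axis0–axis2); the hemisphere midline axis
is configurable and defaults to axis2.

## Detection

**Background subtraction.** Output = input − Gaussian(input, σ), clipped at
zero.  σ (default 15 μm) must exceed the nuclear radius, otherwise the
subtraction eats signal; a warning is raised if it does not.

**Pixel classification.** A random forest (100 trees, depth ≤ 12, fixed
seed) on a per-voxel feature bank: raw intensity plus Gaussian,
gradient-magnitude and Laplacian responses at scales {0.7, 1.6, 3.5} ×
voxel spacing.  The feature set is a standard interactive-segmentation
surrogate; the exact bank used by GUI tools of this kind is not published,
so the scales are exposed in the model record and serialized with it.  A
plain intensity threshold is available as a fallback mode and is flagged in
provenance.

**Three-voxel rule.** Connected components (26-connectivity by default;
configurable, recorded in provenance) with fewer than `min_voxels = 3`
voxels are discarded as noise.  The minimum is deliberately *not* rescaled
with voxel size: the rule is applied at the working resolution of 3.65 μm,
where one nucleus spans ~8 voxels and a single-voxel speckle can never
survive.

**Splitting touching nuclei.** Freshly divided cells sit at
centre-to-centre distances of 1.0–1.5 diameters, so their rendered
footprints merge into one component while their volumes stay nearly
additive.  The default splitter exploits this: the implied count is
`round(component voxels / analytic sphere voxels)` with the sphere volume
(4/3)πr³ taken from the expected nuclear radius (default 4.5 μm), and the
component's voxels are partitioned by intensity-weighted k-means on their
physical positions.  A marker-controlled watershed (h-maxima of the
Euclidean distance transform, h = 0.3 × expected radius, computed on a ×3
upsampled mask) is available as `split_method="watershed"`.  We made the
volume heuristic the default after observing that at 3.65 μm a ~9 μm
nucleus spans only ~2.5 voxels per axis, so the distance transform of the
binarized mask is too quantized to seed a watershed reliably; the volume
route does not have that failure mode, at the price of assuming
approximately equal-sized, sphere-like nuclei — which is exactly the regime
the package targets.

**Centroids.** Intensity-weighted mean of each instance's voxel centres
(unweighted available).  Component voxel counts are recorded per point.

**Validation metrics.** Both metrics are scored against synthetic ground
truth by nearest-centroid matching within one nuclear diameter.
*Signal/noise accuracy*: fraction of ground-truth objects (true nuclei +
injected speckles) classified correctly — a nucleus counts as signal if any
retained detection lies within one diameter; a speckle counts as noise if
no unassigned detection sits within two voxels of it.  *Count accuracy*:
fraction of ground-truth clusters whose assigned-detection count equals the
true member count; every detection is assigned to the cluster of its
nearest true nucleus, so over-splitting is penalized exactly like
under-splitting.  The underlying study validated both quantities against
manual curation; the formulas above are this package's explicit,
reproducible versions of those checks.

## Normalization

The transform chain mirrors the ANTs-style point convention: the forward
affine (tagged `atlas->sample`) is **used inversely**, then the stored
inverse deformation field (displacements in μm on the atlas grid) is
**applied directly** — sampled trilinearly at the affine-mapped position
and added.  Direction tags are mandatory and checked before any maths.
Points falling outside the field support are clamped to the edge
displacement and flagged, never dropped: silent extrapolation hides
registration failure.

Affine estimation initializes from centres of mass (`init="moments"`) and
refines 12 parameters (Euler angles, log-scales, shears, translation) by
Nelder-Mead on mean-squared intensity error, resampling the moving volume
onto the fixed grid each evaluation.  Estimation of the nonlinear field is
out of scope by design — it belongs to dedicated registration tools; the
package consumes their output (4-D NIfTI) or synthetic fields.

The synthetic inverse (atlas→sample, used to render "acquired" data from
atlas-space ground truth) is evaluated by fixed-point iteration
u ← q − D(u), which converges quickly for the smooth, few-voxel-amplitude
fields in scope and keeps forward-then-inverse round trips well under a
quarter voxel RMS.

## Atlas annotations

All annotations are pure relabelings — voxel positions never change.

* **SVZ layer**: parent-region voxels face-adjacent (6-connectivity by
  default, so the layer is genuinely one voxel thick) to the adjacent
  region are relabelled with the reserved custom ID (default 5).  The tool
  refuses if the ID already exists rather than renumbering silently.  A
  flag controls whether the layer is excluded from the parent or counted
  both ways, because both bookkeeping conventions are in legitimate use.
* **Consensus mask**: voxels positive in ≥ `min_votes` (default 4) of N
  (default 7) registered sample masks get the custom ID, optionally
  excluded from their original regions.
* **Hemispheres**: left-side voxels get base ID + 1,000,000,000; right IDs
  stay unedited; ontology records are duplicated with "left "/"right "
  name prefixes.  For an odd midline axis the exact midplane column stays
  on the right (logged).  After this step the ontology is a two-tree
  forest, which every consumer (lookup, aggregation, volumes) handles via
  the offset arithmetic.

## Quantification

* **Density** = count / region volume (nuclei·mm⁻³).  The source workflow
  reports a "ratio of EdU-positive nuclei" without units; per-volume
  density is the natural reading and a per-voxel variant is exposed for
  comparison.  Points mapped to ID 0 (outside the brain) are reported in a
  dedicated unassigned row and excluded from fractions.
* **Voxel collisions** (two or more nuclei in one voxel) are evaluated at
  10/25/50 μm.  Binning is hierarchical: the finest level uses absolute
  half-open binning; each coarser level bins the previous level's voxel
  corner.  Plain absolute binning at every size would violate monotonicity
  because 10 and 25 μm grids do not nest (points at 24 and 26 μm share a
  10 μm voxel but not a 25 μm one); the hierarchical scheme coincides with
  absolute binning for nested sizes, reflects that nuclei are quantized to
  the reference grid before any coarser analysis, and makes "ratio
  non-decreasing in voxel size" a theorem rather than a tendency.
* **Colocalization** uses a strict threshold (distance < 5 μm by default;
  a pair at exactly 5 μm does not match) and one-to-one matching of
  maximum cardinality and, among those, minimum total distance (rectangular
  assignment per connected component of the candidate graph).  Greedy
  nearest-first matching was rejected because it is only maximal, not
  maximum, and can under-count colocalized pairs.  Per-region tallies
  report A⁺B⁺ and A⁻B⁺ counts and the A-within-B ratio; the denominator
  ambiguity (all B⁺ vs B⁺ inside assigned regions) is resolved by emitting
  both.
* **Migration distance** is the pulse-chase product speed × time,
  documented as a displacement estimate (straight-line, constant speed).

## Synthetic generator

The generator emulates, with one explicit integer seed per call:
region-dependent nucleus densities (ventricular-shell enrichment), clusters
of 1–4 nuclei at 1.0–1.5 diameters spacing, spheres of radius 4.5 μm
(mouse-brain nuclei are of order 9–10 μm across), isotropic Gaussian PSF,
Poisson shot noise scaled by `photon_scale` plus Gaussian read noise,
single-voxel speckles disjoint from nuclei, a bright two-voxel surface rim,
a smooth anatomy-correlated autofluorescence channel, depthwise
attenuation, and a known affine + Gaussian-filtered random displacement
field.  `photon_scale` is the mean photon count of a nucleus; setting it to
zero yields an empty channel, and `shot_noise=False` gives analytically
predictable volumes for oracle tests.

It does **not** emulate: tile stitching and overlap, anisotropic or
depth-varying PSFs, nucleus size/shape variability, autofluorescence
bleed-through into the signal channel, or registration-estimation error
(the deformation is known exactly).  Passing benchmarks therefore
demonstrates the correctness of the pipeline's logic under a realistic
noise and clustering regime, not detector performance on real tissue —
in particular, real masks come from a classifier trained on human
annotations, whose errors the ground-truth-derived sparse labels only
approximate.

No quantitative per-region density is published for the real tissue, so the
benchmark defaults (10,000 mm⁻³ in the ventricular shell, 1,800 mm⁻³
elsewhere; cluster mix 40/30/20/10 % for sizes 1–4) are this package's own
choices, sized to produce a few hundred clusters at toy-atlas scale; they
are documented here and are not claims about the source study's data.

## Benchmark problem sizes

The standard benchmark uses a 48³ toy atlas at 10 μm (six regions), five
scenes (seeds 1–5 offset by the run seed), rendering at 3.65 μm (≈ 132³
voxels per volume), 120 speckles per volume, ~170 nuclei in ~87 clusters
per scene.  Scenes 1–2 train the classifier from ground-truth-derived
sparse labels (400 foreground, speckles + halo + 400 background voxels);
scenes 3–5 are held out and pooled for scoring (≈ 256 clusters, above the
200-cluster floor the validation design calls for).  These sizes are the
package's reference configuration: large enough for stable fractions,
small enough to run on a laptop core in well under five minutes.

## Known limitations

* The affine estimator is single-resolution (plus the moments
  initialization) and uses mean-squared error only; multi-modal
  registration (different stains) needs an external tool.
* The volume-based splitter assumes near-equal nucleus volumes; strongly
  size-dispersed populations would need the watershed route with a
  calibrated radius.
* Consensus and SVZ annotations operate on supplied masks/regions; no
  interactive painting is provided.
* Group-level statistics (ANOVA, paired tests) are deliberately out of
  scope; the package emits tidy CSV tables for external stats software.
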