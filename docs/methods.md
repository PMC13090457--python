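# Methods

## Measurement model

The pipeline quantifies where injected radiopaque microspheres ended up
inside a whole organ imaged by microCT at isotropic voxel spacing
(default 0.1 mm). All grids in one analysis must share shape and spacing;
nothing is resampled, and combining mismatched grids raises. Voxel centers
sit at `origin + (index + 0.5)·spacing` (0-based indices).

**Segmentation.** The embolic/vessel mask is `intensity > threshold`
followed by removal of connected components smaller than
`min_component_voxels`. The rule is deliberately simple: radiopaque beads
are engineered for high contrast, and a deterministic rule is reproducible
and monotone in its threshold (raising it never adds a voxel). It replaces
interactive pixel-classifier segmentation; the docs and the API say so
rather than hiding it.

**Depth stratification.** "Eroded by N pixels from the surface inwards" is
read metrically: a foreground voxel survives iff the Euclidean distance
from its center to the nearest background voxel center exceeds N (ball
structuring element via distance-transform thresholding). N iterations of
a 6/26-neighborhood kernel would instead carve chamfer (diamond/cube)
geometry, increasingly anisotropic at N = 50–100. The strict inequality
puts voxels at distance exactly N in the *shell*, so shell(N) is precisely
"within N pixels of the surface", and erosion by 0 is the identity (every
foreground voxel has distance ≥ 1). Distances are computed with a Maurer
exact Euclidean transform in squared-distance mode: squared distances are
exact integers, so integer depth thresholds never hit floating-point ties,
and after `sqrt` the field is bit-identical to
`scipy.ndimage.distance_transform_edt` (which the tests use as an
independent oracle, alongside brute-force nearest-background search). The
mask must have background on every grid face; phantoms guarantee a margin.

**Quantification.** Both overlay volumes are binary, so "intersection at
positive values" is voxel-wise AND. Per depth d:
`efficiency(d) = intersect_voxels / kidney_volume_ml` (voxels/ml) and
`percent_embolized_cortex(d) = 100·intersect_voxels / shell_voxels`.
Conventions that the measurements themselves do not pin down, fixed here:

- the percent metric divides by the shell's own voxel count (a
  "percentage of embolized cortex" is most naturally a fraction of
  cortex); a whole-kidney denominator is available via
  `percent_denominator="whole"`;
- efficiency counts voxels, not components — the literal reading of
  intersecting binary volumes;
- "particle count" is the connected-component count of the segmented mask
  at 26-connectivity (sub-voxel beads touching diagonally after noise must
  not split into two counts). Beads that abut merge into one component and
  under-count; exact-recovery tests therefore use phantoms with a 2-px
  center-separation floor;
- a component belongs to a region iff its voxel centroid (mean voxel
  index, rounded half-up per axis) lies in the region; since shell and
  inner region partition the organ, components are partitioned too;
- kidney volume for normalization defaults to the mask-derived volume
  (`voxels·spacing³`); the sonographic ellipsoid volume
  `V = (π/6)·L·W·H` is available as an alternative normalizer.

**Paired inference.** Each subject contributes one kidney per technique,
so every metric is a within-subject difference d = continuous − pulsed.
The paired t-test is textbook (`t = mean(d)/(sd(d)/√n)`, n−1 df; undefined
and raising when sd = 0). The Wilcoxon signed-rank test is implemented
in-house with an exact mode that enumerates all 2ⁿ sign assignments of the
|d| ranks (n ≤ 20): with n = 7 pairs the attainable two-sided levels are
k/64 and the normal approximation is not trusted. Ties get mid-ranks;
zero differences are dropped (Wilcoxon's original policy); p-values are
two-sided; the tie-corrected normal approximation (`z = W/√Σr²`, no
continuity correction) is available for larger n. No multiple-testing
correction is applied — a handful of prespecified contrasts are reported
with raw p-values, and reports should say so.

## The phantom generator

The generator emulates the study conditions: 7 subjects × 2 kidneys,
technique alternating by side (odd subjects: left = pulsed; even: left =
continuous), ellipsoidal kidneys, 75–100 µm beads, 0.1 mm voxels. Injection
is modeled phenomenologically as a *penetration-depth distribution*, not a
hemodynamic simulation: bead depth-from-surface follows
Exponential(scale) truncated at the organ's maximum interior depth, with
defaults scale = 40 px (continuous) vs 60 px (pulsed) and Poisson bead
counts with means 3,400 vs 3,100 — parameters chosen so synthetic studies
show the observed direction (continuous → more distal cortex, more beads)
and realistic per-kidney loads. Injected embolic volume is drawn uniformly
from the reported per-technique ranges (12–20 ml continuous, 8–22 ml
pulsed). Delivery-to-stasis is represented only by these draws; no flow is
simulated.

Placement uses integer depth bins of the *same* surface-distance field the
stratification module thresholds (bin b = voxels at distance in (b−1, b]),
drawing a continuous depth and snapping to the nearest non-empty bin; the
recorded ground-truth depth is the chosen voxel's actual distance. Bead
centers are grid-registered (voxel centers). With radii in [75, 100) µm at
0.1 mm spacing each bead is strictly sub-voxel in every axis direction and
rasterizes to exactly one voxel, which makes count recovery exact on
noiseless, non-merging phantoms — the property the recovery tests assert.
An optional Chebyshev exclusion zone (`min_center_separation_px`) prevents
bead merging for those tests; when a depth bin is saturated by exclusion
zones the bead spills to the nearest bin with free voxels.

Rendering: background intensity 100, bead intensity 600, additive Gaussian
noise with σ = 50 (0.1 × contrast), clamped at 0. The scanner's actual
bead/parenchyma contrast and noise are not published for this bead/scanner
combination, so these levels are calibration-free choices; the default
segmentation threshold sits midway (350), 5σ from both classes.
Consequences: the kidney interior and exterior share one background level
(segmentation only separates beads), and no beam hardening, streaks,
partial-volume blur, hilum, collecting system or vascular tree is
simulated. Passing tests therefore demonstrate correctness of the
*measurement* pipeline and recoverability of a depth-distribution contrast
under Poisson/Gaussian variability — not robustness to real-scanner
artifacts or real vascular anatomy. In particular, on real scans the
vessel mask contains contrast-filled arteries (many voxels per vessel),
so absolute percent-cortex values from bead-only phantoms are smaller than
scanner-derived ones; only relative comparisons transfer.

## Reproducibility and problem sizes

Every phantom is a pure function of (spec, regime, seed). A study derives
per-kidney child seeds as `seed + subject·10 + side_index`, so arms never
share draws and replicate studies with seeds 100 apart are independent.

Real kidneys (46–138 ml) at 0.1 mm are ~5·10⁷–10⁸ voxels; whole replicate
ensembles at that scale are not desk-scale. `StudyConfig`'s defaults keep
the paper-scale organ sizes (semi-axes drawn from 30–43 × 22–29 × 18–25 mm,
volumes ≈ 50–130 ml) for users with real-scale resources, while
`scaled_study_config()` — used by the test suite and the acceptance
script — shrinks kidneys to semi-axes 66–74 × 58–66 × 54–60 px (~2–4 ml)
*without* rescaling the depth geometry: depth scales stay 40/60 px and
cut-offs 50/100 px, so the 50-px shell still excludes a genuine interior
and the depth-distribution contrast between regimes is exercised. At this
size the deepest interior is ~54–60 px, so the 100-px erosion is empty and
shell(100) equals the whole organ — the 100-px metric degenerates to a
whole-organ fraction there; the 50-px metric is the discriminating one.
One scaled kidney takes ~0.3 s end to end; a 14-kidney study ~4 s; the
100-replicate direction-recovery experiment ~7 min.

Other sizes chosen for test tractability (all stated in the tests
themselves): exact-recovery phantoms use 55 × 48 × 42 px kidneys with
1,100 beads and depths 15/30 px; brute-force oracles run on ≤ 15³–20³
random masks; the large-ellipsoid shell check runs at the full 300 × 250 ×
220 px geometry against an independent fine-grid integration oracle with
exact point-to-ellipsoid-surface distances.

## Known limitations

- Bead merging under default (separation-free) sampling biases component
  counts slightly downward; intersect-voxel metrics are unaffected.
- The exact Wilcoxon is O(2ⁿ) and capped at n = 20; beyond that the
  normal approximation is used.
- TIFF stacks are read-only and require an explicit spacing; NIfTI is the
  canonical format. Anisotropic voxels are rejected, never resampled.
- The generator's noise and intensity levels are uncalibrated
  (see above); conclusions about absolute detectability on a particular
  scanner require measured contrast.
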