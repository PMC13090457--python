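# embolimetry

Quantification of particulate embolic distribution in whole organs from
microCT, with a synthetic kidney-phantom generator for validation.

## The problem

Transarterial embolization occludes target vessels by injecting particulate
embolics (here radiopaque microspheres, 75–100 µm). How the operator injects
them — a steady *continuous* push vs short *pulsed* boluses — may change how
deeply particles penetrate toward the distal cortical vasculature, which in
turn matters for therapeutic efficacy. With radiopaque beads, a whole
explanted organ can be imaged at 0.1 mm resolution and the full 3D particle
distribution measured, instead of sampling a few histology sections.

This package implements that measurement pipeline for anyone analyzing such
scans (or wanting a tested, synthetic test-bed for one):

1. **segmentation** — the embolic/vessel signal is extracted with a global
   intensity threshold plus a minimum-component-size filter (a deterministic,
   reproducible stand-in for interactive pixel classification);
2. **stratification** — the organ mask is eroded from the surface inward by
   a depth *d* in pixels, using Euclidean distance-transform thresholding
   (ball-metric erosion). The *cortical shell* at depth *d* is
   `shell(d) = whole ∖ eroded(d)`: exactly the voxels within *d* pixels of
   the surface (at 0.1 mm, 50 px = 5 mm);
3. **quantification** — with both volumes binary, the intersection count
   `I(d) = |vessel ∧ shell(d)|` gives
   - *embolization efficiency* `E(d) = I(d) / V_kidney` (voxels/ml), and
   - *percent embolized cortex* `P(d) = 100 · I(d) / |shell(d)|`;
   particle counts are connected components (26-connectivity), assigned to a
   region by voxel centroid;
4. **paired statistics** — each subject receives both techniques (one kidney
   each), so metrics are compared within subject by a paired t-test and an
   *exact* Wilcoxon signed-rank test (all 2ⁿ sign assignments enumerated —
   with n = 7 pairs the normal approximation is not trusted).

Because real embolized-organ scans are large and scarce, the `phantom`
module generates ellipsoidal kidney phantoms with beads whose
depth-from-surface follows a truncated exponential law (continuous
technique: mean depth 40 px and ~3,400 beads; pulsed: 60 px and ~3,100),
rendered into noisy microCT-like volumes with full ground truth retained —
every stage of the pipeline is validated against that ground truth.

## Worked example

Simulate and analyze a complete 7-subject paired study (reduced-size
kidneys, full-scale depth geometry; see `docs/methods.md`):

```bash
embolimetry run --seed 1 --out demo_out/
```

prints

```
pct_cortex_50: continuous median 0.305701, pulsed median 0.273517
total_particle_count: continuous median 3116, pulsed median 2800
results written to demo_out
```

i.e. at a 50-pixel (5 mm) cortical depth the continuous technique embolized
a median 0.306 % of the cortical shell vs 0.274 % for pulsed, delivering a
median 3,116 vs 2,800 particles per kidney — the continuous arm penetrates
more cortex, as its shallower depth distribution and larger bead load
dictate. `demo_out/study_per_kidney.csv` holds one row per (subject, kidney,
depth) with counts, volumes and efficiencies; `demo_out/study_summary.json`
holds group medians/ranges and the paired tests (here exact Wilcoxon
p = 0.078, paired t p = 0.057 — a consistent within-subject direction that
does not reach 0.05 with 7 pairs).

The same steps are available piecewise on your own NIfTI/TIFF data:

```bash
embolimetry segment  --in vol.nii.gz --threshold 350 --out vessel.nii.gz
embolimetry stratify --kidney kidney.nii.gz --depths 50,100 --out-prefix strat_
embolimetry quantify --vessel vessel.nii.gz --kidney kidney.nii.gz \
                     --depths 50,100 --out quant.csv
embolimetry compare  --quant study_per_kidney.csv \
                     --metric percent_embolized_cortex --depth 50 \
                     --test wilcoxon --out tests.json
```

or from Python via `embolimetry.run_study`, `quantify_kidney`,
`wilcoxon_signed_rank`, etc.

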