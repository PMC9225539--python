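# bladderwall

Computer-aided characterization of the bladder wall on T2-weighted MRI
slices, aimed at grading the severity of neurogenic bladder involvement
(as in spina bifida): severe cases show a thickened, irregular detrusor
with diverticula, while non-severe bladders have a thin, smooth wall.

The pipeline chains four stages:

1. **Two-phase level-set segmentation.** The wall boundary is the zero
   level of a signed field φ evolved by `dφ/dt = −F |∇φ|` with a geodesic
   active-contour speed: an edge-stopped balloon force, advection along
   `∇g` and a curvature regularizer, where
   `g = 1 / (1 + |∇(G_σ * I)|² / s²)` is the edge indicator. A seed disk
   placed in the bright urine lumen grows to the inner boundary; after
   local contrast enhancement (per-pixel window min/max stretch) and
   lumen-intensity standardization, the outer boundary is found by a
   second evolution confined to an annular search band around the inner
   contour.
2. **40-feature wall characterization** `f0…f39`: five first-order
   histogram statistics; twenty GLCM (Haralick/Soh/Clausi) texture
   statistics on a mask-restricted symmetric co-occurrence matrix; nine
   shape/orientation descriptors of the outer mask; the mean polar wall
   thickness `mean_θ (r_outer(θ) − r_inner(θ))·spacing`; and five
   inner/outer boundary-similarity statistics.
3. **Sequential floating feature selection** (SFFS/SBFS) scored by mean
   stratified 5-fold cross-validated classifier accuracy.
4. **Classification** with an RBF-kernel SVM whose hyperparameters
   (C, γ) are tuned by the Grey Wolf Optimizer, compared against a
   Random Forest; metrics are accuracy, sensitivity, specificity and
   precision from a held-out stratified 20% split.

Because clinical bladder MRI datasets are rarely shareable, the package
ships a first-class synthetic phantom generator: bright lumen, dark wall
ring of controllable thickness/irregularity/diverticula, bright
peri-vesical surround, additive Gaussian noise — with exact ground-truth
masks and contours, so segmentation, feature recovery and classification
are all testable end to end.

## Worked example

```sh
bladderwall run-all --out run --seed 1 --set phantom.n_per_class=8
```

segments a 16-phantom cohort, extracts features, selects a subset, tunes
the SVM and prints `run complete: run`. The run directory then contains
per-image wall masks and contours, `features.csv` (16 × 42:
`id,f0…f39,label`), `selection.json`, and `metrics.json`. On this cohort
`segmentation_metrics.json` reports

```json
"mean_dice": 0.830, "mean_mi_bits": 0.218, "mean_overall_error": 0.217
```

(the segmented wall overlaps the true wall at Dice ≈ 0.83 averaged over
both the thin-walled and the irregular class), and
`metrics.json` shows the GWO-tuned SVM and the Random Forest both
classifying the held-out images perfectly (`"accuracy": 1.0`) — the two
phantom classes differ by 3 px of mean wall thickness plus
irregularity/diverticula, which the thickness and boundary-similarity
features separate cleanly.

The same stages are available individually (`bladderwall phantom`,
`segment`, `extract`, `select`, `train`, `evaluate-seg`), and from Python:

```python
from bladderwall import PhantomSpec, generate_phantom, segment_wall, dice

sample = generate_phantom(PhantomSpec(wall_thickness_mean=5, noise_sigma=12.75, seed=2))
seg = segment_wall(sample.image, seed_center=(63.5, 63.5), seed_radius=5.0)
print(round(dice(sample.wall_mask, seg.wall_mask), 3))   # 0.97
```

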