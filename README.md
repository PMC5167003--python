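# blockdecode

Temporal brain-state decoding of block-design fMRI with linear support
vector machines, for researchers comparing acquisition contrasts — BOLD,
perfusion-weighted arterial spin labeling (ASL), and arterial
volume-weighted arterial spin tagging (AVAST) — in a predictive
(classifier-based) framework rather than a voxel-wise GLM.

Each acquired brain volume is one example **x** (in-brain voxel intensities
are the features) with label y = ±1 given by the 30-s task/rest block
containing its acquisition time.  The classifier is the linear soft-margin
SVM

    min ‖w‖² + C Σᵢ ξᵢ    s.t.  yᵢ(wᵀxᵢ + b) ≥ 1 − ξᵢ,  ξᵢ ≥ 0,   C = 1,

trained on one run and tested on the subject's other run; performance is
the fraction of correctly classified test volumes.  Around it the package
implements the full pipeline:

* **paradigm** — block schedules, ±1 labels, transition times, and
  exclusion of the k frames on each side of every task↔rest switch;
* **synth** — a seeded generator of multi-modality 4D block-design runs
  (BOLD drift, ASL/AVAST control–tag alternation, double-gamma
  hemodynamics, AR(1) noise) with known ground-truth active regions;
* **preprocess** — brain masking, surround subtraction of control/tag
  series, Gaussian smoothing (FWHM in mm), voxel-wise z-normalization,
  temporal subsampling;
* **dataset** — masked, labeled example sets with an invertible
  voxel-order map, so weight vectors render back into brain space;
* **svm** — the classifier above (libsvm via scikit-learn plus an SMO
  polish; brute-force QP reference for validation);
* **permtest** — label-permutation significance of the SVM weight map
  (unit-SD normalized weights, exceedance-count p-values, p < .01 maps);
* **experiment** — the full study analog: subjects × contrasts ×
  exclusion sweep, accuracy tables and curves, permutation maps.

Runs round-trip through NIfTI-1 with JSON sidecars (`save_run` /
`load_run`); tables are pandas DataFrames / TSV.

## Worked example

`examples/04_cross_run_classification.py` synthesizes one subject's two
AVAST runs on a small 16×16×4 grid, preprocesses them (surround
subtraction → 8-mm smoothing → z-normalization), and classifies each run
from the other across the transition-exclusion sweep:

```
AVAST TR 2.2 s
k = 0: 135 examples x 464 voxels, mean cross-run accuracy 0.711
k = 1: 117 examples x 464 voxels, mean cross-run accuracy 0.795
k = 2:  99 examples x 464 voxels, mean cross-run accuracy 0.894
k = 3:  81 examples x 464 voxels, mean cross-run accuracy 0.969
```

Accuracy climbs with k because frames near a block boundary carry the
previous state's still-ramping vascular signal: at k = 0 they are both hard
test cases and label noise during training; excluding them removes both
effects.  `examples/05_permutation_weight_map.py` continues with the
200-permutation significance map for the same subject:

```
significant voxels: 28 at p < .01 (200 permutations)
ground-truth ROI  : 40 voxels
Dice overlap      : 0.74  (1 = perfect localization)
```

i.e. the voxels the SVM provably relies on coincide with the regions where
activation was actually injected.  The other examples cover the paradigm
arithmetic, run synthesis and NIfTI round-tripping, surround subtraction's
drift immunity, and the full multi-subject accuracy-curve experiment.

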