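# segloss

Loss functions and evaluation methodology for **multiclass medical-image
segmentation**, built for researchers comparing training losses under
severe class imbalance — the regime where the background covers ~95% of
pixels, is trivially easy to segment, and silently dominates both the
loss and any all-pixel metric.

The package provides:

* **Per-class metrics** (`metrics_core`): confusion counts TPc/FPc/FNc/TNc
  per class and the derived accuracy, sensitivity, specificity, precision,
  FPR, IoU (Jaccard, JI) and dice (DSC), with class means computed with or
  without the background. Undefined ratios (0/0) are flagged, never coerced.
* **The loss family** (`losses`): class-weighted cross entropy, class-averaged
  IoU and dice losses, the FP/FN-weighted IoU

  $$\mathrm{IoU}_{xy}(\text{loss}) = 1 - \frac{1}{C}\sum_{c=1}^{C}
    \frac{TP_c}{TP_c + \alpha FP_c + \beta FN_c},\qquad \alpha+\beta=2,$$

  and noBK variants that drop the background from the class average.
  Every count-based loss has a *hard* form on labelmap pairs and a *soft*
  differentiable form on probability maps (probability-weighted counts),
  with analytic gradients.
* **Synthetic phantoms** (`synthetic_data`): seeded multi-organ ellipse
  phantoms with controlled background fraction, patient-correlated slice
  series, morphological perturbations with known FP/FN structure, and the
  standard augmentation recipe (translations ≤ 10 px, rotations ≤ 10°,
  shear ≤ 10 px, scale ≤ 10%).
* **The experimental protocol** (`experiment`): patient-wise k-fold
  cross-validation (no slice leakage), uniclass problem derivation, the
  α-sensitivity sweep at step 0.25, and fold statistics — mean, sample
  stdev, 90% Student-t CI, and a two-sided pooled-variance t-test between
  conditions.
* **A desk-scale training harness** (`training_harness`): a per-pixel
  linear softmax segmenter over a fixed multi-scale feature bank, trained
  with SGDM, that accepts any loss spec through one value-and-gradient
  contract.

## Worked example

```python
import numpy as np
from segloss import (PhantomSpec, generate_phantom, perturb, PerturbSpec,
                     per_class_confusion, metric_suite, iouxy_loss, LossSpec)

# a 5-class phantom with exactly 95% background
spec = PhantomSpec(background_fraction=0.95, exact_background_fraction=True, seed=0)
image, gnd = generate_phantom(spec)

# an all-background "classifier" looks 95% accurate but segments nothing
seg = gnd.__class__(np.zeros_like(gnd.values), gnd.class_set)
print(float(np.mean(gnd.values == seg.values)))      # 0.95
table = metric_suite(per_class_confusion(gnd, seg))
print(table.loc[[1, 2, 3, 4], "iou"].tolist())       # [0.0, 0.0, 0.0, 0.0]

# erosion creates pure false negatives; beta>alpha punishes them harder
eroded = perturb(gnd, PerturbSpec(erode={1: 2, 2: 2, 3: 2, 4: 2}))
print(round(iouxy_loss(eroded, gnd, LossSpec("iou", alpha=0.5, beta=1.5)).value, 3))  # 0.641
print(round(iouxy_loss(eroded, gnd, LossSpec("iou", alpha=1.5, beta=0.5)).value, 3))  # 0.466
```

The same FN-heavy prediction costs 0.641 under the FN-heavy weighting
(β=1.5) but only 0.466 under β=0.5 — exactly the lever the weighted loss
exposes for recall-critical targets.

The full pipeline (simulate → split → train each loss per fold → evaluate →
stats → report) runs from a YAML config:

```sh
segloss -v run --config config.yaml --seed 1
```

On the default 10-patient, 3-class phantom cohort it prints, among others,
per-condition mean-IoU fold statistics in `stats.csv`. A representative run
(seed 1) gives mean IoU: crossE 0.891, dice noBK 0.902, dice 0.758, IoU
(background included) 0.649 — with the per-class report showing the
background-included count losses sacrificing the small low-contrast class
(IoU 0.0–0.31) while dice noBK preserves it (0.72). At this deliberately
tiny model capacity the background term visibly drags the average loss
away from the small structures, which is the phenomenon the noBK and
weighted variants exist to counter.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch — phantom cohort generation,
patient-wise 5-fold cross-validation of the five loss conditions
(crossE, IoU, dice, IoU₀.₅,₁.₅, dice noBK), fold statistics with CI and
p-values, and the 9-point α sweep — writing the pipeline artifacts next
to the JSON output.
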