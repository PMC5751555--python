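# nbds — noninvasive brain-disease screening from facial-color key blocks

Reduced blood and oxygen supply to the brain (as in cerebral infarction)
changes facial color in ways that are invisible to the naked eye but
measurable in a calibrated image.  `nbds` implements a complete screening
pipeline built on that premise:

1. **Color correction** — a 24-patch color checker photographed by the
   capture device trains a polynomial regression from device RGB to standard
   sRGB (degree 2, monomials {1, R, G, B, R², G², B², RG, RB, GB} by
   default), removing illumination and device dependence.
2. **Key-block extraction** — the two pupils are located with Canny edge
   detection (closed contours filled, components filtered by area,
   circularity 4πA/P² ≥ 0.6, and darkness).  With pupil centers
   P_left = (x_l, y_l), P_right = (x_r, y_r) and image height H, four s×s
   blocks (s = 64) are cut at, in a y-up frame,

   | block | center |
   |---|---|
   | FHB (forehead)    | ((x_l+x_r)/2, (y_l+y_r)/2 + H/3) |
   | LCB (left cheek)  | (x_l, y_l − H/4) |
   | NBB (nose bridge) | ((x_l+x_r)/2, (y_l+y_r)/2 − 2H/9) |
   | RCB (right cheek) | (x_r, y_r − H/4) |

3. **Color-gamut features** — block pixels go sRGB → CIEXYZ (D65); each
   pixel is assigned to the nearest of six facial-gamut color centroids and
   the block becomes the 6-vector of assignment proportions.  The three
   employed blocks (FHB, LCB, NBB — the cheeks are symmetric, so only the
   left is used) concatenate to an 18-dimensional feature vector.
4. **Classification** — the probabilistic collaborative representation
   classifier (ProCRC).  With training dictionary S = [S₁, …, S_K] it solves

   ```
   Â = argmin_A ‖t − SA‖₂² + λ‖A‖₂² + (γ/K) Σ_k ‖SA − S_k A_k‖₂²
   ```

   in closed form and labels t by the smallest class residual
   ‖SÂ − S_k Â_k‖₂.  CRC (γ = 0 ridge), SRC (ℓ1, FISTA), k-NN, and a linear
   SVM are provided as baselines behind the same fit/predict interface
   (all are scikit-learn compatible estimators).

Evaluation uses a balanced repeated-holdout protocol: the healthy majority
class is shuffled and cut into five equal parts; each part plus the whole
disease class forms one round, split half/half (⌊c/2⌋ train) per class.
Reported accuracy, sensitivity (disease recall), and specificity (healthy
recall) are means over rounds.

Because the clinical cohort is not distributable, the package ships a
synthetic-data module that renders faces (dark circular pupils at plausible
positions, per-region skin-color mixtures over the gamut centroids with a
controllable disease effect size δ and noise σ) and emits feature datasets
with known ground truth, so every stage is testable end to end.

## Worked example

```python
import numpy as np
from nbds.synthetic import ClassProfile, generate_feature_dataset
from nbds.evaluation import (block_combinations, make_split_plan,
                             run_experiment, summarize)

ds = generate_feature_dataset(119, 595, ClassProfile(delta=0.2, sigma=0.05), seed=1)
plan = make_split_plan(119, 595, parts=5, seed=0)
res = run_experiment(ds, block_combinations(), "procrc",
                     {"lam": [0.7], "gamma": [0.001]}, plan, positive="BD")
print(summarize(res).to_string(index=False))
```

prints

```
combination classifier  gamma  lam  accuracy  sensitivity  specificity    error
        FHB     procrc  0.001  0.7  0.998333     0.996667     1.000000 0.001667
    FHB+LCB     procrc  0.001  0.7  1.000000     1.000000     1.000000 0.000000
FHB+LCB+NBB     procrc  0.001  0.7  1.000000     1.000000     1.000000 0.000000
    FHB+NBB     procrc  0.001  0.7  0.998333     0.996667     1.000000 0.001667
        LCB     procrc  0.001  0.7  0.991667     0.983333     1.000000 0.008333
    LCB+NBB     procrc  0.001  0.7  1.000000     1.000000     1.000000 0.000000
        NBB     procrc  0.001  0.7  0.993333     0.993333     0.993333 0.006667
```

Each row is one of the seven block combinations: the mean over the five
rounds of accuracy, sensitivity, and specificity for ProCRC at λ = 0.7,
γ = 0.001, plus error = 1 − accuracy.  At this moderate effect size
(δ = 0.2 of mixture mass shifted between two centroids, σ = 0.05 noise) the
classes are nearly separable, so all combinations score above 99%.

A CLI mirrors the library (`nbds synth faces`, `nbds extract-blocks`,
`nbds features`, `nbds classify`, `nbds evaluate`, `nbds run`); see
`nbds --help`.

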