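# stainshift

Patch-level classifiers in computational pathology routinely fail on
slides from a lab or scanner they were not trained on: hematoxylin–eosin
(H&E) staining and digitization leave every center with its own color
signature, and models trained on a few centers absorb it.  `stainshift`
implements and compares, end to end, the three standard counter-measures:

* **Macenko stain normalization** — estimate each image's 2×3 stain
  absorbance matrix S from the SVD plane of its optical-density cloud
  (Beer–Lambert: I_c = I₀ exp(−S_c·C)), deconvolve per-pixel H/E
  concentrations C, and re-render every image in a template's color frame;
* **random color augmentation** — train-time channel-wise affine jitter
  I′_c = a_c I_c + b_c in RGB, HSV or HED space;
* **domain-adversarial training (DANN)** — a two-head convolutional
  network whose shared trunk θ_f feeds a task head θ_y and, through a
  gradient reversal layer, a domain head θ_d, trained by the saddle-point
  updates

      θ_f ← θ_f − μ(∂L_y/∂θ_f − λ ∂L_d/∂θ_f)
      θ_y ← θ_y − μ ∂L_y/∂θ_y
      θ_d ← θ_d − μλ ∂L_d/∂θ_d

  so the features help classification while defeating center
  identification.

Evaluation separates **internal test** (new patients, training centers)
from **external test** (patients *and* centers unseen), the gap being the
generalization cost of stain variation.  The package also provides the
heatmap-guided patch extractor (h = 0.5·tanh(h₁h₂ − 1.75) + 0.5,
threshold 0.65) used to harvest patches from unannotated slide rasters,
hard-negative mining, a strategy-grid experiment runner, and a synthetic
multi-center cohort generator so the whole pipeline runs and is tested
without any image downloads.  The network layers and the adversarial
update are implemented in pure numpy with hand-verified gradients.

Intended users: researchers studying stain robustness / domain adaptation
who want a small, fully inspectable, CPU-only reference implementation
with testable contracts for every stage.

## Worked example

```python
import numpy as np
from stainshift import CohortConfig, DannClassifier, TrainConfig, make_cohort
from stainshift.evaluation import PredictionSet, f1_score, auc_score

# 3 training centers + 1 protocol-shifted external center, ~2,350 patches
records, manifest = make_cohort(CohortConfig(n_train=350, n_validation=80,
                                             n_internal_test=170,
                                             n_external_test=400, seed=101))
parts = {p: [r for r in records if r.partition == p]
         for p in ("train", "external_test")}

for adversarial in (False, True):
    fit = DannClassifier(parts["train"],
                         TrainConfig(iterations=700, warmup_iters=100, seed=0),
                         adversarial=adversarial).fit()
    ext = parts["external_test"]
    preds = PredictionSet(np.arange(len(ext)), fit.predict_proba(ext),
                          np.array([r.task_label for r in ext]),
                          np.array([r.domain_label for r in ext]),
                          "external_test", 0, "DANN" if adversarial else "baseline")
    print(f"{'DANN    ' if adversarial else 'baseline'} "
          f"external F1={f1_score(preds):.3f}  AUC={auc_score(preds):.3f}")
```

Output from one run of this script:

```
baseline external F1=0.913  AUC=0.992
DANN     external F1=0.935  AUC=0.993
```

Both models rank external patches well (AUC ≈ 0.99): the class signal is
morphological and survives the color shift.  The baseline pays a larger
F1 penalty because the external center's shifted, weaker staining
systematically rescales its evidence and miscalibrates its probabilities,
while the domain-adversarial features — trained to carry no center
information — transfer their calibration better.  The gap widens with the
severity of the external shift and under validation-optimized thresholds
(`stainshift.evaluation.optimal_threshold`), and a linear domain probe on
the DANN embedding drops toward chance while staying high on the baseline
embedding.  The grid runner
(`stainshift.experiment_runner.run`) executes any subset of the 2³
combination grid (color augmentation × stain normalization × DANN) over
multiple seeds and writes per-seed predictions, checkpoints and a
mean (±sd) results table.

A CLI mirrors the pipeline stages:

```bash
stainshift synth --out-dir cohort/ --seed 3
stainshift extract --image slide.png --threshold 0.65 --patch-size 64 \
    --n-patches 200 --out-manifest locs.csv
stainshift normalize --template template.png --input-manifest cohort/manifest.csv \
    --output-dir normalized/
stainshift run --plan plan.json
```

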