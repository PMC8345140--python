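# nucquant

Detection, quantification and prognostic scoring of nuclear IHC
biomarker-positive cells — the motivating case is ICOS (Inducible T-cell
COStimulator), an immune-checkpoint protein whose DAB-stained nuclei are
counted per tissue-microarray core in colorectal-cancer cohorts.

The package is aimed at computational-pathology researchers who want a
self-contained, download-free implementation of the standard workflow:

1. **Segment** — a U-Net (encoder/decoder with skip connections, 23
   convolutional layers in the default configuration) maps an RGB patch to
   a per-pixel foreground probability. Losses: BCE, soft-Dice, soft-IoU,
   focal, Lovász hinge and their sums; SGD-Nesterov or Adam with
   reduce-on-plateau learning rate (initial 0.002).
2. **Separate** — probability maps are thresholded (default 0.5), the
   Euclidean distance transform is computed, maxima shallower than `h`
   (default 6 px) are suppressed with the h-extrema transform, and the
   watershed splits touching nuclei into instances.
3. **Evaluate** — pixel metrics (ACC, SEN, SPE, Dice = 2TP/(2TP+FP+FN)),
   pooled ROC/PR curves with AUC, the aggregated Jaccard index
   AJI = Σᵢ|GTᵢ ∩ PD_j*(i)| / (Σᵢ|GTᵢ ∪ PD_j*(i)| + Σ_{k∉matched}|PD_k|),
   and object-level precision/recall via one-to-one IoU matching.
4. **Score** — per-patient cell density (cells/mm²), a time-dependent ROC
   at a 5-year horizon picks the Youden-optimal density cutoff, and the
   dichotomized groups are compared with Kaplan–Meier curves and the
   log-rank test.

Because clinical IHC cohorts are not redistributable, the `fixtures`
module synthesizes DAB-brown elliptical nuclei (with controllable touching
pairs) and survival cohorts whose hazard depends on density, so every
stage is testable end to end. The neural network runs on a compact numpy
layer core (im2col convolutions with hand-derived backprop, verified
against finite differences); everything else builds on scikit-image,
scikit-learn, scipy, pandas and lifelines.

## Worked example

Train a small model on synthetic patches and score a synthetic cohort:

```python
import numpy as np
from nucquant import fixtures
from nucquant.segnet import UNetConfig, TrainConfig, build_model, train, predict
from nucquant.nn import LossSpec
from nucquant.postproc import PostprocParams, segment
from nucquant.evalmetrics import evaluate_patches
from nucquant.cohort import stratify_cohort

patches = [fixtures.generate_patch(fixtures.SynthPatchConfig(
               patch_size=64, n_nuclei=(3, 7), radius=(4, 7),
               touching_fraction=0.2, seed=s)) for s in range(70)]
data = [(rgb, lab > 0) for rgb, lab in patches]

model = build_model(UNetConfig(input_size=(64, 64, 3), depth=2,
                               base_channels=8), seed=0)
model, history = train(model, data[:45], data[45:50],
                       TrainConfig(optimizer="adam", epochs=25,
                                   batch_size=4, seed=0),
                       LossSpec(("bce",)))

test = patches[50:]
probs = [predict(model, rgb) for rgb, _ in test]
report = evaluate_patches(probs, [lab > 0 for _, lab in test],
                          [lab for _, lab in test],
                          params=PostprocParams(prob_threshold=0.5, h=6.0))
print(f"dice={report.dice:.3f}  aji={report.aji:.3f} "
      f"precision={report.precision:.3f}  recall={report.recall:.3f}")

cohort = fixtures.generate_cohort(fixtures.SynthCohortConfig(
    n_patients=200, log_hazard_ratio_per_unit_density=1.0, seed=1))
s = stratify_cohort(cohort, horizon=5.0)
print(f"cutoff={s.cutoff:.1f} cells/mm^2  td-ROC AUC={s.auc:.3f}  "
      f"logrank chi2={s.logrank_chi2:.1f}  p={s.logrank_p:.2e}")
```

Output (seeds as above):

```
dice=1.000  aji=0.895 precision=1.000  recall=0.909
cutoff=117.6 cells/mm^2  td-ROC AUC=0.722  logrank chi2=19.0  p=1.31e-05
```

The Dice/AJI values say the model recovers nearly every synthetic nucleus
pixel-perfectly and the watershed resolves most touching pairs into the
correct instances; the survival block shows the planted density→hazard
effect is detected: patients above the selected density cutoff have
markedly worse 5-year survival (see `docs/methods.md` for why such
p-values are optimistic when the cutoff is tuned on the same cohort).

The same workflow is scriptable from the shell:

```bash
nucquant synth patches --n 20 --out data/ --seed 0
nucquant synth cohort --n 200 --effect 1.0 --out cohort.csv --seed 0
nucquant run --out runs/demo --seed 0      # full pipeline on synthetic data
nucquant survival --cohort cohort.csv --horizon 5
```

## Layout

```
src/nucquant/
  fixtures.py      synthetic patches, touching pairs, survival cohorts
  patches.py       ingestion, mask conversion, splitting, augmentation
  nn/              numpy layer core: conv/pool/up-conv, losses, optimizers
  segnet.py        U-Net, training loop, inference, checkpoints
  postproc.py      threshold -> distance transform -> h-maxima -> watershed
  evalmetrics.py   pixel metrics, Dice, AJI, matching, ROC/PR, sweeps
  cohort.py        density, concordance, td-ROC cutoff, KM, log-rank
  pipeline.py      staged end-to-end runs with manifests
  cli.py           `nucquant` command-line interface
```
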