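# btiradiomics

Peritumoral radiomics for predicting **brain invasion (BI)** in
meningioma from contrast-enhanced T1-weighted MR images. Brain invasion —
tumor cells extending into adjacent parenchyma without an intervening
leptomeningeal layer — upgrades a meningioma to WHO grade II, but it can
only be confirmed histologically after surgery. The texture of the
**brain–tumor interface (BTI)**, a shell of ±N mm around the tumor
surface, carries the invasion signal; this package asks *how wide that
shell should be* and whether interface radiomics beats whole-tumor
radiomics and clinical predictors.

The package is aimed at medical-image-analysis researchers who want a
tested, fully synthetic-data-driven reimplementation of the analysis:
every stage runs end-to-end on phantom cohorts with a *controllable*
invasion depth, so the pipeline's central claim — the ROI whose
half-width matches the true invasion depth discriminates best — is a
parameter-recovery experiment rather than an anecdote.

## What it implements

* **ROI geometry** — nine ROIs per subject from the tumor mask: interface
  bands BTI-N = {voxels with signed surface distance ∈ [−N, +N]} for
  N ∈ {2, 3, 4, 5} mm, combined regions COM-N = tumor ∪ BTI-N, and the
  whole tumor (WT); automated skull/brain exclusion; tumor volume (TV),
  peritumoral edema volume (PEV = outlined − tumor) and edema index
  (PEI = PEV/TV).
* **Feature extraction** — 18 first-order + 14 shape + 90 texture
  features (GLCM 21, GLSZM 16, GLRLM 16, NGTDM 5, GLDM 14) on the
  original image and a 10-image filter bank (8 stationary-wavelet
  sub-bands + 2 LoG scales): 1004 features per ROI by default, each
  texture family verified against brute-force oracles.
* **Feature selection** — ICC(2,1) ≥ 0.8 reproducibility filter across
  repeated segmentations, |Spearman ρ| > 0.9 redundancy filter,
  cross-validated LASSO screen capped by the events-per-variable rule,
  varimax-rotated PCA (Kaiser rule).
* **Modeling** — temporal 80/20 split; repeated stratified
  subsample + 5-fold CV AUC distributions; backward-stepwise (AIC)
  logistic regression and random forest; clinical (PEV) and combined
  (PEV + interface components) models.
* **Evaluation** — confusion-matrix rates at the 0.20 cutoff with exact
  binomial CIs, ROC AUC with DeLong CIs, PR AUC, decision-curve net
  benefit NB(pt) = TP/n − (FP/n)·pt/(1−pt), categorical/continuous NRI
  and IDI with bootstrap CIs, and BH-FDR-adjusted pairwise Wilcoxon
  comparisons across the nine ROI AUC distributions.
* **Synthetic cohorts** — seeded 3-D MR phantoms with skull-adjacent
  tumors, class-specific peritumoral edema volumes, two synthetic sites,
  sequential acquisition dates, a simulated second rater, clinical tables
  with blood indices (NLR, dNLR, PLR, SII, MLR, PNI), and an invasive
  texture signal confined to a configurable shell depth.

See `docs/methods.md` for the model, all conventions and limitations.

## Worked example

```python
import numpy as np
from btiradiomics import (PhantomConfig, SplitPlan, roi_auc_experiment)

cfg = PhantomConfig(n_subjects=200, seed=1000, second_rater=False)  # depth 4 mm
aucs = roi_auc_experiment(cfg, plan=SplitPlan(n_iterations=10, seed=2000))
print(aucs.mean().sort_values(ascending=False).round(3).head(4))
```

prints

```
BTI4mm    0.822
BTI3mm    0.818
COM4mm    0.795
COM3mm    0.787
dtype: float64
```

the mean cross-validated AUC per ROI on one phantom cohort whose invasive
texture is planted in a 4 mm shell: the 4 mm interface band ranks first,
ahead of its combined region and the narrower bands (whole-tumor features,
which never see the shell, stay near chance). Across 20 such cohorts the
4 mm band ranks first in ~85% of seeds.

The same experiment from the shell:

```bash
btirad simulate --outdir cohort/ --seed 7          # NIfTI + clinical CSV
btirad bands --tumor cohort/S0000_tumor.nii.gz \
             --brain cohort/S0000_brain.nii.gz \
             --skull cohort/S0000_skull.nii.gz --outdir rois/ --subject S0000
btirad run --outdir results/ --seed 7              # full pipeline report
```

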