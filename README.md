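# gliotex

Radiomics pipeline linking 3D MRI tumor texture to CD3 T-cell
infiltration status in glioblastoma.

## The problem

Glioblastoma patients are imaged routinely, but assessing the intratumoral
immune response (CD3 T-cell infiltration) normally requires biopsy or
surgery. Tumor heterogeneity visible in T1-post-contrast and T2-FLAIR MRI
carries information about that immune influx: increased infiltration is
reflected in fine-grained textural diversity of the tumor region.
`gliotex` implements the full quantitative chain from paired MRI volumes
with tumor and normal-appearing-white-matter (NAWM) masks to a
non-invasive binary prediction of CD3 infiltration status:

1. **Preprocessing** — intensities normalized to the NAWM mean, volumes
   resliced to isotropic 1 mm voxels (trilinear; nearest-neighbor for
   masks), and tumor intensities quantized to G = 8 equal-width gray
   levels over the per-ROI min–max range.
2. **Texture panel** — 86 features per patient: for each modality, 6
   histogram statistics, 19 gray-tone spatial-dependence (GLCM) features,
   5 neighborhood gray-tone difference (NGTDM) features, 11 gray-level
   size-zone (GLSZM) features over 26-connected 3D zones, plus tumor
   volume and total normalized intensity (43 per modality).
3. **Robustness screening** — 8 geometric ROI perturbations (2-voxel
   translations, 1°/5° axial rotations, Gaussian boundary jitter at sd
   0.1/0.5 voxels, ±1-voxel dilation/erosion); features kept when the
   one-way intraclass correlation across the 9 ROI versions is ≥ 0.6.
4. **Feature selection** — all-relevant shadow-feature (Boruta-style)
   selection against continuous CD3 z-scores: per round, each feature's
   random-forest importance is compared with the maximum over permuted
   shadow copies, hits tested against Binomial(r, ½) with Bonferroni
   correction; confirmed features are then pruned so all pairwise
   |Pearson r| < 0.6.
5. **Classifier** — genetic-programming symbolic regression: expression
   trees over {+, −, ×, protected ÷} on the selected features, fitness =
   training ROC AUC, decision threshold = training Youden point. A
   logistic baseline is available through the same interface.
6. **Evaluation** — ROC AUC (Mann–Whitney, ties ½) with stratified
   bootstrap percentile CIs, confusion-matrix rates with exact
   Clopper–Pearson accuracy intervals, Spearman concordance with
   continuous CD3, covariate-adjusted multivariate regression (age,
   gender, KPS, both tumor volumes, both total intensities, model
   prediction), Kruskal–Wallis train/test balance tests, and a paired
   bootstrap test for AUC differences between nested models.

Because clinical cohorts cannot be redistributed, the `phantom` module
simulates paired two-modality cohorts: ellipsoidal tumors with a
Gaussian-random-field texture of controllable correlation length and
amplitude, rim enhancement, additive noise, anisotropic native voxels,
and a continuous CD3 z-score generated from known texture parameters plus
noise (label = z > 0). Every stage of the pipeline is exercised and
tested end-to-end on these phantoms.

## Worked example

Confusion-matrix arithmetic with "high infiltration" as the positive
class — a testing cohort with TN=10, FN=6, FP=2, TP=16:

```python
from gliotex.evaluate import ConfusionMatrix, confusion_metrics
m = confusion_metrics(ConfusionMatrix(tp=16, fp=2, tn=10, fn=6))
for k, v in m.items():
    print(f"{k:18s} {v:.4f}")
```

```
accuracy           0.7647
accuracy_ci_low    0.5883
accuracy_ci_high   0.8925
sensitivity        0.7273
specificity        0.8333
fdr                0.1111
```

Accuracy is 26/34 = 76.5% with exact binomial CI [0.588, 0.893];
sensitivity 16/22 = 72.7%; specificity 10/12 = 83.3%; the classifier's
false-discovery rate is FP/(TP+FP) = 2/18 = 11.1%.

The whole pipeline on a synthetic 24-patient cohort:

```bash
gliotex all --workdir demo_run --n-patients 24
```

```
simulate: 24 patients -> demo_run/cohort/manifest.csv
extract: 24 patients x 86 features
robustness: 64/86 features retained at ICC >= 0.60
select: 7 confirmed, 2 after pruning
train: engine=symbolic train AUC 1.000
evaluate: test AUC 0.938 accuracy 91.7%
```

`demo_run/eval.txt` then holds the held-out report (12 test patients):

```
AUC          0.938  CI [0.75, 1.00]
accuracy     91.7%  CI [0.615, 0.998]
sensitivity  87.5%
specificity  100.00%
FDR          0.0%
Spearman rho 0.804 (p = 0.001615)
```

The high AUC is expected here: the synthetic CD3 outcome is generated
from the T1-post fine-scale heterogeneity parameter, and the selection
stage recovers exactly the zone-fragmentation features that read that
parameter out. On such a small test half the CIs are wide.

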