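# brainage

Brain-age estimation from structural MRI with a 3D attention-ResNet and an
SVR head, plus brain-age-gap (BAG) based Alzheimer's detection — built for
researchers who want the full pipeline (preprocessing → deep regression →
kernel refinement → biomarker classification → saliency) runnable and
testable end to end on synthetic data, on one CPU, without any clinical
download.

## The method

A T1-weighted volume is preprocessed (brain extraction, bias-field
correction, resize to 64×64×32, in-mask z-scoring) and fed to a
convolutional regressor that alternates residual and self-attention
blocks, R(8) A(16) R(32) A(64) R(128):

* residual block: H(x) = shortcut(x) + F(x), where F is
  conv3³–BN–ELU–conv3³–BN and the shortcut is a 1×1×1 projection;
  ELU then 2×2×2/2 max-pool;
* attention block: Q = conv3³(x), V = conv3³(x),
  att = softmax(QVᵀ)V over flattened spatial positions,
  out = maxpool(ELU(BN(conv3³(Q ⊕ att)))).

The head flattens the final 2×2×1×128 map, applies dense(128, l2), ELU and
dropout(0.2), concatenates the subject's sex G, and a linear unit emits
the age. Training is Adam (lr 7e-4) on MSE. The penultimate features are
then refined by ε-insensitive SVR, ŷ = SVR(F_l ⊕ G).

The **brain-age gap**, BAG = ŷ − chronological age, is elevated when the
brain ages faster than the calendar — the signature of neurodegeneration.
Four classifiers (logistic regression, SVM, AdaBoost, XGBoost) on the
scalar BAG, combined by majority vote, separate Alzheimer's from
cognitively normal subjects; 3D Grad-CAM shows which regions drive the
age estimate.

The network — 3D convolution, batch norm, attention, pooling, backprop,
Adam — is implemented from scratch in numpy and verified against numerical
gradients and independent oracles, so the whole pipeline is deterministic,
dependency-light and inspectable. A phantom generator provides
age-encoded synthetic cohorts (growing "ventricle", bright "skull" shell,
noise, bias field, accelerated-aging AD subjects) so every stage has
ground truth. See `docs/methods.md` for the full model description and
the generator's scope and limitations.

## Worked example

One command runs the whole pipeline on a small synthetic cohort —
simulate, subject-level split, train, SVR fit, evaluate, BAG
classification:

```bash
brainage demo --seed 7 --out demo_out
```

prints (about seven seconds on one CPU):

```json
{
  "test_mae": 4.270167156672841,
  "baseline_mae": 9.578554792894748,
  "ensemble_accuracy": 1.0
}
```

Reading: on held-out subjects the trained two-block demo network predicts
age from phantom morphology with a mean absolute error of 4.3 years,
against 9.6 years for the no-information mean-age predictor; and the
majority-vote ensemble, given only each subject's brain-age gap,
classifies every held-out subject's CN/AD status correctly (the demo's AD
subjects age-accelerate by ~8 years, well above the regressor's error).
`demo_out/` contains the full regression metrics (MAE, RMSE, Pearson and
Spearman correlations, R², 95% CI of the mean signed error), the
per-classifier and ensemble reports with ROC points and AUC, the model
checkpoint, and the effective configuration for reproduction.

The same stages are available piecemeal — `simulate`, `split`,
`preprocess`, `train`, `svr-fit`, `predict`, `evaluate`, `classify-ad`,
`gradcam` — for real NIfTI volumes and CSV manifests
(columns: subject_id, scan_path, age, sex, diagnosis).

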