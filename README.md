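# swallowtail

Hybrid radiomics + deep-learning classification of **early Parkinson's
disease (PD)** on neuromelanin-sensitive setMag MRI, with a built-in
synthetic midbrain phantom that makes the entire pipeline runnable and
testable without any patient data.

## The problem

PD pathology begins with the loss of neuromelanin-containing
dopaminergic neurons in the substantia nigra pars compacta (SNpc); on
short-echo-time magnitude ("setMag") images reconstructed from a
multi-echo QSM acquisition, this loss appears as fading of the
dorsolateral nigral hyperintensity — the *swallow-tail sign*.  Early
disease changes are subtle, so automated, quantitative readouts are of
clinical interest.  The package implements a full diagnostic pipeline
for this task:

1. **setMag reconstruction** — voxelwise mean of the magnitude volumes
   of the three shortest echo times, S(TE) = S0·e^(−TE/T2\*) decay
   making those echoes the most T1-weighted / neuromelanin-sensitive.
2. **Brainstem localization** — a small convolutional center regressor
   (soft-argmax over a learned heatmap) emits one 40 x 40 crop per
   ROI-bearing axial slice (4 per case), enhanced by grayscale
   inversion + histogram equalization.
3. **Radiomics** — 1781 IBSI-style features per case
   (107 on the original image including 14 3D shape features, plus 93
   texture/first-order features on each of 18 filtered images: 8
   wavelet sub-bands, 5 LoG sigmas, square, square root, logarithm,
   exponential, gradient), reduced by an ICC(2,1) > 0.8 two-rater
   reproducibility filter and LASSO (cross-validated deviance) to a
   ~10-feature signature.
4. **CNN** — a modified LeNet (conv 6@5x5 → pool → conv 16@5x5 → pool →
   784 → **200** → 2) implemented in numpy with hand-written backprop;
   five-fold case-level cross-validation, augmentation (±5% scale, ±5°
   rotation, tripling the training set), best-validation checkpointing,
   and gradient saliency maps.
5. **Fusion** — per-case 4 x 200 deep features averaged over slices,
   ranked by mean decrease in impurity over 100 random forests, top 20
   fused with the 10 radiomics features into a **1 x 30** hybrid vector
   feeding six classifiers (KNN, RF, LR, SVM, MLP, AdaBoost).
6. **Evaluation** — patient-wise metrics under the 3-of-4 image voting
   rule (ACC/SEN/SPE/PPV/NPV/F1), AUC with stratified-bootstrap CI, and
   continuous NRI / IDI comparing the hybrid models against the
   radiomics-only baselines; Dice for inter-rater mask agreement.

The synthetic phantom renders a bright midbrain with bilateral SNpc
crescents on exactly 4 contiguous axial slices, a swallow-tail
hyperintensity that is attenuated and shrunk in the PD class, mono-
exponential multi-echo decay, Rician noise, and jittered second-rater
masks.  See `docs/methods.md` for the model, defaults and limitations.

## Worked example

```python
from swallowtail.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(n_hc=20, n_pd=20, n_rater2=10, seed=3,
                        cnn_epochs=18, detector_epochs=10)
result = run_pipeline(config, variant="hybrid")
print(len(result.selection.selected_features), "radiomics features selected")
print(len(result.fused_columns), "fused features per case")
print(result.table2()[["Feature", "Model", "ACC", "SEN", "SPE", "AUC"]]
      .to_string(index=False))
```

On this 40-case phantom cohort (32 train / 8 test) the run prints:

```
10 radiomics features selected
30 fused features per case
  Feature    Model  ACC  SEN  SPE  AUC
radiomics      KNN  1.0  1.0  1.0  1.0
radiomics       RF  1.0  1.0  1.0  1.0
radiomics       LR  1.0  1.0  1.0  1.0
radiomics      SVM  1.0  1.0  1.0  1.0
radiomics      MLP  1.0  1.0  1.0  1.0
radiomics AdaBoost  1.0  1.0  1.0  1.0
      cnn      CNN  1.0  1.0  1.0  1.0
   hybrid      KNN  1.0  1.0  1.0  1.0
   hybrid       RF  1.0  1.0  1.0  1.0
   hybrid       LR  1.0  1.0  1.0  1.0
   hybrid      SVM  1.0  1.0  1.0  1.0
   hybrid      MLP  1.0  1.0  1.0  1.0
   hybrid AdaBoost  1.0  1.0  1.0  1.0
```

Ten radiomics features survive ICC + LASSO selection, the fused vector
is 1 x 30 (10 radiomics + 20 deep), and at this small size every model
separates the held-out phantom cases perfectly — the phantom's planted
disease effect (swallow-tail attenuation 0.5, area shrink 0.8) is
strong by design so that recovery failures indicate pipeline defects
rather than noise.

A command-line interface wraps the same stages:

```bash
swallowtail simulate --n-hc 65 --n-pd 73 --seed 0 --out-dir cohort/
swallowtail run-all --variant hybrid --seed 0 --out-dir results/
swallowtail explain --model cnn.npz --patch patch.npy --out-png saliency.png
```

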