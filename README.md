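# tausynth

Cross-modal synthesis of tau-PET-like brain volumes with a 3D Dense-U-Net,
plus everything needed to exercise the full workflow on synthetic phantom
cohorts: preprocessing, subject-grouped cross-validation training,
regional-SUVR evaluation, tau-positivity/diagnostic ROC analyses, and
ROI-occlusion interpretability.

## The problem

Tau-PET imaging quantifies neurofibrillary-tangle burden and is central to
the biological characterization of Alzheimer's disease, but the tracer is
far less accessible than FDG-PET, amyloid-PET or structural MRI. A
regression network that *imputes* a tau-PET-like volume from one of those
more common modalities makes tau information available wherever the input
modality is — provided its regional accuracy, its diagnostic value and the
anatomy it relies on can be audited. This package implements that whole
audit loop for a volumetric encoder–decoder:

- **Model.** A 3D Dense-U-Net: four encoder blocks (dense, concatenative
  intra-block connectivity), a bridge block, four decoder blocks with skip
  connections; filters double down the encoder (`base_filters · 2^ℓ`) and
  halve up the decoder; ReLU activations, linear regression head, input
  and output `128³` (any `2^depth`-divisible grid works). One input channel
  per source modality; bimodal inputs stack along the channel axis.
- **Preprocessing.** SUVR normalization (divide by the *median* uptake of
  a reference region), T1w white-matter mean normalization, and the exact
  template↔network crop/pad (121×145×121 → 128³: 8 anterior + 9 posterior
  slices cropped, 7 zero-slices padded on the two 121 axes) with its exact
  inverse.
- **Training.** Subject-grouped 5-fold splits (60/20/20 train/val/test, no
  participant overlap, all scans of a subject in one partition), Adam
  (β₁ = 0.9, β₂ = 0.999), per-voxel MSE, mini-batch 2, lr 1e-4 halved on a
  7-epoch validation plateau with ≥10 epochs between decays (pure fixed
  schedule available), best-validation checkpointing.
- **Evaluation.** Scans×ROIs tables of median uptake with the meta-ROI
  (mean of member-ROI medians); per-ROI Pearson r and MAPE
  (`100·mean(|ŷ−y|/y)`); voxel-wise RMSE maps; 3D MS-SSIM; tau positivity
  at meta-ROI cut-offs 1.11/1.21/1.33/1.46 (strict `>`); ROC/AUROC for
  positivity and diagnostic contrasts (CU vs AD-spectrum, …).
- **Interpretability.** Occlusion sensitivity: zero one ROI in the input,
  re-impute, and record `ΔMAPE_{R1→R2} = MAPE_{R1→R2} − MAPE_{R2}` as an
  R×R adjacency matrix of local and remote influence.

Real tau imaging cohorts are access-restricted, so the package ships a
first-class **phantom generator**: paired-modality cohorts on a template
grid whose target modality is driven by a latent disease stage and by a
known source→target ROI coupling matrix (local and physically remote),
with reference-region pinning, additive noise and an optional
multiplicative scale nuisance. Ground truth is known by construction, so
training recovery, ROC behaviour and occlusion attributions are all
checkable.

The network and its training loop run on numpy (convolutions as batched
BLAS products with hand-written reverse-mode gradients) — no GPU or deep
learning framework required; the desk-scale configurations train in
minutes on one CPU.

## Worked example

```bash
python examples/03_train_and_impute.py
```

trains a depth-2 network for 30 epochs on a 16³, 40-subject phantom with a
planted remote coupling (and the latent stage term active) and prints:

```
epoch  1: train MSE 0.8229, val MSE 0.4364
epoch 30: train MSE 0.0213, val MSE 0.0269
best validation MSE 0.0150 at epoch 27

held-out meta-ROI (8 scans): Pearson r = 0.890, MAPE = 10.33%
```

A meta-ROI Pearson r near 1 means the imputed tau-like volumes preserve
the between-subject ordering of temporal meta-ROI burden on held-out
subjects; MAPE is the typical percentage error of that meta-ROI SUVR. Part
of the residual here is irreducible: the phantom's latent stage drives the
target partly through terms no source region carries (see
`docs/methods.md`).
The other examples cover the phantom generator, the crop/pad geometry,
positivity/ROC analyses and the occlusion matrix.

A thin CLI mirrors the library for shell use:

```bash
tausynth simulate --config phantom.yaml --out cohort/ --seed 1
tausynth train --cohort cohort/ --fold 0 --out ckpt/
tausynth impute --model ckpt/fold0 --in scan_source.nii.gz --out tau_hat.nii.gz
tausynth occlude --model ckpt/fold0 --cohort cohort/ --out occlusion.csv
```

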