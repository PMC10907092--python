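# Methods

This note documents the models, conventions and numerical choices behind
`tausynth`, and what the synthetic phantoms do and do not establish about
behaviour on real imaging data.

## Data model and coordinate conventions

All volumes are 3D scalar grids sharing one voxel grid; no resampling or
reorientation is performed anywhere (registration is assumed done
upstream). Axis order is fixed as (x: left–right, y: posterior–anterior,
z: inferior–superior), 0-based indices. Volumes carry a `space` tag:
`template` (anatomical grid, 121×145×121 at full size) or `network`
(power-of-two grid, 128³ at full size). NIfTI affines are preserved
verbatim through I/O; atlases travel with a JSON sidecar (label names,
meta-ROI members, reference label).

## Template ↔ network geometry

The network needs sides divisible by `2^depth`. The full-size mapping
crops 17 slices from the posterior–anterior axis — 8 at the anterior
(high-index) end, 9 at the posterior end — and zero-pads 7 slices at the
low-index end of each 121-length axis ("left" and "bottom"; the published
description names the ends but not the array axes, so the low-index
convention is fixed here and configurable in `CropPadSpec`). The inverse
restores the template shape exactly: retained voxels are bit-identical
and cropped slices return as zeros. Both directions validate the closure
arithmetic at construction.

## Intensity normalization

PET volumes are converted to SUVR by dividing by the **median** uptake in
the atlas's reference region (a pons / cerebellar-crus surrogate in the
phantoms); the in-reference median is exactly 1 afterwards. T1w-like
volumes divide by the **mean** within a white-matter mask. Both are
scale-equivariant, which is precisely the property that removes the
multiplicative scan-level scale nuisance the phantom can inject. A
non-positive reference median or an empty mask raises instead of
producing silent infinities. Bias-field correction and partial-volume
correction are out of scope.

## Phantom generative model

Per subject: latent stage `s ~ U(0,1)`; source ROI means
`u_r = b_r + a_r·s + dev_r` with cohort-level baselines
`b_r ~ U(1.0, 1.8)` and stage slopes `a_r ~ U(−0.4, 0.4)` drawn once per
cohort, and per-subject deviations `dev_r ~ N(0, 0.12)`. Target ROI means
are the linear coupling `m = Wᵀu + c·s`, where `W[i,j]` is the influence
of source ROI `i` on target ROI `j` (identity by default; planted remote
entries added via `with_remote_coupling`) and the stage effect `c` is 0.8
in meta-ROI members and 0.05 elsewhere — so meta-ROI tau rises ~0.8 SUVR
across the stage range, comparable to the CU→dementia spread of real
temporal meta-ROI values. Reference-region means of both modalities are
pinned to 1 so SUVR is always defined. Voxels are the ROI mean plus
`N(0, noise_sd)` (default 0.06, ≈5% of the ~1.2 signal level), noise
independent across the scans of a subject. ROIs are axis-aligned blocks
shrunk by a one-voxel margin, so distinct ROIs are disconnected — the
geometric precondition for calling an occlusion effect "remote".

Diagnostic labels are deterministic stage bins in the order CU−, CU+,
FTD-spec, DLB-spec, MCI, AD-spec (cut points 0.30/0.45/0.55/0.65/0.80),
placing the non-AD dementias below MCI/AD in tau burden; amyloid
positivity is `s ≥ 0.35`. These labels carry no clinical semantics beyond
"meta-ROI tau increases with stage"; they exist to make ROC contrasts
well-posed with separable classes.

What the phantom does **not** emulate: anatomy (block ROIs, no cortical
geometry), off-target tracer binding, scanner/manufacturer effects,
longitudinal within-subject progression (repeat scans differ only by
noise), and non-linear source→target physiology. Passing tests therefore
demonstrate that the machinery is correct — recoverable couplings are
recovered, splits never leak, metrics match their definitions — not that
any particular accuracy will be attained on clinical data.

## Network and optimizer

Dense blocks: each of `layers_per_block` convolutions (3³, "same"
padding, ReLU) receives the concatenation of the block input and all
previous layer outputs — layer `j` sees `c_in + j·f` channels, where the
block's filter count `f = base_filters·2^level` doubles per encoder level
and halves per decoder level. The block output is the last layer's
activation, which keeps the filter arithmetic exact at the skip
junctions. Downsampling is 2³ max-pooling; upsampling is
nearest-neighbour followed by a convolution (chosen over transposed
convolution to avoid checkerboard artefacts); the head is a linear 3³
convolution to one channel, since the target is continuous SUVR trained
with MSE. Published figures denote per-block filter counts but the text
fixes neither `base_filters` nor `layers_per_block` nor batch
normalization; defaults here are `base_filters=16`, `layers_per_block=2`,
no batch norm, all configurable. Weights are He-uniform with a seeded
generator; biases zero.

The implementation is numpy throughout: convolutions are evaluated as one
batched `(k³·C_out, C_in) × (C_in, N_voxels)` BLAS product plus 27
shifted accumulations (both forward and for the input gradient, which is
the same primitive with a flipped, channel-transposed kernel), and the
weight gradient slides the output gradient over the contiguous input.
Gradients of every primitive are verified against brute-force loop
references and finite differences; float32 arithmetic bounds the
achievable finite-difference agreement, so the end-to-end check asserts
median agreement over the largest-gradient entries.

## Training protocol

Grouped k-fold (k=5) splitting shuffles subjects once, partitions them
into k groups, and rotates: fold i tests on group i, validates on the
next group(s), trains on the rest — every subject is tested exactly once
and no subject ever spans partitions within a fold (asserted, not
assumed). The optimization recipe follows the published protocol: Adam
(β₁=0.9, β₂=0.999), lr₀=1e-4, mini-batch 2 (gradients averaged across
the batch before each step), 150 epochs at full size, per-voxel mean MSE
for both training and validation. The source protocol states both a fixed
halving every 10 epochs *and* a halving when validation fails to improve
for 7 epochs; these are reconciled as plateau-triggered halving with a
minimum of 10 epochs between decays, with the pure fixed schedule
(`schedule="fixed"`) available. No augmentation, no early stopping; the
best-validation parameter set is retained and restored after the last
epoch.

## Evaluation

Regional values are **medians** within each ROI; the meta-ROI (surrogate
for amygdala + entorhinal + fusiform + parahippocampal + inferior/middle
temporal) is the arithmetic mean of its members' medians, recomputable
bit-for-bit from the table. Pearson r and MAPE are computed per ROI
across scans (not across voxels). Tau positivity uses strict `>` at the
cut-off (the published definition is silent on ties; exact equality is
measure-zero in practice). ROC curves come from the standard
all-threshold sweep; the trapezoidal AUROC equals the Mann–Whitney
pair-ordering probability with ties at ½, which the tests verify against
an O(n²) pair-counting oracle. MS-SSIM is hand-written for 3D (uniform
7-voxel window, K₁=0.01/K₂=0.03, sample covariance): contrast–structure
means of coarser scales multiply the finest retained scale's full SSIM
under the conventional exponents, renormalized over however many scales
fit the volume (auto-reduced for desk-scale grids); non-positive factors
clamp the index to 0 so it stays in [0,1] for non-negative images, and
`scales=1` reduces exactly to single-scale SSIM. For diagnostic ROC with
predictors where disease *lowers* the score (FDG hypometabolism), a
`flip_sign` option negates scores rather than hard-coding a direction.

## Occlusion analysis

For each ROI R1: zero R1's voxels in the source, re-impute every test
scan, rebuild the regional table, and record per-ROI
`ΔMAPE[R1,R2] = MAPE_{R1→R2} − MAPE_{R2}` against the baseline from
un-occluded inputs over the same scans. Values may be negative and are
never clamped. Occlusion is applied **after** SUVR normalization (the
source description occludes "the original source images" without fixing
the order; post-normalization is chosen so zeroing a region cannot
corrupt the reference median that scales every other region — occluding
the reference region itself would otherwise redefine the whole volume).
Rows follow atlas label order; lobar regrouping is a reporting concern
left to the caller. The voxelwise copy model is the analytic base case:
its off-diagonal ΔMAPE vanishes identically, which the tests assert to
1e-10.

## Desk-scale problem sizes

Full-size training (128³, depth 4) is supported by the same code paths
but all shipped configurations are desk-scale, chosen so the complete
suite runs on one CPU: unit tests use 16³ grids; the synthesis-recovery
run uses a 32³ grid, 12 ROIs, 60 subjects × 1 scan, a depth-2/8-filter
network and 30 epochs (≈10 min); occlusion-recovery replicates use a 16³
grid with 40 subjects and a depth-2/4-filter network for 50 epochs
(≈40 s each). At these sizes the full-size protocol's lr of 1e-4 would be
far from convergence after 30 epochs, so the desk recipes use lr₀ = 2e-3;
the `TrainConfig` default remains the full-size 1e-4.

The recovery phantom itself (`tausynth.experiments`) differs from the
general defaults in two respects: its source emulates an amyloid-PiB-like
tracer whose ROI uptake *rises consistently* with the latent stage
(slopes U(0.4, 0.8) rather than random-sign), and the target carries no
separate stage term — it is exactly `coupling · source` plus noise. The
between-subject meta-ROI spread (~12% of the mean, comparable to real
amyloid/tau cohort spreads) is therefore inherited through the coupling
and fully observable from the input, so the held-out correlation measures
what the network learned. The alternatives are degenerate for a recovery
experiment: a stage term with random-sign source slopes is largely
unobservable from the input and caps attainable r near 0.85 regardless of
the network, while a stage-free target with random-sign slopes collapses
the meta spread to a few percent and turns r into a coin flip on the
cohort draw. The general phantom defaults keep the stage-driven target —
that configuration is what the ROC and positivity analyses need, and it
is also what the occlusion-recovery replicates use: with random-sign
slopes the planted remote source ROI carries information no other region
duplicates, so a trained model must visibly degrade when it is occluded,
whereas under the informative-source conditions the planted signal is
redundant and occlusion responses shrink to convolutional spillover. These
sizes and conditions are the package's reference configurations for
reproducibility, not statements about the published cohorts.

## Known limitations

- The phantom's linear source→target coupling is exactly the function
  class a convolutional regressor represents easily; recovery results do
  not probe non-linear physiology.
- Determinism guarantees assume a fixed BLAS thread count; loss histories
  are reproducible run-to-run on the same machine configuration.
- The numpy engine is single-sample; batch-2 steps average gradients over
  two forward/backward passes rather than vectorizing them.
- `MS-SSIM` weights beyond five scales are undefined (as in the original
  formulation); volumes smaller than 7 voxels per side are rejected.
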