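# thermofract

Infrared thermography (IRT) offers a radiation-free way to screen for
pediatric wrist fractures: a fracture changes local blood flow, so the
injured wrist's skin runs measurably warmer than the uninjured
(contralateral) wrist. `thermofract` implements a complete classification
pipeline for this problem — from thermal frames to diagnostic metrics —
for researchers who want to study, stress-test, or extend the approach
without access to patient recordings, which cannot be shared.

The pipeline:

1. **Synthetic cohort generation** — 40 participants by default
   (19 fracture / 21 sprain), 299 frames per wrist, each participant with
   a baseline skin temperature, a smooth anatomical temperature field
   shared by both wrists, an injury-site Gaussian hotspot (peak elevation
   0.8–2.0 °C for fractures, 0.1–0.4 °C for sprains), and per-frame
   sensor noise.
2. **Preprocessing** — each injured-wrist ROI is expressed relative to the
   mean of its contralateral ROI, 2D-FFT'd, and the DC-centered magnitude
   spectrum is cropped to its central 100 × 100 window (this both resizes
   variably-sized ROIs and keeps the dominant low frequencies). An 8-bit
   log-scaled grayscale PNG rendering is available for export.
3. **Augmentation** — each spectrum receives exactly one random transform:
   rotation in [−90°, 90°], integer translation in [−3, 3] px per axis, or
   shear with factors in [−2, 2] per axis; the augmented image replaces
   the original, so the dataset never grows.
4. **Participant-level 70:30 split** — stratified by class, with a hard
   guarantee (and an explicit checker) that no participant's images
   straddle the train/validation boundary.
5. **A 34-layer CNN** — 8 convolution blocks (3×3 same-padding conv,
   batch norm, ReLU) with filter counts `min(2^(n+2), 512)` =
   8, 16, …, 512, 512; 2×2/stride-2 max pooling after blocks 1–5 and 8;
   a 512→2 fully connected layer; softmax and classification stages.
   Implemented as a numpy CNN with full backprop and Adam
   (lr 0.005, batch 170, 250 epochs, cross-entropy by default).
6. **Evaluation** — confusion matrix with fracture as the positive class,
   sensitivity/specificity/PPV/NPV/accuracy (in %, `None` when a
   denominator is zero), and a threshold-sweep ROC whose AUC equals the
   Mann–Whitney statistic.

Two experiment variants are wired end to end: **A** (augmentation, no
dropout) and **B** (no augmentation, dropout 0.2 between the last pool
and the FC layer — 35 layers).

## Worked example

Audit the architecture's learnable-parameter accounting:

```bash
$ thermofract describe-model --variant A
variant: augmentation_no_dropout  layers: 34

layer           kind                  params   published  note
Input           input                      0           -
Conv_1          conv2d                    80          80  ok
Batchnorm_1     batchnorm                 16          16  ok
...
Conv_8          conv2d             2,359,808   1,180,160  MISMATCH (published 1,180,160)
...
total learnable parameters: 3,937,458 (3.9 million)
```

Every published per-layer count is reproduced exactly except `Conv_8`:
the published table repeats the `Conv_7` value there, which is
inconsistent with its own `Batchnorm_8` (1024 ⇒ 512 channels) and FC
(1026 = 512·2 + 2) rows. The audit reports the discrepancy instead of
silently adopting either number; with 512 eighth-block filters the total
is 3.9 million parameters, matching the published headline figure.

Run a small end-to-end experiment (about half a minute on one CPU):

```bash
$ thermofract run --variant A --preset desk --seed 0 --out runs/demo
{
  "variant": "A",
  "preset": "desk",
  "images": 160,
  "train_images": 120,
  "validation_images": 40,
  "iterations": 90,
  "validation_accuracy_pct": 100.0,
  "auc": 1.0,
  "wall_seconds": 31.4
}
```

The desk preset simulates 8 participants × 20 frames with a strongly
separated injury effect; 6 participants (120 spectra) train the network
for 15 epochs and 2 held-out participants per class (40 spectra) are
scored. Validation accuracy 100% and AUC 1.0 say the pipeline recovers
the injury signal perfectly under these easy, noise-light conditions —
see `docs/methods.md` for what this does and does not imply about real
thermal data. The output directory receives the run manifest (all derived
seeds and stage configurations), the split table, the per-iteration
training log, training curves, the ROC plot, and the metrics report.

`--preset paper` keeps the full study configuration: 11,960 images,
8372/3588 split (13 + 15 training participants), 49 iterations per epoch
and 12,250 Adam updates.

Individual stages are also exposed (`simulate`, `preprocess`, `split`),
and the library API mirrors the CLI one-to-one
(`thermofract.run_experiment`, `generate_cohort`, `magnitude_spectrum`,
`split_cohort`, `build_architecture`, `train_model`, `evaluate_scores`).

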