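# Methods

## The classification problem

A wrist fracture increases perfusion at the injury site, raising local
skin temperature relative to the patient's uninjured contralateral wrist.
The pipeline classifies a participant's injured-wrist thermal frames as
*fracture* versus *sprain* from the magnitude frequency spectrum of the
contralaterally normalized region of interest (ROI). Fracture is the
positive class everywhere (label index 1).

## Synthetic cohort model

Real recordings cannot be shared, so cohorts are simulated with the
statistical structure the study design implies. For participant *p* with
ROI of size H × W, frame *t*:

    uninjured_t = B_p + F_p + ε_t
    injured_t   = B_p + F_p + δ_p · G + ε'_t

- **B_p** — baseline skin temperature, drawn N(31, 1²) °C per participant.
- **F_p** — smooth zero-mean anatomical field (Gaussian-filtered white
  noise, kernel σ = min(H, W)/6, rescaled to pixel SD 0.3 °C), drawn once
  per participant and **shared by both wrists**. Bilateral thermal
  symmetry is the premise of contralateral normalization; sharing the
  field makes the mean-subtraction cancel it exactly, so the recovered
  effect equals the injected effect.
- **G** — unit-peak centered Gaussian hotspot, σ = min(H, W)/4. The
  injury is modeled as a single smooth warm spot.
- **δ_p** — peak hotspot elevation: uniform 0.8–2.0 °C for fractures
  (the forearm-fracture skin-temperature elevation range reported for
  this cohort's modality), 0.1–0.4 °C for sprains, chosen below the
  smallest reported fracture elevation so the classes are separable but
  adjacent.
- **ε_t** — iid per-pixel sensor noise, SD 0.05 °C per frame (typical
  thermal-camera NETD magnitude).

ROI sides are drawn uniformly from 60–160 px per participant so that the
spectrum-domain resizing is genuinely exercised. Defaults: 19 fracture +
21 sprain participants, 299 frames each (11,960 injured-wrist images).
Both wrists are generated; only injured-wrist spectra feed the
classifier, the uninjured wrist contributing its ROI mean as baseline.

Randomness: one master seed; each participant's stream is keyed by
(seed, SHA-256 of participant id), so adding or removing a participant
never perturbs any other participant's frames, and equal seeds give
bit-identical cohorts.

**What the generator does not emulate:** hand geometry and pose, ROI
placement error, emissivity and radiometric calibration, temporal drift
or motion between frames, ambient-temperature gradients, and any
asymmetric anatomy (the field F_p is perfectly mirrored). Passing tests
therefore demonstrate that the *pipeline machinery* recovers a known
injected signal — not that real wrists are this separable.

## Preprocessing

`normalized = injured − mean(uninjured)` removes the participant-specific
temperature offset. The normalized ROI is 2D-DFT'd; the modulus is
shifted so the zero-frequency (DC) bin sits at (⌊H/2⌋, ⌊W/2⌋) and the
central 100 × 100 window is extracted (rows [c−50, c+50), likewise
columns), placing DC at (50, 50). ROIs smaller than 100 px in a dimension
are first zero-padded symmetrically (odd pixel after): spatial zero
padding refines frequency sampling without altering content, and it
leaves the image sum — hence the DC magnitude — unchanged. Indexing is
0-based, row-major, half-open throughout.

The float magnitude is what augmentation and the network consume by
default. For on-disk export the spectrum is rendered to 8 bits as
`round(255 · log1p(m) / max(log1p(m)))` — without the log the DC bin,
orders of magnitude above the texture bins, would saturate the image.
A `use_png_quantized` flag routes the quantized rendering into the
classifier instead, for strict fidelity to a PNG-file pathway.

## Augmentation

Each image receives exactly one transform, replacing the original
(dataset size is invariant — the study's split totals force this reading,
even though "augmentation" usually implies growth). Rotation is uniform
in [−90°, 90°] (bilinear, about the image center), translation is an
integer shift in [−3, 3] px per axis, shear applies [[1, sx], [sy, 1]]
(factors uniform in [−2, 2], bilinear, about the center). Exposed regions
are zero-filled so no spectral content is invented.

Two caveats are worth knowing. First, shear pairs with sx·sy ≈ 1 make the
affine map near-singular: the output pixel grid then samples almost
entirely outside the source frame and the image comes back (near-)blank.
At full scale this acts as occasional heavy corruption; on an
8-participant cohort it destroys a meaningful share of the data, so the
sampler accepts a narrowing (never widening) `shear_range`, and the desk
preset uses ±0.2. Second, augmentation is applied **after** the
participant split, independently per subset, so no augmented view of a
training participant can reach validation.

## Splitting

The 70:30 split is by participant, stratified by class:
`round_half_away(0.70 · n_class)` participants per class go to training —
the only rounding rule that yields both 13 of 19 and 15 of 21. With 299
frames each this gives 3887 + 4485 = 8372 training and 1794 + 1794 = 3588
validation images. `verify_no_leakage` checks the materialized image
assignment, so a corrupted plan is caught, not just an ill-formed one.
The validation set doubles as the test set (single split, no third
held-out set) — a methodological caveat inherited from the study design.

## Architecture and parameter accounting

Eight conv blocks (3×3 kernels, stride 1, same padding; batch norm;
ReLU), max pooling (2×2, stride 2, floor) after blocks 1–5 and 8, then
FC(512→2), softmax, classification. Same-padding convolution is forced by
the accounting: only pooling changes spatial size, and the trace
100→50→25→12→6→3→3→3→1 is exactly what makes the FC layer see
512 features (FC parameter count 1026 = 512·2 + 2). Filter counts follow
`min(2^(n+2), 512)`. Counting input, activations, pools, softmax and
classification as layers gives 34 (35 with dropout).

Parameter formulas (conv: k²·C_in·C_out + C_out; batch norm: 2·C;
FC: in·out + out) are cross-checked in the tests against exhaustive
enumeration of the instantiated weight arrays. The published per-layer
table is reproduced exactly on every row except the eighth convolution,
where the printed value repeats the seventh row and is inconsistent with
the same table's Batchnorm_8 and FC rows; the audit flags it and the
blueprint keeps 512 filters (total 3,937,458 ≈ 3.9 M).

The network itself is a numpy implementation: im2col convolution,
batch-norm/ReLU/max-pool/dropout/dense layers with full reverse-mode
gradients (validated by central-difference checks), Glorot-uniform
initialization from a seeded generator, and Adam (β = 0.9/0.999,
ε = 1e−8 — standard defaults, unstated in the source protocol). The
blueprint's softmax and classification stages are realized by
`predict_proba`/`predict`; an exact 0.5/0.5 tie resolves to non-fracture.

## Training

Adam at lr 0.005, batch 170, 250 epochs, cross-entropy, no early
stopping. An epoch is ⌊n_train/batch⌋ updates with the final partial
batch dropped — the only reading consistent with 49 iterations per epoch
at 8372 images, giving 12,250 total updates. Shuffling is per-epoch,
seeded; equal seeds give identical loss trajectories. Validation metrics
are computed every epoch; both the across-epoch mean and the final-epoch
value are reported, since the study protocol is ambiguous about which its
headline numbers used. Training refuses to start if any participant
appears in both subsets, and aborts with a diagnostic on a non-finite
loss.

Inputs are standardized with a **single scalar** mean and SD fitted on
the training set. This is deliberate: per-pixel whitening equalizes every
bin's variance, erasing the DC/low-frequency dominance that carries the
injury signal and leaving the network free to key on per-participant
noise-floor fingerprints (which do not generalize across participants);
a global affine rescale preserves the spectrum's internal structure while
bringing it into the optimizer's working range.

## Evaluation

Standard 2×2 confusion tally; the five metrics in percent with zero
denominators reported as an explicit `None` (never 0 or NaN). ROC/AUC via
threshold sweep (scikit-learn); the tests verify the AUC against a
brute-force Mann–Whitney pair-counting oracle and the trapezoid integral
of the reported curve. With balanced classes, accuracy ≡
(sensitivity + specificity)/2 — used as an internal consistency check.

## Problem sizes and presets

The **paper** preset keeps every study constant (40 × 299 images,
batch 170, 250 epochs, full augmentation ranges). The **desk** preset —
used by the test suite's end-to-end check — simulates 8 participants × 20
frames with a strongly separated effect (fracture peak 2.5–3.5 °C vs
sprain 0.1–0.3 °C, ROI sides 80–120 px), trains 15 epochs at batch 20
with lr 0.001 (the paper rate linearly rescaled for the 8.5× smaller
batch) and shear narrowed to ±0.2 as above. A desk run is ~30 s on one
CPU and reaches 100% validation accuracy across seeds; this is a
lower-bound plumbing check on an easy problem, not a performance claim.

## Known limitations

- The headline clinical metrics of the motivating study were computed on
  withheld patient data and are not reproducible here; nothing in this
  package should be read as replicating them.
- Pool placement in the original architecture is not fully documented;
  blocks 1–5 and 8 is the arrangement consistent with the 34-layer count
  and the stated pool-before-FC position, but others are conceivable.
- The numpy engine targets correctness and desk-scale speed, not GPU
  throughput; a paper-scale 250-epoch run is out of reach on one CPU and
  is exercised only through its exact bookkeeping identities.
- Synthetic separability is controlled by the delta ranges; with the
  study-default ranges the classes are closer and small cohorts are
  genuinely hard (few participants, participant-level generalization).
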