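# Methods

This note documents the models, the synthetic data, the numerical choices
and the limits of what the bundled experiments demonstrate.

## Synthetic iEEG generator

Each record is 90 s × 4 channels at 250 Hz, in arbitrary µV-scale units
(only relative amplitudes matter downstream, because spectrogram images are
min-max normalized per image).

**Background.** 1/f-shaped Gaussian noise (amplitude ∝ f^(-1/2) above 1 Hz,
flat below), normalized to unit RMS, plus sparse interictal spikes
(biphasic transients, ~0.08/s, peak amplitude 2–3× background RMS, width
30–60 ms).  The spikes are brief enough that no 5-s window's RMS exceeds 3×
the median window RMS on a non-seizure channel — the windowed-RMS oracle
used in the tests.

**Ictal activity** is added from the onset sample to the end of the record,
with an amplitude envelope that ramps over ~4 s and then sustains, so every
seizure channel exceeds 3× background RMS within 5 s of onset.  Three
morphology families span the mesiotemporal/neocortical phenomenology:

* *low-voltage fast* — a 22–30 Hz rhythm sweeping down to 10–14 Hz while
  growing (amplitude 6);
* *hypersynchronous rhythmic spiking* — a 2–5 Hz train of sharp biphasic
  waves (amplitude 9);
* *evolving spike-wave* — ~3 Hz spike-wave complexes slowing by ~30%
  (amplitude 8).

Lead location (MTL 36% / NEO 29% / MTL+NEO 35% of patients) selects the
admissible families.  The exact waveforms are inventions: the generator
emulates the *spectro-temporal structure* that matters to the analysis
(band-limited power appearing at a well-defined onset), not biophysics.

**Onsets and triggers.** Long-episode records store ~60 s of pre-trigger
signal and the device declares an episode ~30 s after detection begins, so
onsets are drawn from N(30 s, 3 s) by default (`onset_center_s`,
`onset_spread_s`; a uniform option exists for validation cohorts) and the
record trigger is set to `min(onset) + 30 s`, clipped to the record.  The
seizure-record share of a cohort equals `seizure_record_fraction` exactly
(stratified assignment, not i.i.d. coin flips), so prevalence checks hold at
any cohort size.  Seizure records carry 1–4 seizure channels
(probabilities 0.45/0.30/0.15/0.10).

**Reviewer panel.** Each simulated reviewer has sensitivity, specificity,
an unsure rate, a missing rate, and onset jitter/bias.  A latent per-channel
*ambiguity* `a ∈ [0, 1]` pulls every labelling decision toward a fair coin:
on true seizure channels `P(seizure) = sens·(1−a) + a/2`; on true
non-seizure channels `P(seizure) = (1−spec)·(1−a) + a/2` (a configurable
`specificity_floor` can damp the second term).  One knob thus produces the
full 0/1/2/3-of-3 disagreement spectrum.  Annotated onsets are
`clip(true + bias + N(0, jitter), 0, 90)` rounded to 0.1 s; draws below zero
set the before-record-start flag instead.  False-positive seizure calls get
a uniform random onset (nothing anchors them).  The default ambiguity range
(0, 0.5) yields panels that agree on most channels but disagree on a
sizeable minority; experiments that need unambiguous channels set it to 0.

All generation is deterministic: one child random stream per record is
derived from the cohort seed, and the reviewer simulator consumes a single
seeded generator.

## Spectrogram featurization

Hann-tapered, one-sided periodogram per frame with window 256 samples and
step 128; power is `10·log10(P + 1e−12)` so silent channels map to a finite
floor.  Frame *i* covers samples `[128·i, 128·i + 256)` and is stamped at
its center, `(128·i + 128)/250` s — the frame↔time maps are inverses up to
one step.  A 90-s record yields a 129 × 174 image.  Images are min-max
normalized **per image** to [0, 1] (robust to the generator's arbitrary
units; a constant spectrogram maps to 0.5 with a warning) and
bilinearly resized, by default to 32 × 48 (≈ 1.9 s per column), the size at
which desk-scale training is fast while onsets remain localizable.

## Network design

No deep-learning framework is required: the networks are NumPy
implementations with explicit forward/backward passes and Adam.

The shared **backbone** is two 3×3 convolution blocks (8 then 16 channels,
leaky-ReLU slope 0.01, 2×2 max pooling).  Plain ReLU is avoided
deliberately: at these tiny batch counts a single aggressive epoch can kill
every hidden unit (observed as all-equal outputs and zero gradients);
leaky units make that collapse impossible.  Averaging the feature map over
the frequency axis and projecting each time column through a shared dense
layer produces a per-column **ictal evidence profile** `s_j`.

Both task heads read this profile:

* **Classification** — the logit is affine in the *smooth range* of the
  profile, `smoothmax(s) + smoothmax(−s)` with temperature 0.5.  Under
  per-image min-max normalization a non-seizure image is temporally
  homogeneous while a seizure image has a pre-onset regime and an ictal
  regime, so evidence *contrast across time* is exactly the invariant that
  separates the classes.  (Pooling the profile by a plain mean provably
  fails here: normalization equalizes image means between classes.)
* **Onset regression** — a softmax (gain 4) over the first differences of
  `s` yields attention weights over column boundaries; their positional
  expectation is the normalized onset.  The prediction is
  `clip(output × 90 s, 0, 90)`.  The readout is translation-equivariant by
  construction: the model finds *where evidence rises*, wherever that is.

**Transfer.** Fine-tuning the classifier into the regressor copies the
convolution weights *and* the evidence projection.  The classification head
is symmetric in `s → −s`, so a trained classifier may encode ictal columns
as either high or low evidence; `build_sod` resolves this by evaluating
both orientations at epoch 0 on the *training* items and keeping the better
one (deterministic; no validation data involved).  With the orientation
fixed, a task-pretrained regressor starts with a near-step evidence profile
and is accurate almost immediately — the mechanism behind the
initialization ablation.

The `resnet50_class` backbone family is declared for completeness but
raises `NotImplementedError`; the claims exercised here are protocol-level
and the small network is the supported engine.  The *generic* pretraining
arm trains the same architecture on a synthetic texture-discrimination task
(oriented gratings vs smoothed noise): generically useful filters that have
never seen ictal data.

## Training protocol

`TrainConfig` defaults carry the published settings (Adam, learning rate
1e−4, 400 epochs, batch 16, patient-wise 5-fold cross-validation with an
80/20 split).  The desk-scale profile used by the bundled studies and tests
(`ExperimentConfig.desk_scale`) trains the classifier for ≤ 40 epochs and
the regressor for 6 epochs at learning rate 1e−2 — sized so a full study
runs in seconds per fold on one CPU core.  Classification uses
class-weighted binary cross-entropy and keeps the epoch with the lowest
validation loss; regression uses a Huber loss on normalized onsets
(δ = 0.5, effectively quadratic in-range with bounded outlier influence)
and keeps the epoch with the lowest validation *median absolute error* —
the checkpoint rule the selection metric demands.  Validation sets contain
original (non-augmented) items only; a guard raises if an augmented copy
sourced from a validation patient ever reaches a training set.

## Time-shift augmentation

Right shifts only: deleting the tail and duplicating the head cannot paste
ictal activity after a seizure's end, which a left shift could (creating a
spurious second seizure).  "One draw per 5-s bin" is read literally: with
onset `t` and margin `m` (default 5 s, so some post-onset activity survives
the tail deletion), the allowable shift is `M = 90 − t − m`, bins are
`[0,5), [5,10), …` — `floor(M/5)` of them — and one uniform draw is taken
per bin.  A cap (default 6, random subset preserving bin diversity) gives
the ~6–7× expansion characteristic of 30-s onsets.  Shifts snap to whole
samples; the onset label moves by exactly the snapped shift.

## Reviewer statistics

* Agreement excludes unsure/missing labels pairwise; per-class percentages
  condition on the *reference* labeller.  Overall agreement is symmetric,
  per-class breakdowns are not.
* Consensus analyses require all three reviewers to give a definite
  (seizure/non-seizure) vote.  Percentages can be taken over that decided
  set (bins then partition it) or over all channels where three reviewers
  responded, unsure included (`responded_denominator` — the convention in
  which the four bin shares do not sum to 100%).
* Calibration fits OLS to the four bin means of model probability against
  `k/3` and reports the squared Pearson correlation of those means; empty
  bins are dropped from the fit and flagged, a zero-variance fit is flagged
  degenerate.
* Pairwise sensitivity and FPR are computed per patient and averaged over
  patients with defined rates; the bootstrap resamples *patients* (channels
  within a patient are correlated, so channel-level resampling would
  understate uncertainty).  BCa intervals follow Efron: `z₀` from the share
  of bootstrap statistics below the point estimate (clipped away from 0/1),
  acceleration from jackknife skewness, adjusted percentile endpoints by
  linear-interpolation quantiles.  Degenerate (zero-variance) inputs return
  a collapsed, flagged interval.  `z₀`/`a` can be forced (e.g. to 0,
  recovering the percentile bootstrap — a test hook and a sanity check).
* Noninferiority: model mean sensitivity ≥ the smallest expert-pair lower
  bound AND model mean FPR ≤ the largest expert-pair upper bound.  This is
  one concrete reading of "inside the expert band"; the bounds used are
  reported with the verdict so other margins can be applied.
* Precision-recall curves and average-precision AUPRC come from
  scikit-learn; the tests cross-check the area against exhaustive threshold
  enumeration on small sets.

## Onset evaluation

"All three annotations within an X-s window" means max − min of the three
onsets ≤ X; the reference onset is their arithmetic mean (the reference
definition is not uniquely determined by convention, so it is explicit and
configurable).  Channels with any before-record-start flag are excluded.
The subsets nest by construction.  The trigger baseline predicts the record
trigger time for every seizure channel; with the generator's trigger ≈
onset + 30 s it errs by ~30 s, the yardstick the learned model must beat.

## Desk-scale ordering experiment

`ordering_experiment(seed)` trains on an onset-biased cohort (12 patients ×
2 records, onsets ~N(30, 3)) and validates on a disjoint uniform-onset
cohort (6 patients × 2 records, onsets ~U(10, 80)), so memorizing the
training onset distribution fails on validation.  Three arms share data and
folds: original-only/random-init, augmented/random-init, and
augmented/task-pretrained.  Expected pattern (stochastic, judged over a
majority of seeds): augmentation cuts the validation median absolute error
from ~20 s to ~2 s; task pretraining improves on random initialization
within the same epoch budget; both beat the ~30-s trigger baseline.

The augmentation comparison is run under **random** initialization: with
the task-pretrained evidence head the regressor is position-agnostic from
epoch 0 (the rise readout is translation-equivariant), so the training-set
onset bias barely hurts it and the augmentation margin nearly vanishes;
under random initialization the positional prior must be learned from data
and the augmentation effect is large and stable.  The initialization
comparison uses augmented data in both arms.

## What passing does and does not show

The synthetic cohorts have high spectro-temporal signal-to-noise, one
seizure per record, stationary backgrounds, and reviewer errors that follow
the simulator's own model.  Green tests therefore validate the *pipeline*
— exact augmentation arithmetic, leak-free fold handling, checkpoint
selection, statistical machinery, and the qualitative protocol effects
(augmentation repairs onset bias; task transfer helps) — not clinical
performance.  Absolute errors here (~1–2 s) are far better than anything
achievable on real iEEG, where morphologies drift, onsets are equivocal and
artifacts abound.

## Known limitations

* The NumPy engine supports the bundled two-block architecture only; there
  is no GPU path and `resnet50_class` is declared but not implemented.
* EDF export quantizes to 16 bits per channel with a per-channel physical
  range; metadata beyond patient/record ids and device/record type does not
  round-trip.
* The reviewer simulator draws labels independently across reviewers given
  the latent ambiguity; real reviewer errors are correlated in richer ways.
* Record-level statistics treat a record's channels as exchangeable; lead
  geometry is modelled only as a per-patient stratum label.
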