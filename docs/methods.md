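# Methods

## Scope and model

The package studies confidence-filtered self-training for 3-class retinal
OCT classification (normal / drusen / CNV). The semi-supervised scheme is
pure pseudo-labeling: no consistency regularization, no exponential-moving-
average teachers, no soft labels. A teacher trained on the labeled pool
assigns hard argmax pseudo-labels with confidence equal to the maximum
softmax probability; labels at or above a threshold are accepted; a fresh
student trains on labeled + accepted data; the student becomes the next
teacher. "Confidence" is deliberately the maximum class probability — the
simplest reading of a probabilistic classifier's score — and acceptance
uses `>=` so that a threshold of 0 means "accept everything", which the
threshold sweep requires as its permissive endpoint.

Design choices where the design was genuinely open:

* **Re-prediction, not accumulation.** Every iteration re-predicts the
  entire unlabeled pool with the current teacher and rebuilds the accepted
  set from scratch. Sticky pseudo-labels would freeze early mistakes; with
  re-prediction a wrong early call can be revised once the student improves.
* **Fresh students.** Each student starts from a new initialization rather
  than warm-starting from the teacher, limiting confirmation-bias
  accumulation across iterations.
* **Model selection by validation accuracy.** The loop runs up to
  `max_iterations` (default 4) and optionally stops when validation
  accuracy declines; the returned model is the iteration with the best
  validation accuracy. Test data is never consulted for any selection.
* **Full weight for pseudo-labels.** Accepted pseudo-labeled samples get
  the same class weight as true labels (class weights are recomputed on the
  union); a multiplier is exposed (`TrainConfig.pseudo_label_weight`) for
  down-weighting experiments.

## Training protocol

All backbones train under one protocol: Adam (initial learning rate 1e-3),
batch size 64, weighted categorical cross-entropy normalized by the batch
weight sum (so scaling all sample weights is a no-op, which a test
asserts), up to 100 epochs. Validation loss drives both schedules:
reduction of the learning rate by a factor of 0.1 after 10 epochs without
an improvement of at least `min_delta = 1e-4`, and early stopping after 15
such epochs. Checkpointing tracks any strict improvement, so the restored
parameters attain the exact minimum validation loss even when late
improvements are smaller than `min_delta`.

The reference backbone (`small_mlp`) mean-pools the standardized image to a
16×16 grid and applies one 48-unit ReLU layer and a 3-way softmax (~12k
parameters), implemented directly in numpy. This keeps a full multi-seed
sweep on one CPU in minutes while leaving the classifier contract
(`fit` / `predict_proba` / `clone_untrained`, registered by name) open for
convolutional backbones.

## Experimental design

Cohorts are split **patient-wise**: patients are shuffled by seed, ordered
largest-first by image count, and assigned greedily to the split with the
largest remaining image deficit. The assignment is a pure function of
(cohort, fractions, seed), so the test set is constant across every cell of
an experiment. Label-fraction subsetting operates on **whole volumes** — a
clinician labels a scan volume, and volume-level selection keeps
near-duplicate adjacent B-scans on one side of the labeled/unlabeled
boundary. Volumes enter the labeled pool in a seed-fixed, class-stratified
priority order and the pool is the minimal prefix reaching the target image
count; because the order does not depend on the fraction, the 5% pool is
nested inside the 20% pool and so on, making the label-fraction sweep
monotone in information. Class imbalance is handled by inverse-frequency
loss weights `w_c = N/(3 N_c)` (a class with no labeled examples gets
weight 0 plus a recorded warning) rather than oversampling, because
weighting composes cleanly with pseudo-labeled unions.

The experiment runner replays the study design per replicate seed: one
patient-wise split per seed, SL (supervised-only) cells across label
fractions, TS as the single-iteration special case of ITS, and ITS across
confidence thresholds, with a single root seed split into named substreams
(cohort, split, subset, per-cell training) so no two consumers share a
random stream.

## Phantom cohorts

The generator emulates the structure of a clinical AMD OCT archive:
volume-level labels with proportions (0.51, 0.30, 0.19) over
(normal, drusen, cnv), 28–32 B-scans per volume, and a quarter of patients
contributing a second, independently labeled volume (both eyes scanned) —
which is what makes patient-wise splitting strictly stronger than
volume-wise.

A phantom B-scan is a dark background plus three smooth bright horizontal
bands; the lowest, brightest band carries the pathology. Drusen adds 1–5
small dome deflections of that band (heights 0.025–0.085 of image height);
CNV locally attenuates and lifts the band and adds one large bright blob
beneath it. Nuisance variation acts at two scales: per volume (vertical
shift ±0.05, brightness ±15%, thickness ±10%) and per image (small shift
and gain jitter), all column-invariant so that a noise-free normal scan has
identical pixel columns. Pixel noise is Gaussian (default sd 0.05 in [0,1]
intensity units). The nuisance ranges are the difficulty dial of the
benchmark: a handful of labeled volumes cannot cover the nuisance
distribution, so supervised accuracy degrades as the labeled fraction
shrinks — the regime self-training targets — while the task stays learnable
from the full training set. Two hand statistics (band-profile deviation
energy and sub-band brightness) separate the classes with ≥90% accuracy at
the default noise, which pins the intended difficulty independently of any
learned model.

What the phantoms do **not** emulate: OCT speckle statistics, curvature and
layer anatomy, scanner and site effects, segmentation artifacts, or
ambiguous intermediate pathology. Passing tests therefore demonstrate that
the *machinery* (splitting, filtering, iteration, selection, metrics) is
correct and that the method's qualitative behavior (accuracy degradation
with label scarcity, purity/threshold trade-off, gains from iterating)
reproduces on a controlled task — not that any particular accuracy carries
over to clinical data.

## Preprocessing and augmentation

Images are bilinearly resized and standardized per image to zero mean and
unit variance (a constant image maps to zeros with a warning). The
augmentation chain is crop → horizontal flip → rotation → affine
translate + shear, with reflect padding so border artifacts cannot leak
augmentation state as a feature; magnitudes default to small values
(crop scale 0.85–1.0, ±15° rotation, ±10% translation, ±10° shear) chosen
to preserve the class-defining band geometry. Augmentation applies only to
training batches, and the preprocessing pipeline records an audit log that
tests check to rule out augmented validation or test data. Augmentation is
materialized in a single stochastic pass when the training tensor is built
rather than re-drawn every epoch — at phantom scale the task does not need
per-epoch augmentation, and one pass keeps multi-seed sweeps fast; the
experiment defaults leave it disabled, and the `--no-augment` flag /
`augment:` config section control it explicitly.

## Evaluation conventions

Confusion matrices are 3×3 with true classes on rows in the fixed order
(normal, drusen, cnv). Precision/recall/F1 use the zero-denominator = 0
convention with a warning; macro averages are unweighted over the three
classes and support-weighted averages are reported alongside, since a
single printed "precision" is ambiguous on imbalanced classes. ROC curves
are one-vs-rest threshold sweeps with tied scores grouped into one
operating point; the micro curve pools all (record, class) binary
decisions. The macro *curve* averages the per-class upper envelopes on the
union of all breakpoints (exact piecewise-linear averaging, no
interpolation grid); the macro *AUC* is the unweighted mean of per-class
AUCs, the convention consistent with the pairwise Mann–Whitney definition
of AUC (the trapezoid of the averaged curve can differ slightly through
vertical tie segments, and the mean-of-AUCs reading keeps the number
cross-checkable against the pairwise oracle).

## Problem sizes and numerical choices

Study-scale runs (test suite and acceptance script) use 150-patient
phantom cohorts (~5,500 B-scans at 64×64), split 0.64/0.17/0.19, five
replicate seeds, label fractions {1.0, 0.7, 0.5, 0.2, 0.05} and thresholds
{0, 0.90, 0.95, 0.99} — sizes chosen so a complete sweep runs in minutes on
one CPU while keeping ≥1,000 test images per seed. Degenerate inputs are
handled explicitly: empty unlabeled pools degrade to a supervised run with
a warning; probability ties break toward the earlier class in the fixed
order; single-class evaluation sets omit undefined ROC curves with a
warning.

## Known limitations

* The reference backbone is a small MLP; absolute accuracies on phantoms
  say nothing about deep-CNN performance on clinical OCT.
* The self-training gain at very low label fractions (5%) has high
  replicate variance — individual seeds can show losses even when the mean
  gain is positive — mirroring the instability of teachers trained on a
  handful of volumes.
* Per-image (not dataset-level) standardization was chosen for robustness
  as the labeled pool changes across iterations; it discards absolute
  intensity information.
* The stopping rule compares successive validation accuracies only; a
  patience-based rule might squeeze out more iterations on noisy
  validation sets.
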