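# Methods

This note documents the models implemented in `patientrep`, the synthetic
study conditions, and every numerical choice a maintainer might question.

## 1. Raw representation

The pipeline's input is a sparse non-negative patient × descriptor count
matrix: entry (p, d) counts occurrences of normalized clinical code d in
patient p's record before the split-point. Two preprocessing steps produce
the "raw" representation used by every learner:

* **Prevalence filter.** A descriptor is kept iff it appears in at least
  `min_patients` (default 5) patients and in at most `max_prevalence`
  (default 0.8) of them. Near-universal codes carry no contrast;
  ultra-rare ones are noise. Both bounds are inclusive ("more than 80%"
  removes, exactly 80% stays). The filter is fit on the feature-learning
  training patients only and frozen for all held-out patients, and it is
  idempotent by construction.
* **Zero-preserving scaling.** Each retained column is divided by its
  training-set maximum, mapping counts into [0, 1] while keeping zeros
  exactly zero (a generic `(x − min)/(max − min)` would destroy sparsity;
  with counts the minimum is 0, so division by the max is the only min-max
  variant that preserves zero entries). Held-out values above the training
  maximum clip to 1. Counts are used as occurrence frequencies, not
  binarized; a `binary_counts` flag flips that reading.
* **Topic columns** (per-patient means of per-note topic multinomials, when
  present) are already dense values in [0, 1]; they bypass both steps and
  are appended after the descriptor block.

## 2. Stacked denoising autoencoders

One layer is parameterised by θ = {W, b} and θ′ = {Wᵀ, b′} (tied weights —
no separate decoder matrix is ever stored):

    encoder  y = σ(W x̃ + b)          W ∈ R^{h×d}
    decoder  z = σ(Wᵀ y + b′)

`x̃` is the corrupted input: masking noise zeroes exactly `round(ν·d)`
coordinates, sampled uniformly without replacement, independently per
example per epoch (an i.i.d.-Bernoulli masking mode is available behind the
`masking="bernoulli"` flag). The loss is the reconstruction cross-entropy
L_H(x, z) against the **clean** x, so masked coordinates must be inferred
from the surviving ones. Internally the loss and its gradient are computed
from the decoder pre-activation (`softplus(a) − x·a`), which is finite even
for saturated units; the public `cross_entropy` enforces z strictly inside
(0, 1).

Training is plain mini-batch SGD with per-epoch row shuffling; the gradient
of the tied weight is the sum of the encoder-path and decoder-path partials
(verified against central finite differences and against an untied
two-matrix oracle in the tests). Stacking is greedy: layer k trains, with
its own corruption, on the *clean* codes of layer k − 1; all layers share
one hyperparameter set. The final transform composes the encoders; no
supervised fine-tuning is applied.

Numerical choices (the class defaults):

| parameter | default | rationale |
| --- | --- | --- |
| layers × units | 3 × 500 | the reference deep architecture for this method |
| ν (masking fraction) | 0.05 | conventional light corruption; tune per dataset |
| learning rate | 0.1 | standard for sigmoid autoencoders at this scale |
| batch size | 32 | standard |
| epochs | 30 | enough for the loss plateau on mid-sized matrices |
| init | W ~ U(±4·√(6/(d_in+h))), biases 0 | the classical sigmoid heuristic |

The **experiment roster** (`pipeline.default_representations`) deviates
deliberately: on the 300-descriptor synthetic cohort it uses 3 × 400 units,
ν = 0.3 and 100 epochs, selected by validation-style runs at this scale
(heavier corruption forces the fill-in behaviour that sharpens the codes;
more epochs offset the smaller data). Per-layer, per-epoch mean training
losses are recorded in `loss_traces_`; there is no early stopping.

## 3. Shallow baselines

All baselines are fit on the same scaled feature-learning matrix and frozen:

* `rawfeat` — identity; the filtered scaled matrix itself.
* `pca` / `ica` — component scores (conventional default 100 components
  each; ICA is FastICA with PCA whitening).
* `kmeans` — Euclidean distance to each of (default) 500 centroids; the
  argmin over features is the cluster assignment.
* `gmm` — posterior responsibilities of (default) 200 full-covariance
  mixture components, with 1e-6 added to covariance diagonals (full
  covariances on sparse [0, 1] data are otherwise singular). Responsibilities
  are the standard probabilistic analogue of cluster-distance features;
  per-component log-likelihoods are available via `feature_mode="loglik"`.

The experiment roster scales the component counts to the synthetic cohort
(pca/ica 50, kmeans 100, gmm 10): the conventional defaults presume tens of
thousands of descriptors, and full-covariance mixtures with hundreds of
components are unidentifiable from ~1200 × 300 data.

## 4. Disease prediction and evaluation

One random forest (default 100 trees, other hyperparameters at library
defaults and recorded in the run manifest) is fit per disease on the
classifier-training patients — one-vs-all, negatives are all patients
without a novel in-window diagnosis of that disease (a flag excludes
patients with a prior diagnosis from training instead). Forest seeds are
derived from the disease identifier, so removing one disease never perturbs
another's scores.

Labels mark **novel** diagnoses only: disease d, patient p, window w is
positive iff d is first diagnosed at day offset in [1, w] and d is absent
from p's pre-split history. Prior diagnoses are masked in the score matrix
and excluded from every metric, including each disease's evaluation
population. Windowed labels are nested by construction.

Metrics:

* **AUC-ROC** in the Mann–Whitney form (ties get half credit; a constant
  score vector scores exactly 0.5).
* **Accuracy / F-score** at a probability threshold of 0.6, inclusive
  (score = 0.6 counts positive; exact-threshold scores are measure-zero and
  one convention for both classification and tagging is cleaner). F is 0
  when precision + recall is 0.
* **Prec@k** (k = 1, 3, 5): per patient, the fraction of the k top-ranked
  tags (unmasked scores above the threshold; ties broken by ascending
  disease index) that are true; the denominator stays k even when fewer
  candidates clear the threshold. Patients are evaluated in a window iff
  they have ≥ 1 true novel diagnosis in it.
* **R-precision**: precision over the top R tags, R = the patient's number
  of true in-window diagnoses. By default sub-threshold predictions do not
  occupy ranks (they were never asserted as tags); a flag restores them.
* **UppBnd**: the perfect tagger's score, min(R, k)/k per patient — the
  ceiling for any Prec@k.

Summary rows are macro averages (unweighted over diseases), matching the
way mean AUC is usually quoted for this benchmark; micro-averaging (pooling
all unmasked patient × disease cells) is available via `average="micro"`.
Diseases whose evaluable population lacks one of the two classes are
reported in a warnings list and excluded from the macro mean.

## 5. The synthetic cohort

The generator emulates the structure of a de-identified clinical warehouse
at desk scale (defaults: 2000 patients, 300 descriptors, 20 diseases,
12 latent conditions, windows 30/60/90/180 days):

* **Latents.** Each patient carries i.i.d. Bernoulli(0.4) binary conditions.
* **Counts.** Descriptor d has a skewed baseline rate (gamma(0.5) weights
  normalised to `mean_records` = 150 expected records per patient). Each
  latent selects half the vocabulary as markers and multiplies their rates
  by e^a with a ~ U(0.3, 0.7) on half of them and a ~ U(−0.7, −0.3) on the
  other half: conditions elevate some codes and *suppress* others (displaced
  routine care). Counts are Poisson given the latents. Three consequences
  are intentional: descriptors are individually weak, signed mixtures of
  several latents (no single code identifies a condition); recovering a
  condition requires cross-descriptor contrasts; and record volume varies
  through latent burden, not through an independent nuisance factor.
* **Histories.** Each (patient, disease) pair has a pre-split diagnosis with
  probability 0.08, dated uniformly in [−730, −1] — these create the
  re-diagnosis cases the evaluation must discard.
* **Future labels.** Disease base rates are U(0.08, 0.18). For main-effect
  diseases the log-odds add s/2·(h_a + h_b) for two random latents
  (s = `signal_strength` = 3); for the `interaction_frac` (default half) of
  diseases they add s·XOR(h_a, h_b) = s·(h_a + h_b − 2·h_a·h_b) — a
  non-monotone pairwise interaction that no linear function of the latents
  captures. Events are dated uniformly inside the largest window, so
  smaller windows are prefixes and windowed labels nest. With s = 0 the
  labels are independent noise and every representation must score at
  chance.
* **Time** is integer day offsets from the split-point (history < 0,
  future ≥ 1); no calendar arithmetic anywhere.
* Ground-truth latents are stored on the cohort object for tests but are
  never read by the pipeline.

Default split of the 2000 patients: ~1200 feature-learning, 400 classifier
training, 100 validation, 300 test (test and validation require ≥ 10
pre-split records and ≥ 1 future diagnosis; training sets require ≥ 5
records). A hold-back design (`n_test=None`) that keeps every eligible
patient for testing is available but starves feature learning at this scale.

**What the generator does not emulate:** real coding vocabularies and their
hierarchy, free-text notes, calendar seasonality, care-pathway dynamics
(counts are conditionally independent Poisson given the latents), informative
censoring, and the extreme dimensionality of a production warehouse (tens of
thousands of descriptors at ~1% density — here the same sparse-redundant
structure is compressed into 300 columns at ~35% density). Passing the
pipeline's tests therefore demonstrates correctness of the machinery and the
*qualitative* behaviour of representation learning under sparse redundant
noise — not clinical-scale effect sizes.

## 6. Orchestration and reproducibility

`run_experiment` derives one independent sub-seed per stage (cohort, split,
representations, classifier) from the global seed via seed-sequence
spawning; each representation's seed additionally hashes its name, and each
disease's forest seed hashes the disease id. The classifier seed is shared
across representations so the comparison isolates the representation. With
an `output_dir`, per-representation reports are cached keyed by a hash of
the resolved configuration, making interrupted runs resumable; the manifest
records the resolved configuration, all stage seeds and split sizes.

## 7. Known limitations

* The SDA is trained with dense matrix algebra; cohorts far beyond ~10⁵ × 10³
  would need mini-batch streaming from sparse storage.
* Greedy unsupervised stacking loses a little task-relevant information per
  layer (no supervised fine-tuning, by design); on linearly-separable
  cohorts (`interaction_frac = 0`) PCA is nearly as good, as expected.
* Forest probabilities are uncalibrated; the 0.6 tagging threshold is a
  convention, not an optimum, and its validation-based tuning is out of
  scope.
* The GMM baseline is close to chance on the default cohort: 10 full-
  covariance components cannot represent 2¹² latent configurations, and its
  responsibilities collapse. It is kept for completeness of the comparison.
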