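# Methods

`neurossl` implements a two-stage representation-learning procedure for
multi-site, longitudinal, two-modality (MRI-like and PET-like) neuroimaging
cohorts, together with the harmonization pipeline, the evaluation battery,
and a synthetic cohort generator that makes every stage verifiable against
known ground truth. This note describes the models, the defaults and why
they are what they are, and what the synthetic experiments do and do not
demonstrate.

## Problem setting

A cohort contains subjects p with visits t. At each visit there is a
co-registered 3D MRI-like volume, optionally a PET-like volume, clinical
covariates (age, sex), a diagnosis label y ∈ {CN, MCI, AD}, a site/scanner
id s, and per-subject survival outcomes (T, δ) for time to conversion.
Modality-specific encoders f^MRI, f^PET with a projection head g map a
volume x to an ℓ2-normalized embedding z = g(f(x)) / ‖g(f(x))‖₂ ∈ R^d.
All splits are at the subject level, so no visit of a subject ever crosses
a fold boundary.

## Stage 1 — self-supervised pretraining

Six objectives, combined as a non-negatively weighted sum
L = λ₁L_intra + λ₂L_cross + λ₃L_byol + λ₄L_long + λ₅L_long_x + λ₆L_site:

* **Intra-modal InfoNCE** over two augmented views of the same scan.
  Each anchor's candidate set is the positive batch plus an optional FIFO
  momentum queue; with C candidates and all similarities equal the loss is
  exactly ln C, which the tests exploit as a closed form.
* **Cross-modal InfoNCE**, symmetric over MRI→PET and PET→MRI directions,
  over (subject, visit)-matched pairs. In the training loop the cross term
  uses in-batch negatives only: stale queue keys from the other modality
  measurably destabilize the pairing task at small batch counts.
* **Longitudinal consistency**: squared embedding distance over a subject's
  unordered visit pairs within modality, and a cross-time cross-modal
  variant coupling MRI at one visit to PET at another. Both terms
  auto-disable (and report exactly zero) when no subject has two visits.
* **BYOL regression**: a predictor maps the online embedding onto a
  stop-gradient momentum target; the target branch provably receives zero
  gradient (finite-difference tested).
* **Site adversary**: a softmax site classifier on the embeddings behind a
  gradient-reversal layer (GRL). Forward it is the identity; backward the
  encoder receives the classification gradient negated and scaled.

Temperature defaults to τ = 0.1 (the interior of the usual 0.05–0.2 band).
The backbone is a small 3D residual CNN (stem conv, one residual block +
2× average pooling per stage, GroupNorm by default or domain-specific
batch norm, global average pooling, Norm–ReLU–Linear projection head).
Defaults: stage widths (16, 32, 64), d = 32; the experiments below use
narrower variants, chosen so a full cycle runs in minutes on one CPU core.

### Desk-scale training choices

Three choices matter at this scale and are worth recording:

1. **Input normalization.** Brain volumes are dominated by a shared
   anatomical pattern; without correction, per-sample normalization inside
   the network maps every scan to nearly the same embedding and contrastive
   learning cannot escape the collapsed state. The encoders therefore carry
   a per-modality mean volume and a global rescaling fitted on the training
   set, applied before the first convolution.
2. **Adversary schedule.** The site discriminator has its own optimizer
   (3× the encoder learning rate, five refresh steps per batch, weight
   decay 1.0) and standardizes its input per batch. A lagging adversary
   lets the encoder *invert* rather than remove site information; a
   saturated one emits vanishing gradients. A frequently refreshed,
   bounded-confidence discriminator produces the persistent removal
   gradient that makes adversarial invariance work at a few hundred
   optimization steps.
3. **Augmentation strength.** At 16³ voxels, aggressive flips and blur
   destroy the instance identity the contrastive task depends on. The
   default policy is conservative: no flips, rotations ≤ 5°, blur σ ≤ 0.3,
   ±10% intensity jitter; crops are available but off by default.

Optimization is AdamW (lr 2·10⁻³ pretraining, 3·10⁻⁴ fine-tuning backbone
with 10× faster heads, weight decay 10⁻⁴) under a cosine schedule, with a
momentum (0.9) key encoder feeding the queue and the BYOL targets.
Batches are drawn subject-wise and interleaved across sites so the
discriminator always sees within-batch site contrast.

## Stage 2 — multi-task fine-tuning

The fused representation is e = [α·z_MRI ‖ (1−α)·z_PET ‖ c] with a learned
availability gate α = σ(wᵀ[1_MRI, 1_PET] + b); an absent modality's block
is exactly the zero vector, so e has fixed length 2d + q and inference
degrades gracefully to MRI-only input. Heads and objectives:

* class-weighted cross-entropy for diagnosis (weights are inverse class
  frequencies on the training fold, normalized to mean 1);
* Cox partial likelihood on a linear risk head over baseline-visit fused
  representations, Breslow handling of tied event times, censored subjects
  entering risk sets only; per-batch the loss is normalized by the event
  count so its gradient scale is batch-size invariant;
* PET→MRI distillation: mean of 1_PET·‖z^MRI − sg(z^PET)‖² over the batch.
  Distillation engages after a configurable warm-up fraction of the epochs
  (`distill_warmup`); distilling against an untrained PET pathway
  measurably degrades the classifier, while a warmed-up teacher transfers
  its severity ordering into the MRI pathway;
* joint objective a·L_diag + b·L_cox + g·L_distill with defaults
  (1, 1, 0.5) and the experiments using g = 0.1.

Early stopping monitors validation balanced accuracy with patience 10;
on validation ties the kept checkpoint is refreshed, so a flat validation
curve does not silently restore the first epoch. After training, a scalar
temperature T is fitted on held-out validation logits by bounded
one-dimensional NLL minimization over log T ∈ [ln 0.05, ln 20]; scaling by
T is monotone, so argmax predictions (and balanced accuracy) are invariant
while calibration error can improve.

## Harmonization

Fixed order: per-volume z-score (MRI) / SUVR scaling by a reference-region
mean (PET) → histogram matching → ComBat. Histogram matching uses 101
quantile knots and monotone piecewise-linear transfer with tails clamped
to the template extremes, so within-volume voxel ranking is preserved.
ComBat is the canonical parametric empirical-Bayes location/scale model:
feature-wise site means shrink toward a normal prior and site variances
toward an inverse-gamma prior (method-of-moments hyperparameters, iterated
conditional modes), with age and sex protected as biological covariates.
The implementation reproduces R's `sva::ComBat` to ~10⁻⁶ on shared inputs
(cross-checked in the test suite). A model fitted on a single site applies
as the identity. All fitted transforms are visit-independent, and every
fitted object records the subjects it saw so leakage can be audited.

## Evaluation battery

Balanced accuracy (macro recall), F1, Mann–Whitney AUC with ties counted
½, sensitivity at fixed specificity, Harrell's C-index (risk ties ½, tied
event times excluded), IPCW Brier curves and the normalized integrated
Brier score (censoring weights from the Kaplan–Meier estimator of the
censoring distribution, left limits at event times), cumulative/dynamic
time-dependent AUC with the same weights, expected calibration error with
equal-mass bins (remainders to the lowest-confidence bins), ICC(3,1) from
two-way mixed-model mean squares, within-subject CV, the standardized
response mean, subject-level percentile bootstrap intervals, and DeLong's
paired AUC test from placement values. Each estimator is verified against
a brute-force oracle at small n and, where available, against
scikit-survival / lifelines / pingouin / scikit-learn.

## Synthetic cohort generator

The generator emulates exactly the cohort structure the method assumes —
and is the ground-truth oracle for every functional test:

* latent severity per subject from a CN/MCI/AD mixture (means 0.15 / 0.45
  / 0.75, sd 0.08), progressing linearly with a strictly positive
  gamma-distributed slope (mean 0.006/month); diagnosis labels by fixed
  thresholds (0.30, 0.60) on current severity;
* ellipsoidal "brain" with a fixed cortical texture (amplitude 25), a
  per-subject smooth anatomical field (sd 12) shared across modalities and
  visits (co-registration by construction), and an interior target region
  whose mean intensity falls with severity for MRI (slope 40/severity
  unit) and rises for PET (slope 50); texture contrast additionally fades
  with severity (40% at severity 1), a global gray/white-contrast
  signature that survives pooling and intensity normalization;
* per-site affine intensity effects (site s: scale `site_scale`^s, shift
  `site_shift`·s inside the mask), per-scan multiplicative gain jitter
  (lognormal, sd 5%) emulating scanner drift, and i.i.d. Gaussian voxel
  noise (sd 2);
* conversion times by inverse-transform sampling from an exponential
  proportional-hazards model with log hazard linear in baseline severity
  (baseline 0.01/month, log ratio 2), administratively censored at 48
  months; PET availability per visit is Bernoulli.

What the generator does **not** emulate: real neuroanatomy, lesions,
scanner physics, registration error, or any spatial correlation structure
beyond the smooth anatomy field. Passing the functional tests therefore
shows that the algorithms behave as designed under their own assumptions —
not that the method reaches any particular accuracy on clinical data.

## Experiment sizes

The functional experiments are sized for a single CPU core: the
site-invariance and alignment experiments use 200 subjects at 16³ voxels
(5 and 10 epochs respectively; arms within an experiment differ only in
the ablated weight); the distillation comparison uses 120 subjects with
50% PET missingness in a regime where PET is the stronger early biomarker
(MRI atrophy slope 15, PET uptake slope 60, anatomy sd 4 — the
amyloid-PET scenario distillation is designed for); the leakage audit runs
a full 5-fold pipeline on 40 subjects; the Cox-recovery experiment trains
a linear risk head on 500 severity-derived embeddings with hazard log
ratio 4. Larger cohorts and deeper backbones are config knobs, not code
changes.

## Known limitations

* The engine is pure NumPy; it is exact but not fast — paper-scale
  backbones (3D ResNet-50, Swin) are out of reach and out of scope.
* Voxel-wise ComBat assumes a shared brain mask, which the generator
  guarantees but real data would not without registration.
* The momentum queue helps the intra-modal term yet destabilizes the
  cross-modal term at desk scale; the loop therefore restricts queue
  negatives to the intra-modal loss.
* Directional comparisons (e.g., distillation vs none) are single-seed at
  fixed conditions; they demonstrate the mechanism, not an effect size.
* The adversarial equilibrium is delicate at a few hundred optimization
  steps: whether the encoder fully sheds the site signal depends on the
  initialization seed and the discriminator schedule. The packaged
  experiments use a configuration verified to reach invariance; other
  seeds can leave residual linearly decodable site information, which the
  acceptance script reports as measured.
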