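# Methods

## The model

`coxfuse` trains neural survival models whose output layer is the negative
log Cox partial likelihood,

    L(θ) = − Σ_{i : C_i = 1} [ f_θ(X_i) − log Σ_{j : Y_j ≥ Y_i} exp f_θ(X_j) ],

with `Y_i` the follow-up time, `C_i` the event indicator (1 = death
observed) and `f_θ(X_i)` the scalar log-risk produced by a network. The
partial likelihood eliminates the baseline hazard, so the network learns
only *relative* risk. Two consequences shape the implementation:

* **Shift invariance.** Adding any constant to all scores leaves the loss
  unchanged; risk scores are therefore only comparable within a model, and
  all downstream metrics are rank- or baseline-anchored.
* **Batch risk sets.** The inner sum runs over the risk set
  `{j : Y_j ≥ Y_i}` *within the current mini-batch* rather than the whole
  cohort. With reasonably large batches (default 128 elements) this
  stochastic approximation is standard practice for deep Cox models. A
  batch that happens to contain no events contributes zero loss and zero
  gradient (with a warning) so stochastic batching never aborts a run.

Ties in event time follow the Breslow convention: the risk set at `Y_i`
includes every subject with `Y_j ≥ Y_i`, ties included. The log-sum-exp is
computed with max-score subtraction, keeping the loss finite for scores at
least up to ±50.

## Branches and fusion

Each modality has its own feature extractor feeding a linear Cox head:

* **Image branch** — patch-based: every patch of a patient is scored, and
  the patient risk is the mean patch risk (risks at evaluation, features
  when a patient-level vector is needed). The backbone is pluggable; the
  built-in desk-scale backbone is a two-stage strided convolutional network
  (4×4 kernels, stride 4, channels 8→16) with a dense projection to 32
  features, chosen so the whole framework trains on one CPU in seconds.
  The full-scale configuration of the contract is a deep residual network
  with 2048-dim penultimate features in which only the terminal block is
  fine-tuned; `trainable_depth` expresses exactly that freezing pattern
  (0 = encoder fully frozen, only the Cox head trains).
* **Expression branch** — an MLP with ReLU activations and dropout 0.5
  before each layer. Full-scale preset `[n_genes, 4096, 2048]`; desk-scale
  default `[n_genes, 64, 32]`.

Three fusion strategies combine the branches:

* **Early (feature) fusion** — patient-level image features (patch mean)
  are concatenated with expression features, image first, and a fresh Cox
  MLP is trained on the merged vector while both encoders stay frozen. The
  full-scale head is `[4096, 2048, 200, 1]` with dropout 0.5; the
  desk-scale default is the minimal Cox module `[64, 1]` (dropout 0.5
  before the layer). With only a few hundred training patients a deeper
  desk-scale head consistently overfits the 64-dim fused features, while
  the regularized linear head preserves the fused ranking; the full-scale
  head dims remain available as a config preset.
* **Late (score) fusion** — the two unimodal patient risks are merged by a
  linear two-coefficient Cox model fitted on the score pairs by maximum
  partial likelihood (L-BFGS on the package's own loss and gradient).
* **Joint fusion** — both branches train simultaneously. A training
  example is one sampled patch paired with its patient's full expression
  profile, so the 128-element patch-batch convention applies unchanged.
  The concatenated features feed a single fused Cox head with heavy
  dropout (0.8) on the final layer, and one Cox loss backpropagates into
  both branches with per-branch learning rates.

Per-branch learning rates keep a fixed ordering — image branch faster
than expression branch, head fastest — because the image signal is
patch-based and dilute while one expression vector maps directly to one
patient. Desk-scale defaults are image 2e-3, expression 5e-4, head 1e-2
(ratio 4:1; at full scale a much steeper ratio such as 50:1 is
appropriate, but with the tiny desk-scale expression MLP it leaves that
branch underfitted within the short training budget).

## Training protocol

Cohorts are shuffled into an 80/20 train/test split stratified on a
composite label built from age, gender, tumor grade and survival time;
continuous variables are binned into tertiles. Strata too fine for the
cohort size are coarsened by merging the smallest stratum into the largest
until the split is feasible. Stratified k-fold cross-validation (default
k = 3 at desk scale; 10 and 5 are the full-scale presets) runs inside the
training pool. Within each training run the weights of the epoch with the
highest validation concordance index are kept ("validation accuracy" is
undefined for a ranking objective; the concordance index is its natural
counterpart). Across folds the configuration with the lowest validation
loss is selected and evaluated once on the held-out test set. A leakage
assertion verifies on every run that no test identifier reaches a training
or validation batch.

The per-slide patch sample (default 100, configurable over
{1, 10, 100, 500, 1000, 2000}) is drawn once per experiment and recorded,
not re-drawn per epoch — simpler to reproduce bit-for-bit.

Optimization is Adam throughout. All randomness (init, dropout, batch
order, sampling) flows from explicit seeded generators; identical seeds
give bit-identical histories.

## Evaluation

* **Concordance index** — admissible pairs are (i, j) with `Y_i < Y_j` and
  `C_i = 1`, plus time-tied pairs in which both events were observed.
  Concordant means the shorter-lived patient has the higher risk; tied
  scores count 0.5 (Harrell's convention).
* **Brier score / IBS** — the Graf inverse-probability-of-censoring
  weighted form with a Kaplan–Meier censoring curve `G`: events before `t`
  contribute `Ŝ_i(t)² / G(T_i⁻)`, patients still at risk contribute
  `(1 − Ŝ_i(t))² / G(t)`, patients censored before `t` contribute 0. The
  IBS is the trapezoidal integral over `{0} ∪ {unique observed times}`
  normalized by the last observed time. Per-patient survival functions are
  obtained from scalar risks through a Breslow baseline cumulative hazard
  estimated on training data with training-mean score centering:
  `Ŝ_i(t) = exp(−H₀(t) · e^{f_i − f̄})`.
* **Composite Score** — `CS = (CI + (1 − IBS)) / 2`, one number combining
  a ranking metric with an absolute calibration error.
* **Kaplan–Meier / log-rank** — test cohorts are split at the median
  predicted risk (scores exactly at the median go to the good-survival
  group); product-limit curves for the two groups are plotted in one
  figure per model, and a two-group log-rank test (1 df) quantifies the
  separation. Both estimators are delegated to lifelines.

Transfer evaluation is pure inference: a fitted model scores a new cohort
with no parameter updates. Expression inputs are aligned by gene
intersection in the model's gene order with zero fill for missing genes;
an overlap below 50% is a hard error rather than silent degradation.

## Interpretability

Predicted risks are backpropagated to the model inputs. Per-gene gradients
(with respect to the *normalized* expression values — the model's actual
inputs) preserve sign: negative pushes the risk down. Pathway importance
is the unweighted mean gradient over a gene set's measured members
(gene sets from GMT files; genes in several sets contribute to each; sets
with no measured gene are dropped with a warning), and pathways are ranked
by the sum of absolute gradients across samples with a deterministic
name tie-break. Pixel saliency is the channel-max of absolute risk
gradients per pixel, min-max scaled, overlaid at alpha 0.5. Cell-type
fractions from an external segmenter are compared between risk groups with
a pooled-variance Student's t test by default (df = n₁ + n₂ − 2, matching
the usual reporting convention), Welch and Benjamini–Hochberg options off
by default; pathway rankings carry no multiplicity correction because they
are descriptive.

## Synthetic cohorts

The generator plants two independent standard-normal latent factors per
patient. The true log-hazard is `β_img·z_img + β_expr·z_expr`; event times
are exponential with rate `baseline_rate · e^{log-hazard}`, and censoring
times are independent exponentials whose rate is calibrated numerically
(Brent root-finding on the expected censored fraction) to hit the target
censoring rate. Exponential families were chosen for this closed-form
calibration; nothing downstream depends on the distributional family.

`z_expr` is expressed in a module of correlated genes on a count-like
scale (`2^(5 + z_expr + noise)`), so the standard log2(x+1)/z-score
pipeline recovers it; background genes are pure noise. `z_img` is
expressed as image texture: the density of dark, nucleus-like blobs on an
eosin-pink background rises monotonically (through a sigmoid) with
`z_img`, a signal a small CNN can learn at 64×64. Pixel noise and module
noise are configurable.

Defaults are the package's study conditions: 300 patients, 8 patches per
patient at 64 px, 200 genes with a 20-gene module, both effect sizes 1.0,
noise 0.05 (image) / 0.3 (expression), 20% censoring. Under these
conditions the true log-hazard reaches a concordance of about 0.80 and
each single latent factor about 0.71 — the headroom between a single
modality and the oracle is exactly what fusion is supposed to recover.

The generator returns a *public* cohort and a *truth* sidecar; training
entry points accept only the public view, and the planted log-hazard is
available solely through `oracle_risk` for upper-bound benchmarking (it
raises on a truth-stripped cohort).

What the generator does **not** emulate: realistic histology morphology,
batch effects and platform mixing, non-proportional hazards, informative
censoring, and correlation between the two latent factors. Passing tests
therefore demonstrate that the machinery learns and combines planted
multimodal signal under right censoring — not that it reproduces results
on real tumor cohorts.

## Verification problem sizes

The heavier checks run at deliberately chosen desk scales: the fusion
benchmark uses the default study conditions over 5 seeds with a single
stratified 80/20 split per seed (seed-mean comparisons; per-seed test
concordances on 60 held-out patients carry sampling noise of about 0.04,
which seed means reduce below the comparison tolerances). The no-signal
check uses 10 null cohorts of 500 patients with a 40% test split, making
the [0.4, 0.6] chance band a > 4 σ bound for an uninformative model.
Transfer stability uses expression-only models over 5 seed pairs. The
analytic metric values (perfect/independent concordance, indicator IBS,
Composite Score) are exact and independent of scale.

## Known limitations

* The built-in backbone is intentionally tiny; plugging in a pretrained
  deep residual network is supported by the encoder contract but no
  pretrained weights ship with the package.
* The Breslow survival-curve construction assumes proportional hazards of
  the learned score; badly miscalibrated scores affect IBS more than CI.
* Joint fusion at desk scale is sensitive to the per-branch learning-rate
  ratio; the defaults were chosen for the desk-scale architecture and will
  need re-tuning for larger backbones.
* WSI pyramid handling is delegated to pluggable readers; the built-in
  reader treats plain rasters as already being at extraction resolution.
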