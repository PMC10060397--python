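# coxfuse

Multimodal deep survival modelling for tumor prognosis: neural feature
extraction from histopathology patches and gene-expression profiles,
trained end-to-end against a batch-sampled Cox partial-likelihood loss,
with three data-fusion strategies and a full survival-evaluation suite.

## Who this is for

Researchers who want to combine whole-slide histopathology with
transcriptomics to predict right-censored patient survival, compare
unimodal against multimodal models under a controlled protocol, and
inspect *why* a model assigns high or low risk (pathway-level gene
gradients, pixel saliency). A built-in synthetic cohort generator with
planted, tunable risk structure makes every stage testable without any
patient data.

## The model

All models share one output objective, the negative log Cox partial
likelihood over each training batch:

    L(θ) = − Σ_{i : C_i = 1} [ f_θ(X_i) − log Σ_{j : Y_j ≥ Y_i} exp f_θ(X_j) ]

where `Y_i` is follow-up time, `C_i` the event indicator and `f_θ` the
network's scalar log-risk. The risk-set sum runs within the mini-batch
(batch-sampled partial likelihood), ties follow the Breslow convention,
and the baseline hazard is never estimated during training.

Five strategies are built on this loss:

| strategy   | description |
|------------|-------------|
| image      | CNN over 224×224 (desk scale: 64×64) patches; patient risk = mean patch risk |
| expression | MLP over the normalized gene-expression profile |
| early      | concatenated patient-level features → fresh Cox MLP, encoders frozen |
| late       | linear two-coefficient Cox model over the two unimodal risks |
| joint      | both branches trained simultaneously into one fused Cox head, per-branch learning rates |

Evaluation: concordance index (CI), inverse-probability-of-censoring
weighted integrated Brier score (IBS), the Composite Score
`CS = (CI + (1 − IBS)) / 2`, Kaplan–Meier curves of the median-risk split
and the two-group log-rank test. See `docs/methods.md` for conventions
and assumptions.

## Worked example

Simulate a cohort in which image texture and a gene module carry
complementary prognostic signal, then train and evaluate all five
strategies on a stratified 80/20 split:

```python
from coxfuse.synthetic import SyntheticConfig, simulate_cohort
from coxfuse.training import TrainerConfig, benchmark_strategies

cohort = simulate_cohort(SyntheticConfig(seed=1))   # 300 patients, 8 patches,
reports = benchmark_strategies(cohort, TrainerConfig(), seed=1)  # 200 genes
for name, rep in reports.items():
    print(f"{name:10s}  CI={rep.ci:.3f}  IBS={rep.ibs:.3f}  CS={rep.cs:.3f}  "
          f"log-rank p={rep.logrank_p:.2g}")
```

which prints (a few minutes on one CPU):

```
image       CI=0.656  IBS=0.147  CS=0.755  log-rank p=8.7e-05
expression  CI=0.718  IBS=0.102  CS=0.808  log-rank p=8.1e-07
early       CI=0.761  IBS=0.112  CS=0.824  log-rank p=6.8e-06
late        CI=0.753  IBS=0.120  CS=0.816  log-rank p=2.2e-06
joint       CI=0.718  IBS=0.136  CS=0.791  log-rank p=1.1e-06
```

Each line is one model's held-out test performance: CI is the fraction of
correctly risk-ordered patient pairs (0.5 = random), IBS the integrated
squared error of the predicted survival curves (0 = perfect), CS their
combination, and the log-rank p the separation between the two
median-risk Kaplan–Meier groups. On this cohort the generator's true
log-hazard reaches CI ≈ 0.80 and each single latent factor ≈ 0.71; the
fusion models recover part of the gap between the best single modality
and that oracle, which is the package's central claim at desk scale.

The same pipeline is scriptable from the shell:

```sh
coxfuse simulate  --config run.yaml
coxfuse train     --config run.yaml --set train.strategy=joint
coxfuse evaluate  --config run.yaml --set train.strategy=joint
coxfuse transfer  --config run.yaml --set train.strategy=joint
coxfuse interpret --config run.yaml --set train.strategy=joint
```

Every command validates the YAML config up front (unknown keys are
rejected), writes its artifacts under `out_dir`, and appends a manifest
(config hash, seed, timestamps, input checksums) for reproducibility.

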