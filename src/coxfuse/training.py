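"""Cohort splitting, cross-validation, model training and transfer.

The experiment driver trains the five strategies of the framework —
image-only, expression-only, early fusion, late fusion, joint fusion — on a
stratified 80/20 train/test split with stratified k-fold cross-validation
inside the training pool. Stratification combines tertile-binned continuous
variables (age, survival time) with categorical covariates into one
composite label. Within every training run, epoch-level model selection
keeps the weights of the epoch with the highest validation concordance
index; across folds the configuration with the lowest validation loss is
selected and evaluated once on the held-out test set with patient-level
risk averaging.

Transfer evaluation applies a fitted model to a new cohort with no
parameter updates; expression inputs are aligned by gene intersection with
zero fill for missing genes (hard error below 50% overlap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from . import nn
from .encoders import (ExpressionEncoder, ExpressionMLPConfig, ImageEncoder,
                       ImageEncoderConfig, images_to_tensor)
from .expr import log_z_transform
from .fusion import (EarlyFusionModel, ExpressionSurvivalModel, FusionConfig,
                     ImageSurvivalModel, JointFusionModel, LateFusionModel)
from .metrics import (MetricsReport, concordance_index, evaluate_risk_scores)
from .survival import RiskBatch, SurvivalRecord, cox_loss
from .synthetic import SyntheticCohort

__all__ = [
    "FoldPlan",
    "ExperimentResult",
    "TrainerConfig",
    "FittedModel",
    "CohortData",
    "stratified_split",
    "cv_folds",
    "train_model",
    "run_experiment",
    "benchmark_strategies",
    "transfer_evaluate",
    "save_fitted",
    "load_fitted",
    "STRATEGIES",
]

STRATEGIES = ("image", "expression", "early", "late", "joint")
DEFAULT_STRATA = ("age", "gender", "grade", "time")


@dataclass
class FoldPlan:
    test_ids: list[str]
    folds: list[tuple[list[str], list[str]]]  # (train_ids, validation_ids)
    strata_spec: tuple[str, ...]
    seed: int


@dataclass
class ExperimentResult:
    per_fold: dict[str, list[dict]]         # strategy -> fold records
    selected_fold: dict[str, int]
    test_reports: dict[str, MetricsReport]
    config: "TrainerConfig"
    seed: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for strategy in self.per_fold:
            tr = [f["train_report"].cs for f in self.per_fold[strategy]]
            va = [f["val_report"].cs for f in self.per_fold[strategy]]
            rows.append({
                "strategy": strategy,
                "train_cs": f"{np.mean(tr):.3f} ± {np.std(tr):.3f}",
                "val_cs": f"{np.mean(va):.3f} ± {np.std(va):.3f}",
                "test_cs": round(self.test_reports[strategy].cs, 3),
            })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrainerConfig:
    """Desk-scale training settings for the five strategies."""

    image_config: ImageEncoderConfig = ImageEncoderConfig()
    expr_hidden: tuple[int, ...] = (64, 32)
    expr_dropout: float = 0.5
    fusion: FusionConfig = FusionConfig(strategy="joint")
    batch_size: int = 128
    lr_image: float = 2e-3
    lr_expr: float = 2e-3
    epochs_image: int = 15
    epochs_expr: int = 60
    epochs_early: int = 150
    epochs_joint: int = 15
    patches_per_slide: int = 100
    val_fraction: float = 0.15
    k_folds: int = 3
    strata_spec: tuple[str, ...] = DEFAULT_STRATA


@dataclass
class CohortData:
    """Model-facing view of one cohort: records, normalized expression rows
    aligned with ``ids``, and per-patient patch stacks."""

    records: list[SurvivalRecord]
    X_expr: np.ndarray               # (n_patients, n_genes)
    gene_ids: list[str]
    images: Mapping[str, np.ndarray]

    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort,
                    normalize: bool = True) -> "CohortData":
        m = cohort.expression
        if normalize and not m.normalized:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                m = log_z_transform(m)
        order = [m.samples.index(pid) for pid in cohort.patient_ids]
        return cls(records=list(cohort.records),
                   X_expr=m.values.T[order],
                   gene_ids=list(m.gene_ids),
                   images=cohort.images)

    @property
    def ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    def subset(self, ids: Sequence[str]) -> "CohortData":
        wanted = set(ids)
        keep = [i for i, r in enumerate(self.records) if r.patient_id in wanted]
        return CohortData(records=[self.records[i] for i in keep],
                          X_expr=self.X_expr[keep],
                          gene_ids=self.gene_ids,
                          images=self.images)

    def times_events(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.array([r.time for r in self.records]),
                np.array([r.event for r in self.records]))


# ---------------------------------------------------------------------------
# stratification


def _composite_labels(records: Sequence[SurvivalRecord],
                      strata_spec: Sequence[str]) -> np.ndarray:
    """Tertile-bin continuous strata, join with categoricals, merge
    singleton strata into the nearest (most common) label."""
    parts = []
    for name in strata_spec:
        if name == "time":
            vals = np.array([r.time for r in records], dtype=float)
        else:
            raw = [r.covariates.get(name) for r in records]
            if any(v is None for v in raw):
                continue
            try:
                vals = np.array(raw, dtype=float)
            except (TypeError, ValueError):
                parts.append(np.array([str(v) for v in raw]))
                continue
        if len(np.unique(vals)) <= 3:
            parts.append(vals.astype(str))
        else:
            qs = np.quantile(vals, [1 / 3, 2 / 3])
            parts.append(np.digitize(vals, qs).astype(str))
    if not parts:
        return np.array(["all"] * len(records))
    labels = np.array(["|".join(row) for row in zip(*parts)])
    values, counts = np.unique(labels, return_counts=True)
    singletons = values[counts == 1]
    if len(singletons):
        warnings.warn(f"merging {len(singletons)} singleton stratum(=a) into "
                      f"the largest stratum", RuntimeWarning, stacklevel=2)
        biggest = values[np.argmax(counts)]
        labels[np.isin(labels, singletons)] = biggest
    return labels


def _coarsen_labels(labels: np.ndarray, max_classes: int,
                    min_count: int) -> np.ndarray:
    """Merge the smallest strata into the largest until the label set is
    feasible for the requested split (few enough classes, none too small)."""
    labels = labels.copy()
    while True:
        values, counts = np.unique(labels, return_counts=True)
        if len(values) <= 1:
            return labels
        if len(values) <= max_classes and counts.min() >= min_count:
            return labels
        smallest = values[np.argmin(counts)]
        biggest = values[np.argmax(counts)]
        labels[labels == smallest] = biggest


def stratified_split(records: Sequence[SurvivalRecord], ratio: float,
                     strata_spec: Sequence[str] = DEFAULT_STRATA,
                     seed: int = 0) -> tuple[list[str], list[str]]:
    """Shuffle into train/test at ``ratio`` preserving composite-stratum
    proportions; deterministic under seed. Strata too fine for the cohort
    size are coarsened by merging the smallest into the largest."""
    if len(records) < 10:
        raise ValueError("cohort too small to split (need >= 10 patients)")
    labels = _composite_labels(records, strata_spec)
    n = len(records)
    test_n = max(1, int(round(n * (1.0 - ratio))))
    labels = _coarsen_labels(labels, max_classes=min(test_n, n - test_n),
                             min_count=2)
    ids = np.array([r.patient_id for r in records])
    if len(np.unique(labels)) < 2:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        return (ids[perm[test_n:]].tolist(), ids[perm[:test_n]].tolist())
    splitter = StratifiedShuffleSplit(n_splits=1, train_size=ratio,
                                      random_state=seed)
    train_idx, test_idx = next(splitter.split(ids, labels))
    return ids[train_idx].tolist(), ids[test_idx].tolist()


def cv_folds(records: Sequence[SurvivalRecord], k: int,
             strata_spec: Sequence[str] = DEFAULT_STRATA,
             seed: int = 0, test_ids: Sequence[str] = ()) -> FoldPlan:
    """Stratified k-fold plan over the training pool."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(records) // 2:
        raise ValueError(f"k={k} too large for {len(records)} patients; "
                         f"maximum feasible k is {len(records) // 2}")
    labels = _composite_labels(records, strata_spec)
    labels = _coarsen_labels(labels, max_classes=len(records) // k,
                             min_count=k)
    ids = np.array([r.patient_id for r in records])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [(ids[tr].tolist(), ids[va].tolist())
             for tr, va in skf.split(ids, labels)]
    return FoldPlan(test_ids=list(test_ids), folds=folds,
                    strata_spec=tuple(strata_spec), seed=seed)


# ---------------------------------------------------------------------------
# training loops


def _batch_iter(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for k in range(0, n, batch_size):
        idx = order[k:k + batch_size]
        if len(idx) >= 2:
            yield idx


def _patch_arrays(data: CohortData, patches_per_slide: int,
                  rng: np.random.Generator):
    """Patch tensor plus per-patch survival labels; the per-slide sample is
    drawn once (not per epoch) for reproducibility."""
    xs, ts, es = [], [], []
    for rec in data.records:
        stack = data.images[rec.patient_id]
        if len(stack) > patches_per_slide:
            sel = np.sort(rng.choice(len(stack), patches_per_slide,
                                     replace=False))
            stack = stack[sel]
        xs.append(images_to_tensor(stack))
        ts.append(np.full(len(stack), rec.time))
        es.append(np.full(len(stack), rec.event))
    return (np.concatenate(xs), np.concatenate(ts),
            np.concatenate(es).astype(int))


def _epoch_select(history: list[dict]) -> int:
    """Index of the epoch with the highest validation concordance."""
    return int(np.argmax([h["val_ci"] for h in history]))


def _safe_cox(scores: np.ndarray, times: np.ndarray,
              events: np.ndarray) -> tuple[float, np.ndarray]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return cox_loss(RiskBatch(scores=scores, times=times, events=events))


def _train_image(train: CohortData, val: CohortData, config: TrainerConfig,
                 seed: int) -> tuple[ImageSurvivalModel, list[dict]]:
    rng = np.random.default_rng(seed)
    size = next(iter(train.images.values())).shape[1]
    encoder = ImageEncoder(config.image_config, size, rng)
    model = ImageSurvivalModel(encoder, rng)
    X, T, E = _patch_arrays(train, config.patches_per_slide, rng)
    params, grads = encoder.trainable()
    head_p, head_g = [model.head.W, model.head.b], [model.head.dW, model.head.db]
    opt = nn.Adam([(params, grads, config.lr_image),
                   (head_p, head_g, config.lr_image)])
    vt, ve = val.times_events()
    history: list[dict] = []
    best_state: list[np.ndarray] | None = None
    for epoch in range(config.epochs_image):
        losses = []
        for idx in _batch_iter(len(X), config.batch_size, rng):
            feats = encoder.forward(X[idx], train=True)
            scores = model.head.forward(feats)[:, 0]
            loss, dscore = _safe_cox(scores, T[idx], E[idx])
            opt.zero_grad()
            dfeat = model.head.backward(dscore[:, None] / len(idx))
            encoder.backward(dfeat)
            opt.step()
            losses.append(loss / max(E[idx].sum(), 1))
        val_scores = model.predict_risk(val.images, val.ids)
        val_loss, _ = _safe_cox(val_scores, vt, ve)
        val_ci = concordance_index(val_scores, val.records)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": float(val_loss), "val_ci": float(val_ci)})
        if best_state is None or val_ci >= history[_epoch_select(history)]["val_ci"]:
            best_state = [p.copy() for p in encoder.params() + head_p]
    if history and best_state is not None:
        for p, s in zip(encoder.params() + head_p, best_state, strict=True):
            p[...] = s
    return model, history


def _train_expression(train: CohortData, val: CohortData,
                      config: TrainerConfig, seed: int,
                      ) -> tuple[ExpressionSurvivalModel, list[dict]]:
    rng = np.random.default_rng(seed)
    dims = (train.X_expr.shape[1],) + config.expr_hidden
    encoder = ExpressionEncoder(
        ExpressionMLPConfig(layer_dims=dims, dropout=config.expr_dropout), rng)
    model = ExpressionSurvivalModel(encoder, rng)
    T, E = train.times_events()
    vt, ve = val.times_events()
    head_p, head_g = [model.head.W, model.head.b], [model.head.dW, model.head.db]
    opt = nn.Adam([(encoder.params(), encoder.grads(), config.lr_expr),
                   (head_p, head_g, config.lr_expr)])
    history: list[dict] = []
    best_state = None
    for epoch in range(config.epochs_expr):
        losses = []
        for idx in _batch_iter(len(T), config.batch_size, rng):
            feats = encoder.forward(train.X_expr[idx], train=True)
            scores = model.head.forward(feats)[:, 0]
            loss, dscore = _safe_cox(scores, T[idx], E[idx])
            opt.zero_grad()
            dfeat = model.head.backward(dscore[:, None] / len(idx))
            encoder.backward(dfeat)
            opt.step()
            losses.append(loss / max(E[idx].sum(), 1))
        val_scores = model.predict_risk(val.X_expr)
        val_loss, _ = _safe_cox(val_scores, vt, ve)
        val_ci = concordance_index(val_scores, val.records)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": float(val_loss), "val_ci": float(val_ci)})
        if best_state is None or val_ci >= history[_epoch_select(history)]["val_ci"]:
            best_state = [p.copy() for p in encoder.params() + head_p]
    if history and best_state is not None:
        for p, s in zip(encoder.params() + head_p, best_state, strict=True):
            p[...] = s
    return model, history


def _train_early(image_model: ImageSurvivalModel,
                 expr_model: ExpressionSurvivalModel,
                 train: CohortData, val: CohortData, config: TrainerConfig,
                 seed: int) -> tuple[EarlyFusionModel, list[dict]]:
    rng = np.random.default_rng(seed)
    fused_dim = (image_model.encoder.output_dim
                 + expr_model.encoder.output_dim)
    dims = config.fusion.early_head_dims
    if dims[0] != fused_dim:
        dims = (fused_dim,) + dims[1:]
    fcfg = replace(config.fusion, strategy="early", early_head_dims=dims)
    model = EarlyFusionModel(image_model, expr_model, fcfg, rng)
    # frozen upstream features: all available patches at evaluation mode
    Ztr_img = image_model.patient_features(train.images, train.ids)
    Ztr_exp = expr_model.features(train.X_expr)
    Zva_img = image_model.patient_features(val.images, val.ids)
    Zva_exp = expr_model.features(val.X_expr)
    T, E = train.times_events()
    vt, ve = val.times_events()
    opt = nn.Adam([(model.head.params(), model.head.grads(),
                    config.fusion.lr_head)])
    Ztr = model.fused_features(Ztr_img, Ztr_exp)
    history: list[dict] = []
    best_state = None
    for epoch in range(config.epochs_early):
        losses = []
        for idx in _batch_iter(len(T), config.batch_size, rng):
            scores = model.head.forward(Ztr[idx], train=True)[:, 0]
            loss, dscore = _safe_cox(scores, T[idx], E[idx])
            opt.zero_grad()
            model.head.backward(dscore[:, None] / len(idx))
            opt.step()
            losses.append(loss / max(E[idx].sum(), 1))
        val_scores = model.predict_risk_from_features(Zva_img, Zva_exp)
        val_loss, _ = _safe_cox(val_scores, vt, ve)
        val_ci = concordance_index(val_scores, val.records)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": float(val_loss), "val_ci": float(val_ci)})
        if best_state is None or val_ci >= history[_epoch_select(history)]["val_ci"]:
            best_state = [p.copy() for p in model.head.params()]
    if best_state is not None:
        model.head.load_state(best_state)
    return model, history


def _train_joint(train: CohortData, val: CohortData, config: TrainerConfig,
                 seed: int) -> tuple[JointFusionModel, list[dict]]:
    rng = np.random.default_rng(seed)
    size = next(iter(train.images.values())).shape[1]
    img_encoder = ImageEncoder(config.image_config, size, rng)
    dims = (train.X_expr.shape[1],) + config.expr_hidden
    expr_encoder = ExpressionEncoder(
        ExpressionMLPConfig(layer_dims=dims, dropout=config.expr_dropout), rng)
    model = JointFusionModel(img_encoder, expr_encoder, config.fusion, rng)
    # per-patch training pairs: patch tensor + owner's expression row
    X, T, E = _patch_arrays(train, config.patches_per_slide, rng)
    owner = np.concatenate([
        np.full(min(len(train.images[r.patient_id]), config.patches_per_slide),
                i)
        for i, r in enumerate(train.records)]).astype(int)
    img_p, img_g = img_encoder.trainable()
    head_p = [model.head.W, model.head.b]
    head_g = [model.head.dW, model.head.db]
    opt = nn.Adam([
        (img_p, img_g, config.fusion.lr_image),
        (expr_encoder.params(), expr_encoder.grads(), config.fusion.lr_expr),
        (head_p, head_g, config.fusion.lr_head),
    ])
    vt, ve = val.times_events()
    history: list[dict] = []
    best_state = None
    all_params = img_encoder.params() + expr_encoder.params() + head_p
    for epoch in range(config.epochs_joint):
        losses = []
        for idx in _batch_iter(len(X), config.batch_size, rng):
            scores = model.forward(X[idx], train.X_expr[owner[idx]], train=True)
            loss, dscore = _safe_cox(scores, T[idx], E[idx])
            opt.zero_grad()
            model.backward(dscore / len(idx))
            opt.step()
            losses.append(loss / max(E[idx].sum(), 1))
        val_scores = model.predict_patient_risk(val.images, val.X_expr, val.ids)
        val_loss, _ = _safe_cox(val_scores, vt, ve)
        val_ci = concordance_index(val_scores, val.records)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": float(val_loss), "val_ci": float(val_ci)})
        if best_state is None or val_ci >= history[_epoch_select(history)]["val_ci"]:
            best_state = [p.copy() for p in all_params]
    if history and best_state is not None:
        for p, s in zip(all_params, best_state, strict=True):
            p[...] = s
    return model, history


@dataclass
class FittedModel:
    """A trained strategy plus everything needed to score new cohorts."""

    strategy: str
    predictor: object
    gene_ids: list[str]
    train_records: list[SurvivalRecord]
    train_scores: np.ndarray
    history: list[dict] = field(default_factory=list)

    def predict(self, data: CohortData) -> np.ndarray:
        X = _align_genes(data, self.gene_ids)
        s = self.strategy
        if s == "image":
            return self.predictor.predict_risk(data.images, data.ids)
        if s == "expression":
            return self.predictor.predict_risk(X)
        if s == "early":
            zi = self.predictor.image_model.patient_features(data.images,
                                                             data.ids)
            ze = self.predictor.expr_model.features(X)
            return self.predictor.predict_risk_from_features(zi, ze)
        if s == "late":
            ri = self.predictor.image_model.predict_risk(data.images, data.ids)
            re = self.predictor.expr_model.predict_risk(X)
            return self.predictor.combine(ri, re)
        if s == "joint":
            return self.predictor.predict_patient_risk(data.images, X, data.ids)
        raise ValueError(f"unknown strategy {s!r}")


def _align_genes(data: CohortData, gene_ids: Sequence[str]) -> np.ndarray:
    """Align a cohort's expression columns to a model's gene order, zero
    filling genes the cohort lacks; <50% overlap is a hard error."""
    if list(data.gene_ids) == list(gene_ids):
        return data.X_expr
    index = {g: j for j, g in enumerate(data.gene_ids)}
    overlap = sum(g in index for g in gene_ids)
    if overlap < 0.5 * len(gene_ids):
        raise ValueError(
            f"only {overlap}/{len(gene_ids)} model genes present in the "
            f"target cohort (<50%); refusing silent degradation")
    X = np.zeros((data.X_expr.shape[0], len(gene_ids)))
    for j, g in enumerate(gene_ids):
        if g in index:
            X[:, j] = data.X_expr[:, index[g]]
    return X


def train_model(strategy: str, train: CohortData, val: CohortData,
                config: TrainerConfig, seed: int,
                unimodal: dict[str, FittedModel] | None = None,
                ) -> FittedModel:
    """Train one strategy; fusion strategies reuse (or train) the unimodal
    branches. Returns the fitted model with its per-epoch history."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; "
                         f"expected one of {STRATEGIES}")
    needs_images = strategy in ("image", "early", "late", "joint")
    if needs_images and (not train.images
                         or all(len(s) == 0 for s in train.images.values())):
        raise ValueError(f"strategy {strategy!r} needs image data")
    if strategy == "image":
        model, hist = _train_image(train, val, config, seed)
    elif strategy == "expression":
        model, hist = _train_expression(train, val, config, seed)
    elif strategy == "joint":
        model, hist = _train_joint(train, val, config, seed)
    else:
        if unimodal is None or ("image" not in unimodal
                                or "expression" not in unimodal):
            img = train_model("image", train, val, config, seed)
            exp = train_model("expression", train, val, config, seed + 1)
            unimodal = {"image": img, "expression": exp}
        image_model = unimodal["image"].predictor
        expr_model = unimodal["expression"].predictor
        if strategy == "early":
            model, hist = _train_early(image_model, expr_model, train, val,
                                       config, seed)
        else:  # late
            model = LateFusionModel(image_model, expr_model)
            T, E = train.times_events()
            ri = image_model.predict_risk(train.images, train.ids)
            re = expr_model.predict_risk(train.X_expr)
            model.fit_combiner(ri, re, T, E)
            hist = []
    fitted = FittedModel(strategy=strategy, predictor=model,
                         gene_ids=list(train.gene_ids),
                         train_records=list(train.records),
                         train_scores=np.zeros(len(train.records)),
                         history=hist)
    fitted.train_scores = fitted.predict(train)
    return fitted


def _assert_no_leakage(test_ids: Sequence[str], *pools: Sequence[str]) -> None:
    test = set(test_ids)
    for pool in pools:
        shared = test & set(pool)
        if shared:
            raise AssertionError(f"test identifiers leaked into training: "
                                 f"{sorted(shared)[:5]}")


def benchmark_strategies(cohort: SyntheticCohort, config: TrainerConfig,
                         seed: int,
                         strategies: Sequence[str] = STRATEGIES,
                         test_fraction: float = 0.2,
                         ) -> dict[str, MetricsReport]:
    """Single train/test run of the requested strategies: stratified split,
    training with an inner validation carve-out for epoch selection, test
    metrics per strategy."""
    data = CohortData.from_cohort(cohort.public_view())
    train_ids, test_ids = stratified_split(data.records, 1.0 - test_fraction,
                                           config.strata_spec, seed)
    inner_train, inner_val = stratified_split(
        data.subset(train_ids).records, 1.0 - config.val_fraction,
        config.strata_spec, seed + 1)
    _assert_no_leakage(test_ids, inner_train, inner_val)
    tr = data.subset(inner_train)
    va = data.subset(inner_val)
    te = data.subset(test_ids)
    reports: dict[str, MetricsReport] = {}
    unimodal: dict[str, FittedModel] = {}
    for strategy in strategies:
        fitted = train_model(strategy, tr, va, config, seed,
                             unimodal=unimodal or None)
        if strategy in ("image", "expression"):
            unimodal[strategy] = fitted
        scores = fitted.predict(te)
        reports[strategy] = evaluate_risk_scores(
            fitted.train_records, fitted.train_scores, te.records, scores)
    return reports


def run_experiment(cohort: SyntheticCohort, config: TrainerConfig,
                   seed: int = 0,
                   strategies: Sequence[str] = STRATEGIES,
                   ) -> ExperimentResult:
    """The full five-model experiment: stratified test split, stratified
    k-fold CV, per-fold training, lowest-validation-loss fold selection,
    one held-out evaluation per strategy."""
    data = CohortData.from_cohort(cohort.public_view())
    train_ids, test_ids = stratified_split(data.records, 0.8,
                                           config.strata_spec, seed)
    pool = data.subset(train_ids)
    plan = cv_folds(pool.records, config.k_folds, config.strata_spec, seed,
                    test_ids=test_ids)
    te = data.subset(test_ids)
    per_fold: dict[str, list[dict]] = {s: [] for s in strategies}
    selected: dict[str, int] = {}
    test_reports: dict[str, MetricsReport] = {}
    fold_models: dict[str, list[FittedModel]] = {s: [] for s in strategies}
    for fold_id, (ftr, fva) in enumerate(plan.folds):
        _assert_no_leakage(test_ids, ftr, fva)
        tr, va = pool.subset(ftr), pool.subset(fva)
        unimodal: dict[str, FittedModel] = {}
        for strategy in strategies:
            fitted = train_model(strategy, tr, va, config, seed + fold_id,
                                 unimodal=unimodal or None)
            if strategy in ("image", "expression"):
                unimodal[strategy] = fitted
            tr_scores = fitted.predict(tr)
            va_scores = fitted.predict(va)
            val_loss, _ = _safe_cox(va_scores, *va.times_events())
            per_fold[strategy].append({
                "fold": fold_id,
                "val_loss": float(val_loss),
                "train_report": evaluate_risk_scores(
                    tr.records, tr_scores, tr.records, tr_scores),
                "val_report": evaluate_risk_scores(
                    tr.records, tr_scores, va.records, va_scores),
            })
            fold_models[strategy].append(fitted)
    for strategy in strategies:
        losses = [f["val_loss"] for f in per_fold[strategy]]
        best = int(np.argmin(losses))
        selected[strategy] = best
        fitted = fold_models[strategy][best]
        scores = fitted.predict(te)
        test_reports[strategy] = evaluate_risk_scores(
            fitted.train_records, fitted.train_scores, te.records, scores)
    return ExperimentResult(per_fold=per_fold, selected_fold=selected,
                            test_reports=test_reports, config=config,
                            seed=seed)


def evaluate_and_save(fitted: FittedModel, test: CohortData, out_dir,
                      tag: str) -> MetricsReport:
    """Score a test cohort with a fitted model and write the metrics JSON."""
    from pathlib import Path

    scores = fitted.predict(test)
    report = evaluate_risk_scores(fitted.train_records, fitted.train_scores,
                                  test.records, scores)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_json(out / f"metrics_{tag}.json")
    return report


def save_fitted(fitted: FittedModel, out_dir) -> None:
    """Persist a fitted model: weights as .npz plus a JSON sidecar with the
    architecture, gene order and training-cohort reference data."""
    import dataclasses
    import json
    from pathlib import Path

    from .survival import write_survival_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m = fitted.predictor
    meta: dict = {"strategy": fitted.strategy, "gene_ids": fitted.gene_ids,
                  "train_scores": np.asarray(fitted.train_scores).tolist()}
    if fitted.strategy == "image":
        meta["image_config"] = dataclasses.asdict(m.encoder.config)
        meta["image_size"] = m.encoder.image_size
    elif fitted.strategy == "expression":
        meta["expr_config"] = dataclasses.asdict(m.encoder.config)
    elif fitted.strategy in ("early", "late"):
        meta["image_config"] = dataclasses.asdict(m.image_model.encoder.config)
        meta["image_size"] = m.image_model.encoder.image_size
        meta["expr_config"] = dataclasses.asdict(m.expr_model.encoder.config)
        if fitted.strategy == "early":
            meta["fusion_config"] = dataclasses.asdict(m.config)
    else:  # joint
        meta["image_config"] = dataclasses.asdict(m.image_encoder.config)
        meta["image_size"] = m.image_encoder.image_size
        meta["expr_config"] = dataclasses.asdict(m.expr_encoder.config)
        meta["fusion_config"] = dataclasses.asdict(m.config)
    params = m.all_params()
    np.savez(out / "weights.npz", **{f"p{i}": p for i, p in enumerate(params)})
    (out / "model.json").write_text(json.dumps(meta))
    write_survival_table(fitted.train_records, out / "train_survival.tsv")


def load_fitted(in_dir) -> FittedModel:
    """Reload a model persisted by :func:`save_fitted`."""
    import json
    from pathlib import Path

    from .survival import read_survival_table

    src = Path(in_dir)
    meta = json.loads((src / "model.json").read_text())
    with np.load(src / "weights.npz") as z:
        params = [z[f"p{i}"] for i in range(len(z.files))]
    rng = np.random.default_rng(0)
    strategy = meta["strategy"]

    def _image_model():
        enc = ImageEncoder(ImageEncoderConfig(
            **{k: tuple(v) if isinstance(v, list) else v
               for k, v in meta["image_config"].items()}),
            meta["image_size"], rng)
        return ImageSurvivalModel(enc, rng)

    def _expr_model():
        cfg = meta["expr_config"]
        enc = ExpressionEncoder(ExpressionMLPConfig(
            layer_dims=tuple(cfg["layer_dims"]), dropout=cfg["dropout"],
            activation=cfg.get("activation", "relu")), rng)
        return ExpressionSurvivalModel(enc, rng)

    def _fusion_config():
        cfg = dict(meta["fusion_config"])
        cfg["early_head_dims"] = tuple(cfg["early_head_dims"])
        return FusionConfig(**cfg)

    if strategy == "image":
        model = _image_model()
    elif strategy == "expression":
        model = _expr_model()
    elif strategy == "early":
        model = EarlyFusionModel(_image_model(), _expr_model(),
                                 _fusion_config(), rng)
    elif strategy == "late":
        model = LateFusionModel(_image_model(), _expr_model())
    elif strategy == "joint":
        img = _image_model()
        exp = _expr_model()
        model = JointFusionModel(img.encoder, exp.encoder,
                                 _fusion_config(), rng)
    else:
        raise ValueError(f"unknown strategy {strategy!r} in checkpoint")
    for p, s in zip(model.all_params(), params, strict=True):
        p[...] = s
    return FittedModel(strategy=strategy, predictor=model,
                       gene_ids=list(meta["gene_ids"]),
                       train_records=read_survival_table(
                           src / "train_survival.tsv"),
                       train_scores=np.array(meta["train_scores"]))


def transfer_evaluate(fitted: FittedModel,
                      new_cohort: SyntheticCohort | CohortData,
                      ) -> MetricsReport:
    """Pure inference of a fitted model on a new cohort (no updates)."""
    data = (new_cohort if isinstance(new_cohort, CohortData)
            else CohortData.from_cohort(new_cohort.public_view()
                                        if new_cohort.truth is not None
                                        else new_cohort))
    scores = fitted.predict(data)
    return evaluate_risk_scores(fitted.train_records, fitted.train_scores,
                                data.records, scores)
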