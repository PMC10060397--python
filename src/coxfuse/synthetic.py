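"""Synthetic multimodal cohort generator.

Every cohort carries two partially independent standard-normal latent
factors per patient: ``z_img`` is expressed as image texture (the density of
dark nucleus-like blobs on an eosin-pink background rises monotonically with
``z_img``) and ``z_expr`` as a correlated gene module (module genes measure
``z_expr`` plus noise on a count-like scale, background genes are pure
noise). The true log-hazard is ``beta_img * z_img + beta_expr * z_expr``;
event times are exponential with rate ``baseline_rate * exp(log_hazard)``
and censoring times are independent exponentials whose rate is calibrated so
the expected censored fraction matches ``censor_rate``.

The generator returns a public cohort plus a truth sidecar; training entry
points only ever accept the public view, and :func:`oracle_risk` exposes the
planted log-hazard for upper-bound benchmarking only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .errors import CapabilityError
from .expr import ExpressionMatrix, write_expression_tsv, read_expression_tsv
from .survival import SurvivalRecord, write_survival_table, read_survival_table

__all__ = ["SyntheticConfig", "SyntheticCohort", "CohortTruth",
           "simulate_cohort", "oracle_risk", "write_cohort", "load_cohort"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; the defaults are the package's desk-scale
    study conditions (n=300 patients, 8 patches/patient at 64 px, 200 genes
    with a 20-gene signal module, unit effect sizes, 20% censoring)."""

    n_patients: int = 300
    patches_per_patient: int = 8
    image_size: int = 64
    n_genes: int = 200
    module_size: int = 20
    beta_img: float = 1.0
    beta_expr: float = 1.0
    noise_img: float = 0.05
    noise_expr: float = 0.3
    baseline_rate: float = 0.1
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.module_size > self.n_genes:
            raise ValueError("module_size cannot exceed n_genes")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")


@dataclass
class CohortTruth:
    """Hidden generator state, for benchmarking only."""

    z_img: np.ndarray
    z_expr: np.ndarray
    log_hazard: np.ndarray
    module_gene_ids: list[str]
    config: SyntheticConfig


@dataclass
class SyntheticCohort:
    """Paired survival + images + expression; ``images[pid]`` is a
    (patches, H, W, 3) uint8 stack."""

    records: list[SurvivalRecord]
    images: dict[str, np.ndarray]
    expression: ExpressionMatrix
    truth: CohortTruth | None = field(default=None, repr=False)

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    def public_view(self) -> "SyntheticCohort":
        """The cohort without its truth sidecar (what training code sees)."""
        return SyntheticCohort(records=self.records, images=self.images,
                               expression=self.expression, truth=None)

    @property
    def censored_fraction(self) -> float:
        e = np.array([r.event for r in self.records])
        return float(1.0 - e.mean())


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _render_patch(rng: np.random.Generator, size: int, n_blobs: int,
                  noise_img: float) -> np.ndarray:
    """Eosin-pink background with dark hematoxylin-like blobs."""
    img = np.empty((size, size, 3))
    img[..., 0] = 0.92
    img[..., 1] = 0.72
    img[..., 2] = 0.80
    yy, xx = np.mgrid[0:size, 0:size]
    blob_color = np.array([0.35, 0.22, 0.50])
    for _ in range(n_blobs):
        cx, cy = rng.uniform(0, size, 2)
        r = rng.uniform(1.8, 3.6)
        x0, x1 = max(0, int(cx - r - 1)), min(size, int(cx + r + 2))
        y0, y1 = max(0, int(cy - r - 1)), min(size, int(cy + r + 2))
        if x0 >= x1 or y0 >= y1:
            continue
        d2 = (xx[y0:y1, x0:x1] - cx) ** 2 + (yy[y0:y1, x0:x1] - cy) ** 2
        inside = d2 <= r * r
        img[y0:y1, x0:x1][inside] = blob_color
    img += rng.normal(0.0, noise_img, img.shape)
    return np.clip(img * 255.0 + 0.5, 0, 255).astype(np.uint8)


def simulate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw one cohort; fully deterministic under ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    z_img = rng.standard_normal(n)
    z_expr = rng.standard_normal(n)
    log_hazard = cfg.beta_img * z_img + cfg.beta_expr * z_expr
    rates = cfg.baseline_rate * np.exp(log_hazard)
    event_times = rng.exponential(1.0 / rates)

    if cfg.censor_rate == 0.0:
        times = event_times
        events = np.ones(n, dtype=int)
    else:
        def expected_censored(log_rc: float) -> float:
            rc = np.exp(log_rc)
            return float(np.mean(rc / (rc + rates))) - cfg.censor_rate
        lo, hi = -20.0, 20.0
        if expected_censored(lo) > 0 or expected_censored(hi) < 0:
            raise ValueError(
                f"censor_rate {cfg.censor_rate} not calibratable for these "
                f"hazards; achievable range is (0, 1)")
        rate_c = np.exp(brentq(expected_censored, lo, hi))
        censor_times = rng.exponential(1.0 / rate_c, n)
        events = (event_times <= censor_times).astype(int)
        times = np.minimum(event_times, censor_times)

    ids = [f"P{i:04d}" for i in range(n)]
    ages = rng.normal(55.0, 12.0, n)
    genders = rng.choice(["F", "M"], n)
    grades = (log_hazard > np.median(log_hazard)).astype(int)
    records = [
        SurvivalRecord(patient_id=ids[i], time=float(times[i]) + 1e-9,
                       event=int(events[i]),
                       covariates={"age": float(ages[i]),
                                   "gender": str(genders[i]),
                                   "grade": int(grades[i])})
        for i in range(n)
    ]

    # expression on a count-like scale so log2(x+1) z-scoring recovers z_expr
    gene_ids = [f"G{j:04d}" for j in range(cfg.n_genes)]
    module_ids = gene_ids[:cfg.module_size]
    signal = np.empty((cfg.n_genes, n))
    signal[:cfg.module_size] = (z_expr[None, :]
                                + rng.normal(0, cfg.noise_expr,
                                             (cfg.module_size, n)))
    signal[cfg.module_size:] = rng.standard_normal(
        (cfg.n_genes - cfg.module_size, n))
    raw = np.power(2.0, 5.0 + signal)
    expression = ExpressionMatrix(gene_ids=gene_ids, samples=ids,
                                  values=raw, normalized=False)

    # blob count rises monotonically with z_img: 6..36 through a sigmoid
    n_blobs = np.round(6 + 30 * _sigmoid(z_img)).astype(int)
    images = {}
    empty = np.zeros((0, cfg.image_size, cfg.image_size, 3), dtype=np.uint8)
    for i, pid in enumerate(ids):
        if cfg.patches_per_patient == 0:
            images[pid] = empty
            continue
        stack = np.stack([
            _render_patch(rng, cfg.image_size, int(n_blobs[i]), cfg.noise_img)
            for _ in range(cfg.patches_per_patient)
        ])
        images[pid] = stack

    truth = CohortTruth(z_img=z_img, z_expr=z_expr, log_hazard=log_hazard,
                        module_gene_ids=module_ids, config=cfg)
    return SyntheticCohort(records=records, images=images,
                           expression=expression, truth=truth)


def oracle_risk(cohort: SyntheticCohort) -> dict[str, float]:
    """True log-hazard per patient — benchmarking upper bound only."""
    if cohort.truth is None:
        raise CapabilityError("cohort carries no truth sidecar; oracle risk "
                              "is unavailable on the public view")
    return dict(zip(cohort.patient_ids,
                    (float(h) for h in cohort.truth.log_hazard)))


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Standard on-disk layout: survival TSV, expression TSV, patch PNGs plus
    manifest, and (when present) a truth JSON sidecar."""
    from PIL import Image
    import pandas as pd

    out = Path(out_dir)
    (out / "patches").mkdir(parents=True, exist_ok=True)
    write_survival_table(cohort.records, out / "survival.tsv")
    write_expression_tsv(cohort.expression, out / "expression.tsv")
    rows = []
    for pid, stack in cohort.images.items():
        for k in range(stack.shape[0]):
            rel = f"patches/{pid}_{k:03d}.png"
            Image.fromarray(stack[k]).save(out / rel)
            rows.append({"patient_id": pid, "slide_id": pid, "x": 0,
                         "y": k * stack.shape[1], "foreground_fraction": 1.0,
                         "path": rel})
    pd.DataFrame(rows).to_csv(out / "patch_manifest.tsv", sep="\t", index=False)
    if cohort.truth is not None:
        t = cohort.truth
        payload = {
            "z_img": t.z_img.tolist(),
            "z_expr": t.z_expr.tolist(),
            "log_hazard": t.log_hazard.tolist(),
            "module_gene_ids": t.module_gene_ids,
            "config": dataclasses.asdict(t.config),
        }
        (out / "truth.json").write_text(json.dumps(payload))


def load_cohort(in_dir: str | Path) -> SyntheticCohort:
    from PIL import Image
    import pandas as pd

    src = Path(in_dir)
    records = read_survival_table(src / "survival.tsv")
    expression = read_expression_tsv(src / "expression.tsv")
    manifest = pd.read_csv(src / "patch_manifest.tsv", sep="\t")
    images: dict[str, np.ndarray] = {}
    for pid, group in manifest.groupby("patient_id", sort=True):
        stack = np.stack([
            np.asarray(Image.open(src / row["path"]).convert("RGB"))
            for _, row in group.iterrows()
        ])
        images[str(pid)] = stack
    truth = None
    truth_path = src / "truth.json"
    if truth_path.exists():
        payload = json.loads(truth_path.read_text())
        truth = CohortTruth(
            z_img=np.array(payload["z_img"]),
            z_expr=np.array(payload["z_expr"]),
            log_hazard=np.array(payload["log_hazard"]),
            module_gene_ids=list(payload["module_gene_ids"]),
            config=SyntheticConfig(**payload["config"]),
        )
    return SyntheticCohort(records=records, images=images,
                           expression=expression, truth=truth)
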