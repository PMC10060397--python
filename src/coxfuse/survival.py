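"""Cox partial-likelihood loss and batch risk-set machinery.

The negative log partial likelihood

    L = - sum_{i : C_i = 1} ( f_i - log sum_{j : Y_j >= Y_i} exp(f_j) )

is the output objective of every model in the package. ``f`` is the scalar
log-risk emitted by a network for each batch element, ``Y`` the follow-up
time and ``C`` the event indicator (1 = death observed, 0 = censored). The
sum over the risk set is taken within the current batch (batch-sampled
partial likelihood): stochastic batches approximate the full-cohort risk
sets, which is what makes the loss usable as a neural output layer.

Ties are handled with the Breslow convention: the risk set at an event time
includes every subject with ``Y_j >= Y_i``, ties included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalRecord",
    "RiskBatch",
    "build_risk_sets",
    "cox_loss",
    "read_survival_table",
    "write_survival_table",
]

REQUIRED_COLUMNS = ("patient_id", "time", "event")


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time, event indicator, optional covariates."""

    patient_id: str
    time: float
    event: int
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"time must be positive, got {self.time!r} "
                             f"for patient {self.patient_id!r}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event!r}")


@dataclass
class RiskBatch:
    """Aligned score/time/event vectors for one loss evaluation."""

    scores: np.ndarray
    times: np.ndarray
    events: np.ndarray
    element_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        n = len(self.scores)
        if n == 0:
            raise ValueError("risk batch must be non-empty")
        if not (len(self.times) == len(self.events) == n):
            raise ValueError("scores, times and events must have equal length")
        if self.element_ids is not None and len(self.element_ids) != n:
            raise ValueError("element_ids length mismatch")

    def __len__(self) -> int:
        return len(self.scores)


def records_to_batch(records: Sequence[SurvivalRecord],
                     scores: np.ndarray) -> RiskBatch:
    return RiskBatch(
        scores=np.asarray(scores, dtype=float),
        times=np.array([r.time for r in records]),
        events=np.array([r.event for r in records]),
        element_ids=[r.patient_id for r in records],
    )


def build_risk_sets(batch: RiskBatch) -> dict[int, set[int]]:
    """Risk set per event: index i with event=1 -> {j : Y_j >= Y_i}.

    Breslow tie convention; every risk set contains its own index.
    """
    times = batch.times
    out: dict[int, set[int]] = {}
    for i in np.flatnonzero(batch.events == 1):
        out[int(i)] = set(np.flatnonzero(times >= times[i]).tolist())
    return out


def cox_loss(batch: RiskBatch) -> tuple[float, np.ndarray]:
    """Negative log partial likelihood and its gradient w.r.t. the scores.

    Returns ``(loss, grad)``. A batch with zero observed events is a
    degenerate but legal outcome of stochastic batching and yields loss 0
    with zero gradient (and a warning) rather than aborting training.

    The log-sum-exp over each risk set subtracts the batch maximum score, so
    the loss stays finite for scores up to at least +/-50.
    """
    f = batch.scores
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite risk score in batch")
    times, events = batch.times, batch.events
    n = len(f)
    if events.sum() == 0:
        warnings.warn("batch contains no observed events; Cox loss is 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0, np.zeros(n)

    # Sort descending by time: the risk set of the i-th sorted event is the
    # prefix of sorted elements up to and including every tie with Y_i.
    order = np.argsort(-times, kind="stable")
    f_s = f[order]
    t_s = times[order]
    e_s = events[order]

    fmax = f_s.max()
    exp_s = np.exp(f_s - fmax)
    cum = np.cumsum(exp_s)
    # extend each prefix through ties: -t_s is ascending, so for each i the
    # rightmost j with t_s[j] == t_s[i] closes its Breslow risk set
    asc = -t_s
    right = np.searchsorted(asc, asc, side="right") - 1
    denom_log = np.log(cum[right]) + fmax

    event_idx = np.flatnonzero(e_s == 1)
    loss = float(np.sum(denom_log[event_idx] - f_s[event_idx]))

    # gradient: dL/df_k = -C_k + exp(f_k) * sum_{i events : Y_k >= Y_i} 1/D_i
    # in sorted space, "Y_k >= Y_i" means k <= right[i]; accumulate inverse
    # denominators with a reverse cumulative sum over event positions.
    inv_d = np.zeros(n)
    np.add.at(inv_d, right[event_idx], 1.0 / np.exp(denom_log[event_idx] - fmax))
    suffix = np.cumsum(inv_d[::-1])[::-1]
    grad_s = exp_s * suffix - e_s
    grad = np.empty(n)
    grad[order] = grad_s
    return loss, grad


def read_survival_table(path: str | Path) -> list[SurvivalRecord]:
    """Read a TSV/CSV survival table (columns patient_id, time, event [, ...])."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survival table {path} lacks required columns {missing}")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    records = []
    for _, row in df.iterrows():
        records.append(SurvivalRecord(
            patient_id=str(row["patient_id"]),
            time=float(row["time"]),
            event=int(row["event"]),
            covariates={c: row[c] for c in extra},
        ))
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate patient_id in {path}")
    return records


def write_survival_table(records: Sequence[SurvivalRecord],
                         path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    cov_keys: list[str] = []
    for r in records:
        for k in r.covariates:
            if k not in cov_keys:
                cov_keys.append(k)
    rows = [{"patient_id": r.patient_id, "time": r.time, "event": r.event,
             **{k: r.covariates.get(k) for k in cov_keys}} for r in records]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
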