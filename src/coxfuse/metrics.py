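"""Survival-prediction evaluation.

Concordance index (Harrell), inverse-probability-of-censoring-weighted Brier
score and its time integral (IBS), the Composite Score CS = (CI + (1-IBS))/2,
Kaplan–Meier curves, median-risk stratification and the two-group log-rank
test. Kaplan–Meier estimation and the log-rank test are delegated to
lifelines; the concordance and Brier machinery is implemented here because
their tie and weighting conventions are part of the package contract.

Predicted survival functions for the IBS are derived from scalar Cox risk
scores through a Breslow baseline cumulative hazard estimated on training
data (``survival_curves_from_risks``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .survival import SurvivalRecord

__all__ = [
    "UndefinedMetricError",
    "SurvivalCurve",
    "RiskGroupSplit",
    "MetricsReport",
    "concordance_index",
    "kaplan_meier",
    "censoring_curve",
    "brier_score",
    "integrated_brier_score",
    "composite_score",
    "median_risk_split",
    "logrank_test",
    "survival_curves_from_risks",
    "evaluate_risk_scores",
    "plot_km_by_risk_group",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value on the given input."""


@dataclass
class SurvivalCurve:
    """Right-continuous step survival function S(t) on a time grid.

    ``times`` starts at 0 with ``survival[0] == 1``; ``at_risk`` and
    ``n_events`` record the product-limit bookkeeping at each grid time.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.at_risk = np.asarray(self.at_risk, dtype=int)
        self.n_events = np.asarray(self.n_events, dtype=int)
        if not (len(self.times) == len(self.survival)
                == len(self.at_risk) == len(self.n_events)):
            raise ValueError("curve vectors must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def evaluate(self, t: np.ndarray | float) -> np.ndarray | float:
        """S(t), right-continuous (value at the last grid time <= t)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return float(out) if out.ndim == 0 else out

    def evaluate_left(self, t: np.ndarray | float) -> np.ndarray | float:
        """S(t-), the left limit (value just before t)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="left") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return float(out) if out.ndim == 0 else out


@dataclass
class StepPredictor:
    """Arbitrary right-continuous step function of time in [0, 1].

    Used for predicted survival probabilities where no monotonicity is
    imposed (a deliberately bad predictor may be increasing in time); the
    estimated :class:`SurvivalCurve` keeps its non-increasing invariant.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("predicted probabilities must lie in [0, 1]")

    def evaluate(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 1.0)
        return float(out) if out.ndim == 0 else out


@dataclass
class RiskGroupSplit:
    poor_ids: set
    good_ids: set
    threshold: float


@dataclass
class MetricsReport:
    ci: float
    ibs: float
    cs: float
    logrank_p: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.cs - composite_score(self.ci, self.ibs)) > 1e-12:
            raise ValueError("cs inconsistent with (ci + (1 - ibs)) / 2")

    @classmethod
    def build(cls, ci: float, ibs: float, logrank_p: float, n: int) -> "MetricsReport":
        return cls(ci=ci, ibs=ibs, cs=composite_score(ci, ibs),
                   logrank_p=logrank_p, n=n)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _times_events(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    return (np.array([r.time for r in records], dtype=float),
            np.array([r.event for r in records], dtype=int))


def concordance_index(scores: Sequence[float],
                      records: Sequence[SurvivalRecord]) -> float:
    """Harrell's C: correctly ordered admissible pairs / admissible pairs.

    A pair with Y_i < Y_j is admissible iff the shorter time is an event; a
    time-tied pair is admissible iff both are events. The shorter-lived
    patient should carry the higher risk score; tied scores count 0.5, and a
    time-tied pair counts 1 for tied scores, 0.5 otherwise.
    """
    f = np.asarray(scores, dtype=float)
    t, e = _times_events(records)
    if len(f) != len(t):
        raise ValueError("scores and records must have equal length")
    dt = t[:, None] - t[None, :]          # t_i - t_j
    df = f[:, None] - f[None, :]
    # ordered pairs (i, j) with t_i < t_j and event_i = 1
    lt = (dt < 0) & (e[:, None] == 1)
    n_ordered = lt.sum()
    conc = np.sum(lt & (df > 0)) + 0.5 * np.sum(lt & (df == 0))
    # unordered time-tied pairs with both events (count each once: i < j)
    iu = np.triu(np.ones_like(lt, dtype=bool), k=1)
    tied = iu & (dt == 0) & (e[:, None] == 1) & (e[None, :] == 1)
    n_tied = tied.sum()
    conc += np.sum(tied & (df == 0)) + 0.5 * np.sum(tied & (df != 0))
    n_adm = int(n_ordered + n_tied)
    if n_adm == 0:
        raise UndefinedMetricError("no admissible pairs: concordance undefined")
    return float(conc / n_adm)


def kaplan_meier(records: Sequence[SurvivalRecord]) -> SurvivalCurve:
    """Product-limit survival estimate for one cohort."""
    if len(records) == 0:
        raise ValueError("empty cohort")
    t, e = _times_events(records)
    return _km_from_arrays(t, e)


def censoring_curve(records: Sequence[SurvivalRecord]) -> SurvivalCurve:
    """Kaplan–Meier estimate of the censoring distribution G (events flipped)."""
    t, e = _times_events(records)
    return _km_from_arrays(t, 1 - e)


def _km_from_arrays(t: np.ndarray, e: np.ndarray) -> SurvivalCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table  # indexed by time, includes t=0 row
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy()
    if times[0] != 0.0:
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
        at_risk = np.concatenate([[int(table["at_risk"].iloc[0])],
                                  table["at_risk"].to_numpy(dtype=int)])
        n_events = np.concatenate([[0], table["observed"].to_numpy(dtype=int)])
    else:
        at_risk = table["at_risk"].to_numpy(dtype=int)
        n_events = table["observed"].to_numpy(dtype=int)
    return SurvivalCurve(times=times, survival=surv,
                         at_risk=at_risk, n_events=n_events)


def brier_score(t: float,
                predicted_survival: Sequence[float],
                records: Sequence[SurvivalRecord],
                censor_curve: SurvivalCurve) -> float:
    """IPCW (Graf) Brier score at time t.

    Patients with an observed event at or before t contribute
    S_i(t)^2 / G(T_i-); patients still under observation beyond t contribute
    (1 - S_i(t))^2 / G(t); patients censored at or before t contribute 0.
    """
    s = np.asarray(predicted_survival, dtype=float)
    T, e = _times_events(records)
    if len(s) != len(T):
        raise ValueError("predicted_survival and records length mismatch")
    n = len(T)
    had_event = (T <= t) & (e == 1)
    at_risk = T > t
    total = 0.0
    if had_event.any():
        g_left = np.atleast_1d(censor_curve.evaluate_left(T[had_event]))
        if np.any(g_left <= 0):
            raise UndefinedMetricError(
                "censoring survival G(T-) is 0 for an event before t; "
                "truncate the time grid before the last censoring time")
        total += np.sum(s[had_event] ** 2 / g_left)
    if at_risk.any():
        g_t = float(censor_curve.evaluate(t))
        if g_t <= 0:
            raise UndefinedMetricError(
                "censoring survival G(t) is 0; truncate the time grid")
        total += np.sum((1.0 - s[at_risk]) ** 2) / g_t
    return float(total / n)


def integrated_brier_score(curves: Sequence[SurvivalCurve | StepPredictor],
                           records: Sequence[SurvivalRecord]) -> float:
    """Trapezoidal integral of the Brier score over [0, t_max] / t_max.

    The grid is {0} plus the unique observed times; ``curves`` holds one
    predicted survival function per patient (any object with an
    ``evaluate(t)`` method), aligned with ``records``.
    """
    T, _ = _times_events(records)
    grid = np.unique(T)
    if len(grid) < 2:
        raise UndefinedMetricError(
            "integrated Brier score needs >= 2 distinct observed times")
    grid = np.concatenate([[0.0], grid])
    g_curve = censoring_curve(records)
    bs = np.empty(len(grid))
    for k, t in enumerate(grid):
        preds = [c.evaluate(t) for c in curves]
        bs[k] = brier_score(t, preds, records, g_curve)
    t_max = grid[-1]
    return float(np.trapezoid(bs, grid) / t_max)


def composite_score(ci: float, ibs: float) -> float:
    """CS = (CI + (1 - IBS)) / 2; both inputs must lie in [0, 1]."""
    if not (0.0 <= ci <= 1.0 and 0.0 <= ibs <= 1.0):
        raise ValueError(f"ci and ibs must be in [0, 1], got ci={ci}, ibs={ibs}")
    return (ci + (1.0 - ibs)) / 2.0


def median_risk_split(scores: Sequence[float],
                      ids: Sequence[str]) -> RiskGroupSplit:
    """Split patients at the median predicted risk.

    Poor-survival group: risk strictly greater than the median; scores equal
    to the median go to the good-survival group.
    """
    f = np.asarray(scores, dtype=float)
    if len(f) < 2:
        raise ValueError("median split needs >= 2 patients")
    if len(f) != len(ids):
        raise ValueError("scores and ids length mismatch")
    med = float(np.median(f))
    poor = {i for i, s in zip(ids, f) if s > med}
    good = {i for i, s in zip(ids, f) if s <= med}
    if not poor:
        warnings.warn("degenerate split: no score exceeds the median "
                      "(all scores identical?)", RuntimeWarning, stacklevel=2)
    return RiskGroupSplit(poor_ids=poor, good_ids=good, threshold=med)


def logrank_test(group_a: Sequence[SurvivalRecord],
                 group_b: Sequence[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p-value), 1 df."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    ta, ea = _times_events(group_a)
    tb, eb = _times_events(group_b)
    if ea.sum() + eb.sum() == 0:
        raise UndefinedMetricError("log-rank test undefined with zero events")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def survival_curves_from_risks(train_records: Sequence[SurvivalRecord],
                               train_scores: Sequence[float],
                               eval_scores: Sequence[float],
                               ) -> list[SurvivalCurve]:
    """Per-patient survival curves from Cox risk scores via a Breslow baseline.

    The baseline cumulative hazard H0 is estimated on the training cohort
    with scores centred at their training mean; each evaluated patient gets
    S_i(t) = exp(-H0(t) * exp(f_i - mean(f_train))).
    """
    if len(train_records) == 0:
        raise ValueError("empty training cohort")
    f_train = np.asarray(train_scores, dtype=float)
    T, e = _times_events(train_records)
    mu = f_train.mean()
    w = np.exp(f_train - mu)
    event_times = np.unique(T[e == 1])
    # Breslow: dH0(t_k) = d_k / sum_{j: T_j >= t_k} w_j
    increments = np.array([
        (e[T == tk].sum()) / w[T >= tk].sum() for tk in event_times
    ])
    H0 = np.cumsum(increments)
    grid = np.concatenate([[0.0], event_times])
    H0 = np.concatenate([[0.0], H0])
    at_risk = np.concatenate([[len(T)],
                              [(T >= tk).sum() for tk in event_times]]).astype(int)
    n_ev = np.concatenate([[0], [e[T == tk].sum() for tk in event_times]]).astype(int)
    curves = []
    for fi in np.asarray(eval_scores, dtype=float):
        surv = np.exp(-H0 * np.exp(fi - mu))
        curves.append(SurvivalCurve(times=grid, survival=surv,
                                    at_risk=at_risk, n_events=n_ev))
    return curves


def evaluate_risk_scores(train_records: Sequence[SurvivalRecord],
                         train_scores: Sequence[float],
                         eval_records: Sequence[SurvivalRecord],
                         eval_scores: Sequence[float]) -> MetricsReport:
    """Full report (CI, IBS, CS, median-split log-rank p) for one model."""
    ci = concordance_index(eval_scores, eval_records)
    curves = survival_curves_from_risks(train_records, train_scores, eval_scores)
    ibs = integrated_brier_score(curves, eval_records)
    split = median_risk_split(eval_scores, [r.patient_id for r in eval_records])
    by_id = {r.patient_id: r for r in eval_records}
    poor = [by_id[i] for i in split.poor_ids]
    good = [by_id[i] for i in split.good_ids]
    if poor and good:
        try:
            _, p = logrank_test(poor, good)
        except UndefinedMetricError:
            p = 1.0
    else:
        p = 1.0
    return MetricsReport.build(ci=ci, ibs=min(ibs, 1.0), logrank_p=p,
                               n=len(eval_records))


def plot_km_by_risk_group(records: Sequence[SurvivalRecord],
                          scores: Sequence[float],
                          path: str | Path,
                          title: str = "") -> RiskGroupSplit:
    """Kaplan–Meier figure with the two median-split risk groups overlaid."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    split = median_risk_split(scores, [r.patient_id for r in records])
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, ids, color in (("poor survival", split.poor_ids, "tab:red"),
                             ("good survival", split.good_ids, "tab:blue")):
        group = [r for r in records if r.patient_id in ids]
        if not group:
            continue
        curve = kaplan_meier(group)
        ax.step(curve.times, curve.survival, where="post",
                label=f"{name} (n={len(group)})", color=color)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return split
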