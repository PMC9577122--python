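"""Survival stratification of predicted risk groups.

Kaplan-Meier product-limit estimation, the two-group log-rank test, and
univariate Cox proportional-hazards fitting (Breslow tie handling,
Newton iteration, Wald confidence intervals). Times are months
throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "CoxResult",
    "NonEstimableError",
    "km_estimate",
    "median_survival",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
]


class ValidationError(ValueError):
    pass


class NonEstimableError(RuntimeError):
    """Hazard ratio cannot be estimated (e.g. one group has no events)."""


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float  # months
    event: int  # 1 = death, 0 = censored
    group: str | None = None

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValidationError(f"time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValidationError(f"event must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray  # distinct event times, sorted
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # risk-set size at each event time
    n_events: np.ndarray  # deaths at each event time
    horizon: float | None = None

    def survival_at(self, t: float) -> float:
        """S(t); 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.n_events,
            }
        )


def _validate(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    if not records:
        raise ValidationError("no survival records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    return times, events


def km_estimate(
    records: Sequence[SurvivalRecord], horizon: float | None = None
) -> KMCurve:
    """Kaplan-Meier estimator; ties decrement simultaneously; event times
    beyond `horizon` are ignored (administrative truncation)."""
    times, events = _validate(records)
    event_times = np.unique(times[events == 1])
    if horizon is not None:
        event_times = event_times[event_times <= horizon]
    survival = np.empty(len(event_times))
    at_risk = np.empty(len(event_times), dtype=int)
    deaths = np.empty(len(event_times), dtype=int)
    s = 1.0
    for i, t in enumerate(event_times):
        n = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n
        survival[i], at_risk[i], deaths[i] = s, n, d
    return KMCurve(
        times=event_times,
        survival=survival,
        at_risk=at_risk,
        n_events=deaths,
        horizon=horizon,
    )


def median_survival(curve: KMCurve) -> float | None:
    """Smallest event time with S <= 0.5, or None when not reached."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    return float(curve.times[below[0]]) if len(below) else None


def logrank_test(
    group_low: Sequence[SurvivalRecord], group_high: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic on 1 df, p-value)."""
    t1, e1 = _validate(group_low)
    t2, e2 = _validate(group_high)
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2])
    in_low = np.concatenate([np.ones(len(t1), bool), np.zeros(len(t2), bool)])
    event_times = np.unique(times[events == 1])
    if len(event_times) == 0:
        warnings.warn("no events in either group; log-rank statistic is 0")
        return 0.0, 1.0
    observed_minus_expected = 0.0
    variance = 0.0
    for t in event_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in_low).sum())
        d = int(np.sum((times == t) & (events == 1)))
        d1 = int(np.sum((times == t) & (events == 1) & in_low))
        observed_minus_expected += d1 - d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if variance == 0:
        warnings.warn("zero log-rank variance; statistic set to 0")
        return 0.0, 1.0
    statistic = observed_minus_expected**2 / variance
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


@dataclass(frozen=True)
class CoxResult:
    log_hazard_ratio: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    se: float
    n_events: int
    n_iterations: int


def _risk_set_sums(
    times: np.ndarray, events: np.ndarray, x: np.ndarray
) -> list[tuple[int, float, np.ndarray]]:
    """Per distinct event time: (d, sum of x over deaths, risk-set x)."""
    groups = []
    for t in np.unique(times[events == 1]):
        dead = (times == t) & (events == 1)
        groups.append((int(dead.sum()), float(x[dead].sum()), x[times >= t]))
    return groups


def cox_fit(
    records: Sequence[SurvivalRecord],
    high_label: str | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxResult:
    """Univariate Cox PH fit for a binary group covariate.

    Maximizes the Breslow partial likelihood by Newton iteration to
    |delta beta| < tol. The Wald 95% CI is exp(beta +/- 1.96 * SE).
    Raises NonEstimableError when either group has no events (monotone
    likelihood) or there are no events at all.
    """
    times, events = _validate(records)
    groups = [r.group for r in records]
    distinct = sorted(set(groups))
    if len(distinct) != 2:
        raise ValidationError(f"need exactly 2 groups, got {distinct}")
    if high_label is None:
        candidates = [g for g in distinct if "high" in g.lower()]
        if len(candidates) != 1:
            raise ValidationError(
                f"cannot infer the high-risk group from {distinct}; pass high_label"
            )
        high_label = candidates[0]
    x = np.array([1.0 if g == high_label else 0.0 for g in groups])

    n_events = int(events.sum())
    if n_events == 0:
        raise NonEstimableError("no events in the data")
    for value, name in ((1.0, "high"), (0.0, "low")):
        if events[x == value].sum() == 0:
            raise NonEstimableError(
                f"no events in the {name}-risk group; hazard ratio is not estimable"
            )

    risk_sets = _risk_set_sums(times, events, x)
    beta = 0.0
    for iteration in range(1, max_iter + 1):
        score = 0.0
        info = 0.0
        for d, x_dead_sum, x_risk in risk_sets:
            w = np.exp(beta * x_risk)
            s0 = w.sum()
            s1 = (w * x_risk).sum()
            s2 = (w * x_risk**2).sum()
            mean = s1 / s0
            score += x_dead_sum - d * mean
            info += d * (s2 / s0 - mean**2)
        if info <= 0:
            raise NonEstimableError("singular information; monotone likelihood")
        delta = score / info
        beta += delta
        if abs(delta) < tol:
            break
    else:
        raise NonEstimableError("Newton iteration did not converge")

    se = 1.0 / np.sqrt(info)
    z = beta / se
    return CoxResult(
        log_hazard_ratio=float(beta),
        hazard_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p_value=float(2 * stats.norm.sf(abs(z))),
        se=float(se),
        n_events=n_events,
        n_iterations=iteration,
    )


def cox_score_test(records: Sequence[SurvivalRecord], high_label: str | None = None) -> float:
    """Cox score test statistic at beta = 0 (equals the log-rank
    statistic when there is no censoring and no tied event times)."""
    times, events = _validate(records)
    groups = [r.group for r in records]
    if high_label is None:
        high_label = sorted(set(groups))[-1]
    x = np.array([1.0 if g == high_label else 0.0 for g in groups])
    score = 0.0
    info = 0.0
    for d, x_dead_sum, x_risk in _risk_set_sums(times, events, x):
        s0 = len(x_risk)
        mean = x_risk.mean()
        score += x_dead_sum - d * mean
        info += d * (x_risk**2).mean() - d * mean**2
    return float(score**2 / info)
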