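"""Survival machinery from first principles.

Kaplan-Meier product-limit estimation, median survival read off the curve,
the two-group log-rank test with hypergeometric moments, and the comparison
of predicted-sensitive vs predicted-resistant strata on PFS and OS that
validates a classifier against the raw (undiscretized) survival outcomes.

Conventions: at tied times, events precede censorings (censored subjects are
still at risk at their censoring time); the log-rank statistic carries no
continuity correction; the median is the earliest event time where S(t)
first reaches 0.5 or below, and is undefined when the curve never gets there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2

__all__ = [
    "SurvivalCurve",
    "SurvivalComparison",
    "km_estimate",
    "km_median",
    "survival_at",
    "logrank_test",
    "compare_predicted_groups",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate over the distinct event times."""

    event_times: np.ndarray    # strictly increasing, events only
    survival_prob: np.ndarray  # S(t) just after each event time
    n_at_risk: np.ndarray      # subjects at risk just before each event time
    n_events: np.ndarray       # events at each time

    def __post_init__(self) -> None:
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(np.diff(self.survival_prob) > 1e-15):
            raise ValueError("survival probabilities must be non-increasing")


def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan-Meier estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise ValueError("empty input")
    if len(t) != len(e):
        raise ValueError("times and events lengths differ")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    n = len(t)
    n_at_risk = np.array([np.sum(t >= et) for et in event_times])
    n_events = np.array([np.sum((t == et) & (e == 1)) for et in event_times])
    surv = np.cumprod(1.0 - n_events / n_at_risk) if len(event_times) else np.array([])
    return SurvivalCurve(event_times, surv, n_at_risk, n_events)


def survival_at(curve: SurvivalCurve, t: float) -> float:
    """S(t) of the step function (1 before the first event)."""
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    return 1.0 if idx < 0 else float(curve.survival_prob[idx])


def km_median(curve: SurvivalCurve) -> float | None:
    """Smallest event time with S(t) <= 0.5; None if never reached."""
    below = np.flatnonzero(curve.survival_prob <= 0.5 + 1e-12)
    return float(curve.event_times[below[0]]) if len(below) else None


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank test.

    At each distinct event time the observed group-A events are compared with
    their hypergeometric expectation d * n_a / n, with variance
    d (n_a/n)(1 - n_a/n)(n - d)/(n - 1); the statistic
    (sum (O - E))^2 / sum V is chi-square with 1 df under the null.  Returns
    (nan, nan) when the total variance is zero (no informative event times).
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("at least one event is required")
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    group_a = np.r_[np.ones(len(ta), dtype=bool), np.zeros(len(tb), dtype=bool)]
    o_minus_e = 0.0
    var = 0.0
    for et in np.unique(all_t[all_e == 1]):
        at_risk = all_t >= et
        n = int(at_risk.sum())
        n_a = int((at_risk & group_a).sum())
        dying = (all_t == et) & (all_e == 1)
        d = int(dying.sum())
        d_a = int((dying & group_a).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var <= 0:
        return float("nan"), float("nan")
    stat = o_minus_e**2 / var
    return float(stat), float(chi2.sf(stat, df=1))


@dataclass
class SurvivalComparison:
    """KM curves, medians and log-rank result for two predicted strata."""

    endpoint: str
    group_labels: tuple[str, str]
    curves: dict[str, SurvivalCurve | None]
    medians: dict[str, float | None]
    group_sizes: dict[str, int]
    logrank_statistic: float
    p_value: float

    @property
    def test_defined(self) -> bool:
        return not math.isnan(self.logrank_statistic)


def compare_predicted_groups(
    model,
    features,
    cohort: Sequence,
    indices: Sequence[int],
    endpoint: str = "pfs",
    threshold: float = 0.5,
) -> SurvivalComparison:
    """Stratify patients by predicted class and compare raw survival curves.

    Patients with predicted probability >= threshold form the
    predicted-sensitive stratum.  The comparison uses the observed
    times/event flags of the chosen endpoint, not the discretized labels.
    If every patient lands in one stratum the comparison is returned with the
    test flagged undefined (NaN statistic).
    """
    from .models import predict_proba  # local import to avoid a cycle

    if endpoint not in ("pfs", "os"):
        raise ValueError("endpoint must be 'pfs' or 'os'")
    if len(indices) == 0:
        raise ValueError("indices must be non-empty")
    proba = predict_proba(model, features, indices)
    labels = ("predicted_sensitive", "predicted_resistant")
    times_attr = f"{endpoint}_months"
    event_attr = f"{endpoint}_event"
    groups: dict[str, tuple[list[float], list[int]]] = {lab: ([], []) for lab in labels}
    for p_hat, i in zip(proba, indices):
        patient = cohort[i]
        lab = labels[0] if p_hat >= threshold else labels[1]
        groups[lab][0].append(getattr(patient, times_attr))
        groups[lab][1].append(getattr(patient, event_attr))
    curves: dict[str, SurvivalCurve | None] = {}
    medians: dict[str, float | None] = {}
    sizes: dict[str, int] = {}
    for lab in labels:
        t, e = groups[lab]
        sizes[lab] = len(t)
        curves[lab] = km_estimate(t, e) if t else None
        medians[lab] = km_median(curves[lab]) if t else None
    if all(sizes[lab] > 0 for lab in labels) and (
        sum(groups[labels[0]][1]) + sum(groups[labels[1]][1]) > 0
    ):
        stat, p = logrank_test(
            groups[labels[0]][0], groups[labels[0]][1],
            groups[labels[1]][0], groups[labels[1]][1],
        )
    else:
        stat, p = float("nan"), float("nan")
    return SurvivalComparison(endpoint, labels, curves, medians, sizes, stat, p)
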