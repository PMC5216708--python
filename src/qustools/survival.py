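"""Recurrence-free-survival comparison: Kaplan-Meier, log-rank, right-tailed t.

The survival comparison asks whether patients predicted to respond have better
recurrence-free survival than predicted non-responders.  The product-limit
(Kaplan-Meier) estimator and the one-degree-of-freedom log-rank test are
implemented directly (they are part of the re-implemented analysis surface);
group-mean comparisons of individual QUS parameters use Student's unpaired
pooled-variance t-test, right-tailed at the 95% level, with Welch's correction
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["SurvivalData", "km_estimate", "logrank_test", "ttest_right"]


@dataclass
class SurvivalData:
    """Follow-up time (months), recurrence indicator and group per patient."""

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        if np.any(self.time < 0):
            raise ValueError("follow-up times must be >= 0")
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have the same length")


def km_estimate(data: SurvivalData) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier product-limit curve.

    Returns ``(times, survival)`` where ``times`` starts at 0 (S=1) and steps
    down at each distinct event time by the factor ``1 - d_i / n_i`` (d_i
    events among n_i at risk).  Censored subjects leave the risk set without
    producing a step.
    """
    order = np.argsort(data.time, kind="stable")
    t = data.time[order]
    e = data.event[order]
    times = [0.0]
    surv = [1.0]
    s = 1.0
    for et in np.unique(t[e]):
        at_risk = np.sum(t >= et)
        d = np.sum((t == et) & e)
        s *= 1.0 - d / at_risk
        times.append(float(et))
        surv.append(float(s))
    return np.array(times), np.array(surv)


def logrank_test(
    time_a: np.ndarray,
    event_a: np.ndarray,
    time_b: np.ndarray,
    event_b: np.ndarray,
) -> tuple[float, float]:
    """Two-group log-rank test -> (chi-square statistic, p-value, 1 df).

    Standard observed-minus-expected summation over distinct event times with
    the hypergeometric variance (handles simultaneous events/ties).
    """
    ta, ea = np.asarray(time_a, float), np.asarray(event_a, bool)
    tb, eb = np.asarray(time_b, float), np.asarray(event_b, bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    event_times = np.unique(all_t[all_e])

    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = all_t >= et
        n_tot = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        d_tot = (all_e & (all_t == et)).sum()
        d_a = (all_e & (all_t == et) & in_a).sum()
        o_minus_e += d_a - d_tot * n_a / n_tot
        if n_tot > 1:
            var += (
                d_tot * (n_a / n_tot) * (1.0 - n_a / n_tot) * (n_tot - d_tot) / (n_tot - 1.0)
            )
    if var == 0.0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def ttest_right(
    group_a: np.ndarray, group_b: np.ndarray, welch: bool = False
) -> tuple[float, float]:
    """Unpaired Student's t-test of mean(A) > mean(B) -> (t statistic, right-tail p).

    Pooled-variance by default; ``welch=True`` drops the equal-variance
    assumption.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need >= 2 observations")
    if welch:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    else:
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
            a.size + b.size - 2
        )
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
        df = a.size + b.size - 2
    p = float(stats.t.sf(t, df))
    return float(t), p
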