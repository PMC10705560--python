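"""Median stratification, Kaplan–Meier estimation, and the log-rank test.

Implements the survival workflow used for expression-stratified cohorts:
subjects are split into high (>= median) and low (< median) covariate
groups, each group's survival is estimated with the product-limit
estimator, and the groups are compared with the log-rank test (observed vs
hypergeometric-expected events at each distinct event time). The k-group
generalization (chi-square with k−1 degrees of freedom) is available for
joint stratifications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from immunosift.io import SurvivalTable, ValidationError

__all__ = ["KMEstimate", "stratify_by_median", "km_estimate", "logrank_test", "logrank_test_k"]


@dataclass
class KMEstimate:
    """Product-limit survival curve: S(t) at each distinct event time."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous; S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def stratify_by_median(covariate) -> np.ndarray:
    """Label each value "high" iff it is at or above the cohort median.

    The median is the standard midpoint of the two central order statistics
    for even n; a value exactly at the median is high (inclusive rule), so
    an all-constant covariate yields all-high labels.
    """
    x = np.asarray(covariate, dtype=float)
    if x.size == 0:
        raise ValidationError("empty covariate")
    med = np.median(x)
    return np.where(x >= med, "high", "low")


def km_estimate(table: SurvivalTable, label: str = "") -> KMEstimate:
    """Kaplan–Meier product-limit estimator.

    Censored subjects leave the risk set after their recorded time; when an
    event and a censoring share a time, the event is counted first (the
    censored subject is still at risk at that event time).
    """
    if len(table) == 0:
        raise ValidationError("empty survival table")
    df = table.df
    time = df["time"].to_numpy()
    event = df["event"].to_numpy()
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    event_times = np.unique(time[event == 1])
    n = len(time)
    at_risk = np.empty(len(event_times), dtype=int)
    d = np.empty(len(event_times), dtype=int)
    surv = np.empty(len(event_times))
    s = 1.0
    for i, t in enumerate(event_times):
        at_risk[i] = int((time >= t).sum())
        d[i] = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d[i] / at_risk[i]
        surv[i] = s
    return KMEstimate(event_times=event_times, survival=surv, at_risk=at_risk, events=d, label=label)


def _logrank_tables(groups: list[SurvivalTable]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-group observed events, expected events and variance terms."""
    times = np.concatenate([g.df["time"].to_numpy() for g in groups])
    events = np.concatenate([g.df["event"].to_numpy() for g in groups])
    gidx = np.concatenate([np.full(len(g.df), i) for i, g in enumerate(groups)])
    if events.sum() == 0:
        raise ValidationError("log-rank test requires at least one event")
    k = len(groups)
    event_times = np.unique(times[events == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros(k)  # variance of O_i - E_i per group (diagonal terms)
    for t in event_times:
        at_risk = times >= t
        n_t = int(at_risk.sum())
        d_t = int(((times == t) & (events == 1)).sum())
        for i in range(k):
            n_it = int((at_risk & (gidx == i)).sum())
            d_it = int(((times == t) & (events == 1) & (gidx == i)).sum())
            O[i] += d_it
            E[i] += d_t * n_it / n_t
            if n_t > 1:
                V[i] += d_t * (n_it / n_t) * (1 - n_it / n_t) * (n_t - d_t) / (n_t - 1)
    return O, E, V


def logrank_test(table_a: SurvivalTable, table_b: SurvivalTable) -> dict:
    """Two-group log-rank test: chi-square = (ΣO−ΣE)² / ΣV, 1 df."""
    O, E, V = _logrank_tables([table_a, table_b])
    if V[0] == 0:
        return {"chi_square": 0.0, "p_value": 1.0, "observed": O, "expected": E}
    chi2 = (O[0] - E[0]) ** 2 / V[0]
    p = float(scipy.stats.chi2.sf(chi2, df=1))
    return {"chi_square": float(chi2), "p_value": p, "observed": O, "expected": E}


def logrank_test_k(tables: list[SurvivalTable]) -> dict:
    """k-group log-rank generalization with k−1 degrees of freedom.

    Uses the standard score statistic with the diagonal variance
    approximation Σ (O_i − E_i)² / E_i for k > 2 (the exact covariance
    inverse reduces to the two-group formula at k = 2, which is special-
    cased through :func:`logrank_test`).
    """
    if len(tables) == 2:
        res = logrank_test(tables[0], tables[1])
        res["df"] = 1
        return res
    O, E, _ = _logrank_tables(tables)
    ok = E > 0
    chi2 = float((((O - E) ** 2)[ok] / E[ok]).sum())
    df = len(tables) - 1
    return {
        "chi_square": chi2,
        "p_value": float(scipy.stats.chi2.sf(chi2, df=df)),
        "observed": O,
        "expected": E,
        "df": df,
    }
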