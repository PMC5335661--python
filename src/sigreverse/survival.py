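"""Biomarker-stratified survival analysis.

A cohort is dichotomized at mean + 1 sample SD of the biomarker ("high"
expressors versus the rest), survival in each stratum is estimated by the
Kaplan-Meier product-limit estimator, and the strata are compared with the
two-group log-rank test (chi-square, 1 df).  The module is agnostic to
event semantics: it consumes a generic (time, event) table with event = 1
for the event of interest and 0 for right censoring.

The estimators are implemented here because downstream reporting needs the
per-time risk-set and event counts and the per-group observed/expected
event totals; tests cross-check both against lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io import SurvivalCohort, ValidationError

__all__ = [
    "KMCurve",
    "LogRankResult",
    "dichotomize_mean_plus_sd",
    "km_estimate",
    "logrank_test",
    "BiomarkerSurvival",
    "SurvivalStratificationResults",
]


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate: a right-continuous,
    non-increasing step function starting at S(0) = 1."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time
    at_risk: np.ndarray     # risk-set size n_i at each event time
    events: np.ndarray      # event count d_i at each event time

    def step_function(self) -> "callable":
        """S as a callable: S(t) = product over event times <= t."""
        def S(t: float) -> float:
            idx = np.searchsorted(self.times, t, side="right")
            return 1.0 if idx == 0 else float(self.survival[idx - 1])
        return S

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "survival": self.survival,
            "at_risk": self.at_risk, "events": self.events,
        })


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p: float
    observed: np.ndarray    # per-group observed event totals
    expected: np.ndarray    # per-group expected event totals
    groups: tuple[str, ...]

    def as_dict(self) -> dict:
        return {
            "chi_square": self.chi_square, "df": self.df, "p": self.p,
            "observed": self.observed.tolist(), "expected": self.expected.tolist(),
            "groups": list(self.groups),
        }


def dichotomize_mean_plus_sd(cohort: SurvivalCohort) -> tuple[pd.Series, float]:
    """Label samples 'high' when biomarker strictly exceeds mean + 1 sample
    SD (n-1 denominator), else 'low'.  Returns (labels, threshold).

    Translation-invariant: adding a constant to every biomarker leaves the
    grouping unchanged.  A zero-SD cohort gets all-'low' with a warning.
    """
    x = cohort.biomarker
    if len(x) < 2:
        raise ValidationError("need >= 2 samples to dichotomize")
    sd = float(np.std(x, ddof=1))
    threshold = float(np.mean(x)) + sd
    if sd == 0.0:
        warnings.warn("biomarker SD is zero: every sample labelled 'low'")
    labels = pd.Series(np.where(x > threshold, "high", "low"),
                       index=cohort.table["id"].values, name="group")
    return labels, threshold


def km_estimate(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Product-limit survival estimate over distinct event times.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i); censored subjects leave the risk
    set just after their censoring time (they count as at-risk at an event
    occurring at the same time).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValidationError("empty cohort")
    if times.size != events.size:
        raise ValueError("times and events must have the same length")
    if (times < 0).any():
        raise ValidationError("negative time")

    order = np.argsort(times, kind="mergesort")
    t_sorted, e_sorted = times[order], events[order]
    n = times.size
    ev_times = np.unique(t_sorted[e_sorted == 1])
    surv, at_risk, d_counts = [], [], []
    s = 1.0
    for t in ev_times:
        n_i = int(np.sum(t_sorted >= t))
        d_i = int(np.sum((t_sorted == t) & (e_sorted == 1)))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        d_counts.append(d_i)
    return KMCurve(
        times=np.asarray(ev_times, dtype=float),
        survival=np.asarray(surv, dtype=float),
        at_risk=np.asarray(at_risk, dtype=int),
        events=np.asarray(d_counts, dtype=int),
    )


def logrank_test(times: np.ndarray, events: np.ndarray,
                 groups: np.ndarray) -> LogRankResult:
    """Two-group log-rank test with pooled handling of tied event times.

    At each distinct event time with d events and n at risk (n1 in group 1),
    the expected group-1 events are d*n1/n with hypergeometric variance
    d*(n1/n)*(1-n1/n)*(n-d)/(n-1); chi_square = (O1-E1)^2 / sum(V), compared
    to chi-square with 1 df.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    if events.sum() == 0:
        raise ValidationError("no events observed in either group")
    g1 = groups == labels[0]
    if g1.all() or (~g1).all():
        raise ValidationError("one group is empty")

    ev_times = np.unique(times[events == 1])
    O1 = E1 = V = 0.0
    obs = np.zeros(2)
    for t in ev_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        dying = (times == t) & (events == 1)
        d = int(dying.sum())
        d1 = int((dying & g1).sum())
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        obs[0] += d1
        obs[1] += d - d1
    total = float(events.sum())
    expected = np.array([E1, total - E1])
    stat = 0.0 if V == 0 else (O1 - E1) ** 2 / V
    p = float(chi2.sf(stat, df=1))
    return LogRankResult(chi_square=float(stat), df=1, p=p,
                         observed=obs, expected=expected,
                         groups=tuple(str(l) for l in labels))


class BiomarkerSurvival:
    """Mean+1SD biomarker stratification with Kaplan-Meier comparison.

    Parameters
    ----------
    cohort
        Per-sample biomarker value, follow-up time and event indicator.
        Time units are whatever the cohort was recorded in; they propagate
        unchanged to the curves.
    """

    def __init__(self, cohort: SurvivalCohort):
        self.cohort = cohort

    @classmethod
    def from_file(cls, path) -> "BiomarkerSurvival":
        from .io import read_survival_table

        return cls(read_survival_table(path))

    def fit(self) -> "SurvivalStratificationResults":
        labels, threshold = dichotomize_mean_plus_sd(self.cohort)
        t, e = self.cohort.time, self.cohort.event
        arr = labels.to_numpy()
        curves: dict[str, KMCurve] = {}
        for g in ("high", "low"):
            mask = arr == g
            if mask.any():
                curves[g] = km_estimate(t[mask], e[mask])
        if len(curves) == 2:
            lr = logrank_test(t, e, arr)
        else:
            warnings.warn("only one stratum is populated; log-rank not computed")
            lr = None
        sizes = {g: int((arr == g).sum()) for g in ("high", "low")}
        return SurvivalStratificationResults(
            model=self, labels=labels, threshold=threshold,
            group_sizes=sizes, curves=curves, logrank=lr,
        )


@dataclass
class SurvivalStratificationResults:
    """Stratified Kaplan-Meier curves with the log-rank comparison."""

    model: BiomarkerSurvival
    labels: pd.Series
    threshold: float
    group_sizes: dict[str, int]
    curves: dict[str, KMCurve]
    logrank: LogRankResult | None

    def as_dict(self) -> dict:
        out = {
            "threshold": self.threshold,
            "threshold_rule": "mean + 1 sample SD (strict >)",
            "group_sizes": self.group_sizes,
            "curves": {g: c.as_frame().to_dict(orient="list") for g, c in self.curves.items()},
        }
        if self.logrank is not None:
            out["logrank"] = self.logrank.as_dict()
        return out

    def summary(self) -> str:
        lines = [
            "Biomarker-stratified survival",
            "=" * 37,
            f"cohort size        {len(self.model.cohort)}",
            f"threshold          mean + 1 SD = {self.threshold:.4g} (strict >)",
            f"group sizes        high={self.group_sizes['high']}, low={self.group_sizes['low']}",
        ]
        if self.logrank is not None:
            lines += [
                f"log-rank chi2 (1 df)  {self.logrank.chi_square:.4g}",
                f"log-rank p            {self.logrank.p:.4g}",
            ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Step plot of the stratified survival curves."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        for g, curve in self.curves.items():
            x = np.concatenate([[0.0], curve.times])
            y = np.concatenate([[1.0], curve.survival])
            ax.step(x, y, where="post",
                    label=f"{g} (n={self.group_sizes[g]})")
        ax.set_xlabel("time")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.05)
        if self.logrank is not None:
            ax.set_title(f"log-rank p = {self.logrank.p:.3g}")
        ax.legend()
        return ax
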