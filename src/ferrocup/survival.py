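"""Kaplan-Meier estimation and log-rank testing for expression-split cohorts.

Cohorts are dichotomized at the median of a continuous covariate (gene
expression): ``high`` strictly above the median, ``low`` at or below it.
Curve fitting and the unweighted log-rank test are delegated to lifelines;
this module adapts them to the pipeline's record containers and adds the
product-limit summaries downstream tables need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .types import SurvivalRecord

__all__ = [
    "KMCurve",
    "LogRankResult",
    "km_fit",
    "logrank_test",
    "dichotomize_by_expression",
    "prognostic_screen",
]


@dataclass
class KMCurve:
    """Product-limit estimate for one group.

    ``table`` has one row per distinct event time with at-risk counts,
    event counts and the survival estimate after that time. Ties between
    events and censorings at the same time count the events first (the
    censored subjects remain in the risk set at their own time).
    """

    group: str
    table: pd.DataFrame  # columns: time, n_at_risk, n_events, survival
    median_survival: float  # inf when S never reaches 0.5

    def survival_at(self, t: float) -> float:
        past = self.table[self.table["time"] <= t]
        return 1.0 if past.empty else float(past["survival"].iloc[-1])


@dataclass
class LogRankResult:
    chi_sq: float
    p: float
    df: int
    group_sizes: dict[str, int]


def km_fit(records: list[SurvivalRecord], group: str = "all") -> KMCurve:
    """Fit the Kaplan-Meier estimator to one group of records."""
    if not records:
        raise ValueError("no survival records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    ev = kmf.event_table
    ev = ev[ev["observed"] > 0]
    table = pd.DataFrame(
        {
            "time": ev.index.to_numpy(dtype=float),
            "n_at_risk": ev["at_risk"].to_numpy(dtype=int),
            "n_events": ev["observed"].to_numpy(dtype=int),
            "survival": kmf.survival_function_.loc[ev.index, "KM_estimate"].to_numpy(),
        }
    )
    median = float(kmf.median_survival_time_)
    return KMCurve(group=group, table=table.reset_index(drop=True), median_survival=median)


def logrank_test(
    records: list[SurvivalRecord], groups: list[str]
) -> LogRankResult:
    """Unweighted two-group log-rank test.

    ``groups`` holds one label per record; exactly two distinct labels are
    required and each group must contribute at least one event.
    """
    if len(records) != len(groups):
        raise ValueError("one group label per record required")
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"log-rank test requires exactly 2 groups, got {labels}")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    mask = np.array([g == labels[0] for g in groups])
    if mask.all() or not mask.any():
        raise ValueError("one group is empty")
    if events[mask].sum() + events[~mask].sum() == 0:
        raise ValueError("no observed events in either group")
    res = _ll_logrank(times[mask], times[~mask], events[mask], events[~mask])
    return LogRankResult(
        chi_sq=float(res.test_statistic),
        p=float(min(1.0, res.p_value)),
        df=1,
        group_sizes={labels[0]: int(mask.sum()), labels[1]: int((~mask).sum())},
    )


def dichotomize_by_expression(
    records: list[SurvivalRecord], quantile: float = 0.5
) -> list[str]:
    """Split subjects into ``high``/``low`` at a covariate quantile.

    ``high`` is strictly above the cut; subjects at the cut go ``low``.
    """
    if len(records) < 4:
        raise ValueError("need >=4 subjects to dichotomize")
    cov = np.array([r.covariate for r in records], dtype=float)
    if np.isnan(cov).any():
        raise ValueError("records lack covariate values")
    if np.ptp(cov) == 0:
        raise ValueError("all covariate values equal; no split possible")
    cut = float(np.quantile(cov, quantile))
    return ["high" if r.covariate > cut else "low" for r in records]


def prognostic_screen(
    expression: pd.DataFrame,
    times: np.ndarray,
    events: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Gene-by-gene median-split log-rank screen.

    ``expression`` is genes x subjects. Returns per-gene chi-square and raw
    p-value with a ``prognostic`` flag at ``alpha``. P-values are reported
    raw (no multiplicity adjustment), and the output notes that, mirroring a
    per-gene screening convention; callers wanting FDR control can feed the
    p column to :func:`ferrocup.stats.bh_adjust`.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    rows = []
    for gene, values in expression.iterrows():
        cov = values.to_numpy(dtype=float)
        if np.ptp(cov) == 0:
            rows.append({"gene_id": gene, "chi_sq": 0.0, "p": 1.0, "prognostic": False})
            continue
        cut = np.median(cov)
        mask = cov > cut
        if mask.all() or not mask.any() or events.sum() == 0:
            rows.append({"gene_id": gene, "chi_sq": 0.0, "p": 1.0, "prognostic": False})
            continue
        res = _ll_logrank(times[mask], times[~mask], events[mask], events[~mask])
        p = float(min(1.0, res.p_value))
        rows.append(
            {
                "gene_id": gene,
                "chi_sq": float(res.test_statistic),
                "p": p,
                "prognostic": p < alpha,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["multiplicity"] = "raw p-values; no FDR control applied"
    return out
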