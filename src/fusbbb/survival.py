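"""Closure "survival" analysis of focal spots.

The per-focus permeable/closed classifications at 0/6/12/20 h are reduced to
an event table (first assessment time at which a focus was closed, or
censoring at 20 h if it never closed), summarized as percent-permeable
curves, and compared between groups with the log-rank (Mantel-Cox) test at
Bonferroni-corrected significance thresholds. Each focal spot is treated as
an independent unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .enhancement import EnhancementRecord

logger = logging.getLogger(__name__)

EVENT_CLOSED = "closed"
EVENT_CENSORED = "censored"


@dataclass(frozen=True)
class SurvivalCurve:
    """Percent of a group's foci still permeable at each assessment time."""

    group: str
    timepoints_h: tuple[float, ...]
    percent_permeable: tuple[float, ...]
    at_risk: tuple[int, ...]

    def as_dict(self) -> dict[float, float]:
        return dict(zip(self.timepoints_h, self.percent_permeable))


@dataclass(frozen=True)
class LogRankResult:
    """Mantel-Cox comparison of two groups' closure-time distributions."""

    chi_square: float
    df: int
    p_value: float
    comparison: str
    significant: bool = False
    threshold: float | None = None


def build_closure_table(
    records: list[EnhancementRecord] | pd.DataFrame,
    group_by_mouse: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Reduce longitudinal classifications to one event row per focus.

    The event time is the first assessment timepoint at which the focus was
    classified closed; a focus still permeable at the last timepoint is
    censored there. Foci not permeable at t=0 (opening failed) are excluded
    with a warning. Re-opening after a closure is logged as an anomaly; the
    first closure stands as the event.

    Returns a table with columns ``mouse, focus, group, event_time_h, event``.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    required = {"mouse", "focus", "timepoint_h", "permeable"}
    if missing := required - set(df.columns):
        raise ValueError(f"records missing columns {sorted(missing)}")

    timepoints = np.sort(df["timepoint_h"].unique())
    rows = []
    for (mouse, focus), g in df.groupby(["mouse", "focus"], sort=True):
        g = g.sort_values("timepoint_h")
        if not np.array_equal(g["timepoint_h"].to_numpy(), timepoints):
            raise ValueError(f"focus {mouse}/{focus} is missing a timepoint")
        flags = g["permeable"].to_numpy(dtype=bool)
        if not flags[0]:
            logger.warning(
                "focus %s/%s not permeable at t=0 (opening failed); excluded",
                mouse,
                focus,
            )
            continue
        closed_idx = np.flatnonzero(~flags[1:])
        if closed_idx.size and flags[1:][closed_idx[0] :].any():
            logger.warning("focus %s/%s re-opened after closure (anomaly)", mouse, focus)
        if closed_idx.size:
            event_time = float(timepoints[1:][closed_idx[0]])
            event = EVENT_CLOSED
        else:
            event_time = float(timepoints[-1])
            event = EVENT_CENSORED
        group = g["group"].iloc[0] if "group" in g else None
        if group_by_mouse is not None:
            group = group_by_mouse.get(str(mouse), group)
        rows.append(
            {
                "mouse": mouse,
                "focus": focus,
                "group": group,
                "event_time_h": event_time,
                "event": event,
            }
        )
    return pd.DataFrame(rows)


def percent_permeable(
    table: pd.DataFrame,
    group: str,
    timepoints_h: tuple[float, ...] = (0.0, 6.0, 12.0, 20.0),
) -> SurvivalCurve:
    """Percent of a group's foci permeable at each assessment timepoint.

    A focus counts as permeable at time t if its closure event lies strictly
    after t, or if it was censored (permeable through the last assessment).
    At t=0 the curve is 100% by construction.
    """
    sub = table[table["group"] == group]
    n = len(sub)
    if n == 0:
        raise ValueError(f"no foci found for group {group!r}")
    event_time = sub["event_time_h"].to_numpy(dtype=float)
    censored = (sub["event"] == EVENT_CENSORED).to_numpy()
    percents, at_risk = [], []
    for t in timepoints_h:
        open_now = censored | (event_time > t)
        percents.append(100.0 * open_now.sum() / n)
        at_risk.append(int((censored | (event_time >= t)).sum()))
    return SurvivalCurve(
        group=group,
        timepoints_h=tuple(timepoints_h),
        percent_permeable=tuple(percents),
        at_risk=tuple(at_risk),
    )


def _events_arrays(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    t = table["event_time_h"].to_numpy(dtype=float)
    observed = (table["event"] == EVENT_CLOSED).to_numpy()
    return t, observed


def logrank_test(
    table_a: pd.DataFrame, table_b: pd.DataFrame, comparison: str = ""
) -> LogRankResult:
    """Mantel-Cox log-rank test between two closure tables.

    At each pooled distinct event time the observed closures in group A are
    compared with the hypergeometric expectation given the at-risk counts;
    chi-square = (sum(O_A - E_A))^2 / sum(V), referred to a chi-square
    distribution with 1 df. Censored foci leave the risk set after the
    events at their censoring time.
    """
    if len(table_a) == 0 or len(table_b) == 0:
        raise ValueError("both groups must be non-empty")
    ta, oa = _events_arrays(table_a)
    tb, ob = _events_arrays(table_b)
    if not (oa.any() or ob.any()):
        raise ValueError("no closure events in either group")

    event_times = np.unique(np.concatenate([ta[oa], tb[ob]]))
    num = 0.0
    var = 0.0
    for t in event_times:
        # at risk: event or censoring time >= t
        n_a = float((ta >= t).sum())
        n_b = float((tb >= t).sum())
        n = n_a + n_b
        d_a = float(((ta == t) & oa).sum())
        d_b = float(((tb == t) & ob).sum())
        d = d_a + d_b
        if n <= 1 or d == 0:
            continue
        e_a = d * n_a / n
        v = d * (n_a / n) * (1.0 - n_a / n) * (n - d) / (n - 1.0)
        num += d_a - e_a
        var += v
    if var == 0.0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = num * num / var
        p = float(sps.chi2.sf(chi2, df=1))
    return LogRankResult(chi_square=float(chi2), df=1, p_value=p, comparison=comparison)


def bonferroni_threshold(alpha: float, n_comparisons: int) -> float:
    """Corrected per-comparison significance threshold, alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha / n_comparisons


def compare_all_groups(
    table: pd.DataFrame,
    comparisons: list[tuple[str, str]],
    alpha: float = 0.05,
) -> list[LogRankResult]:
    """Pairwise log-rank tests at the Bonferroni-corrected threshold.

    Each of the requested pairs is tested individually; a pair is flagged
    significant iff p < alpha / len(comparisons).
    """
    if not comparisons:
        raise ValueError("comparisons must be non-empty")
    groups = set(table["group"].unique())
    threshold = bonferroni_threshold(alpha, len(comparisons))
    results = []
    for a, b in comparisons:
        for g in (a, b):
            if g not in groups:
                raise ValueError(f"unknown group {g!r} in comparison ({a}, {b})")
        res = logrank_test(
            table[table["group"] == a],
            table[table["group"] == b],
            comparison=f"{a} vs {b}",
        )
        results.append(
            LogRankResult(
                chi_square=res.chi_square,
                df=res.df,
                p_value=res.p_value,
                comparison=res.comparison,
                significant=res.p_value < threshold,
                threshold=threshold,
            )
        )
    return results
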