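"""Kaplan-Meier overall-survival estimation and log-rank comparison.

Status coding follows the clinical tables: "deceased" is an event,
"living" is censored, and patients with unknown status or missing time are
excluded upstream with a logged count. Ties of events and censorings at
the same time follow the standard convention (events first, censored
records still at risk at their own time). Medians are the smallest event
time at which the survival curve falls to 0.5 or below, undefined if the
curve never reaches 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger(__name__)


def survival_input(clin: pd.DataFrame, groups: pd.DataFrame | pd.Series | None = None) -> pd.DataFrame:
    """Build the (patient_id, time, event, group) frame from a clinical
    table, excluding unknown-status / missing-time patients with a log.

    ``groups`` is an assignment frame (patient_id, label) or a Series
    indexed by patient_id; omitted, all patients share one group.
    """
    df = clin.drop_duplicates(subset="patient_id")[["patient_id", "os_months", "os_status"]].copy()
    known = df["os_status"].isin(["deceased", "living"]) & df["os_months"].notna()
    n_excluded = int((~known).sum())
    if n_excluded:
        logger.info("survival_input: excluded %d patients without usable survival data", n_excluded)
    df = df.loc[known].copy()
    df["time"] = df["os_months"].astype(float)
    if (df["time"] < 0).any():
        raise ValueError("negative survival times")
    df["event"] = (df["os_status"] == "deceased").astype(int)
    if groups is None:
        df["group"] = "all"
    else:
        if isinstance(groups, pd.DataFrame):
            groups = groups.set_index("patient_id")["label"]
        df["group"] = df["patient_id"].map(groups)
    out = df[["patient_id", "time", "event", "group"]].reset_index(drop=True)
    out.attrs["n_excluded"] = n_excluded
    return out


@dataclass
class KMCurve:
    """Product-limit curve evaluated at the distinct event times."""

    event_times: np.ndarray  # increasing, distinct times with >=1 event
    survival: np.ndarray  # S(t) at each event time, non-increasing
    at_risk: np.ndarray  # n at risk just before each event time
    n_events: np.ndarray  # events at each event time
    n: int  # subjects
    median: float | None  # months, None if S never reaches 0.5

    def survival_at(self, t: float) -> float:
        """Step-function evaluation; S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate S(t) = prod (1 - d_i/n_i).

    Censored-at-event-time subjects count as at risk at that time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("need at least one record")
    if (times < 0).any():
        raise ValueError("negative survival times")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    has_event = table["observed"] > 0
    event_times = table.index.to_numpy(dtype=float)[has_event]
    at_risk = table["at_risk"].to_numpy(dtype=float)[has_event].astype(int)
    n_events = table["observed"].to_numpy(dtype=float)[has_event].astype(int)
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    curve = KMCurve(
        event_times=event_times,
        survival=surv,
        at_risk=at_risk,
        n_events=n_events,
        n=len(times),
        median=None,
    )
    curve.median = median_survival(curve)
    return curve


def median_survival(curve: KMCurve) -> float | None:
    """Smallest event time with S(t) <= 0.5; None if never reached."""
    below = curve.survival <= 0.5 + 1e-12
    if not below.any():
        return None
    return float(curve.event_times[np.argmax(below)])


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p_value: float
    groups: tuple[str, ...]


def logrank(groups: dict[str, pd.DataFrame]) -> LogrankResult:
    """k-group log-rank chi-squared test (df = k - 1).

    ``groups`` maps label -> frame with ``time`` and ``event`` columns.
    Empty groups are dropped with a warning.
    """
    usable = {k: v for k, v in groups.items() if len(v) > 0}
    dropped = set(groups) - set(usable)
    if dropped:
        logger.warning("logrank: dropped empty groups %s", sorted(dropped))
    if len(usable) < 2:
        raise ValueError("log-rank test needs at least two non-empty groups")
    frames = []
    for label, df in usable.items():
        frames.append(pd.DataFrame({"time": df["time"], "event": df["event"], "group": label}))
    data = pd.concat(frames, ignore_index=True)
    res = multivariate_logrank_test(data["time"], data["group"], data["event"])
    return LogrankResult(
        statistic=float(res.test_statistic),
        df=len(usable) - 1,
        p_value=float(res.p_value),
        groups=tuple(sorted(usable)),
    )


def survival_by_group(data: pd.DataFrame) -> tuple[pd.DataFrame, LogrankResult | None]:
    """Per-group KM curves (long table) plus the log-rank comparison.

    ``data`` is the output of :func:`survival_input`. The log-rank result
    is None when fewer than two groups have subjects.
    """
    rows = []
    groups = {}
    for label, block in data.groupby("group", sort=True):
        groups[str(label)] = block
        curve = km_estimate(block["time"], block["event"])
        for t, s, r, d in zip(curve.event_times, curve.survival, curve.at_risk, curve.n_events):
            rows.append(
                {
                    "group": label,
                    "time": t,
                    "survival": s,
                    "at_risk": r,
                    "n_events": d,
                    "n_group": curve.n,
                    "median": curve.median if curve.median is not None else np.nan,
                }
            )
    curves = pd.DataFrame(rows)
    test = None
    if sum(len(v) > 0 for v in groups.values()) >= 2:
        test = logrank(groups)
    return curves, test
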