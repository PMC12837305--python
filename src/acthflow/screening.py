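"""ROUT outlier screening and the animal-level exclusion rules.

Screening runs per equid type per sampling event.  Because each event is a
single batch of measurements, the "robust regression" step of ROUT reduces to
an intercept-only robust fit: a Tukey-bisquare M-estimate of location.  The
robust SD of residuals (RSDR) is the 68.27th percentile of absolute
residuals with an n/(n-1) small-sample correction; two-sided p-values come
from a t distribution with n-1 df, and outliers are called by a step-up
false-discovery procedure at rate q (default 1%).

Month-level propagation: if any sampling event of a month is flagged for an
animal, the whole month counts as an outlier month (the month is the unit of
analysis).  Animals are then classified:

* ``outlier_suspected_ppid`` - >= 3 outlier months within a single period
  (configurable to >= 3 pooled across periods);
* ``insufficient_data``       - >= 3 calendar months without a measurement;
* ``apparently_healthy``      - everyone else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calendar import CALENDAR, PERIOD_EARLY, PERIOD_MID, get_event, month_key
from .cohort import CohortTable

OUTLIER = "outlier_suspected_ppid"
INSUFFICIENT = "insufficient_data"
HEALTHY = "apparently_healthy"

BISQUARE_C = 4.685        # 95% Gaussian efficiency
RSDR_PERCENTILE = 68.27
MIN_EVENT_N = 3


@dataclass
class EventScreen:
    """Per-(type, event) screening result."""
    equid_type: str
    event: str
    n: int
    robust_center: float
    rsdr: float
    flags: np.ndarray               # bool per input value
    p_values: np.ndarray
    thresholds: np.ndarray          # step-up threshold per sorted rank, in input order
    screenable: bool = True
    degenerate: bool = False


@dataclass
class ScreeningOutcome:
    month_flags: pd.DataFrame       # equid_id, month, period(s) of the flagged events
    missing_months: pd.Series       # per-animal count of months without ACTH
    classification: pd.Series       # per-animal class
    event_screens: list = field(default_factory=list)
    exclusion_report: pd.DataFrame | None = None


def biweight_location(values: np.ndarray, c: float = BISQUARE_C,
                      tol: float = 1e-8, max_iter: int = 100) -> float:
    """Tukey-bisquare M-estimate of location (IRLS from the median).

    The residual scale is held at 1.4826*MAD of the input, which makes the
    estimate scale-equivariant; convergence when the centre moves by less
    than ``tol`` relative to max(|centre|, scale).
    """
    x = np.asarray(values, dtype=float)
    center = float(np.median(x))
    scale = 1.4826 * float(np.median(np.abs(x - center)))
    if scale == 0.0:
        return center
    for _ in range(max_iter):
        u = (x - center) / (c * scale)
        w = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
        if w.sum() == 0.0:
            break
        new = float((w * x).sum() / w.sum())
        done = abs(new - center) <= tol * max(abs(center), scale)
        center = new
        if done:
            break
    return center


def _step_up_flags(p: np.ndarray, q: float) -> tuple[np.ndarray, np.ndarray]:
    """FDR step-up scan: flag the largest prefix of sorted p with p_(i) <= q*i/n."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    thr_sorted = q * np.arange(1, n + 1) / n
    passed = p[order] <= thr_sorted
    flags = np.zeros(n, dtype=bool)
    if passed.any():
        k = int(np.max(np.nonzero(passed)[0]))
        flags[order[:k + 1]] = True
    thresholds = np.empty(n)
    thresholds[order] = thr_sorted
    return flags, thresholds


def rout_flag_event(values, q: float = 0.01, equid_type: str = "", event: str = "") -> EventScreen:
    """Apply the ROUT call to one event's measurements.

    Events with fewer than 3 values are unscreenable (no flags); identical
    values give RSDR = 0 and a degenerate, flag-free result.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < MIN_EVENT_N:
        return EventScreen(equid_type, event, n, float("nan"), float("nan"),
                           np.zeros(n, bool), np.ones(n), np.ones(n), screenable=False)
    center = biweight_location(x)
    resid = x - center
    rsdr = float(np.percentile(np.abs(resid), RSDR_PERCENTILE)) * n / (n - 1)
    if rsdr == 0.0:
        warnings.warn(f"degenerate event ({equid_type}, {event}): zero RSDR, no flags",
                      stacklevel=2)
        return EventScreen(equid_type, event, n, center, 0.0,
                           np.zeros(n, bool), np.ones(n), np.ones(n), degenerate=True)
    t = np.abs(resid) / rsdr
    p = 2.0 * stats.t.sf(t, df=n - 1)
    flags, thresholds = _step_up_flags(p, q)
    return EventScreen(equid_type, event, n, center, rsdr, flags, p, thresholds)


def pre_enrollment_filter(values: pd.Series, threshold_pg_ml: float = 40.0):
    """Pre-enrollment screen: animals whose value strictly exceeds the
    threshold are excluded.  Missing values keep the animal, with a warning.

    Parameters
    ----------
    values : Series indexed by equid_id (one pre-enrollment ACTH per animal).
    """
    missing = values.index[values.isna()].tolist()
    if missing:
        warnings.warn(f"no pre-enrollment ACTH for {len(missing)} animal(s); kept: {missing}",
                      stacklevel=2)
    excluded = values.index[values > threshold_pg_ml].tolist()
    kept = [a for a in values.index if a not in set(excluded)]
    reasons = pd.DataFrame({
        "equid_id": excluded,
        "reason": [f"pre-enrollment ACTH {values[a]:g} pg/mL > {threshold_pg_ml:g}"
                   for a in excluded],
    })
    return kept, excluded, reasons


def propagate_to_month(record_flags: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-record flags to per-animal outlier months.

    A month is flagged for an animal iff any of that animal's measurements in
    the month's event(s) was flagged.  Each flagged month remembers the
    period(s) of the event(s) that triggered it (August can belong to either
    period depending on the flagged half).

    Parameters
    ----------
    record_flags : DataFrame with columns equid_id, event, flagged (bool).
    """
    flagged = record_flags[record_flags["flagged"]].copy()
    if flagged.empty:
        return pd.DataFrame(columns=["equid_id", "month", "periods"])
    flagged["month"] = flagged["event"].map(month_key)
    flagged["period"] = flagged["event"].map(lambda e: get_event(e).period)
    out = (flagged.groupby(["equid_id", "month"])["period"]
           .agg(lambda s: frozenset(s)).reset_index()
           .rename(columns={"period": "periods"}))
    return out


def classify_animal(flagged_months: pd.DataFrame, missing_month_count: int,
                    rule: str = "per-period", min_outlier_months: int = 3,
                    min_missing_months: int = 3) -> str:
    """Three-way classification of one animal.

    ``rule='per-period'`` (default): outlier iff >= ``min_outlier_months``
    flagged months fall within a single period.  ``rule='total'``: pooled
    count across periods.
    """
    if rule not in ("per-period", "total"):
        raise ValueError(f"unknown classification rule {rule!r}")
    n_flagged = len(flagged_months)
    if rule == "total":
        is_outlier = n_flagged >= min_outlier_months
    else:
        per_period = {PERIOD_MID: 0, PERIOD_EARLY: 0}
        for periods in flagged_months.get("periods", ()):
            for p in periods:
                per_period[p] += 1
        is_outlier = max(per_period.values()) >= min_outlier_months
    if is_outlier:
        return OUTLIER
    if missing_month_count >= min_missing_months:
        return INSUFFICIENT
    return HEALTHY


def count_missing_months(cohort: CohortTable) -> pd.Series:
    """Months (of the 12 study months) in which an animal has no measurement."""
    months = sorted({month_key(e) for e in CALENDAR})
    present = (cohort.data.dropna(subset=["acth_pg_ml"])
               .assign(month=lambda d: d["event"].map(month_key))
               .groupby("equid_id")["month"].agg(lambda s: len(set(s))))
    animals = cohort.animals.index
    present = present.reindex(animals).fillna(0).astype(int)
    return (len(months) - present).rename("missing_months")


def screen_cohort(cohort: CohortTable, q: float = 0.01, rule: str = "per-period"):
    """Full screening stage: ROUT per type x event, month propagation,
    classification, and removal of non-healthy animals.

    Returns ``(outcome, analyzable)`` where ``analyzable`` is the cohort
    restricted to apparently healthy animals.
    """
    data = cohort.data
    screens, flag_rows = [], []
    for etype, group in data.groupby("equid_type"):
        if group["acth_pg_ml"].notna().sum() == 0:
            warnings.warn(f"equid type {etype!r} has no measurements; group skipped",
                          stacklevel=2)
            continue
        for label, ev_data in group.groupby("event"):
            present = ev_data.dropna(subset=["acth_pg_ml"])
            if present.empty:
                continue
            screen = rout_flag_event(present["acth_pg_ml"].to_numpy(), q=q,
                                     equid_type=etype, event=label)
            screens.append(screen)
            for eid, fl in zip(present["equid_id"], screen.flags):
                flag_rows.append((eid, label, bool(fl)))

    record_flags = pd.DataFrame(flag_rows, columns=["equid_id", "event", "flagged"])
    month_flags = propagate_to_month(record_flags)
    missing = count_missing_months(cohort)

    classes = {}
    for aid in cohort.animals.index:
        mf = month_flags[month_flags["equid_id"] == aid]
        classes[aid] = classify_animal(mf, int(missing[aid]), rule=rule)
    classification = pd.Series(classes, name="classification")

    flagged_month_str = (month_flags.groupby("equid_id")["month"]
                         .agg(lambda s: ";".join(sorted(s))))
    report = pd.DataFrame({
        "equid_id": classification.index,
        "class": classification.values,
        "flagged_months": flagged_month_str.reindex(classification.index).fillna(""),
        "missing_months": missing.reindex(classification.index).values,
    })
    report = report[report["class"] != HEALTHY].reset_index(drop=True)

    outcome = ScreeningOutcome(month_flags=month_flags, missing_months=missing,
                               classification=classification,
                               event_screens=screens, exclusion_report=report)
    healthy = classification.index[classification == HEALTHY]
    return outcome, cohort.subset_animals(healthy)
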