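"""Descriptive summary surfaces: per-event statistics, cohort composition,
and per-event marginal means with t-based 95% confidence intervals."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .calendar import EVENT_LABELS
from .cohort import CohortTable


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Display rounding: round half away from zero (so 14.35 -> 14.4)."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return float("nan")
    exp = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(exp, rounding=ROUND_HALF_UP))


def summarize_events(cohort: CohortTable) -> pd.DataFrame:
    """Per equid_type x event: n, mean, sd, median, min, q1, q3, max.

    Quartiles use linear interpolation between order statistics; sd is the
    n-1 sample SD.  A single observation reports sd = 0 with ``sd_defined``
    False; events with no data keep n = 0 and NaN statistics (the published
    table prints these as "ND").  Raw precision is kept; display rounding is
    the caller's concern (see :func:`round_half_away`).
    """
    grouped = {k: g for k, g in cohort.data.groupby(["equid_type", "event"])}
    rows = []
    for etype in sorted(set(cohort.data["equid_type"])):
        for label in EVENT_LABELS:
            grp = grouped.get((etype, label))
            v = (grp["acth_pg_ml"].dropna().to_numpy() if grp is not None
                 else np.empty(0))
            n = len(v)
            if n == 0:
                rows.append((etype, label, 0, *([np.nan] * 7), False))
                continue
            sd = float(np.std(v, ddof=1)) if n > 1 else 0.0
            rows.append((etype, label, n, float(np.mean(v)), sd, float(np.median(v)),
                         float(np.min(v)), float(np.percentile(v, 25)),
                         float(np.percentile(v, 75)), float(np.max(v)), n > 1))
    out = pd.DataFrame(rows, columns=["equid_type", "event", "n", "mean", "sd",
                                      "median", "min", "q1", "q3", "max", "sd_defined"])
    out["event"] = pd.Categorical(out["event"], categories=EVENT_LABELS, ordered=True)
    return out.sort_values(["equid_type", "event"]).reset_index(drop=True)


def cohort_composition(enrolled: CohortTable, analyzed: CohortTable) -> pd.DataFrame:
    """Counts and within-type percentages by type x {location, sex, age_class}
    for the enrolled and analyzed cohorts (percentages rounded to integers)."""
    enr, ana = enrolled.animals, analyzed.animals
    stray = set(ana.index) - set(enr.index)
    if stray:
        raise ValueError(f"analyzed animals absent from enrolled cohort: {sorted(stray)}")

    rows = []
    for etype in sorted(set(enr["equid_type"])):
        e_grp = enr[enr["equid_type"] == etype]
        a_grp = ana[ana["equid_type"] == etype]
        for var in ("location", "sex", "age_class"):
            levels = sorted(set(e_grp[var]) | set(a_grp[var]))
            for lev in levels:
                ne = int((e_grp[var] == lev).sum())
                na = int((a_grp[var] == lev).sum())
                rows.append({
                    "equid_type": etype, "variable": var, "level": lev,
                    "enrolled_n": ne,
                    "enrolled_pct": round_half_away(100 * ne / len(e_grp), 0) if len(e_grp) else 0.0,
                    "analyzed_n": na,
                    "analyzed_pct": round_half_away(100 * na / len(a_grp), 0) if len(a_grp) else 0.0,
                })
    return pd.DataFrame(rows)


def event_marginal_means(cohort: CohortTable, conf: float = 0.95) -> pd.DataFrame:
    """Raw per-type x event means with t-based confidence intervals.

    Half-width is t_{n-1,(1+conf)/2} * sd / sqrt(n); omitted (NaN) for n < 2.
    These are simple group means; model-based marginal means live in the
    mixed-model stage and are labelled separately.
    """
    summ = summarize_events(cohort)
    half = np.full(len(summ), np.nan)
    ok = summ["n"] >= 2
    tcrit = stats.t.ppf((1 + conf) / 2, summ.loc[ok, "n"] - 1)
    half[ok.to_numpy()] = tcrit * summ.loc[ok, "sd"] / np.sqrt(summ.loc[ok, "n"])
    out = summ[["equid_type", "event", "n", "mean"]].copy()
    out["ci_half_width"] = half
    out["ci_lb"] = out["mean"] - half
    out["ci_ub"] = out["mean"] + half
    return out
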