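"""Synthetic seasonal ACTH cohorts with the study's statistical structure.

The generative model is lognormal on the measurement scale, matching the
downstream analysis which models ln(ACTH):

    ln(ACTH)_{i,e} = profile[type(i), e] + b_i + m_e + l_{loc(i)} + eps_{i,e}

with independent zero-mean normal animal intercepts ``b_i`` (SD ``sd_id``),
per-event effects ``m_e`` (period-specific SD), location effects and residual
noise (period-specific SD).  The default profile is the natural log of the
published per-event medians (the lognormal median is exp of the ln-scale
location); default variance components come from the period-split mixed
models of the source cohort.

PPID-like outlier animals are injected multiplicatively.  The default
inflation is 20x with chronic (all-event) elevation: the extreme measurements
observed in the real cohort ran ~20x and more above their event medians
(1054 vs 53.2 pg/mL; 1250 vs 13.4 pg/mL), and pituitary dysfunction elevates
baseline ACTH year-round.  Animals with insufficient data are emulated by
blanking whole calendar months.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._tables import ANALYZED_GROUP_SIZES, COMPOSITION, EQUID_TYPES, default_ln_profile
from .calendar import CALENDAR, PERIOD_EARLY, PERIOD_MID, month_key
from .cohort import CohortTable, age_class_of

CLEAN = "clean"
INJECTED_OUTLIER = "injected_outlier"
INSUFFICIENT_DATA = "insufficient_data"

_ID_PREFIX = {"standard": "S", "miniature": "M", "hybrid": "H"}


@dataclass
class SyntheticConfig:
    """Study-condition defaults for the cohort generator."""

    group_sizes: dict = field(default_factory=lambda: dict(ANALYZED_GROUP_SIZES))
    seasonal_profile: dict = field(default_factory=default_ln_profile)
    sd_id: float = 0.32
    sd_month: dict = field(default_factory=lambda: {PERIOD_MID: 0.13, PERIOD_EARLY: 0.41})
    sd_location: float = 2e-5
    sd_resid: dict = field(default_factory=lambda: {PERIOD_MID: 0.42, PERIOD_EARLY: 0.53})
    n_outlier_animals: int = 0
    outlier_animals: list | None = None      # explicit ids override n_outlier_animals
    outlier_inflation: float = 20.0          # multiplicative ACTH factor
    outlier_period: str | None = None        # None = chronic elevation in all events
    n_outlier_months: int | None = None      # None = every month of the chosen scope
    missing_month_counts: dict = field(default_factory=dict)  # equid_id -> months blanked
    seed: int = 0

    def __post_init__(self):
        for t, n in self.group_sizes.items():
            if t not in EQUID_TYPES:
                raise ValueError(f"unknown equid type {t!r}")
            if n < 1:
                raise ValueError(f"group size for {t!r} must be >= 1, got {n}")
        if self.sd_id < 0 or self.sd_location < 0:
            raise ValueError("standard deviations must be >= 0")
        if any(v < 0 for v in self.sd_month.values()) or any(v < 0 for v in self.sd_resid.values()):
            raise ValueError("standard deviations must be >= 0")
        if self.outlier_inflation <= 1:
            raise ValueError("outlier_inflation must be > 1")

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


def _apportion(weights: dict, n: int) -> list:
    """Largest-remainder apportionment of n items over weighted categories."""
    total = sum(weights.values())
    quotas = {k: n * v / total for k, v in weights.items()}
    counts = {k: int(q) for k, q in quotas.items()}
    rem = n - sum(counts.values())
    order = sorted(weights, key=lambda k: (quotas[k] - counts[k], weights[k]), reverse=True)
    for k in order[:rem]:
        counts[k] += 1
    return [k for k in weights for _ in range(counts[k])]


def _animal_frame(config: SyntheticConfig) -> pd.DataFrame:
    """Animal roster with the study's marginal composition per group.

    Attribute lists are shuffled independently within each group (seeded) so
    that location, sex and age class are not artificially correlated with
    each other or with animal order."""
    rng = np.random.default_rng([int(config.seed), 303])
    rows = []
    for etype in EQUID_TYPES:
        n = config.group_sizes.get(etype, 0)
        if n == 0:
            continue
        comp = COMPOSITION[etype]["analyzed"]
        locs = list(rng.permutation(_apportion(comp["location"], n)))
        sexes = list(rng.permutation(_apportion(comp["sex"], n)))
        ages_cls = list(rng.permutation(_apportion(comp["age_class"], n)))
        ny, ns = 0, 0
        for i in range(n):
            if ages_cls[i] == "young":
                age = 3 + (ny % 13)
                ny += 1
            else:
                age = 16 + (ns % 10)
                ns += 1
            rows.append({
                "equid_id": f"{_ID_PREFIX[etype]}{i + 1:02d}",
                "equid_type": etype, "location": locs[i], "sex": sexes[i],
                "age_years": float(age), "age_class": age_class_of(age),
            })
    return pd.DataFrame(rows)


def _plan(config: SyntheticConfig):
    """Deterministic injection plan: outlier animals, inflated events, blanked months."""
    animals = _animal_frame(config)
    rng = np.random.default_rng([int(config.seed), 101])

    missing = {k: int(v) for k, v in config.missing_month_counts.items()}
    months = sorted({month_key(e) for e in CALENDAR})
    blanked = {aid: sorted(rng.choice(months, size=min(k, 12), replace=False))
               for aid, k in missing.items() if k > 0}

    if config.outlier_animals is not None:
        out_ids = list(config.outlier_animals)
    else:
        # round-robin across types (largest group first), from the end of each
        # group so injected animals do not collide with blanked ones by default
        pools = {t: [a for a in animals.loc[animals.equid_type == t, "equid_id"][::-1]
                     if a not in blanked]
                 for t in EQUID_TYPES}
        order = sorted(config.group_sizes, key=config.group_sizes.get, reverse=True)
        out_ids, i = [], 0
        while len(out_ids) < config.n_outlier_animals:
            t = order[i % len(order)]
            if pools[t]:
                out_ids.append(pools[t].pop(0))
            i += 1
            if i > 1000:
                raise ValueError("not enough animals to inject the requested outliers")

    if config.outlier_period is None:
        scope = list(CALENDAR)  # chronic elevation
    else:
        scope = [e for e in CALENDAR if e.period == config.outlier_period]
    if config.n_outlier_months is not None:
        chosen_months = []
        for e in scope:
            if month_key(e) not in chosen_months:
                chosen_months.append(month_key(e))
            if len(chosen_months) == config.n_outlier_months:
                break
        scope = [e for e in scope if month_key(e) in chosen_months]
    inflated_events = {aid: [e.label for e in scope] for aid in out_ids}

    return animals, inflated_events, blanked


def generate_cohort(config: SyntheticConfig) -> CohortTable:
    """Draw one cohort; fully reproducible from ``config.seed``."""
    animals, inflated_events, blanked = _plan(config)
    rng = np.random.default_rng([int(config.seed), 202])

    n_animals = len(animals)
    b = rng.normal(0.0, config.sd_id, n_animals) if config.sd_id > 0 else np.zeros(n_animals)
    loc_levels = sorted(animals["location"].unique())
    l_loc = dict(zip(loc_levels,
                     rng.normal(0.0, config.sd_location, len(loc_levels))
                     if config.sd_location > 0 else np.zeros(len(loc_levels))))
    m = {e.label: (rng.normal(0.0, config.sd_month[e.period])
                   if config.sd_month[e.period] > 0 else 0.0)
         for e in CALENDAR}

    rows = []
    for i, a in animals.iterrows():
        infl = set(inflated_events.get(a.equid_id, ()))
        gone = set(blanked.get(a.equid_id, ()))
        for e in CALENDAR:
            sd_e = config.sd_resid[e.period]
            eps = rng.normal(0.0, sd_e) if sd_e > 0 else 0.0
            ln_y = (config.seasonal_profile[(a.equid_type, e.label)]
                    + b[i] + m[e.label] + l_loc[a.location] + eps)
            y = float(np.exp(ln_y))
            if e.label in infl:
                y *= config.outlier_inflation
            if month_key(e) in gone:
                y = np.nan
            rows.append((a.equid_id, a.equid_type, a.location, a.sex,
                         a.age_years, a.age_class, e.label, None, y))
    df = pd.DataFrame(rows, columns=["equid_id", "equid_type", "location", "sex",
                                     "age_years", "age_class", "event",
                                     "collection_date", "acth_pg_ml"])
    return CohortTable(df, provenance="synthetic")


def truth_table(config: SyntheticConfig) -> pd.DataFrame:
    """Ground-truth animal labels implied by the injection plan.

    ``injected_outlier`` takes precedence over ``insufficient_data``; animals
    with >= 3 blanked months and no injection are ``insufficient_data``.
    """
    animals, inflated_events, blanked = _plan(config)
    labels = []
    for aid in animals["equid_id"]:
        if aid in inflated_events:
            labels.append(INJECTED_OUTLIER)
        elif len(blanked.get(aid, ())) >= 3:
            labels.append(INSUFFICIENT_DATA)
        else:
            labels.append(CLEAN)
    return pd.DataFrame({"equid_id": animals["equid_id"], "truth": labels})


def study_default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The study conditions: analyzed group sizes 19/14/28, published profile
    and variance components, no injected pathology unless requested."""
    return SyntheticConfig(seed=seed, **overrides)
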