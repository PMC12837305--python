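"""Simulation studies that validate the pipeline's operating characteristics.

Each function runs a self-contained, seeded experiment and returns plain
numbers: false-discovery control and contaminant detection of the ROUT
screen, animal-level sensitivity/specificity of the exclusion rules,
parameter recovery and bootstrap-CI coverage of the reference-limit
estimator, the type-I error of the normality test, and sign/variance
recovery of the period-split mixed models on study-parameterized cohorts.
The analysis drivers, the test suite and the acceptance script all call
these with their own problem sizes.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .calendar import PERIOD_EARLY, PERIOD_MID
from .mixedmodel import fit_period_model
from .reflimits import _url_back_transformed, bootstrap_ci
from .screening import HEALTHY, rout_flag_event, screen_cohort
from .simulate import CLEAN, generate_cohort, study_default_config, truth_table


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible sub-seeds (< 2^31) derived from one master seed."""
    return np.array([int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0]
                         % (2 ** 31)) for i in range(n)])


# -- ROUT operating characteristics ------------------------------------------

def rout_false_flag_rate(n_events: int = 10_000, n: int = 20, q: float = 0.01,
                         seed: int = 0) -> float:
    """Fraction of clean Gaussian events with at least one outlier call."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_events):
        x = rng.normal(50.0, 10.0, n)
        hits += bool(rout_flag_event(x, q=q).flags.any())
    return hits / n_events


def rout_contaminant_detection(n_events: int = 2_000, n: int = 20,
                               shift_sd: float = 10.0, q: float = 0.01,
                               seed: int = 1) -> float:
    """Detection rate of a single contaminant displaced by ``shift_sd`` SDs."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_events):
        x = rng.normal(50.0, 10.0, n)
        x[0] = 50.0 + shift_sd * 10.0
        hits += bool(rout_flag_event(x, q=q).flags[0])
    return hits / n_events


# -- exclusion rules ----------------------------------------------------------

DEFAULT_MISSING = {"S01": 3, "M01": 4, "H01": 3}


def screening_operating_characteristics(n_seeds: int = 100, n_outliers: int = 5,
                                        missing: dict | None = None,
                                        seed: int = 0) -> dict:
    """Animal-level sensitivity and specificity of ``screen_cohort`` on
    study-default cohorts with injected PPID-like animals and blanked months."""
    missing = DEFAULT_MISSING if missing is None else missing
    sens, spec, exact = [], [], 0
    for s in _child_seeds(seed, n_seeds):
        cfg = study_default_config(seed=int(s), n_outlier_animals=n_outliers,
                                   missing_month_counts=missing)
        truth = truth_table(cfg).set_index("equid_id")["truth"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            outcome, _ = screen_cohort(generate_cohort(cfg))
        removed = set(outcome.classification.index[outcome.classification != HEALTHY])
        should = set(truth.index[truth != CLEAN])
        clean = set(truth.index[truth == CLEAN])
        sens.append(len(removed & should) / len(should) if should else 1.0)
        spec.append(1.0 - len(removed & clean) / len(clean))
        exact += removed == should
    return {"sensitivity": float(np.mean(sens)), "specificity": float(np.mean(spec)),
            "exact_removal_fraction": exact / n_seeds, "n_seeds": n_seeds}


# -- reference limits ---------------------------------------------------------

def url_recovery(n_reps: int = 200, n: int = 200, mu: float = 3.0,
                 sigma: float = 0.5, coverage: float = 0.95, seed: int = 0) -> dict:
    """Back-transformed URL vs the true 97.5th percentile of a lognormal."""
    rng = np.random.default_rng(seed)
    true = float(np.exp(mu + sigma * stats.norm.ppf((1 + coverage) / 2)))
    urls = [_url_back_transformed(np.exp(rng.normal(mu, sigma, n)), coverage)
            for _ in range(n_reps)]
    med = float(np.median(urls))
    return {"true_percentile": true, "median_url": med,
            "median_bias_pct": 100.0 * abs(med - true) / true,
            "median_abs_rel_err_pct": float(np.median(
                [100.0 * abs(u - true) / true for u in urls])),
            "n_reps": n_reps}


def bootstrap_coverage(n_reps: int = 500, n: int = 200, B: int = 300,
                       mu: float = 3.0, sigma: float = 0.5,
                       coverage: float = 0.95, seed: int = 0) -> dict:
    """Empirical coverage of the percentile-bootstrap 90% CI of the URL."""
    rng = np.random.default_rng(seed)
    true = float(np.exp(mu + sigma * stats.norm.ppf((1 + coverage) / 2)))
    covered = 0
    for s in _child_seeds(seed + 1, n_reps):
        x = np.exp(rng.normal(mu, sigma, n))
        lb, ub, _ = bootstrap_ci(x, coverage=coverage, B=B, seed=int(s),
                                 cap_pg_ml=np.inf)
        covered += lb <= true <= ub
    return {"coverage": covered / n_reps, "n_reps": n_reps, "B": B}


# -- normality test -----------------------------------------------------------

def dagostino_type1_error(n_sims: int = 100_000, n: int = 28,
                          alpha: float = 0.05, seed: int = 0) -> float:
    """Type-I error of the omnibus K^2 test on standard-normal samples."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, (n_sims, n))
    _, p = stats.normaltest(x, axis=1)
    return float((p < alpha).mean())


# -- mixed-model recovery -----------------------------------------------------

def expected_variance_components(period: str) -> dict:
    """Model-recovered variance components implied by the study conditions.

    The period model is additive (type + event + animal), so the REML fit
    absorbs two deterministic features of the seasonal profile on top of the
    configured stochastic components: the event random effect absorbs the
    within-period seasonal trend (variance of the cohort-weighted per-event
    profile means), and the residual absorbs the type-by-event interaction of
    the profiles.  Both are computable in closed form from the default
    profile by a two-way weighted sweep.
    """
    from ._tables import ANALYZED_GROUP_SIZES, VARIANCE_COMPONENTS, default_ln_profile
    from .calendar import CALENDAR
    prof = default_ln_profile()
    comp = VARIANCE_COMPONENTS[period]
    types = list(ANALYZED_GROUP_SIZES)
    events = [e.label for e in CALENDAR if e.period == period]
    P = np.array([[prof[(t, e)] for e in events] for t in types])
    wts = np.array([ANALYZED_GROUP_SIZES[t] for t in types], float)
    wts /= wts.sum()
    gamma = wts @ P
    D = P.copy()
    for _ in range(20):  # sweep out type and (weighted) event means
        D = D - (wts @ D)[None, :]
        D = D - D.mean(axis=1)[:, None]
    v_interaction = float((wts @ (D ** 2)).mean())
    return {"id": comp["sd_id"] ** 2,
            "month": comp["sd_month"] ** 2 + float(np.var(gamma)),
            "location": comp["sd_location"] ** 2,
            "residual": comp["sd_resid"] ** 2 + v_interaction}


def mixed_model_recovery(n_reps: int = 100, seed: int = 0,
                         use_child_seeds: bool = False) -> dict:
    """Sign recovery of the hybrid deficit and variance-component recovery on
    study-parameterized synthetic cohorts, both periods.

    With ``use_child_seeds`` False the replications use cohort seeds
    0..n_reps-1 (the canonical enumeration); otherwise they derive from
    ``seed``.
    """
    cohort_seeds = (_child_seeds(seed, n_reps) if use_child_seeds
                    else np.arange(n_reps))
    out = {p: {"hybrid_neg": 0, "mini_pos": 0, "vc": []} for p in (PERIOD_MID, PERIOD_EARLY)}
    both = 0
    for s in cohort_seeds:
        cohort = generate_cohort(study_default_config(seed=int(s)))
        neg = {}
        for period in (PERIOD_MID, PERIOD_EARLY):
            summary = fit_period_model(cohort, period)
            fe = summary.fixed_effects
            hyb = float(fe.loc[fe["term"].str.contains("hybrid"), "coef"].iloc[0])
            mini = float(fe.loc[fe["term"].str.contains("miniature"), "coef"].iloc[0])
            neg[period] = hyb < 0
            out[period]["hybrid_neg"] += hyb < 0
            out[period]["mini_pos"] += mini > 0
            out[period]["vc"].append(summary.variance_components)
        both += all(neg.values())
    res = {"n_reps": n_reps, "both_periods_hybrid_negative": both / n_reps}
    for period, acc in out.items():
        vc_mean = {k: float(np.mean([v[k] for v in acc["vc"]]))
                   for k in ("id", "month", "location", "residual")}
        res[period] = {"hybrid_negative": acc["hybrid_neg"] / n_reps,
                       "miniature_positive": acc["mini_pos"] / n_reps,
                       "vc_mean": vc_mean}
    return res
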