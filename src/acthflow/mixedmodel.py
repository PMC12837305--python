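"""Period-split linear mixed-effects analysis of ln(ACTH).

For each seasonal period the response is ln(ACTH) with a fixed effect (one of
equid type, sex, age class — univariable screening first) and random
intercepts for animal, sampling event and location, fitted by REML.  The
shared per-animal intercept realizes a compound-symmetry correlation among an
animal's repeated measures; an independence structure (no animal intercept)
is the alternative candidate, chosen by AIC.  Estimated marginal means of
equid type, Bonferroni-adjusted pairwise contrasts and back-transformed
percent differences complete the surface.

Small-sample inference: p-values and CIs use a t reference with a
between-animal containment-style df (number of animals minus fixed-effect
parameters), a pragmatic stand-in for the Kenward-Roger adjustment; the df
method is recorded in the model metadata.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .calendar import PERIOD_EARLY, PERIOD_MID
from .cohort import CohortTable

CANDIDATE_FIXED = ("age_class", "sex", "equid_type")

_FORMULAS = {
    "equid_type": "ln_acth ~ C(equid_type, Treatment('standard'))",
    "age_class": "ln_acth ~ C(age_class, Treatment('young'))",
    "sex": "ln_acth ~ C(sex, Treatment('female'))",
}

CS = "compound_symmetry"
INDEPENDENCE = "independence"


@dataclass
class PeriodModelSummary:
    period: str
    fixed: str
    fixed_effects: pd.DataFrame           # term, coef, se, p, ci_lb, ci_ub
    variance_components: dict             # id, event(month), location, residual
    n_obs: int
    n_animals: int
    df_method: str
    df_resid: float
    joint_p: float                        # Wald p of the fixed factor
    structure: str = CS
    result: object = field(default=None, repr=False)
    cov_fe: np.ndarray | None = field(default=None, repr=False)


def prepare_period_data(cohort: CohortTable, period: str) -> pd.DataFrame:
    """Period-restricted modelling frame with ln(ACTH); listwise-drops
    records with missing ACTH."""
    from .calendar import assign_period
    if period not in (PERIOD_MID, PERIOD_EARLY):
        raise ValueError(f"unknown period {period!r}")
    d = cohort.data.dropna(subset=["acth_pg_ml"]).copy()
    d = d[d["event"].map(assign_period) == period]
    d["ln_acth"] = np.log(d["acth_pg_ml"])
    d["_one"] = 1
    return d.reset_index(drop=True)


def collinearity_screen(data: pd.DataFrame, predictors: list, r_max: float = 0.8) -> list:
    """Drop one of every pair of numeric predictors with |Pearson r| > r_max
    (strictly greater: r = 0.8 keeps both).  The first in declared order wins."""
    kept: list = []
    dropped: list = []
    for p in predictors:
        clash = None
        for kprev in kept:
            r = np.corrcoef(data[kprev].astype(float), data[p].astype(float))[0, 1]
            if abs(r) > r_max + 1e-9:  # inclusive threshold, float-safe
                clash = (kprev, r)
                break
        if clash is None:
            kept.append(p)
        else:
            dropped.append((p, *clash))
    for p, kprev, r in dropped:
        warnings.warn(f"predictor {p!r} dropped: |r|={abs(r):.3f} with {kprev!r} "
                      f"exceeds {r_max}", stacklevel=2)
    return kept


def _vc_formula(structure: str) -> dict:
    vc = {"event": "0 + C(event)", "location": "0 + C(location)"}
    if structure == CS:
        vc["id"] = "0 + C(equid_id)"
    return vc


def _fit_mixed(data: pd.DataFrame, formula: str, structure: str = CS):
    """REML fit; the weakly identified location component makes gradient
    optimizers stall on inferior optima, so fit with two optimizers and keep
    the higher restricted likelihood."""
    model = MixedLM.from_formula(formula, data=data, groups="_one",
                                 vc_formula=_vc_formula(structure), re_formula="0")
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        for method in ("lbfgs", "powell"):
            try:
                res = model.fit(reml=True, method=method, maxiter=2000)
            except Exception:
                continue
            if np.isfinite(res.llf) and (best is None or res.llf > best.llf):
                best = res
    if best is None:
        raise RuntimeError("mixed-model fit failed with all optimizers")
    return model, best


def _gls_fe_covariance(model, res) -> np.ndarray:
    """Fixed-effect covariance (X' V^-1 X)^-1 at the estimated components.

    The Hessian-based covariance statsmodels reports can be indefinite when a
    variance component sits on the boundary; the GLS form is always valid
    conditional on the estimated components.
    """
    X = np.asarray(model.exog)
    n = X.shape[0]
    V = res.scale * np.eye(n)
    vcomp = np.maximum(np.asarray(res.vcomp), 0.0)
    for j, _name in enumerate(model.exog_vc.names):
        Z = np.asarray(model.exog_vc.mats[j][0])
        V += vcomp[j] * (Z @ Z.T)
    Vinv_X = np.linalg.solve(V, X)
    return np.linalg.inv(X.T @ Vinv_X)


def fit_period_model(data, period: str, fixed: str = "equid_type",
                     structure: str = CS) -> PeriodModelSummary:
    """REML fit of ln(ACTH) ~ fixed + (1|animal) + (1|event) + (1|location)
    on one period.  ``data`` is a CohortTable or a prepared period frame."""
    if isinstance(data, CohortTable):
        data = prepare_period_data(data, period)
    if fixed not in _FORMULAS:
        raise ValueError(f"unknown fixed effect {fixed!r}")
    model, res = _fit_mixed(data, _FORMULAS[fixed], structure)

    fe = res.fe_params
    k = len(fe)
    n_animals = data["equid_id"].nunique()
    df_resid = max(n_animals - k, 2)
    cov_fe = _gls_fe_covariance(model, res)
    se = np.sqrt(np.diag(cov_fe))
    tcrit = stats.t.ppf(0.975, df_resid)
    tvals = np.asarray(fe) / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    fixed_effects = pd.DataFrame({
        "term": fe.index, "coef": np.asarray(fe), "se": se, "p": pvals,
        "ci_lb": np.asarray(fe) - tcrit * se, "ci_ub": np.asarray(fe) + tcrit * se,
    })

    vc = dict(zip(model.exog_vc.names, np.maximum(np.asarray(res.vcomp), 0.0)))
    components = {
        "id": float(vc.get("id", 0.0)),
        "month": float(vc.get("event", 0.0)),
        "location": float(vc.get("location", 0.0)),
        "residual": float(res.scale),
    }

    joint_p = _joint_wald_p(res, cov_fe, df_resid)
    return PeriodModelSummary(period=period, fixed=fixed, fixed_effects=fixed_effects,
                              variance_components=components, n_obs=len(data),
                              n_animals=n_animals,
                              df_method=f"containment (animals - {k} fixed params)",
                              df_resid=df_resid, joint_p=joint_p,
                              structure=structure, result=res, cov_fe=cov_fe)


def _joint_wald_p(res, cov_fe: np.ndarray, df_resid: float) -> float:
    """Wald test of all non-intercept fixed-effect terms (F with containment df)."""
    fe = res.fe_params
    idx = [i for i, name in enumerate(fe.index) if name != "Intercept"]
    if not idx:
        return float("nan")
    beta = np.asarray(fe)[idx]
    cov = cov_fe[np.ix_(idx, idx)]
    w = float(beta @ np.linalg.solve(cov, beta))
    r = len(idx)
    return float(stats.f.sf(w / r, r, df_resid))


def univariable_screen(data, period: str, candidates=CANDIDATE_FIXED,
                       alpha: float = 0.05) -> dict:
    """Fit each candidate fixed effect alone; retain those with Wald p <= alpha.

    Returns the per-candidate p-values, the retained set, and the final model
    (multivariable only when two or more candidates survive)."""
    if isinstance(data, CohortTable):
        data = prepare_period_data(data, period)
    fits, pvals = {}, {}
    for cand in candidates:
        summary = fit_period_model(data, period, fixed=cand)
        fits[cand] = summary
        pvals[cand] = summary.joint_p
    retained = [c for c in candidates if pvals[c] <= alpha]
    if len(retained) >= 2:
        rhs = " + ".join(_FORMULAS[c].split("~")[1].strip() for c in retained)
        model, res = _fit_mixed(data, f"ln_acth ~ {rhs}")
        final = ("multivariable", res)
    elif len(retained) == 1:
        final = (retained[0], fits[retained[0]])
    else:
        final = (None, None)
    return {"p_values": pvals, "retained": retained, "final": final, "fits": fits}


def covariance_structure_aic(data, period: str, fixed: str = "equid_type",
                             candidates=(CS, INDEPENDENCE)) -> tuple:
    """Pick the covariance structure with minimal REML AIC; ties go to
    compound symmetry."""
    if isinstance(data, CohortTable):
        data = prepare_period_data(data, period)
    aics = {}
    for structure in candidates:
        model, res = _fit_mixed(data, _FORMULAS[fixed], structure)
        k = len(res.fe_params) + len(res.vcomp) + 1  # + residual variance
        aics[structure] = float(-2 * res.llf + 2 * k)
    best = min(aics.values())
    chosen = CS if (CS in aics and aics[CS] <= best + 1e-8) else \
        min(aics, key=aics.get)
    return chosen, aics


# -- marginal means and contrasts --------------------------------------------

_TYPE_ORDER = ("standard", "miniature", "hybrid")


def emm_pairwise(summary: PeriodModelSummary) -> tuple:
    """Estimated marginal means of equid type (ln scale) and the three
    Bonferroni-adjusted pairwise contrasts with percent differences."""
    if summary.fixed != "equid_type":
        raise ValueError("EMM contrasts require an equid_type model")
    res = summary.result
    fe = res.fe_params
    names = list(fe.index)
    cov = summary.cov_fe

    def design_row(etype):
        row = np.zeros(len(names))
        row[names.index("Intercept")] = 1.0
        for i, nm in enumerate(names):
            if nm.endswith(f"[T.{etype}]"):
                row[i] = 1.0
        return row

    emms = {t: float(design_row(t) @ np.asarray(fe)) for t in _TYPE_ORDER}

    pairs = list(itertools.combinations(_TYPE_ORDER, 2))
    tcrit = stats.t.ppf(0.975, summary.df_resid)
    rows = []
    for a, b_ in pairs:
        cvec = design_row(a) - design_row(b_)
        diff = float(cvec @ np.asarray(fe))
        se = float(np.sqrt(cvec @ cov @ cvec))
        if se == 0.0:
            p_adj = 1.0
        else:
            p_raw = 2 * stats.t.sf(abs(diff) / se, summary.df_resid)
            p_adj = min(1.0, p_raw * len(pairs))
        lb, ub = diff - tcrit * se, diff + tcrit * se
        pct = percent_difference(-diff, -ub, -lb)  # b_ relative to a
        rows.append({"pair": f"{b_} vs {a}", "diff_ln": -diff, "se": se,
                     "p_bonferroni": p_adj, "percent": pct["percent"],
                     "direction": pct["direction"],
                     "percent_ci_lb": pct["ci"][0], "percent_ci_ub": pct["ci"][1]})
    return emms, pd.DataFrame(rows)


def percent_difference(beta: float, ci_lb: float = float("nan"),
                       ci_ub: float = float("nan")) -> dict:
    """Back-transform an ln-scale difference to a percent difference.

    beta < 0: 100*(1 - e^beta) percent *lower*; beta > 0: 100*(e^beta - 1)
    percent *higher*; CI endpoints map through the same monotone transform
    with order preserved.
    """
    if beta < 0:
        pct = 100.0 * (1.0 - np.exp(beta))
        direction = "lower"
        ends = sorted([100.0 * (1.0 - np.exp(ci_ub)), 100.0 * (1.0 - np.exp(ci_lb))])
    elif beta > 0:
        pct = 100.0 * (np.exp(beta) - 1.0)
        direction = "higher"
        ends = sorted([100.0 * (np.exp(ci_lb) - 1.0), 100.0 * (np.exp(ci_ub) - 1.0)])
    else:
        pct, direction = 0.0, "equal"
        ends = sorted([100.0 * (np.exp(ci_lb) - 1.0), 100.0 * (np.exp(ci_ub) - 1.0)])
    return {"percent": float(pct), "direction": direction,
            "ci": (float(ends[0]), float(ends[1]))}
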