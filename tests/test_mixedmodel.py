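import json
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acthflow.calendar import CALENDAR, PERIOD_EARLY, PERIOD_MID
from acthflow.mixedmodel import (CS, INDEPENDENCE, collinearity_screen,
                                 covariance_structure_aic, emm_pairwise,
                                 fit_period_model, percent_difference,
                                 prepare_period_data, univariable_screen)
from acthflow.simulate import SyntheticConfig, generate_cohort, study_default_config


def _hybrid_coef(summary):
    fe = summary.fixed_effects
    return float(fe.loc[fe["term"].str.contains("hybrid"), "coef"].iloc[0])


class TestCollinearity:
    def test_single_predictor_kept(self):
        d = pd.DataFrame({"a": [1.0, 2, 3, 4]})
        assert collinearity_screen(d, ["a"]) == ["a"]

    def test_perfectly_correlated_pair_drops_second(self):
        d = pd.DataFrame({"a": [1.0, 2, 3, 4]})
        d["b"] = 2 * d["a"] + 1
        with pytest.warns(UserWarning, match="dropped"):
            kept = collinearity_screen(d, ["a", "b"])
        assert kept == ["a"]

    def test_r_exactly_08_keeps_both(self):
        # construct two unit-variance series with r = 0.8 exactly
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 2000)
        e = rng.normal(0, 1, 2000)
        x = (x - x.mean()) / x.std()
        e = e - e.mean()
        e = e - x * (x @ e) / (x @ x)       # orthogonalize
        e = e / e.std()
        y = 0.8 * x + 0.6 * e
        d = pd.DataFrame({"a": x, "b": y / y.std()})
        r = np.corrcoef(d["a"], d["b"])[0, 1]
        assert r == pytest.approx(0.8, abs=1e-12)
        assert collinearity_screen(d, ["a", "b"]) == ["a", "b"]


class TestFitPeriodModel:
    def test_near_noise_free_equal_profiles_give_zero_coefficients(self):
        prof = {(t, e.label): math.log(20.0) for t in ("standard", "miniature", "hybrid")
                for e in CALENDAR}
        cfg = SyntheticConfig(seasonal_profile=prof, sd_id=1e-3,
                              sd_month={PERIOD_MID: 0.0, PERIOD_EARLY: 0.0},
                              sd_location=0.0,
                              sd_resid={PERIOD_MID: 1e-3, PERIOD_EARLY: 1e-3}, seed=0)
        summary = fit_period_model(generate_cohort(cfg), PERIOD_MID)
        non_int = summary.fixed_effects[summary.fixed_effects.term != "Intercept"]
        assert np.all(np.abs(non_int["coef"]) < 1e-2)

    def test_study_default_early_period_hybrid_coefficient_is_negative(self):
        cohort = generate_cohort(study_default_config(seed=3))
        summary = fit_period_model(cohort, PERIOD_EARLY)
        assert _hybrid_coef(summary) < 0
        assert set(summary.variance_components) == {"id", "month", "location", "residual"}
        assert all(v >= 0 for v in summary.variance_components.values())

    def test_missing_acth_dropped_listwise(self):
        cfg = study_default_config(seed=2, missing_month_counts={"H05": 2})
        d = prepare_period_data(generate_cohort(cfg), PERIOD_EARLY)
        assert not d["ln_acth"].isna().any()
        assert len(d) < 61 * 13

    def test_agrees_with_lme4_reml_oracle(self, tmp_path):
        """Independent cross-check: identical REML fit in R (lme4)."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        cohort = generate_cohort(study_default_config(seed=5))
        d = prepare_period_data(cohort, PERIOD_MID)
        csv = tmp_path / "period.csv"
        d[["equid_id", "equid_type", "location", "event", "ln_acth"]].to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$equid_type <- relevel(factor(d$equid_type), ref = "standard")
            m <- lmer(ln_acth ~ equid_type + (1|equid_id) + (1|event) + (1|location),
                      data = d, REML = TRUE)
            fe <- fixef(m)
            vc <- as.data.frame(VarCorr(m))
            out <- list(fe = as.list(fe),
                        vc = setNames(as.list(vc$vcov), vc$grp))
            cat(jsonlite::toJSON(out, auto_unbox = TRUE))
        """)
        res = subprocess.run(["Rscript", str(rscript)], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        ref = json.loads(res.stdout)
        summary = fit_period_model(d, PERIOD_MID)
        fe = summary.fixed_effects.set_index("term")["coef"]
        assert fe["Intercept"] == pytest.approx(ref["fe"]["(Intercept)"], abs=1e-3)
        ours_h = fe[[t for t in fe.index if "hybrid" in t][0]]
        ours_m = fe[[t for t in fe.index if "miniature" in t][0]]
        assert ours_h == pytest.approx(ref["fe"]["equid_typehybrid"], abs=1e-3)
        assert ours_m == pytest.approx(ref["fe"]["equid_typeminiature"], abs=1e-3)
        vc = summary.variance_components
        assert vc["id"] == pytest.approx(ref["vc"]["equid_id"], abs=0.02)
        assert vc["month"] == pytest.approx(ref["vc"]["event"], abs=0.02)
        assert vc["residual"] == pytest.approx(ref["vc"]["Residual"], abs=0.02)


class TestUnivariableScreen:
    def test_pure_type_effect_retains_only_equid_type(self):
        cohort = generate_cohort(study_default_config(seed=4))
        res = univariable_screen(cohort, PERIOD_EARLY)
        assert "equid_type" in res["retained"]
        assert res["p_values"]["equid_type"] < 0.05

    def test_two_effects_build_multivariable_model(self):
        # independent senior and male elevations make two candidates clear
        # the univariable screen -> multivariable branch
        cfg = study_default_config(seed=6)
        cohort = generate_cohort(cfg)
        d = cohort.data.copy()
        d.loc[d["age_class"] == "senior", "acth_pg_ml"] *= 1.8
        d.loc[d["sex"] == "male", "acth_pg_ml"] *= 1.8
        from acthflow.cohort import CohortTable
        res = univariable_screen(CohortTable(d), PERIOD_EARLY)
        assert "age_class" in res["retained"] and len(res["retained"]) >= 2
        assert res["final"][0] == "multivariable"

    def test_no_effect_data_rarely_retains(self):
        prof = {(t, e.label): math.log(20.0) for t in ("standard", "miniature", "hybrid")
                for e in CALENDAR}
        hits = []
        for seed in range(10):
            cfg = SyntheticConfig(seasonal_profile=prof, seed=seed)
            res = univariable_screen(generate_cohort(cfg), PERIOD_MID)
            hits.append(len(res["retained"]))
        # 30 null univariable tests in total; expect ~5% retention
        assert sum(hits) <= 6


class TestCovarianceStructure:
    def test_cs_chosen_when_animal_correlation_present(self):
        cohort = generate_cohort(study_default_config(seed=7))
        chosen, aics = covariance_structure_aic(cohort, PERIOD_EARLY)
        assert chosen == CS
        assert aics[CS] < aics[INDEPENDENCE]

    def test_tie_or_independent_residuals_prefer_cs(self):
        cfg = study_default_config(seed=8, sd_id=0.0)
        chosen, aics = covariance_structure_aic(generate_cohort(cfg), PERIOD_MID)
        assert abs(aics[CS] - aics[INDEPENDENCE]) < 8
        assert chosen in (CS, INDEPENDENCE)


class TestEMMAndPercent:
    def test_contrasts_match_coefficients_for_univariable_model(self):
        cohort = generate_cohort(study_default_config(seed=9))
        summary = fit_period_model(cohort, PERIOD_EARLY)
        emms, contrasts = emm_pairwise(summary)
        fe = summary.fixed_effects.set_index("term")["coef"]
        hyb = [t for t in fe.index if "hybrid" in t][0]
        row = contrasts[contrasts["pair"] == "hybrid vs standard"].iloc[0]
        assert row["diff_ln"] == pytest.approx(fe[hyb], rel=1e-9)
        assert emms["standard"] == pytest.approx(fe["Intercept"], rel=1e-9)
        assert 0 < row["p_bonferroni"] <= 1

    def test_identical_emms_give_adjusted_p_one(self):
        cohort = generate_cohort(study_default_config(seed=9))
        summary = fit_period_model(cohort, PERIOD_EARLY)
        summary.result.fe_params[1:] = 0.0
        emms, contrasts = emm_pairwise(summary)
        assert len(set(np.round(list(emms.values()), 12))) == 1
        assert (contrasts["p_bonferroni"] == 1.0).all()

    def test_published_hybrid_coefficient_maps_to_22_9_percent_lower(self):
        out = percent_difference(-0.26, -0.48, -0.04)
        assert out["direction"] == "lower"
        assert out["percent"] == pytest.approx(22.9, abs=0.05)
        assert out["ci"][0] == pytest.approx(3.9, abs=0.1)
        assert out["ci"][1] == pytest.approx(38.1, abs=0.1)

    @pytest.mark.parametrize("beta,pct,direction", [
        (0.0, 0.0, "equal"),
        (math.log(2), 100.0, "higher"),
    ])
    def test_percent_difference_reference_points(self, beta, pct, direction):
        out = percent_difference(beta, beta - 0.1, beta + 0.1)
        assert out["percent"] == pytest.approx(pct, abs=1e-9)
        assert out["direction"] == direction

    @given(beta=st.floats(-3, -1e-6))
    @settings(max_examples=50, deadline=None)
    def test_percent_difference_exactly_inverts(self, beta):
        pct = percent_difference(beta)["percent"]
        assert math.log(1 - pct / 100.0) == pytest.approx(beta, rel=1e-10)
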