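import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from acthflow.calendar import PERIOD_EARLY, PERIOD_MID
from acthflow.screening import (HEALTHY, INSUFFICIENT, OUTLIER, classify_animal,
                                pre_enrollment_filter, propagate_to_month,
                                rout_flag_event, screen_cohort)
from acthflow.simulate import generate_cohort, study_default_config
from conftest import make_cohort


# --- independent brute-force oracle for the ROUT steps -----------------------

def _oracle_percentile(sorted_abs, pct):
    """Linear interpolation between order statistics, written out longhand."""
    n = len(sorted_abs)
    pos = (pct / 100.0) * (n - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return sorted_abs[lo] * (1 - frac) + sorted_abs[hi] * frac


def oracle_rout(values, q=0.01):
    """Direct re-computation of the five ROUT steps with explicit loops."""
    x = [float(v) for v in values]
    n = len(x)
    # (1) intercept-only bisquare fit, IRLS from the median
    center = sorted(x)[n // 2] if n % 2 else 0.5 * (sorted(x)[n // 2 - 1] + sorted(x)[n // 2])
    mad = sorted(abs(v - center) for v in x)
    mad = mad[n // 2] if n % 2 else 0.5 * (mad[n // 2 - 1] + mad[n // 2])
    scale = 1.4826 * mad
    if scale > 0:
        for _ in range(100):
            num = den = 0.0
            for v in x:
                u = (v - center) / (4.685 * scale)
                if abs(u) < 1:
                    w = (1 - u * u) ** 2
                    num += w * v
                    den += w
            if den == 0:
                break
            new = num / den
            moved = abs(new - center)
            center = new
            if moved <= 1e-8 * max(abs(center), scale):
                break
    # (2)+(3) residuals and RSDR
    resid = [v - center for v in x]
    rsdr = _oracle_percentile(sorted(abs(r) for r in resid), 68.27) * n / (n - 1)
    if rsdr == 0:
        return [False] * n
    # (4) two-sided t p-values
    p = [2 * stats.t.sf(abs(r) / rsdr, n - 1) for r in resid]
    # (5) step-up scan
    order = sorted(range(n), key=lambda i: p[i])
    k = -1
    for rank, i in enumerate(order, start=1):
        if p[i] <= q * rank / n:
            k = rank
    flags = [False] * n
    for i in order[:max(k, 0)]:
        flags[i] = True
    return flags


def test_identical_values_yield_no_flags():
    with pytest.warns(UserWarning, match="degenerate"):
        screen = rout_flag_event([50.0] * 19)
    assert screen.degenerate and not screen.flags.any()
    assert screen.rsdr == 0.0


def test_gross_outlier_from_published_september_values_is_flagged():
    # one animal at 1054 pg/mL against an ordinary event
    values = [10, 11, 9, 10.5, 9.5, 10, 1054]
    screen = rout_flag_event(values)
    assert screen.flags.tolist() == [False] * 6 + [True]
    assert oracle_rout(values) == screen.flags.tolist()


def test_small_events_are_unscreenable():
    screen = rout_flag_event([10.0, 1000.0])
    assert not screen.screenable and not screen.flags.any()


def test_oracle_agreement_on_100_random_events():
    rng = np.random.default_rng(314)
    for _ in range(100):
        n = int(rng.integers(3, 30))
        x = rng.lognormal(3.0, 0.5, n)
        if rng.random() < 0.5:
            x[0] *= rng.uniform(3, 30)
        screen = rout_flag_event(x)
        assert screen.flags.tolist() == oracle_rout(x)


@given(c=st.floats(min_value=1e-3, max_value=1e4, allow_nan=False),
       seed=st.integers(0, 10_000))
@settings(max_examples=40, deadline=None)
def test_flags_are_scale_equivariant(c, seed):
    rng = np.random.default_rng(seed)
    x = rng.lognormal(3, 0.6, 15)
    x[-1] *= 12
    assert np.array_equal(rout_flag_event(x).flags, rout_flag_event(c * x).flags)


def test_adding_a_center_value_does_not_flag_others():
    rng = np.random.default_rng(99)
    for _ in range(50):
        x = rng.normal(40, 8, 18)
        base = rout_flag_event(x)
        extended = rout_flag_event(np.append(x, base.robust_center))
        assert not (extended.flags[:18] & ~base.flags).any()


class TestPreEnrollment:
    def test_boundary_40_is_kept_and_40_1_excluded(self):
        vals = pd.Series({"A": 40.0, "B": 40.1, "C": 12.0})
        kept, excluded, reasons = pre_enrollment_filter(vals)
        assert excluded == ["B"] and set(kept) == {"A", "C"}
        assert "40.1" in reasons["reason"].iloc[0]

    def test_missing_values_keep_animal_with_warning(self):
        vals = pd.Series({"A": np.nan, "B": np.nan})
        with pytest.warns(UserWarning, match="pre-enrollment"):
            kept, excluded, _ = pre_enrollment_filter(vals)
        assert kept == ["A", "B"] and excluded == []


class TestMonthPropagationAndClassification:
    def test_single_flagged_event_flags_whole_month(self):
        flags = pd.DataFrame({"equid_id": ["D1"], "event": ["September_1-15"],
                              "flagged": [True]})
        months = propagate_to_month(flags)
        assert months["month"].tolist() == ["September"]
        assert months["periods"].iloc[0] == frozenset({PERIOD_MID})

    def test_two_flagged_events_in_october_count_one_month(self):
        flags = pd.DataFrame({"equid_id": ["D1"] * 2,
                              "event": ["October_1-15", "October_16-31"],
                              "flagged": [True, True]})
        assert len(propagate_to_month(flags)) == 1

    def test_no_flags_no_months(self):
        flags = pd.DataFrame({"equid_id": ["D1"], "event": ["October_1-15"],
                              "flagged": [False]})
        assert propagate_to_month(flags).empty

    def test_august_month_period_follows_the_flagged_half(self):
        flags = pd.DataFrame({"equid_id": ["D1"], "event": ["August_1-15"],
                              "flagged": [True]})
        assert propagate_to_month(flags)["periods"].iloc[0] == frozenset({PERIOD_EARLY})

    def _months(self, specs):
        return pd.DataFrame({"equid_id": ["X"] * len(specs),
                             "month": [m for m, _ in specs],
                             "periods": [frozenset({p}) for _, p in specs]})

    def test_three_flagged_months_in_one_period_is_outlier(self):
        months = self._months([("August", PERIOD_MID), ("September", PERIOD_MID),
                               ("October", PERIOD_MID)])
        assert classify_animal(months, 0) == OUTLIER

    def test_two_plus_two_across_periods_is_not_outlier_per_period(self):
        months = self._months([("September", PERIOD_MID), ("October", PERIOD_MID),
                               ("January", PERIOD_EARLY), ("March", PERIOD_EARLY)])
        assert classify_animal(months, 0) == HEALTHY
        assert classify_animal(months, 0, rule="total") == OUTLIER

    def test_three_missing_months_is_insufficient_data(self):
        months = self._months([])
        assert classify_animal(months, 3) == INSUFFICIENT
        assert classify_animal(months, 2) == HEALTHY

    def test_outlier_takes_precedence_over_missing(self):
        months = self._months([("January", PERIOD_EARLY), ("March", PERIOD_EARLY),
                               ("May", PERIOD_EARLY)])
        assert classify_animal(months, 5) == OUTLIER


class TestScreenCohort:
    def test_clean_noise_free_cohort_all_healthy(self, noise_free_config):
        cohort = generate_cohort(noise_free_config)
        with pytest.warns(UserWarning, match="degenerate"):
            outcome, analyzable = screen_cohort(cohort)
        assert (outcome.classification == HEALTHY).all()
        assert len(analyzable.animals) == len(cohort.animals)

    def test_injected_and_blanked_animals_are_exactly_removed(self):
        cfg = study_default_config(seed=1, n_outlier_animals=5,
                                   missing_month_counts={"S01": 3, "M01": 3, "H01": 3})
        from acthflow.simulate import truth_table, CLEAN
        truth = truth_table(cfg).set_index("equid_id")["truth"]
        outcome, analyzable = screen_cohort(generate_cohort(cfg))
        removed = set(outcome.exclusion_report["equid_id"])
        assert removed == set(truth.index[truth != CLEAN])
        assert len(removed) == 8
        assert len(analyzable.animals) == 53

    def test_single_group_cohort_screens_independently(self):
        recs = [("S%02d" % i, "standard", "NY", "female", 5.0, "March_1-31",
                 50.0 + i * 0.5) for i in range(10)]
        recs.append(("S99", "standard", "NY", "female", 5.0, "March_1-31", 5000.0))
        outcome, analyzable = screen_cohort(make_cohort(recs))
        assert len(outcome.month_flags) == 1
        assert outcome.month_flags["equid_id"].iloc[0] == "S99"

    def test_sensitivity_increases_with_inflation(self):
        hits = {}
        for infl in (1.5, 20.0):
            n_hit = 0
            for seed in range(5):
                cfg = study_default_config(seed=seed, n_outlier_animals=3,
                                           outlier_inflation=infl)
                from acthflow.simulate import truth_table, INJECTED_OUTLIER
                truth = truth_table(cfg).set_index("equid_id")["truth"]
                outcome, _ = screen_cohort(generate_cohort(cfg))
                removed = set(outcome.exclusion_report["equid_id"])
                n_hit += len(removed & set(truth.index[truth == INJECTED_OUTLIER]))
            hits[infl] = n_hit
        assert hits[20.0] == 15
        assert hits[20.0] >= hits[1.5]
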