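import numpy as np
import pandas as pd
import pytest

from conftest import INTERVIEW, make_respondents, make_siblings
from helpers import brute_force_exposure, random_sibling_table
from sibmort.estimation import (annual_series, chain_35q15, estimate_35q15,
                                jackknife_ci, q_from_m, rates_from_exposure,
                                scale_subnational, tabulate_exposure)
from sibmort.synthetic import calibrate_regime, simulate_sibships

WINDOW = (1440, 1476)


class TestTabulateExposure:
    def test_survivor_person_years(self):
        resp = make_respondents([40])
        sib = make_siblings([{"alive": True, "age_now": 20, "birth_cmc": 1236}])
        t = tabulate_exposure(sib, resp, WINDOW)
        assert t.person_years_w[0] == pytest.approx(3.0)   # ages 17-19
        assert t.person_years_w[1:].sum() == 0
        assert t.deaths_w.sum() == 0

    def test_death_mid_window(self):
        resp = make_respondents([40])
        sib = make_siblings([{"alive": False, "age_at_death": 30,
                              "death_cmc": 1450, "birth_cmc": 1080}])
        t = tabulate_exposure(sib, resp, WINDOW)
        assert t.deaths_w[3] == 1.0            # 30-34 group
        assert t.person_years_w[3] == pytest.approx(10 / 12)  # age 30 at 1440

    def test_birth_after_window_contributes_nothing(self):
        resp = make_respondents([40])
        sib = make_siblings([{"alive": True, "age_now": 0, "birth_cmc": 1476}])
        t = tabulate_exposure(sib, resp, (1440, 1476))
        assert t.person_years_w.sum() == 0

    def test_matches_month_by_month_oracle(self):
        rng = np.random.default_rng(123)
        sib, resp = random_sibling_table(rng, 1000, INTERVIEW)
        weights = rng.uniform(0.5, 2.0, len(resp))
        for window in [(1440, 1476), (1350, 1476), (1429, 1465)]:
            t = tabulate_exposure(sib, resp, window, weights=weights)
            D, PY = brute_force_exposure(sib, resp, window, weights=weights)
            np.testing.assert_allclose(t.deaths_w, D, atol=1e-9)
            np.testing.assert_allclose(t.person_years_w, PY, atol=1e-9)

    def test_window_additivity(self):
        rng = np.random.default_rng(7)
        sib, resp = random_sibling_table(rng, 400, INTERVIEW)
        whole = tabulate_exposure(sib, resp, (1400, 1476))
        a = tabulate_exposure(sib, resp, (1400, 1450))
        b = tabulate_exposure(sib, resp, (1450, 1476))
        np.testing.assert_allclose(whole.deaths_w, a.deaths_w + b.deaths_w)
        np.testing.assert_allclose(whole.person_years_w,
                                   a.person_years_w + b.person_years_w,
                                   atol=1e-9)

    def test_missing_dates_direct_to_imputation(self):
        resp = make_respondents([40])
        sib = make_siblings([{"alive": True, "age_now": 20}])
        with pytest.raises(ValueError, match="birth"):
            tabulate_exposure(sib, resp, WINDOW)


class TestRatesAndChaining:
    def test_rate_arithmetic(self):
        resp = make_respondents([40])
        rows = [{"alive": True, "age_now": 17, "birth_cmc": 1266,
                 "line_no": i} for i in range(50)]
        t = tabulate_exposure(make_siblings(rows), resp, (1464, 1476))
        m = rates_from_exposure(t)
        assert m[0] == 0.0
        assert np.isnan(m[1:]).all()

    def test_weighted_vs_unweighted_rates(self):
        resp = make_respondents([40, 40])
        sib = make_siblings([
            {"respondent_id": "p0000", "alive": False, "age_at_death": 17,
             "death_cmc": 1470, "birth_cmc": 1470 - 17 * 12 - 6},
            {"respondent_id": "p0001", "alive": True, "age_now": 17,
             "birth_cmc": 1266},
        ])
        t = tabulate_exposure(sib, resp, (1464, 1476), weights=[1.0, 2.0])
        # hand computation: death weight 1; PY = 0.5*1 + 1.0*2 = 2.5
        assert t.deaths_w[0] == 1.0
        assert t.person_years_w[0] == pytest.approx(0.5 + 2.0)
        m = rates_from_exposure(t)
        assert m[0] == pytest.approx(1.0 / 2.5)

    @pytest.mark.parametrize("m,expected", [
        (0.0, 0.0),
        (0.01, 0.04878048780487805),
    ])
    def test_q_from_m_values(self, m, expected):
        assert q_from_m(m) == pytest.approx(expected, abs=1e-12)

    def test_q_from_m_monotone(self):
        grid = np.arange(0, 0.2001, 0.001)
        q = q_from_m(grid)
        assert np.all(np.diff(q) > 0)

    def test_q_from_m_rejects_negative(self):
        with pytest.raises(ValueError):
            q_from_m(-0.01)

    def test_chain_constant_schedule_closed_form(self):
        m = np.full(7, 0.01)
        q0 = q_from_m(0.01)
        assert chain_35q15(m) == pytest.approx(1 - (1 - q0) ** 7, abs=1e-12)
        assert chain_35q15(np.zeros(7)) == 0.0

    def test_chain_absorbing_group(self):
        m = np.full(7, 0.001)
        m[3] = 1e9  # q -> 1
        assert chain_35q15(m) == pytest.approx(1.0)

    def test_chain_names_missing_group(self):
        m = np.full(7, 0.01)
        m[2] = np.nan
        with pytest.raises(ValueError, match="25-29"):
            chain_35q15(m)


class TestJackknife:
    def test_identical_units_zero_se(self):
        se, (lo, hi) = jackknife_ci([5.0] * 10, np.mean, truncate=None)
        assert se == 0.0 and lo == hi == 5.0

    def test_mean_matches_classical_formula(self):
        rng = np.random.default_rng(2)
        ages = rng.integers(15, 60, 40).astype(float)
        se, _ = jackknife_ci(ages, np.mean, truncate=None)
        assert se == pytest.approx(ages.std(ddof=1) / np.sqrt(len(ages)),
                                   rel=1e-10)

    def test_failed_replicates_skipped_with_warning(self):
        def fragile(xs):
            if len(xs) == 3 and xs[0] == 2.0:   # only the delete-first replicate
                raise RuntimeError("boom")
            return float(np.mean(xs))
        with pytest.warns(UserWarning, match="skipped"):
            se, _ = jackknife_ci([1.0, 2.0, 3.0, 4.0], fragile, truncate=None)
        assert np.isfinite(se)

    def test_coverage_of_jackknife_intervals(self, regime15):
        """95% CIs should cover the true 35q15 in >= 90% of replicates."""
        target = regime15.implied_35q15("m")
        hits = total = 0
        for rep in range(200):
            resp, sib = simulate_sibships(regime15, 2000, INTERVIEW,
                                          seed=10_000 + rep)
            est = estimate_35q15(sib, resp, (INTERVIEW - 36, INTERVIEW), sex="m")
            hits += est.ci_low <= target <= est.ci_high
            total += 1
        assert hits / total >= 0.90


class TestEstimate35q15:
    def test_zero_hazard_data_gives_zero(self):
        reg = calibrate_regime(0.0)
        for sex in reg.hazards:
            reg.hazards[sex] = np.zeros_like(reg.hazards[sex])
        resp, sib = simulate_sibships(reg, 400, INTERVIEW, seed=8)
        est = estimate_35q15(sib, resp, (INTERVIEW - 36, INTERVIEW))
        assert est.q == 0.0 and est.se == 0.0

    def test_parameter_recovery(self, regime15):
        resp, sib = simulate_sibships(regime15, 20000, INTERVIEW, seed=77)
        est = estimate_35q15(sib, resp, (INTERVIEW - 36, INTERVIEW))
        assert abs(est.q - 0.15) <= 3 * est.se

    def test_both_sexes_between_single_sex_estimates(self):
        rows = []
        for g, lo in enumerate(range(15, 50, 5)):
            birth = WINDOW[0] - 12 * (lo + 1)
            for i in range(10):
                rows.append({"respondent_id": f"p{i % 2:04d}", "sex": "m",
                             "alive": True, "age_now": lo + 4,
                             "birth_cmc": birth})
                rows.append({"respondent_id": f"p{i % 2:04d}", "sex": "f",
                             "alive": True, "age_now": lo + 4,
                             "birth_cmc": birth})
            rows.append({"respondent_id": f"p{g % 2:04d}", "sex": "m",
                         "alive": False, "age_at_death": lo + 1,
                         "death_cmc": WINDOW[0] + 6,
                         "birth_cmc": WINDOW[0] + 6 - 12 * (lo + 1) - 3})
        sib = make_siblings(rows)
        resp = make_respondents([40, 40])
        qm = estimate_35q15(sib, resp, WINDOW, sex="m").q
        qf = estimate_35q15(sib, resp, WINDOW, sex="f").q
        qb = estimate_35q15(sib, resp, WINDOW, sex="both").q
        assert qf < qb < qm

    def test_weight_rescaling_invariance(self, survey):
        resp, sib = survey
        window = (INTERVIEW - 36, INTERVIEW)
        ones = estimate_35q15(sib, resp, window, weights=np.ones(len(resp)))
        twos = estimate_35q15(sib, resp, window, weights=2 * np.ones(len(resp)))
        assert ones.q == pytest.approx(twos.q, rel=1e-12)
        assert ones.se == pytest.approx(twos.se, rel=1e-12)


class TestAnnualSeries:
    def test_years_partition_pooled_window(self, survey):
        resp, sib = survey
        whole = tabulate_exposure(sib, resp, (1417, 1453))  # 2019-2021
        parts = [tabulate_exposure(sib, resp, (1417 + 12 * k, 1429 + 12 * k))
                 for k in range(3)]
        np.testing.assert_allclose(whole.deaths_w,
                                   sum(p.deaths_w for p in parts))
        np.testing.assert_allclose(whole.person_years_w,
                                   sum(p.person_years_w for p in parts),
                                   atol=1e-9)

    def test_stationary_series_has_no_trend(self, regime15):
        from scipy.stats import linregress
        resp, sib = simulate_sibships(regime15, 20000, INTERVIEW, seed=31)
        series = annual_series(sib, resp, [2018, 2019, 2020, 2021, 2022])
        q = [e.q for e in series]
        fit = linregress(range(5), q)
        assert abs(fit.slope) <= 1.96 * fit.stderr

    def test_empty_year_flagged(self, survey):
        resp, sib = survey
        series = annual_series(sib, resp, [1900])
        assert np.isnan(series[0].q)
        assert any("unestimable" in f for f in series[0].flags)


class TestSubnationalScaling:
    def test_unit_ratio_identity(self):
        m = np.full(7, 0.004)
        assert scale_subnational(m, 0.08, 0.08) == pytest.approx(chain_35q15(m))

    def test_zero_ratio_gives_zero(self):
        assert scale_subnational(np.full(7, 0.004), 0.0, 0.08) == 0.0

    def test_small_rates_scale_first_order(self):
        m = np.full(7, 0.003)
        q1 = scale_subnational(m, 0.05, 0.05)
        q2 = scale_subnational(m, 0.10, 0.05)
        assert q2 / q1 == pytest.approx(2.0, rel=0.06)

    def test_accepts_national_probability(self):
        q = scale_subnational(0.15, 0.08, 0.08)
        assert q == pytest.approx(0.15, rel=1e-9)
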