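"""Birth-history ASFR/TFR estimation, jackknife variance, vital rates."""

import numpy as np
import pandas as pd
import pytest

import fertdecomp as fd
from fertdecomp.constants import AGE_MIN_MONTHS
from fertdecomp.errors import EstimationError, ParameterError
from fertdecomp.fertility_rates import RatePeriod, parse_birth_history

from conftest import INTERVIEW, make_women

# printed 2017 schedules used as known inputs
NATIONAL = [26.9, 109.5, 156.1, 137.1, 87.8, 26.9, 1.6]
JORDANIAN = [17.2, 103.9, 153.0, 136.7, 89.7, 24.9, 1.4]
SYRIAN = [133.3, 247.5, 216.4, 188.7, 85.3, 53.5, 7.5]


def brute_force_asfr(women, period):
    """Independent month-by-month tally of exposure and births."""
    exp_months = np.zeros(7)
    births = np.zeros(7)
    for _, w in women.iterrows():
        for cmc in range(period.start_cmc, period.end_cmc):
            if cmc >= w.v008:
                continue
            age = cmc - w.v011
            if 180 <= age < 600:
                exp_months[(age - 180) // 60] += w.sample_weight
        for b in parse_birth_history(w.bh_cmcs):
            if period.start_cmc <= b < min(period.end_cmc, w.v008):
                age = b - w.v011
                if 180 <= age < 600:
                    births[(age - 180) // 60] += w.sample_weight
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(exp_months > 0, 1000.0 * births / (exp_months / 12.0), np.nan)


class TestComputeASFR:
    def test_single_woman_hand_computation(self):
        # exactly 5 years observed in 20-24 with one birth there
        period = RatePeriod(1000, 1060)
        women = make_women(
            [dict(v011=760, v008=1415, marriage_cmc=1000, bh_cmcs="1030")]
        )
        asfr = fd.compute_asfr(women, period)
        assert asfr.rates[1] == pytest.approx(200.0)
        # no exposure outside 20-24 for this woman: flagged, contributes 0
        others = np.delete(asfr.rates, 1)
        assert np.all(np.isnan(others) | (others == 0.0))
        assert asfr.tfr == pytest.approx(1.0)

    def test_no_births_all_zero(self):
        women = make_women([dict(), dict()])
        asfr = fd.compute_asfr(women, RatePeriod(INTERVIEW - 36, INTERVIEW))
        assert np.allclose(asfr.rates[~np.isnan(asfr.rates)], 0.0)

    def test_matches_brute_force_oracle_on_small_fixture(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(10):
            age = int(rng.integers(200, 590))
            v011 = INTERVIEW - age
            births = sorted(rng.integers(v011 + 190, INTERVIEW + 1, size=rng.integers(0, 4)))
            rows.append(
                dict(v011=v011, sample_weight=float(rng.uniform(0.5, 2.0)),
                     bh_cmcs=" ".join(map(str, births)))
            )
        women = make_women(rows)
        period = RatePeriod(INTERVIEW - 60, INTERVIEW - 10)
        got = fd.compute_asfr(women, period).rates
        want = brute_force_asfr(women, period)
        assert np.allclose(got, want, equal_nan=True)

    def test_additivity_over_period_partition(self, survey_2017, period_2017):
        whole = fd.compute_asfr(survey_2017.population, period_2017).table
        parts = [
            fd.compute_asfr(
                survey_2017.population,
                RatePeriod(period_2017.start_cmc + 12 * k, period_2017.start_cmc + 12 * (k + 1)),
            ).table
            for k in range(3)
        ]
        for col in ("births", "exposure_years"):
            assert np.allclose(whole[col], sum(p[col] for p in parts))

    def test_equal_weights_match_unweighted(self, survey_2017, period_2017):
        w = fd.compute_asfr(survey_2017.women, period_2017, weights="sample_weight")
        u = fd.compute_asfr(survey_2017.women, period_2017, weights=None)
        assert np.allclose(w.rates, u.rates, equal_nan=True)

    def test_zero_exposure_group_flagged_not_zero(self):
        women = make_women([dict(v011=INTERVIEW - 300)])  # aged 25: never in 45-49
        asfr = fd.compute_asfr(women, RatePeriod(INTERVIEW - 36, INTERVIEW))
        assert "45-49" in asfr.undefined_groups
        assert np.isnan(asfr.rates[6])


class TestTFRFromASFR:
    @pytest.mark.parametrize(
        "rates,expected",
        [(NATIONAL, 2.7), (JORDANIAN, 2.6), (SYRIAN, 4.7)],
    )
    def test_published_schedules(self, rates, expected):
        assert round(fd.tfr_from_asfr(rates), 1) == expected

    def test_zero_rates(self):
        assert fd.tfr_from_asfr(np.zeros(7)) == 0.0

    def test_missing_group_errors(self):
        with pytest.raises(EstimationError):
            fd.tfr_from_asfr(np.array(NATIONAL[:6]))
        with pytest.raises(EstimationError):
            fd.tfr_from_asfr(np.array(NATIONAL[:6] + [np.nan]))


class TestAnnualSeries:
    def test_interview_truncation(self):
        # interview July 2017 (CMC 1411): only Jan-Jun contribute exposure
        women = make_women([dict(v011=1411 - 300, v008=1411)], v008=1411)
        asfr = fd.compute_asfr(women, RatePeriod.calendar_year(2017))
        assert asfr.table["exposure_years"].sum() == pytest.approx(0.5)

    def test_stationary_series_is_flat(self, survey_2017):
        series = fd.annual_tfr_series(survey_2017.population, range(2013, 2017))
        assert series.notna().all()
        assert series.max() - series.min() < 0.35  # Monte-Carlo wiggle only


class TestJackknife:
    @staticmethod
    def _weighted_parity(df):
        w = df["sample_weight"].to_numpy()
        return float(np.dot(w, df["n_births"].to_numpy()) / w.sum())

    def test_constant_statistic_zero_se(self):
        women = make_women([dict(cluster_id=c, bh_cmcs="1200") for c in range(4)])
        res = fd.jackknife_ci(women, self._weighted_parity)
        assert res.se == 0.0

    def test_matches_enumerated_replicates_three_clusters(self):
        women = make_women(
            [
                dict(cluster_id=0, bh_cmcs="1200 1250"),
                dict(cluster_id=0, bh_cmcs=""),
                dict(cluster_id=1, bh_cmcs="1300"),
                dict(cluster_id=2, bh_cmcs="1210 1260 1310"),
                dict(cluster_id=2, bh_cmcs="1220"),
            ]
        )
        # enumerate leave-one-out replicates by hand
        full = [2, 0, 1, 3, 1]
        drop0 = np.mean([1, 3, 1])          # clusters 1,2
        drop1 = np.mean([2, 0, 3, 1])       # clusters 0,2
        drop2 = np.mean([2, 0, 1])          # clusters 0,1
        reps = np.array([drop0, drop1, drop2])
        want_se = np.sqrt(2 / 3 * np.sum((reps - reps.mean()) ** 2))
        res = fd.jackknife_ci(women, self._weighted_parity)
        assert res.estimate == pytest.approx(np.mean(full))
        assert res.se == pytest.approx(want_se)
        assert res.high - res.low == pytest.approx(2 * 1.959963984540054 * want_se)

    def test_se_scales_with_cluster_count(self):
        rng = np.random.default_rng(11)

        def build(k):
            return make_women(
                [dict(cluster_id=c, bh_cmcs=" ".join(["1200"] * int(rng.integers(0, 5))))
                 for c in range(k)]
            )

        se_small = fd.jackknife_ci(build(60), self._weighted_parity).se
        se_large = fd.jackknife_ci(build(240), self._weighted_parity).se
        assert se_small / se_large == pytest.approx(2.0, rel=0.35)

    def test_requires_two_clusters(self):
        women = make_women([dict(cluster_id=0), dict(cluster_id=0)])
        with pytest.raises(EstimationError):
            fd.jackknife_ci(women, self._weighted_parity)


class TestVitalRates:
    def test_closed_form_interpolation(self):
        vitals = pd.DataFrame(
            dict(year=[2000, 2001], births=[1000.0, 3000.0],
                 pop_end_year_total=[100000.0, 110000.0],
                 wra_end_year=[26000.0, 28600.0])
        )
        vr = fd.vital_rates(vitals)
        assert vr["midyear_pop"].iloc[0] == pytest.approx(100000 * np.sqrt(1.1))
        assert vr["cbr"].iloc[0] == pytest.approx(28.60, abs=0.005)

    def test_zero_growth_midyear_equals_endyear(self):
        vitals = pd.DataFrame(
            dict(year=[2000, 2001], births=[100.0, 100.0],
                 pop_end_year_total=[5000.0, 5000.0], wra_end_year=[1300.0, 1300.0])
        )
        vr = fd.vital_rates(vitals)
        assert vr["midyear_pop"].iloc[0] == pytest.approx(5000.0)

    def test_recovers_planted_gfr(self):
        vitals = fd.generate_vitals(range(2007, 2019), gfr=82.7, growth_rate=0.05)
        vr = fd.vital_rates(vitals)
        assert np.allclose(vr["gfr"], 82.7)

    def test_nonpositive_population_rejected(self):
        vitals = pd.DataFrame(
            dict(year=[2000, 2001], births=[1.0, 1.0],
                 pop_end_year_total=[100.0, 0.0], wra_end_year=[10.0, 10.0])
        )
        with pytest.raises(ParameterError):
            fd.vital_rates(vitals)
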