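"""Prevalence, unmet need, wanted fertility, infecundity, comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fertdecomp as fd
from fertdecomp.constants import NON_NUMERIC
from fertdecomp.errors import ClassificationError, EstimationError, ParameterError
from fertdecomp.fertility_rates import parse_birth_history
from fertdecomp.fp_indicators import UNMET_CATEGORIES, unmet_need
from fertdecomp.params import national_2017_schedule

from conftest import INTERVIEW, make_roster, make_women

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")


class TestCPR:
    def test_hand_counted_toy(self):
        rows = (
            [dict(current_method=m) for m in ("pill", "iud", "condom")]  # modern
            + [dict(current_method=m) for m in ("withdrawal", "periodic_abstinence")]
            + [dict() for _ in range(5)]
        )
        women = make_women(rows)
        assert fd.cpr(women) == pytest.approx(50.0)
        assert fd.cpr(women, modern_only=True) == pytest.approx(30.0)

    def test_no_users_zero(self):
        assert fd.cpr(make_women([dict(), dict()])) == 0.0

    def test_empty_denominator_errors(self):
        with pytest.raises(EstimationError):
            fd.cpr(make_women([dict(currently_married=False)]))

    def test_modern_plus_traditional_equals_total(self, survey_2017):
        total = fd.cpr(survey_2017.women)
        mcpr = fd.cpr(survey_2017.women, modern_only=True)
        mix = fd.method_mix(survey_2017.women)
        tcpr = mix.loc[~mix["modern"], "prevalence_pct"].sum()
        assert mcpr + tcpr == pytest.approx(total, abs=1e-9)


class TestAverageEffectiveness:
    def test_single_method(self):
        assert fd.average_effectiveness({"pill": 1.0}, {"pill": 0.10}) == pytest.approx(0.90)

    def test_even_mix(self):
        got = fd.average_effectiveness({"iud": 0.5, "condom": 0.5},
                                       {"iud": 0.02, "condom": 0.20})
        assert got == pytest.approx(0.89)

    def test_dropping_low_effectiveness_methods_raises_mean(self):
        before = {"iud": 0.21, "pill": 0.09, "condom": 0.075, "withdrawal": 0.136,
                  "periodic_abstinence": 0.034}
        after = {"iud": 0.21, "pill": 0.09, "condom": 0.048, "withdrawal": 0.121,
                 "periodic_abstinence": 0.012}
        assert fd.average_effectiveness(after) > fd.average_effectiveness(before)

    def test_missing_method_errors(self):
        with pytest.raises(ParameterError):
            fd.average_effectiveness({"pill": 1.0}, {"iud": 0.02})


class TestUnmetNeed:
    def test_user_limiting_branch(self):
        women = make_women([dict(current_method="pill", preference="want_no_more")])
        assert unmet_need(women).iloc[0] == "met_limiting"

    def test_pregnant_mistimed_is_unmet_spacing(self):
        women = make_women(
            [dict(pregnant_now=True, wantedness_current_or_last="mistimed")]
        )
        assert unmet_need(women).iloc[0] == "unmet_spacing"

    def test_quoted_infecundity_criteria(self):
        # married 6 years, no births in 5 years, never used, "can't get pregnant"
        women = make_women(
            [dict(marriage_cmc=INTERVIEW - 72, bh_cmcs="", ever_used=False,
                  preference="declared_infecund")]
        )
        assert unmet_need(women).iloc[0] == "infecund_menopausal"

    def test_long_married_never_user_without_recent_birth(self):
        women = make_women(
            [dict(marriage_cmc=INTERVIEW - 100, bh_cmcs=str(INTERVIEW - 90),
                  ever_used=False, preference="want_no_more")]
        )
        assert unmet_need(women).iloc[0] == "infecund_menopausal"

    def test_never_user_with_recent_birth_never_infecund(self):
        women = make_women(
            [dict(marriage_cmc=INTERVIEW - 100, bh_cmcs=str(INTERVIEW - 12),
                  ever_used=False, preference="declared_infecund", amenorrheic=False)]
        )
        assert unmet_need(women).iloc[0] != "infecund_menopausal"

    def test_missing_field_is_explicit_error(self):
        women = make_women([dict()]).drop(columns=["preference"])
        with pytest.raises(ClassificationError):
            unmet_need(women)
        women = make_women([dict()])
        women.loc[0, "wantedness_current_or_last"] = np.nan
        with pytest.raises(ClassificationError):
            unmet_need(women)

    @given(st.data())
    def test_partition_sums_to_100(self, data):
        n = data.draw(st.integers(1, 8))
        rows = []
        for _ in range(n):
            rows.append(
                dict(
                    current_method=data.draw(st.sampled_from(
                        ["none", "pill", "iud", "withdrawal", "female_sterilization"])),
                    preference=data.draw(st.sampled_from(
                        ["want_soon", "want_later", "undecided", "want_no_more",
                         "sterilized", "declared_infecund"])),
                    pregnant_now=data.draw(st.booleans()),
                    amenorrheic=data.draw(st.booleans()),
                    wantedness_current_or_last=data.draw(st.sampled_from(
                        ["then", "mistimed", "unwanted", "none"])),
                    ever_used=data.draw(st.booleans()),
                    marriage_cmc=INTERVIEW - data.draw(st.integers(1, 300)),
                    bh_cmcs=data.draw(st.sampled_from(
                        ["", str(INTERVIEW - 10), str(INTERVIEW - 100)])),
                    sample_weight=data.draw(st.floats(0.1, 3.0)),
                )
            )
        women = make_women(rows)
        dist = fd.unmet_need_distribution(women)
        assert set(dist.index) == set(UNMET_CATEGORIES)
        assert dist.sum() == pytest.approx(100.0)

    def test_generator_output_partitions(self, survey_2017):
        dist = fd.unmet_need_distribution(survey_2017.women)
        assert dist.sum() == pytest.approx(100.0)


class TestWantedTFR:
    def test_equals_tfr_when_ideals_unreached(self, period_2017):
        women = make_women(
            [dict(v011=INTERVIEW - 360, bh_cmcs=f"{INTERVIEW - 20} {INTERVIEW - 5}",
                  ideal_children=8)]
        )
        assert fd.wanted_tfr(women, period_2017) == pytest.approx(
            fd.compute_asfr(women, period_2017).tfr
        )

    def test_non_numeric_ideal_counts_all_wanted(self, period_2017):
        women = make_women(
            [dict(v011=INTERVIEW - 360, bh_cmcs=f"{INTERVIEW - 20} {INTERVIEW - 5}",
                  ideal_children=NON_NUMERIC)]
        )
        assert fd.wanted_tfr(women, period_2017) == pytest.approx(
            fd.compute_asfr(women, period_2017).tfr
        )

    def test_wtfr_never_exceeds_tfr(self, survey_2017, period_2017):
        wtfr = fd.wanted_tfr(survey_2017.women, period_2017)
        tfr = fd.compute_asfr(survey_2017.women, period_2017).tfr
        assert wtfr <= tfr + 1e-12

    def test_matches_history_pruning_oracle(self, period_2017):
        """Dropping unwanted births from histories and recomputing the plain
        TFR must equal the wanted-TFR path (denominators are exposure,
        unaffected by removing births)."""
        params = national_2017_schedule(n_women=1500, seed=42, calendar_length_months=12)
        women = fd.generate_survey(params).women.copy()
        pruned = women.copy()
        kept = []
        for bh, ideal in zip(women["bh_cmcs"], women["ideal_children"]):
            h = parse_birth_history(bh)
            if ideal == NON_NUMERIC:
                kept.append(" ".join(map(str, h)))
                continue
            keep = [b for j, b in enumerate(h)
                    if sum(1 for x in h if x < b - 9) < ideal]
            kept.append(" ".join(map(str, keep)))
        pruned["bh_cmcs"] = kept
        want = fd.compute_asfr(pruned, period_2017).tfr
        got = fd.wanted_tfr(women, period_2017)
        assert got == pytest.approx(want, abs=1e-12)

    def test_planted_one_child_ideal_gap(self, period_2017):
        params = national_2017_schedule(
            n_women=3000, seed=13, calendar_length_months=12,
            ideal_family_size_dist={1: 1.0},
        )
        women = fd.generate_survey(params).women
        tfr = fd.compute_asfr(women, period_2017).tfr
        wtfr = fd.wanted_tfr(women, period_2017)
        assert wtfr < tfr - 0.3  # most recent births exceed a 1-child ideal


class TestInfecundity:
    def test_all_mothers_no_primary_sterility(self):
        women = make_women(
            [dict(v011=INTERVIEW - 570, bh_cmcs=str(INTERVIEW - 200)) for _ in range(5)]
        )
        assert fd.infecundity_measures(women)["primary_sterility_pct"] == 0.0

    def test_hand_counted_primary_sterility(self):
        rows = [dict(v011=INTERVIEW - 570, bh_cmcs=str(INTERVIEW - 200))
                for _ in range(9)]
        rows.append(dict(v011=INTERVIEW - 570, bh_cmcs=""))
        got = fd.infecundity_measures(make_women(rows))["primary_sterility_pct"]
        assert got == pytest.approx(10.0)

    def test_secondary_near_planted_share(self):
        params = national_2017_schedule(n_women=5000, seed=8, calendar_length_months=12)
        survey = fd.generate_survey(params)
        got = fd.infecundity_measures(survey.women)["secondary_infecund_pct"]
        assert got == pytest.approx(14.5, abs=3.0)


class TestMarriageExposure:
    def test_all_newlyweds_in_first_band(self):
        women = make_women([dict(marriage_cmc=INTERVIEW) for _ in range(4)])
        tabs = fd.marriage_exposure_tabs(women, make_roster([dict()]))
        assert tabs["time_since_first_marriage"]["<2"] == pytest.approx(100.0)

    def test_published_2017_band_shares_from_weights(self):
        shares = (8.85, 11.65, 19.78, 17.19, 42.52)
        durations_years = (1, 3, 7, 12, 20)
        women = make_women(
            [dict(marriage_cmc=INTERVIEW - 12 * d, sample_weight=s)
             for d, s in zip(durations_years, shares)]
        )
        tabs = fd.marriage_exposure_tabs(women, make_roster([dict()]))
        got = tabs["time_since_first_marriage"].to_numpy()
        # printed shares sum to 100.04; agreement at printed precision
        assert np.allclose(got, shares, atol=0.01)

    def test_four_week_boundary_is_one_month(self):
        women = make_women(
            [dict(months_since_last_sex=1), dict(months_since_last_sex=2)]
        )
        tabs = fd.marriage_exposure_tabs(women, make_roster([dict()]))
        assert tabs["pct_sex_last_4_weeks"] == pytest.approx(50.0)


class TestCompareSurveys:
    def test_identical_surveys_not_significant(self):
        women = make_women(
            [dict(cluster_id=c % 5, current_method="pill" if c % 2 else "none")
             for c in range(20)]
        )
        res = fd.compare_surveys(fd.cpr, women, women.copy())
        assert res.difference == 0.0
        assert not res.significant

    def test_planted_difference_detected(self):
        a = fd.generate_survey(national_2017_schedule(
            n_women=2500, seed=31, calendar_length_months=12)).women
        low_mix = {m: v * 0.75 for m, v in
                   national_2017_schedule().method_mix.items()}
        b = fd.generate_survey(national_2017_schedule(
            n_women=2500, seed=32, calendar_length_months=12,
            method_mix=low_mix)).women
        res = fd.compare_surveys(fd.cpr, a, b)
        assert res.difference < -5
        assert res.significant

    def test_too_few_clusters_error(self):
        women = make_women([dict(cluster_id=0), dict(cluster_id=0)])
        with pytest.raises(EstimationError):
            fd.compare_surveys(fd.cpr, women, women)
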