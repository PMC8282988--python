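"""Shared fixtures and toy-record builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import fertdecomp as fd
from fertdecomp.params import national_2017_schedule

INTERVIEW = 1415  # November 2017


def make_women(rows, v008: int = INTERVIEW) -> pd.DataFrame:
    """Build a respondent DataFrame from partial row dicts.

    Unspecified fields get a consistent default: a 25-year-old married
    woman, weight 1, no births, not using contraception.
    """
    out = []
    for i, row in enumerate(rows):
        base = dict(
            woman_id=i,
            cluster_id=row.get("cluster_id", i % 3),
            stratum_id=0,
            sample_weight=1.0,
            v008=v008,
            v011=v008 - 300,
            ever_married=True,
            marriage_cmc=None,
            currently_married=True,
            living_with_husband=True,
            nationality="jordanian",
            bh_cmcs="",
            n_births=0,
            current_method="none",
            ever_used=False,
            ideal_children=4,
            preference="want_soon",
            pregnant_now=False,
            wantedness_current_or_last="none",
            months_since_last_sex=0,
            amenorrheic=False,
        )
        base.update(row)
        if base["marriage_cmc"] is None:
            base["marriage_cmc"] = base["v011"] + 240  # married at age 20
        base["n_births"] = len(str(base["bh_cmcs"]).split())
        out.append(base)
    return pd.DataFrame(out)


def make_roster(rows) -> pd.DataFrame:
    out = []
    for i, row in enumerate(rows):
        base = dict(
            member_id=i,
            age_years=25,
            sex="female",
            marital_status="ever_married",
            nationality="jordanian",
            hh_weight=1.0,
            cluster_id=i % 3,
        )
        base.update(row)
        out.append(base)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def survey_2017():
    """Mid-sized synthetic round under the published 2017 national schedule."""
    params = national_2017_schedule(n_women=4000, seed=20170)
    survey = fd.generate_survey(params)
    fd.generate_calendars(survey)
    return survey


@pytest.fixture(scope="session")
def period_2017():
    return fd.RatePeriod.years_before_interview(INTERVIEW, 3)
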