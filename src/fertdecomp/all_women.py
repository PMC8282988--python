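"""Ever-married-sample to all-women conversion via the household roster.

Surveys that interview only ever-married women understate all-women
fertility denominators.  Where non-marital childbearing is negligible,
never-married women counted in the household roster can be assumed
childless and added to the exposure: each age group's denominator is
inflated by ``(ever_married + never_married) / ever_married`` while the
numerator (births) is unchanged.  The roster records age only in
completed years, so a woman aged ``a`` years is treated as exactly
``a + 0.5`` years old (halfway through the single-year age group).

Two factor flavours are provided.  The snapshot factor uses weighted
headcounts at the interview.  The exposure factor, given a reporting
period and the respondent file, back-projects roster ages over the period
and forms the ratio of woman-months — the exact decomposition of
all-women exposure under the childlessness assumption, equivalent to
appending the never-married women to the sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import (
    AGE_GROUP_LABELS,
    AGE_MAX_MONTHS,
    AGE_MIN_MONTHS,
    GROUP_WIDTH_MONTHS,
    N_AGE_GROUPS,
)
from .errors import EstimationError, ParameterError
from .fertility_rates import ASFRTable, RatePeriod, compute_asfr


def _roster_age_months(roster: pd.DataFrame) -> np.ndarray:
    # age + 0.5 years: completed years -> assume mid single-year group
    return roster["age_years"].to_numpy(dtype=float) * 12.0 + 6.0


def _headcount_by_group(roster: pd.DataFrame, mask: np.ndarray) -> np.ndarray:
    age_m = _roster_age_months(roster)
    w = roster["hh_weight"].to_numpy(dtype=float)
    g = ((age_m - AGE_MIN_MONTHS) // GROUP_WIDTH_MONTHS).astype(int)
    ok = mask & (age_m >= AGE_MIN_MONTHS) & (age_m < AGE_MAX_MONTHS)
    return np.bincount(g[ok], weights=w[ok], minlength=N_AGE_GROUPS)[:N_AGE_GROUPS]


def _exposure_months_by_group(
    roster: pd.DataFrame, mask: np.ndarray, period: RatePeriod, interview_cmc: int
) -> np.ndarray:
    """Weighted woman-months per age group contributed over ``period``."""
    age_m = _roster_age_months(roster)
    w = roster["hh_weight"].to_numpy(dtype=float)
    pseudo_v011 = interview_cmc - age_m  # fractional CMC of birth
    lo = np.maximum(period.start_cmc, pseudo_v011 + AGE_MIN_MONTHS)
    hi = np.minimum.reduce(
        [
            np.full_like(pseudo_v011, min(period.end_cmc, interview_cmc)),
            pseudo_v011 + AGE_MAX_MONTHS,
        ]
    )
    out = np.zeros(N_AGE_GROUPS)
    for g in range(N_AGE_GROUPS):
        g_lo = pseudo_v011 + AGE_MIN_MONTHS + g * GROUP_WIDTH_MONTHS
        g_hi = g_lo + GROUP_WIDTH_MONTHS
        overlap = np.clip(np.minimum(hi, g_hi) - np.maximum(lo, g_lo), 0, None)
        out[g] = float(np.dot(w[mask], overlap[mask]))
    return out


def roster_factors(
    roster: pd.DataFrame,
    by_nationality: bool = False,
    period: RatePeriod | None = None,
    women: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """All-women inflation factors per age group (and nationality stratum).

    Without ``period``: snapshot headcount factors,
    ``(EM + NM) / EM`` from weighted roster counts at interview.  With
    ``period`` (and the respondent file ``women`` for exact ever-married
    exposure), factors are ratios of woman-months over the period.
    Cells with no ever-married women get an undefined (NaN) factor.
    """
    ever = roster["marital_status"].to_numpy() == "ever_married"
    never = roster["marital_status"].to_numpy() == "never_married"
    strata = roster["nationality"].unique().tolist() if by_nationality else [None]

    rows = []
    for nat in strata:
        in_stratum = np.ones(len(roster), dtype=bool)
        if nat is not None:
            in_stratum = roster["nationality"].to_numpy() == nat
        if period is None:
            em = _headcount_by_group(roster, ever & in_stratum)
            nm = _headcount_by_group(roster, never & in_stratum)
        else:
            if women is None:
                raise ParameterError("period-based factors need the respondent file")
            wsel = women if nat is None else women[women["nationality"] == nat]
            interview = int(women["v008"].iloc[0])
            em_tab = compute_asfr(wsel, period).table
            em = em_tab["exposure_years"].to_numpy() * 12.0
            nm = _exposure_months_by_group(roster, never & in_stratum, period, interview)
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(em > 0, (em + nm) / em, np.nan)
        for g in range(N_AGE_GROUPS):
            rows.append(
                dict(
                    age_group=AGE_GROUP_LABELS[g],
                    nationality=nat if nat is not None else "all",
                    ever_married=em[g],
                    never_married=nm[g],
                    factor=factor[g],
                )
            )
    return pd.DataFrame(rows)


def all_women_tfr(asfr_evermarried: ASFRTable, factors: pd.DataFrame, nationality: str = "all") -> ASFRTable:
    """Adjust an ever-married-sample ASFR table to the all-women scale.

    Exposure in each group is inflated by its factor; births are
    unchanged.  A group with births but no defined factor is an error.
    """
    f = factors[factors["nationality"] == nationality].set_index("age_group")["factor"]
    f = f.reindex(AGE_GROUP_LABELS).to_numpy(dtype=float)
    tab = asfr_evermarried.table.copy()
    births = tab["births"].to_numpy(dtype=float)
    if np.any(np.isnan(f) & (births > 0)):
        raise EstimationError("missing all-women factor for a group with births")
    exp_years = tab["exposure_years"].to_numpy(dtype=float) * np.where(np.isnan(f), 1.0, f)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(exp_years > 0, 1000.0 * births / exp_years, np.nan)
    tab["exposure_years"] = exp_years
    tab["rate_per_1000"] = rate
    return ASFRTable(tab)
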