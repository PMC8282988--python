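"""Retrospective contraceptive-calendar analysis.

The calendar records one code per month, index 1 = interview month,
increasing index = earlier months: ``B`` birth, ``P`` pregnant, ``T``
termination, method codes, ``0`` non-use.  Monthly prevalence applies the
standard exclusion rules for retrospective calendars: months before a
woman's first marriage are excluded (marital status within the calendar
is unknown), and so are months in which she was 45 or older (women over
45 at a past month would be over 49, hence outside the sample, had they
been interviewed then).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import CALENDAR_CODE_TO_METHOD, MODERN_METHODS, NON_METHOD_CODES
from .errors import SchemaError

_CAL_AGE_MIN = 15 * 12
_CAL_AGE_MAX = 45 * 12  # exclusive: married women aged 15-44 at the month

OUTCOME_CATEGORIES = ("none", "birth", "miscarriage", "abortion", "stillbirth")


def _require_calendar(women: pd.DataFrame) -> None:
    if "calendar" not in women.columns:
        raise SchemaError("calendar analysis requires a 'calendar' column")


def monthly_cpr(women: pd.DataFrame, modern_only: bool = False,
                weights: str | None = "sample_weight") -> pd.DataFrame:
    """Monthly contraceptive prevalence (%) reconstructed from calendars.

    For each calendar month: the denominator is women already married by
    that month and aged 15-44 in it; the numerator is those whose calendar
    cell is a method code.  Months with an empty denominator are NaN.
    """
    _require_calendar(women)
    lengths = women["calendar"].str.len().unique()
    if len(lengths) != 1:
        raise SchemaError("all calendar strings must have equal length")
    L = int(lengths[0])
    w = np.ones(len(women)) if weights is None else women[weights].to_numpy(dtype=float)
    v008 = women["v008"].to_numpy(dtype=np.int64)
    v011 = women["v011"].to_numpy(dtype=np.int64)
    marr = women["marriage_cmc"].to_numpy(dtype=np.int64)
    cal = np.array([list(c) for c in women["calendar"]])

    rows = []
    for idx in range(1, L + 1):
        month_cmc = v008 - (idx - 1)
        age = month_cmc - v011
        eligible = (marr >= 0) & (marr <= month_cmc) & (age >= _CAL_AGE_MIN) & (age < _CAL_AGE_MAX)
        denom = float(w[eligible].sum())
        codes = cal[:, idx - 1]
        using = ~np.isin(codes, list(NON_METHOD_CODES))
        if modern_only:
            modern = np.array([CALENDAR_CODE_TO_METHOD.get(c) in MODERN_METHODS for c in codes])
            using &= modern
        num = float(w[eligible & using].sum())
        rows.append(
            dict(
                month_index=idx,
                cmc=int(month_cmc[0]) if len(month_cmc) else np.nan,
                eligible_weight=denom,
                prevalence_pct=100.0 * num / denom if denom > 0 else np.nan,
            )
        )
    return pd.DataFrame(rows)


def pregnancy_outcomes(women: pd.DataFrame,
                       weights: str | None = "sample_weight") -> dict:
    """Most recent pregnancy outcome in the calendar, among married women.

    The most recent outcome is the ``B`` or ``T`` cell with the smallest
    month index (closest to the interview); ``T`` cells take their type
    from ``termination_type_last``.  Returns weighted unconditional shares
    (including "none") and shares conditional on having an outcome; a
    termination without a recorded type is reported separately as
    ``unclassified``.
    """
    _require_calendar(women)
    m = women[women["currently_married"].astype(bool)]
    w = np.ones(len(m)) if weights is None else m[weights].to_numpy(dtype=float)

    outcome = []
    for cal, ttype in zip(m["calendar"], m.get("termination_type_last", "none")):
        pos_b = cal.find("B")
        pos_t = cal.find("T")
        candidates = [p for p in (pos_b, pos_t) if p >= 0]
        if not candidates:
            outcome.append("none")
        elif pos_b >= 0 and (pos_t < 0 or pos_b < pos_t):
            outcome.append("birth")
        else:
            outcome.append(
                ttype if ttype in ("miscarriage", "abortion", "stillbirth")
                else "unclassified"
            )
    outcome = np.array(outcome, dtype=object)

    total = float(w.sum())
    cats = list(OUTCOME_CATEGORIES) + (["unclassified"] if (outcome == "unclassified").any() else [])
    uncond = pd.Series(
        {c: 100.0 * float(w[outcome == c].sum()) / total for c in cats}, name="pct"
    )
    has = outcome != "none"
    denom = float(w[has].sum())
    cond_cats = [c for c in cats if c != "none"]
    cond = pd.Series(
        {c: (100.0 * float(w[outcome == c].sum()) / denom if denom > 0 else np.nan)
         for c in cond_cats},
        name="pct",
    )
    return dict(unconditional=uncond, conditional=cond)
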