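"""Family-planning indicators: prevalence and method mix, average
effectiveness, the revised unmet-need classification, wanted fertility,
infecundity measures, marriage/exposure tabulations, and between-survey
significance tests.
"""

from __future__ import annotations

from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .constants import (
    AGE_GROUP_LABELS,
    DEFAULT_FAILURE_RATES,
    MODERN_METHODS,
    NON_NUMERIC,
    age_group_index,
)
from .errors import ClassificationError, EstimationError, ParameterError
from .fertility_rates import (
    RatePeriod,
    compute_asfr,
    jackknife_ci,
    parse_birth_history,
    tfr_from_asfr,
)

UNMET_CATEGORIES = (
    "unmet_spacing",
    "unmet_limiting",
    "met_spacing",
    "met_limiting",
    "no_need_fecund",
    "infecund_menopausal",
    "want_soon",
)

_INFECUND_NO_BIRTH_MONTHS = 60
_INFECUND_MARRIAGE_MONTHS = 60


def _married(women: pd.DataFrame) -> pd.DataFrame:
    return women[women["currently_married"].astype(bool)]


def _weights(df: pd.DataFrame, weights) -> np.ndarray:
    if weights is None:
        return np.ones(len(df))
    return df[weights].to_numpy(dtype=float)


def cpr(women: pd.DataFrame, modern_only: bool = False,
        weights: str | None = "sample_weight") -> float:
    """Contraceptive prevalence (%) among currently married women."""
    m = _married(women)
    if len(m) == 0:
        raise EstimationError("CPR undefined: no currently married women")
    w = _weights(m, weights)
    method = m["current_method"].astype(str)
    using = method != "none"
    if modern_only:
        using &= method.isin(MODERN_METHODS)
    return 100.0 * float(np.dot(w, using)) / float(w.sum())


def method_mix(women: pd.DataFrame, weights: str | None = "sample_weight") -> pd.DataFrame:
    """Per-method prevalence (%) among currently married women."""
    m = _married(women)
    w = _weights(m, weights)
    total = float(w.sum())
    rows = []
    for method, grp in m.groupby("current_method"):
        if method == "none":
            continue
        share = 100.0 * float(_weights(grp, weights).sum()) / total
        rows.append(dict(method=method, prevalence_pct=share,
                         modern=method in MODERN_METHODS))
    return pd.DataFrame(rows, columns=["method", "prevalence_pct", "modern"])


def average_effectiveness(mix: pd.DataFrame | dict,
                          failure_rates: dict | None = None) -> float:
    """Use-weighted mean of (1 - 12-month failure probability)."""
    failure_rates = failure_rates or DEFAULT_FAILURE_RATES
    if isinstance(mix, pd.DataFrame):
        mix = dict(zip(mix["method"], mix["prevalence_pct"]))
    total = sum(mix.values())
    if total <= 0:
        raise EstimationError("average effectiveness undefined for empty mix")
    missing = [m for m in mix if m not in failure_rates]
    if missing:
        raise ParameterError(f"no failure rate for {missing}")
    return sum(share * (1.0 - failure_rates[m]) for m, share in mix.items()) / total


# ---------------------------------------------------------------------------
# Unmet need
# ---------------------------------------------------------------------------

_REQUIRED_UNMET_FIELDS = (
    "currently_married", "current_method", "preference", "pregnant_now",
    "amenorrheic", "wantedness_current_or_last", "ever_used",
    "marriage_cmc", "v008", "bh_cmcs",
)


def unmet_need(women: pd.DataFrame) -> pd.Series:
    """Classify each currently married woman into one unmet-need category.

    Revised DHS-style algorithm: contraceptive users are met need by
    intent; pregnant or postpartum-amenorrheic women are classified by the
    wantedness of that pregnancy (wanted then -> no need, mistimed ->
    unmet spacing, unwanted -> unmet limiting); remaining non-users are
    tested for infecundity (no birth in the past 5 years AND (self-reported
    "can't get pregnant" OR married 5+ years and never used
    contraception)); the fecund rest are allocated by stated preference.

    Returns a Series aligned with ``women`` (``not_married`` for women
    outside the denominator).  Missing required fields raise
    :class:`ClassificationError`.
    """
    for col in _REQUIRED_UNMET_FIELDS:
        if col not in women.columns:
            raise ClassificationError(f"unmet-need classification requires column {col!r}")
        if women[col].isna().any():
            raise ClassificationError(f"missing values in required column {col!r}")

    out = np.full(len(women), "not_married", dtype=object)
    married = women["currently_married"].to_numpy(dtype=bool)
    method = women["current_method"].astype(str).to_numpy()
    pref = women["preference"].astype(str).to_numpy()
    pregnant = women["pregnant_now"].to_numpy(dtype=bool)
    amen = women["amenorrheic"].to_numpy(dtype=bool)
    wanted = women["wantedness_current_or_last"].astype(str).to_numpy()
    ever_used = women["ever_used"].to_numpy(dtype=bool)
    v008 = women["v008"].to_numpy(dtype=np.int64)
    marr = women["marriage_cmc"].to_numpy(dtype=np.int64)

    recent_birth = np.zeros(len(women), dtype=bool)
    for i, (bh, v) in enumerate(zip(women["bh_cmcs"], v008)):
        h = parse_birth_history(bh)
        recent_birth[i] = bool(((h >= v - _INFECUND_NO_BIRTH_MONTHS) & (h < v)).any())

    using = married & (method != "none")
    limit_intent = np.isin(pref, ("want_no_more", "sterilized")) | (method == "female_sterilization")
    out[using & limit_intent] = "met_limiting"
    out[using & ~limit_intent] = "met_spacing"

    preg_pp = married & ~using & (pregnant | amen)
    out[preg_pp & (wanted == "mistimed")] = "unmet_spacing"
    out[preg_pp & (wanted == "unwanted")] = "unmet_limiting"
    out[preg_pp & ~np.isin(wanted, ("mistimed", "unwanted"))] = "no_need_fecund"

    rest = married & ~using & ~preg_pp
    long_married_never_user = (v008 - marr >= _INFECUND_MARRIAGE_MONTHS) & ~ever_used
    infecund = rest & ~recent_birth & ((pref == "declared_infecund") | long_married_never_user)
    out[infecund] = "infecund_menopausal"

    fecund = rest & ~infecund
    out[fecund & (pref == "want_soon")] = "want_soon"
    out[fecund & np.isin(pref, ("want_later", "undecided"))] = "unmet_spacing"
    out[fecund & (pref == "want_no_more")] = "unmet_limiting"
    out[fecund & (pref == "sterilized")] = "met_limiting"
    # a self-declared infecund woman with a recent birth is demonstrably fecund
    out[fecund & (pref == "declared_infecund")] = "no_need_fecund"

    bad = married & ~np.isin(out, UNMET_CATEGORIES)
    if bad.any():
        raise ClassificationError(
            f"unclassifiable preference values: {sorted(set(pref[bad]))}"
        )
    return pd.Series(out, index=women.index, name="unmet_need_status")


def unmet_need_distribution(women: pd.DataFrame,
                            weights: str | None = "sample_weight") -> pd.Series:
    """Weighted % of currently married women in each category (sums to 100)."""
    status = unmet_need(women)
    m = _married(women)
    w = _weights(m, weights)
    s = status.loc[m.index]
    total = float(w.sum())
    shares = {c: 100.0 * float(w[(s == c).to_numpy()].sum()) / total for c in UNMET_CATEGORIES}
    return pd.Series(shares, name="pct")


def unmet_need_rate(women: pd.DataFrame, weights: str | None = "sample_weight") -> float:
    """Total unmet need (%): spacing plus limiting."""
    d = unmet_need_distribution(women, weights)
    return float(d["unmet_spacing"] + d["unmet_limiting"])


# ---------------------------------------------------------------------------
# Wanted fertility
# ---------------------------------------------------------------------------

def wanted_birth_mask(women: pd.DataFrame) -> np.ndarray:
    """Flag each birth (history explosion order) as wanted.

    A birth is wanted when the mother's parity at its conception (births
    more than 9 months before it) was below her ideal family size;
    non-numeric ideal responses count all births as wanted.
    """
    flags = []
    for bh, ideal in zip(women["bh_cmcs"], women["ideal_children"]):
        h = parse_birth_history(bh)
        if h.size == 0:
            continue
        if int(ideal) == NON_NUMERIC:
            flags.extend([True] * h.size)
            continue
        parity_at_conception = np.searchsorted(h, h - 9, side="left")
        flags.extend((parity_at_conception < int(ideal)).tolist())
    return np.array(flags, dtype=bool)


def wanted_tfr(women: pd.DataFrame, period: RatePeriod,
               weights: str | None = "sample_weight") -> float:
    """Wanted TFR: the TFR recomputed keeping only wanted births.

    Denominators are unchanged, so WTFR <= TFR by construction.
    """
    mask = wanted_birth_mask(women)
    asfr = compute_asfr(women, period, weights=weights, birth_mask=mask)
    return tfr_from_asfr(asfr)


# ---------------------------------------------------------------------------
# Infecundity, marriage and exposure
# ---------------------------------------------------------------------------

def infecundity_measures(women: pd.DataFrame,
                         weights: str | None = "sample_weight") -> dict:
    """Primary sterility and secondary (classified) infecundity.

    Primary sterility: weighted % of ever-married women aged 45-49 with an
    empty birth history.  Secondary: weighted % of currently married women
    classified ``infecund_menopausal``, overall and per age group.
    """
    w_all = _weights(women, weights)
    age_m = (women["v008"] - women["v011"]).to_numpy(dtype=np.int64)
    g = age_group_index(age_m)
    parity = np.array([parse_birth_history(bh).size for bh in women["bh_cmcs"]])

    cell = (g == 6)
    if not cell.any():
        primary = np.nan
    else:
        primary = 100.0 * float(np.dot(w_all[cell], parity[cell] == 0)) / float(w_all[cell].sum())

    status = unmet_need(women)
    married = women["currently_married"].to_numpy(dtype=bool)
    infec = (status == "infecund_menopausal").to_numpy()
    secondary = 100.0 * float(np.dot(w_all[married], infec[married])) / float(w_all[married].sum())

    by_age = []
    for k, label in enumerate(AGE_GROUP_LABELS):
        sel = married & (g == k)
        share = (
            100.0 * float(np.dot(w_all[sel], infec[sel])) / float(w_all[sel].sum())
            if sel.any() else np.nan
        )
        by_age.append(dict(age_group=label, infecund_pct=share))
    return dict(
        primary_sterility_pct=primary,
        secondary_infecund_pct=secondary,
        by_age=pd.DataFrame(by_age),
    )


MARRIAGE_DURATION_BANDS = ("<2", "2-4", "5-9", "10-14", ">=15")


def marriage_exposure_tabs(women: pd.DataFrame, roster: pd.DataFrame,
                           weights: str | None = "sample_weight") -> dict:
    """Marriage-duration bands, cohabitation, recent sex, and % married by age."""
    m = _married(women)
    w = _weights(m, weights)
    total = float(w.sum())
    years = (m["v008"] - m["marriage_cmc"]).to_numpy(dtype=float) / 12.0
    edges = [0, 2, 5, 10, 15, np.inf]
    duration = {
        band: 100.0 * float(w[(years >= lo) & (years < hi)].sum()) / total
        for band, lo, hi in zip(MARRIAGE_DURATION_BANDS, edges[:-1], edges[1:])
    }
    living = 100.0 * float(np.dot(w, m["living_with_husband"].to_numpy(dtype=bool))) / total
    # month-granularity convention: <= 1 month counts as "within 4 weeks"
    sex4w = 100.0 * float(np.dot(w, m["months_since_last_sex"].to_numpy() <= 1)) / total

    age_m = roster["age_years"].to_numpy(dtype=float) * 12.0 + 6.0
    rw = roster["hh_weight"].to_numpy(dtype=float)
    ever = roster["marital_status"].to_numpy() == "ever_married"
    g = age_group_index(age_m)
    married_by_age = []
    for k, label in enumerate(AGE_GROUP_LABELS):
        sel = g == k
        share = 100.0 * float(np.dot(rw[sel], ever[sel])) / float(rw[sel].sum()) if sel.any() else np.nan
        married_by_age.append(dict(age_group=label, pct_ever_married=share))
    return dict(
        time_since_first_marriage=pd.Series(duration, name="pct"),
        pct_living_with_husband=living,
        pct_sex_last_4_weeks=sex4w,
        pct_married_by_age=pd.DataFrame(married_by_age),
    )


# ---------------------------------------------------------------------------
# Survey comparison
# ---------------------------------------------------------------------------

class CompareResult(NamedTuple):
    stat_a: float
    stat_b: float
    difference: float
    se: float
    z: float
    significant: bool


def compare_surveys(statistic_fn: Callable[[pd.DataFrame], float],
                    survey_a: pd.DataFrame, survey_b: pd.DataFrame,
                    level: float = 0.95) -> CompareResult:
    """Two-sided z-test for a change in a survey statistic.

    Jackknife standard errors are computed independently in each survey
    and combined as sqrt(se_a^2 + se_b^2).
    """
    ja = jackknife_ci(survey_a, statistic_fn)
    jb = jackknife_ci(survey_b, statistic_fn)
    diff = jb.estimate - ja.estimate
    se = float(np.hypot(ja.se, jb.se))
    if se == 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        z = diff / se
    crit = stats.norm.ppf(0.5 + level / 2)
    return CompareResult(ja.estimate, jb.estimate, diff, se, float(z), bool(abs(z) > crit))
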