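"""Birth-history fertility estimation and vital-registration rates.

Age-specific fertility rates follow the DHS convention: a woman's exact
age in months at any CMC is ``cmc - v011``; births are attributed to the
mother's age group at the birth CMC; exposure is weighted woman-months in
the intersection of the age group and the reporting period, truncated at
the interview month (which is incomplete and excluded).  Confidence
intervals come from a delete-one-cluster jackknife over the primary
sampling units.

Crude birth rates and general fertility rates from vital registration use
exponential mid-year interpolation of end-year populations,
``P_mid = P_prev * exp(r/2)`` with ``r = ln(P / P_prev)``, taking the
mid-year population as the person-years lived in the year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .constants import (
    AGE_GROUP_LABELS,
    AGE_MAX_MONTHS,
    AGE_MIN_MONTHS,
    GROUP_WIDTH_MONTHS,
    N_AGE_GROUPS,
    cmc,
)
from .errors import EstimationError, ParameterError


@dataclass(frozen=True)
class RatePeriod:
    """Half-open CMC interval [start_cmc, end_cmc)."""

    start_cmc: int
    end_cmc: int
    label: str = ""

    def __post_init__(self):
        if self.start_cmc >= self.end_cmc:
            raise ParameterError("RatePeriod requires start_cmc < end_cmc")

    @classmethod
    def years_before_interview(cls, interview_cmc: int, years: int = 3) -> "RatePeriod":
        return cls(interview_cmc - 12 * years, interview_cmc, f"{years}y before interview")

    @classmethod
    def calendar_year(cls, year: int) -> "RatePeriod":
        return cls(cmc(year, 1), cmc(year + 1, 1), str(year))


@dataclass
class ASFRTable:
    """Seven age-group rates per 1,000 woman-years with their ingredients."""

    table: pd.DataFrame  # age_group, births, exposure_years, rate_per_1000[, ci_low, ci_high]

    @property
    def rates(self) -> np.ndarray:
        return self.table["rate_per_1000"].to_numpy(dtype=float)

    @property
    def tfr(self) -> float:
        # an undefined (zero-exposure) group can carry no births, so it
        # contributes nothing to the sum; it stays flagged in
        # ``undefined_groups`` rather than being reported as a zero rate
        rates = self.rates
        if np.isnan(rates).all():
            return np.nan
        return 5.0 * float(np.nansum(rates)) / 1000.0

    @property
    def undefined_groups(self) -> list[str]:
        """Age groups whose rate is undefined because exposure is zero."""
        bad = self.table["rate_per_1000"].isna()
        return self.table.loc[bad, "age_group"].tolist()


def parse_birth_history(bh: str) -> np.ndarray:
    """Birth CMCs from the space-separated ``bh_cmcs`` column."""
    if not isinstance(bh, str) or not bh.strip():
        return np.empty(0, dtype=np.int64)
    return np.array(bh.split(), dtype=np.int64)


def _weights(women: pd.DataFrame, weights) -> np.ndarray:
    if weights is None:
        return np.ones(len(women))
    if isinstance(weights, str):
        return women[weights].to_numpy(dtype=float)
    return np.asarray(weights, dtype=float)


def compute_asfr(
    women: pd.DataFrame,
    period: RatePeriod,
    weights: str | None = "sample_weight",
    exposure: str = "any",
    birth_mask: np.ndarray | None = None,
) -> ASFRTable:
    """Weighted ASFRs (births per 1,000 woman-years) over ``period``.

    ``exposure='any'`` counts all woman-months of the input records
    (the all-women / ever-married-sample convention); ``'married'``
    restricts the denominator to months at or after first marriage, giving
    marital rates.  ``birth_mask`` optionally keeps a subset of births in
    the numerator (aligned with the birth-history explosion order); the
    wanted-fertility calculation uses it.

    Groups with zero exposure get an undefined (NaN) rate and are listed in
    ``ASFRTable.undefined_groups`` rather than reported as zero.
    """
    w = _weights(women, weights)
    v008 = women["v008"].to_numpy(dtype=np.int64)
    v011 = women["v011"].to_numpy(dtype=np.int64)

    lo = np.maximum(period.start_cmc, v011 + AGE_MIN_MONTHS)
    if exposure == "married":
        marr = women["marriage_cmc"].to_numpy(dtype=np.int64)
        lo = np.maximum(lo, np.where(marr >= 0, marr, np.iinfo(np.int64).max // 2))
    elif exposure != "any":
        raise ParameterError("exposure must be 'any' or 'married'")
    hi = np.minimum.reduce([np.full_like(v008, period.end_cmc), v008, v011 + AGE_MAX_MONTHS])

    exp_months = np.zeros(N_AGE_GROUPS)
    for g in range(N_AGE_GROUPS):
        g_lo = v011 + AGE_MIN_MONTHS + g * GROUP_WIDTH_MONTHS
        g_hi = g_lo + GROUP_WIDTH_MONTHS
        overlap = np.clip(np.minimum(hi, g_hi) - np.maximum(lo, g_lo), 0, None)
        exp_months[g] = float(np.dot(w, overlap))

    # explode birth histories
    histories = [parse_birth_history(bh) for bh in women["bh_cmcs"]]
    counts = np.array([h.size for h in histories])
    if counts.sum():
        b_cmc = np.concatenate([h for h in histories if h.size])
        b_idx = np.repeat(np.arange(len(women)), counts)
    else:
        b_cmc = np.empty(0, dtype=np.int64)
        b_idx = np.empty(0, dtype=np.int64)
    keep = (b_cmc >= period.start_cmc) & (b_cmc < period.end_cmc) & (b_cmc < v008[b_idx])
    if birth_mask is not None:
        mask = np.asarray(birth_mask, dtype=bool)
        if mask.size != b_cmc.size:
            raise ParameterError("birth_mask length must match total births")
        keep &= mask
    age_at_birth = b_cmc - v011[b_idx]
    g_idx = (age_at_birth - AGE_MIN_MONTHS) // GROUP_WIDTH_MONTHS
    keep &= (age_at_birth >= AGE_MIN_MONTHS) & (age_at_birth < AGE_MAX_MONTHS)
    births = np.bincount(
        g_idx[keep], weights=w[b_idx[keep]], minlength=N_AGE_GROUPS
    )[:N_AGE_GROUPS]

    exp_years = exp_months / 12.0
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(exp_years > 0, 1000.0 * births / exp_years, np.nan)
    table = pd.DataFrame(
        {
            "age_group": AGE_GROUP_LABELS,
            "births": births,
            "exposure_years": exp_years,
            "rate_per_1000": rate,
        }
    )
    return ASFRTable(table)


def tfr_from_asfr(asfr) -> float:
    """Total fertility rate, ``5 * sum(rates) / 1000``.

    Accepts an :class:`ASFRTable` (zero-exposure groups, which carry no
    births, contribute nothing) or a length-7 rate vector, for which a
    missing (NaN) group makes the TFR undefined and raises.
    """
    if isinstance(asfr, ASFRTable):
        return asfr.tfr
    rates = np.asarray(asfr, dtype=float)
    if rates.shape != (N_AGE_GROUPS,):
        raise EstimationError(f"expected {N_AGE_GROUPS} age-group rates, got {rates.shape}")
    if np.isnan(rates).any():
        raise EstimationError("TFR undefined: some age groups have no exposure")
    return 5.0 * float(rates.sum()) / 1000.0


def annual_tfr_series(women: pd.DataFrame, years) -> pd.Series:
    """TFR per calendar year (Jan-Dec CMC windows), truncated at interview.

    Years with an undefined group rate (no exposure) are reported as NaN.
    """
    out = {}
    for year in years:
        asfr = compute_asfr(women, RatePeriod.calendar_year(int(year)))
        try:
            out[int(year)] = tfr_from_asfr(asfr)
        except EstimationError:
            out[int(year)] = np.nan
    return pd.Series(out, name="tfr")


class JackknifeResult(NamedTuple):
    estimate: float
    low: float
    high: float
    se: float
    n_clusters: int


def jackknife_ci(
    women: pd.DataFrame,
    statistic_fn: Callable[[pd.DataFrame], float],
    level: float = 0.95,
) -> JackknifeResult:
    """Delete-one-cluster jackknife CI for a survey statistic.

    ``statistic_fn`` maps a respondent DataFrame to a scalar; replicates
    drop one ``cluster_id`` at a time.  ``se^2 = (k-1)/k * sum((th_i - mean)^2)``.
    """
    clusters = pd.unique(women["cluster_id"])
    k = len(clusters)
    if k < 2:
        raise EstimationError("jackknife requires at least 2 clusters")
    point = float(statistic_fn(women))
    cl = women["cluster_id"].to_numpy()
    reps = np.array([float(statistic_fn(women[cl != c])) for c in clusters])
    se = float(np.sqrt((k - 1) / k * np.sum((reps - reps.mean()) ** 2)))
    z = stats.norm.ppf(0.5 + level / 2)
    return JackknifeResult(point, point - z * se, point + z * se, se, k)


def vital_rates(vitals: pd.DataFrame) -> pd.DataFrame:
    """CBR and GFR from annual births and end-year populations.

    Growth within year ``t`` is taken as constant exponential,
    ``r = ln(P_t / P_{t-1})``; the mid-year population
    ``P_{t-1} * exp(r/2)`` serves as person-years lived.  The first year of
    the series has no predecessor and is dropped.
    """
    df = vitals.sort_values("year").reset_index(drop=True)
    for col in ("births", "pop_end_year_total", "wra_end_year"):
        if col not in df:
            raise ParameterError(f"vitals table missing column {col!r}")
        if (df[col] <= 0).any():
            raise ParameterError(f"vitals column {col!r} must be positive")
    if not (np.diff(df["year"]) == 1).all():
        raise ParameterError("vitals years must be consecutive")
    pop = df["pop_end_year_total"].to_numpy(dtype=float)
    wra = df["wra_end_year"].to_numpy(dtype=float)
    births = df["births"].to_numpy(dtype=float)

    r_pop = np.log(pop[1:] / pop[:-1])
    r_wra = np.log(wra[1:] / wra[:-1])
    mid_pop = pop[:-1] * np.exp(r_pop * 0.5)
    mid_wra = wra[:-1] * np.exp(r_wra * 0.5)
    return pd.DataFrame(
        {
            "year": df["year"].to_numpy()[1:],
            "cbr": 1000.0 * births[1:] / mid_pop,
            "gfr": 1000.0 * births[1:] / mid_wra,
            "midyear_pop": mid_pop,
            "midyear_wra": mid_wra,
        }
    )
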