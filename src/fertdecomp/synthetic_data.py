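"""Synthetic DHS-like microdata with known ground truth.

The generator simulates a female population aged 15-49 at interview, month
by month: first marriage (piecewise-constant hazard by age), conceptions,
pregnancies ending in births or terminations, postpartum insusceptibility,
secondary infecundity, and a stationary contraceptive-use process.  The
ever-married members of the population form the respondent file (the survey
only interviews ever-married women); every woman enters the household
roster with age in completed years only.

Birth placement uses cohort-calibrated thinning: each month the expected
number of births in every nationality x age-group cell is pinned to
``rate/12000`` times the realized all-women headcount of the cell, and the
corresponding conceptions are allocated among currently married, fecund,
non-pregnant, non-insusceptible women by balanced (floor + Bernoulli)
sampling.  Realized age-specific fertility rates are therefore unbiased
for the planted schedule at any sample size, while pregnancy and
postpartum insusceptibility still suppress conception at the individual
level.  See docs/methods.md for the rationale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    AGE_MAX_MONTHS,
    AGE_MIN_MONTHS,
    DEFAULT_CYP_TABLE,
    GESTATION_MONTHS,
    METHOD_NAMES,
    METHODS,
    MODERN_METHODS,
    N_AGE_GROUPS,
    NON_NUMERIC,
    TERMINATION_PREGNANCY_MONTHS,
    age_group_index,
)
from .errors import ParameterError
from .params import NATIONALITIES, SimParams, INFECUND_AGE_RAMP

_NEVER = 10**9          # sentinel for "event never happens"
_HISTORY_MONTHS = AGE_MAX_MONTHS - AGE_MIN_MONTHS  # 420: full reproductive span
_INFECUND_MIN_LEAD = 69  # onset at least 69 months pre-interview -> no birth in past 5y


@dataclass
class SurveyData:
    """Output bundle of :func:`generate_survey`.

    ``population`` holds one row per simulated woman aged 15-49 (the
    all-women sampling frame); ``women`` is the ever-married respondent
    subset; ``roster`` the household-roster view (completed years of age
    only).  Private fields carry simulation state consumed by
    :func:`generate_calendars`.
    """

    population: pd.DataFrame
    women: pd.DataFrame
    roster: pd.DataFrame
    params: SimParams
    _events: dict = field(default_factory=dict, repr=False)
    _use_window: np.ndarray | None = field(default=None, repr=False)


def _sample_insusceptibility(rng, size, mean, mode):
    """Postpartum insusceptible durations (months)."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if mode == "fixed":
        return np.full(size, int(round(mean)), dtype=np.int64)
    if mean < 1:
        return (rng.random(size) < mean).astype(np.int64)
    return rng.geometric(1.0 / mean, size).astype(np.int64)


def _marriage_age_cdf(annual_hazard):
    """Cumulative first-marriage probability at each exact age in months."""
    monthly = 1.0 - (1.0 - np.asarray(annual_hazard, dtype=float)) ** (1.0 / 12.0)
    h = np.repeat(monthly, 60)                      # ages 180..599
    surv = np.cumprod(1.0 - h)
    return 1.0 - surv


def generate_survey(params: SimParams) -> SurveyData:
    """Simulate a survey round under ``params``; deterministic in ``params.seed``."""
    params.validate()
    n = params.n_women
    V = params.interview_cmc
    ss = np.random.SeedSequence(params.seed)
    (r_demo, r_fert, r_use, r_resp) = [np.random.default_rng(s) for s in ss.spawn(4)]

    # -- demographics ------------------------------------------------------
    shares = np.array([params.nationality_shares.get(nat, 0.0) for nat in NATIONALITIES])
    nat_idx = r_demo.choice(len(NATIONALITIES), size=n, p=shares)
    age_m = r_demo.integers(AGE_MIN_MONTHS, AGE_MAX_MONTHS, size=n)
    v011 = V - age_m

    # first marriage by inverse-CDF sampling on the monthly age grid
    marr_age = np.full(n, _NEVER, dtype=np.int64)
    for k, nat in enumerate(NATIONALITIES):
        sel = nat_idx == k
        if not sel.any():
            continue
        cdf = _marriage_age_cdf(params.marriage_hazard[nat])
        u = r_demo.random(sel.sum())
        pos = np.searchsorted(cdf, u, side="left")
        age_at_marriage = np.where(pos < cdf.size, AGE_MIN_MONTHS + pos, _NEVER)
        marr_age[sel] = age_at_marriage
    ever = marr_age <= age_m
    marriage_cmc = np.where(ever, v011 + marr_age, _NEVER)

    # -- secondary infecundity (sterility onset) ---------------------------
    onset_cmc = np.full(n, _NEVER, dtype=np.int64)
    if params.infecund_share > 0 and ever.any():
        ramp = np.asarray(INFECUND_AGE_RAMP)[age_group_index(age_m)]
        eligible = ever & (marriage_cmc <= V - _INFECUND_MIN_LEAD)
        ramp_sum = ramp[eligible].sum()
        if ramp_sum > 0:
            scale = params.infecund_share * ever.sum() / ramp_sum
            p = np.where(eligible, np.minimum(ramp * scale, 0.95), 0.0)
            hit = r_demo.random(n) < p
            onset = V - _INFECUND_MIN_LEAD - r_demo.integers(0, 60, size=n)
            onset_cmc[hit] = np.maximum(onset[hit], v011[hit] + AGE_MIN_MONTHS)

    # -- fertility process -------------------------------------------------
    rates = np.zeros(len(NATIONALITIES) * N_AGE_GROUPS)
    for k, nat in enumerate(NATIONALITIES):
        rates[k * N_AGE_GROUPS:(k + 1) * N_AGE_GROUPS] = params.asfr_target[nat]
    rho = params.termination_share / (1.0 - params.termination_share)

    blocked_until = np.full(n, -_NEVER, dtype=np.int64)
    ev_w, ev_conc, ev_term, ev_end, ev_block_end = [], [], [], [], []
    # per-cell carry of expected events not yet realized (small cells can
    # momentarily exhaust their susceptible pool; the deficit is deferred,
    # not dropped, so realized totals stay unbiased)
    pending = {"birth": np.zeros(rates.size), "term": np.zeros(rates.size)}
    shortfall = 0.0

    t0 = V - _HISTORY_MONTHS
    for t in range(t0, V):
        b = t + GESTATION_MONTHS - 1              # birth month for conceptions at t
        age_at_b = b - v011
        valid = (age_at_b >= AGE_MIN_MONTHS) & (age_at_b < AGE_MAX_MONTHS)
        key = nat_idx * N_AGE_GROUPS + (age_at_b - AGE_MIN_MONTHS) // 60
        counts = np.bincount(key[valid], minlength=rates.size)
        expected = rates * counts / 12000.0
        if not expected.any() and not any(p.any() for p in pending.values()):
            continue
        susc = (
            valid
            & (marriage_cmc <= t)
            & (t >= blocked_until)
            & (onset_cmc > t)
        )
        for phase, exp_vec in (("birth", expected), ("term", expected * rho)):
            pend = pending[phase]
            pend += exp_vec
            base = np.floor(pend)
            n_events = base.astype(int) + (r_fert.random(pend.size) < pend - base)
            n_events = np.maximum(n_events, 0)
            for k in np.flatnonzero(n_events):
                pool = np.flatnonzero(susc & (key == k))
                take = min(int(n_events[k]), pool.size)
                pend[k] -= take
                if take == 0:
                    continue
                chosen = r_fert.choice(pool, size=take, replace=False) if take < pool.size else pool
                susc[chosen] = False
                if phase == "birth":
                    pp = _sample_insusceptibility(
                        r_fert, take, params.mean_insusceptibility_months,
                        params.insusceptibility_mode,
                    )
                    end = np.full(take, b)
                    block_end = b + pp
                    is_term = False
                else:
                    end = np.full(take, t + TERMINATION_PREGNANCY_MONTHS - 1)
                    block_end = end
                    is_term = True
                blocked_until[chosen] = block_end + 1
                ev_w.extend(chosen.tolist())
                ev_conc.extend([t] * take)
                ev_term.extend([is_term] * take)
                ev_end.extend(end.tolist())
                ev_block_end.extend(np.asarray(block_end).tolist())
    shortfall = float(sum(p.sum() for p in pending.values()))
    if shortfall > max(12.0, 0.02 * max(len(ev_w), 1)):
        warnings.warn(
            f"fertility thinning left {shortfall:.1f} expected conceptions "
            "unrealized (susceptible pools exhausted); realized rates may be low",
            stacklevel=2,
        )

    ev_w = np.asarray(ev_w, dtype=np.int64)
    ev_conc = np.asarray(ev_conc, dtype=np.int64)
    ev_term = np.asarray(ev_term, dtype=bool)
    ev_end = np.asarray(ev_end, dtype=np.int64)
    ev_block_end = np.asarray(ev_block_end, dtype=np.int64)

    # birth histories (births realized by the interview)
    birth_mask = ~ev_term & (ev_end <= V)
    order = np.lexsort((ev_end, ev_w))
    histories: list[list[int]] = [[] for _ in range(n)]
    for w, e, is_b in zip(ev_w[order], ev_end[order], (birth_mask)[order]):
        if is_b:
            histories[w].append(int(e))
    parity = np.array([len(h) for h in histories], dtype=np.int64)

    pregnant_now = np.zeros(n, dtype=bool)
    np.logical_or.at(pregnant_now, ev_w, (ev_conc <= V) & (ev_end > V))
    # insusceptible months are the i months after the birth month
    amen = np.zeros(n, dtype=bool)
    np.logical_or.at(amen, ev_w, ~ev_term & (ev_end < V) & (ev_block_end >= V))
    blocked_at_V = np.zeros(n, dtype=bool)
    np.logical_or.at(blocked_at_V, ev_w, (ev_conc <= V) & (ev_block_end >= V))

    # -- contraceptive-use chain -------------------------------------------
    married = ever  # respondents are treated as currently married (see methods note)
    infecund_now = onset_cmc <= V
    n_married = max(int(married.sum()), 1)
    beta = float((blocked_at_V & married).sum()) / n_married
    phi = float((infecund_now & married).sum()) / n_married
    avail = max(1.0 - beta - phi, 1e-9)
    mix = np.array([params.method_mix.get(m, 0.0) for m in METHOD_NAMES])
    u_tilde = mix / avail
    if u_tilde.sum() > 0.98:
        warnings.warn(
            "planted method mix close to saturation after pregnancy/infecundity "
            "calibration; scaling within-susceptible use down to 0.98",
            stacklevel=2,
        )
        u_tilde *= 0.98 / u_tilde.sum()
    pi0 = 1.0 - u_tilde.sum()
    disc = np.array(
        [0.0] + [params.discontinuation_rate.get(m, METHODS[m]["discontinuation"])
                 for m in METHOD_NAMES]
    )
    adopt = disc[1:] * u_tilde / pi0 if pi0 > 1e-12 else np.zeros(len(METHOD_NAMES))
    init_cum = np.cumsum(np.concatenate(([pi0], u_tilde)))
    adopt_cum = np.cumsum(adopt)

    L = params.calendar_length_months
    n_months = _HISTORY_MONTHS + 1
    blocked_mat = np.zeros((n, n_months), dtype=bool)
    for w, c, be in zip(ev_w, ev_conc, ev_block_end):
        blocked_mat[w, max(c - t0, 0):min(be - t0, n_months - 1) + 1] = True

    state = np.zeros(n, dtype=np.int8)
    use_window = np.zeros((n, L), dtype=np.int8)
    ever_used = np.zeros(n, dtype=bool)
    for t in range(t0, V + 1):
        j = t - t0
        newly = married & (marriage_cmc == t)
        if newly.any():
            u = r_use.random(int(newly.sum()))
            state[newly] = np.searchsorted(init_cum, u, side="right").astype(np.int8)
        state[onset_cmc <= t] = 0
        active = married & (marriage_cmc <= t) & ~blocked_mat[:, j] & (onset_cmc > t)
        if active.any():
            u = r_use.random(n)
            prev = state.copy()
            adopters = active & (prev == 0)
            if adopters.any() and adopt_cum.size and adopt_cum[-1] > 0:
                pick = np.searchsorted(adopt_cum, u, side="right")
                new_state = np.where(pick < len(METHOD_NAMES), pick + 1, 0)
                state[adopters] = new_state[adopters].astype(np.int8)
            quitters = active & (prev > 0) & (u < disc[prev])
            state[quitters] = 0
        shown = np.where(active, state, 0).astype(np.int8)
        ever_used |= shown > 0
        pos = V - t
        if pos < L:
            use_window[:, pos] = shown

    current_idx = use_window[:, 0]
    method_names_arr = np.array(["none"] + list(METHOD_NAMES))
    current_method = method_names_arr[current_idx]

    # -- respondent-report fields ------------------------------------------
    ideal_vals = np.array(list(params.ideal_family_size_dist.keys()))
    ideal_p = np.array(list(params.ideal_family_size_dist.values()), dtype=float)
    ideal = r_resp.choice(ideal_vals, size=n, p=ideal_p / ideal_p.sum())

    # parity at conception of the current pregnancy / most recent birth
    last_event_parity = np.full(n, -1, dtype=np.int64)
    for w in range(n):
        if pregnant_now[w]:
            last_event_parity[w] = parity[w]
        elif parity[w] > 0:
            last_event_parity[w] = parity[w] - 1
    numeric_ideal = np.where(ideal == NON_NUMERIC, 10**6, ideal)
    u = r_resp.random(n)
    wantedness = np.full(n, "none", dtype=object)
    has_event = last_event_parity >= 0
    unwanted = has_event & (last_event_parity >= numeric_ideal)
    mistimed = has_event & ~unwanted & (u < params.mistimed_prob)
    wantedness[has_event] = "then"
    wantedness[mistimed] = "mistimed"
    wantedness[unwanted] = "unwanted"

    u = r_resp.random(n)
    preference = np.full(n, "want_soon", dtype=object)
    reached = parity >= numeric_ideal
    preference[reached & (u < 0.92)] = "want_no_more"
    preference[reached & (u >= 0.92)] = "undecided"
    below = ~reached
    preference[below & (u < 0.50)] = "want_later"
    preference[below & (u >= 0.50) & (u < 0.65)] = "undecided"
    preference[below & (u >= 0.65)] = "want_soon"
    preference[current_method == "female_sterilization"] = "sterilized"
    preference[infecund_now] = "declared_infecund"

    u = r_resp.random(n)
    months_since_sex = np.where(
        u < params.sex_last_4_weeks_prob,
        r_resp.integers(0, 2, size=n),
        2 + r_resp.geometric(0.3, size=n),
    )
    living_with = r_resp.random(n) < params.living_with_husband_prob

    cluster_id = r_resp.integers(0, params.n_clusters, size=n)
    stratum_id = cluster_id % 2
    weight = np.ones(n)
    if params.weight_noise > 0:
        cv2 = params.weight_noise**2
        cw = r_resp.gamma(1.0 / cv2, cv2, size=params.n_clusters)
        weight = cw[cluster_id]

    population = pd.DataFrame(
        {
            "woman_id": np.arange(n),
            "cluster_id": cluster_id,
            "stratum_id": stratum_id,
            "sample_weight": weight,
            "v008": V,
            "v011": v011,
            "ever_married": ever,
            "marriage_cmc": np.where(ever, marriage_cmc, -1),
            "currently_married": ever,
            "living_with_husband": living_with & ever,
            "nationality": np.array(NATIONALITIES)[nat_idx],
            "bh_cmcs": [" ".join(map(str, h)) for h in histories],
            "n_births": parity,
            "current_method": current_method,
            "ever_used": ever_used,
            "ideal_children": ideal.astype(np.int64),
            "preference": preference,
            "pregnant_now": pregnant_now,
            "wantedness_current_or_last": wantedness,
            "months_since_last_sex": months_since_sex.astype(np.int64),
            "amenorrheic": amen,
        }
    )
    women = population[population["ever_married"]].reset_index(drop=True)
    roster = pd.DataFrame(
        {
            "member_id": np.arange(n),
            "age_years": (age_m // 12).astype(np.int64),
            "sex": "female",
            "marital_status": np.where(ever, "ever_married", "never_married"),
            "nationality": np.array(NATIONALITIES)[nat_idx],
            "hh_weight": weight,
            "cluster_id": cluster_id,
        }
    )
    events = dict(woman=ev_w, conception=ev_conc, is_termination=ev_term,
                  end=ev_end, block_end=ev_block_end)
    return SurveyData(population=population, women=women, roster=roster,
                      params=params, _events=events, _use_window=use_window)


# ---------------------------------------------------------------------------
# Calendar strings
# ---------------------------------------------------------------------------

def generate_calendars(survey: SurveyData, params: SimParams | None = None) -> pd.DataFrame:
    """Fill contraceptive-calendar strings for the respondent file.

    Index 1 of the calendar (string position 0) is the interview month;
    increasing index means earlier months.  Cells: ``B`` birth, ``P``
    pregnant, ``T`` termination, method codes, ``0`` non-use.  Pre-marriage
    months are generated (all ``0``) and counted in
    ``premarital_window_months``.  Returns ``survey.women`` with the
    calendar columns appended (also updates the frame in place).
    """
    params = params or survey.params
    if survey._use_window is None:
        raise ParameterError("generate_calendars requires the output of generate_survey")
    L = params.calendar_length_months
    V = params.interview_cmc
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 104729]))

    pop = survey.population
    n = len(pop)
    codes = np.full((n, L), "0", dtype="<U1")
    method_codes = np.array([""] + [METHODS[m]["calendar_code"] for m in METHOD_NAMES])
    use = survey._use_window
    for s in range(1, len(METHOD_NAMES) + 1):
        codes[use == s] = method_codes[s]

    ev = survey._events
    has_term_in_window = np.zeros(n, dtype=bool)
    for w, c, is_t, e in zip(ev["woman"], ev["conception"], ev["is_termination"], ev["end"]):
        # pregnant cells: conception .. end-1; outcome cell at `end`
        lo = max(V - e, 0)           # position of the outcome month
        hi = min(V - c, L - 1)       # position of the conception month
        if hi < 0 or lo > L - 1:
            continue
        for pos in range(max(lo, 0), hi + 1):
            codes[w, pos] = "P"
        if 0 <= V - e < L and e <= V:
            codes[w, V - e] = "T" if is_t else "B"
            if is_t:
                has_term_in_window[w] = True

    term_types = np.array(list(survey.params.termination_type_dist.keys()))
    term_p = np.array(list(survey.params.termination_type_dist.values()), dtype=float)
    drawn = rng.choice(term_types, size=n, p=term_p / term_p.sum())
    termination_type_last = np.where(has_term_in_window, drawn, "none")

    window_start = V - L + 1
    marr = pop["marriage_cmc"].to_numpy()
    premarital = np.where(marr >= 0, np.clip(marr - window_start, 0, L), L)

    cal = pd.DataFrame(
        {
            "woman_id": pop["woman_id"],
            "calendar": ["".join(row) for row in codes],
            "termination_type_last": termination_type_last,
            "premarital_window_months": premarital.astype(np.int64),
        }
    )
    for frame in (survey.population,):
        frame["calendar"] = cal["calendar"]
        frame["termination_type_last"] = cal["termination_type_last"]
        frame["premarital_window_months"] = cal["premarital_window_months"]
    survey.women = survey.population[survey.population["ever_married"]].reset_index(drop=True)
    return survey.women


# ---------------------------------------------------------------------------
# Registry series
# ---------------------------------------------------------------------------

def generate_service_stats(
    years,
    mcpr,
    wra,
    method_mix=None,
    cyp_table=None,
    fp_visits_per_user: float = 2.0,
    facility_buffer: float = 1.15,
    poisson_noise: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Commodity-distribution series implied by a planted mCPR path.

    Users of each modern method are ``mcpr * wra * share``; short-term
    commodity units invert the CYP factors (users x units/CYP), long-acting
    insertions assume steady state (users / years-per-insertion).
    """
    years = np.asarray(years)
    mcpr = np.asarray(mcpr, dtype=float)
    wra = np.asarray(wra, dtype=float)
    if mcpr.shape != years.shape or wra.shape != years.shape:
        raise ParameterError("years, mcpr and wra must have equal length")
    if (mcpr < 0).any():
        raise ParameterError("mCPR path must be nonnegative")
    cyp_table = cyp_table or DEFAULT_CYP_TABLE
    from .params import METHOD_MIX_2017

    mix = method_mix or {m: v for m, v in METHOD_MIX_2017.items() if m in MODERN_METHODS}
    mix = {m: v for m, v in mix.items() if m in cyp_table}
    total = sum(mix.values())
    if total <= 0:
        raise ParameterError("method mix has no commodity-backed modern methods")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7919]))

    rows = []
    for y, m_, w_ in zip(years, mcpr, wra):
        users_total = m_ * w_
        visits = users_total * fp_visits_per_user
        for method, share in mix.items():
            users = users_total * share / total
            spec = cyp_table[method]
            if spec["kind"] == "short":
                units = users * spec["units_per_cyp"]
            else:
                units = users / spec["years_per_insertion"]
            fac = units * facility_buffer
            if poisson_noise:
                units = rng.poisson(units)
                fac = rng.poisson(fac)
            rows.append(
                dict(year=int(y), method=method,
                     commodities_to_clients=float(units),
                     commodities_to_facilities=float(fac),
                     fp_visits=float(visits), wra_population=float(w_))
            )
    return pd.DataFrame(rows)


def generate_vitals(
    years,
    pop_start: float = 9_500_000.0,
    growth_rate: float = 0.025,
    gfr: float = 82.7,
    wra_share: float = 0.26,
    poisson_noise: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Vital-registration series with a planted general fertility rate.

    Emits one leading year before ``years[0]`` so the exponential mid-year
    interpolation of :func:`fertdecomp.fertility_rates.vital_rates` can
    recover the planted GFR for every requested year.  ``gfr`` may be a
    scalar or a per-year path (births per 1,000 WRA).
    """
    years = np.asarray(years, dtype=int)
    gfr_path = np.broadcast_to(np.asarray(gfr, dtype=float), years.shape)
    if pop_start <= 0 or wra_share <= 0:
        raise ParameterError("populations must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 15485863]))

    all_years = np.concatenate(([years[0] - 1], years))
    elapsed = all_years - (years[0] - 1)
    pop_end = pop_start * np.exp(growth_rate * elapsed)
    wra_end = pop_end * wra_share
    births = np.zeros_like(pop_end)
    for i, y in enumerate(all_years):
        prev_wra = wra_end[i - 1] if i > 0 else pop_start * wra_share / np.exp(growth_rate)
        mid_wra = prev_wra * np.exp(growth_rate * 0.5)
        g = gfr_path[max(i - 1, 0)]
        births[i] = g * mid_wra / 1000.0
    if poisson_noise:
        births = rng.poisson(births).astype(float)
    return pd.DataFrame(
        {
            "year": all_years,
            "births": births,
            "pop_end_year_total": pop_end,
            "wra_end_year": wra_end,
        }
    )
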