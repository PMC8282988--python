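"""End-to-end orchestration: simulate (or load) -> estimate -> decompose -> report.

``run_analysis`` reproduces the full analysis on one survey round: ASFR
and TFR with the all-women adjustment, wanted TFR, contraceptive
prevalence and method mix, unmet need, infecundity, the Bongaarts
decomposition with the implied abortion rate, calendar reconstructions
and, when registry series are configured, vital rates and EMU.  Reported
rates are rounded to 1 decimal and indices to 3 decimals; internal values
stay unrounded.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .all_women import all_women_tfr, roster_factors
from .calendar_analysis import monthly_cpr, pregnancy_outcomes
from .errors import ParameterError
from .fertility_rates import RatePeriod, compute_asfr, tfr_from_asfr, vital_rates
from .fp_indicators import (
    average_effectiveness,
    cpr,
    infecundity_measures,
    marriage_exposure_tabs,
    method_mix,
    unmet_need_distribution,
    wanted_birth_mask,
)
from .io import read_table, write_table
from .params import PRESETS, SimParams
from .proximate_determinants import (
    DEFAULT_TOTAL_FECUNDITY,
    ProximateIndices,
    implied_tar,
    index_contraception,
    index_marriage,
    index_postpartum,
    mean_insusceptibility,
    mean_use_effectiveness,
)
from .service_statistics import emu as compute_emu
from .synthetic_data import SurveyData, generate_calendars, generate_survey

log = logging.getLogger("fertdecomp")


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict) or not config:
        raise ParameterError("empty config: provide a 'simulate' or 'inputs' section")
    if "simulate" not in config and "inputs" not in config:
        raise ParameterError("config must contain a 'simulate' or 'inputs' section")
    return config


def _get_survey(config: dict, seed: int | None) -> SurveyData:
    if "simulate" in config:
        sim = dict(config["simulate"])
        preset = sim.pop("preset", None)
        if seed is not None:
            sim["seed"] = seed
        params = PRESETS[preset](**sim) if preset else SimParams(**sim)
        survey = generate_survey(params)
        if config.get("calendar", True):
            generate_calendars(survey)
        return survey
    inputs = config["inputs"]
    women = read_table(inputs["women"], "women")
    roster = read_table(inputs["roster"], "roster")
    if "calendar" in inputs:
        cal = read_table(inputs["calendar"], "calendar")
        women = women.merge(cal, on="woman_id", how="left")
    population = read_table(inputs["population"], "women") if "population" in inputs else women
    params = SimParams(seed=seed or 0)
    return SurveyData(population=population, women=women, roster=roster, params=params)


def proximate_from_survey(survey: SurveyData, period: RatePeriod,
                          tf: float = DEFAULT_TOTAL_FECUNDITY,
                          observed_tfr: float | None = None) -> ProximateIndices:
    """Bongaarts indices measured from a survey round.

    m(a) comes from the household roster, g(a) from marital-exposure
    ASFRs, u and the method mix from current-status use, and i from the
    current-status insusceptibility estimator.
    """
    women, roster = survey.women, survey.roster
    tabs = marriage_exposure_tabs(women, roster)
    m_a = tabs["pct_married_by_age"]["pct_ever_married"].to_numpy() / 100.0
    g_a = compute_asfr(women, period, exposure="married").rates
    g_a = np.nan_to_num(g_a)
    cm = index_marriage(m_a, g_a)
    u = cpr(women) / 100.0
    mix_tab = method_mix(women)
    mix = dict(zip(mix_tab["method"], mix_tab["prevalence_pct"] / 100.0))
    e = mean_use_effectiveness(mix)
    cc = index_contraception(u, e)
    i = mean_insusceptibility(women)
    ci = index_postpartum(i)
    idx = ProximateIndices(Cm=cm, Cc=cc, Ci=ci, Tf=tf)
    if observed_tfr is not None and observed_tfr <= idx.predicted_tfr_no_abortion:
        ca, tar = implied_tar(observed_tfr, idx.predicted_tfr_no_abortion, u)
        idx.Ca, idx.implied_tar = ca, tar
    return idx


def run_analysis(config, out_dir=None, seed: int | None = None) -> dict:
    """Run the full pipeline; returns the machine-readable summary.

    With ``out_dir``, also writes the table CSVs, ``summary.json`` and a
    run log.  Deterministic for a fixed config and seed.
    """
    config = _load_config(config)
    survey = _get_survey(config, seed)
    women, roster = survey.women, survey.roster
    interview = int(women["v008"].iloc[0])
    window_years = int(config.get("window_years", 3))
    period = RatePeriod.years_before_interview(interview, window_years)
    tf = float(config.get("tf", DEFAULT_TOTAL_FECUNDITY))
    used_seed = seed if seed is not None else config.get("simulate", {}).get("seed", 0)
    log.info("run_analysis: fertdecomp %s seed=%s window=%dy", __version__, used_seed, window_years)

    asfr_em = compute_asfr(women, period)
    factors = roster_factors(roster, period=period, women=women)
    asfr_all = all_women_tfr(asfr_em, factors)
    tfr = asfr_all.tfr
    wtfr_all = all_women_tfr(
        compute_asfr(women, period, birth_mask=wanted_birth_mask(women)), factors
    )
    wtfr = wtfr_all.tfr

    mix_tab = method_mix(women)
    unmet = unmet_need_distribution(women)
    infec = infecundity_measures(women)
    prox = proximate_from_survey(survey, period, tf=tf, observed_tfr=tfr)
    tabs = marriage_exposure_tabs(women, roster)

    summary = {
        "interview_cmc": interview,
        "seed": used_seed,
        "tfr": round(tfr, 1),
        "wtfr": round(wtfr, 1),
        "cpr": round(cpr(women), 1),
        "mcpr": round(cpr(women, modern_only=True), 1),
        "tcpr": round(cpr(women) - cpr(women, modern_only=True), 1),
        "average_effectiveness_pct": round(100 * average_effectiveness(mix_tab), 1),
        "unmet_need": round(float(unmet["unmet_spacing"] + unmet["unmet_limiting"]), 1),
        "unmet_need_categories": {k: round(float(v), 1) for k, v in unmet.items()},
        "primary_sterility_pct": round(infec["primary_sterility_pct"], 1),
        "secondary_infecund_pct": round(infec["secondary_infecund_pct"], 1),
        "indices": {
            "Cm": round(prox.Cm, 3),
            "Cc": round(prox.Cc, 3),
            "Ci": round(prox.Ci, 3),
            "Tf": prox.Tf,
            "product": round(prox.product, 3),
            "predicted_tfr_no_abortion": round(prox.predicted_tfr_no_abortion, 1),
        },
        "implied_tar": None if prox.implied_tar is None else round(prox.implied_tar, 1),
        "pct_living_with_husband": round(tabs["pct_living_with_husband"], 1),
        "pct_sex_last_4_weeks": round(tabs["pct_sex_last_4_weeks"], 1),
    }

    outputs = {"asfr_all_women": asfr_all.table, "asfr_ever_married": asfr_em.table,
               "all_women_factors": factors, "method_mix": mix_tab,
               "unmet_need": unmet.rename_axis("category").reset_index(),
               "infecundity_by_age": infec["by_age"],
               "time_since_first_marriage": tabs["time_since_first_marriage"]
               .rename_axis("band").reset_index()}

    if "calendar" in women.columns:
        mcpr_series = monthly_cpr(women, modern_only=True)
        outcomes = pregnancy_outcomes(women)
        summary["calendar_month1_mcpr"] = round(float(mcpr_series["prevalence_pct"].iloc[0]), 1)
        summary["pregnancy_outcomes_conditional"] = {
            k: round(float(v), 1) for k, v in outcomes["conditional"].items()
        }
        outputs["monthly_mcpr"] = mcpr_series
        outputs["pregnancy_outcomes"] = outcomes["unconditional"].rename_axis("outcome").reset_index()

    if "vitals" in config:
        from .synthetic_data import generate_vitals

        vit_cfg = dict(config["vitals"])
        vit = generate_vitals(**vit_cfg) if "years" in vit_cfg else read_table(vit_cfg["path"], "vitals")
        vr = vital_rates(vit)
        outputs["vital_rates"] = vr
        summary["latest_cbr"] = round(float(vr["cbr"].iloc[-1]), 1)
        summary["latest_gfr"] = round(float(vr["gfr"].iloc[-1]), 1)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tab in outputs.items():
            write_table(tab.round(6), out / f"{name}.csv", name)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        with open(out / "run.log", "w") as fh:
            fh.write(f"fertdecomp {__version__}\nseed {used_seed}\n"
                     f"window_years {window_years}\ninterview_cmc {interview}\n")
    return summary
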