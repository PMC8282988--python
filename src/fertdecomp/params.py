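"""Simulation parameters and survey-round presets.

``SimParams`` collects the ground-truth quantities the synthetic-data
generator plants: age-specific fertility schedules per nationality,
first-marriage hazards, the contraceptive method mix and its monthly
discontinuation, postpartum insusceptibility, ideal-family-size
distribution, secondary-infecundity prevalence, pregnancy-termination
behaviour, and the survey design (population size, clusters, weights,
calendar length).

Presets encode the 2017-18 and 2012 Jordan survey rounds: schedules and
prevalences are the published round-level values; quantities the surveys
do not publish directly (marriage hazards, discontinuation, preference
splits) are set to demographically plausible values documented in
docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .constants import METHODS, N_AGE_GROUPS, NON_NUMERIC, cmc
from .errors import ParameterError

NATIONALITIES = ("jordanian", "syrian", "other")

# Published 2017-18 national / Jordanian / Syrian ASFR schedules
# (births per 1,000 woman-years, seven 5-year age groups).
ASFR_2017_NATIONAL = (26.9, 109.5, 156.1, 137.1, 87.8, 26.9, 1.6)     # TFR 2.73
ASFR_2017_JORDANIAN = (17.2, 103.9, 153.0, 136.7, 89.7, 24.9, 1.4)    # TFR 2.63
ASFR_2017_SYRIAN = (133.3, 247.5, 216.4, 188.7, 85.3, 53.5, 7.5)      # TFR 4.66

# 2012-like national schedule: the 2012 round published only the TFR (3.5),
# so the 2017 national shape is scaled to that level.
_SCALE_2012 = 3.5 / (5 * sum(ASFR_2017_NATIONAL) / 1000.0)
ASFR_2012_NATIONAL = tuple(round(r * _SCALE_2012, 1) for r in ASFR_2017_NATIONAL)

# Annual first-marriage probabilities by age group (per never-married woman).
MARRIAGE_HAZARD_JORDANIAN = (0.022, 0.070, 0.090, 0.050, 0.020, 0.010, 0.005)
MARRIAGE_HAZARD_SYRIAN = (0.095, 0.120, 0.090, 0.050, 0.020, 0.010, 0.005)

# Method mixes consistent with the published round totals
# (2017: CPR 51.8 = 37.4 modern + 14.4 traditional;
#  2012: CPR 61.2 = 42.3 modern + 18.9 traditional).
METHOD_MIX_2017 = {
    "iud": 0.212, "pill": 0.077, "condom": 0.048, "injectable": 0.008,
    "implant": 0.004, "female_sterilization": 0.015, "lam": 0.010,
    "withdrawal": 0.121, "periodic_abstinence": 0.012, "other_traditional": 0.011,
}
METHOD_MIX_2012 = {
    "iud": 0.210, "pill": 0.089, "condom": 0.075, "injectable": 0.008,
    "implant": 0.003, "female_sterilization": 0.023, "lam": 0.015,
    "withdrawal": 0.136, "periodic_abstinence": 0.034, "other_traditional": 0.019,
}

# Ideal-family-size distribution (mode 4, mean ~3.8, DHS code 96 non-numeric).
IDEAL_DIST_DEFAULT = {
    0: 0.01, 1: 0.02, 2: 0.12, 3: 0.20, 4: 0.40, 5: 0.12,
    6: 0.06, 7: 0.02, 8: 0.01, 9: 0.005, 10: 0.005, NON_NUMERIC: 0.03,
}

# Relative age ramp for secondary-infecundity onset (normalised internally).
INFECUND_AGE_RAMP = (0.0, 0.2, 0.4, 0.8, 1.2, 1.8, 2.4)

# Most-recent-termination type split, conditional on a termination
# (consistent with the 2017 calendar outcome distribution).
TERMINATION_TYPES_DEFAULT = {"miscarriage": 0.78, "abortion": 0.183, "stillbirth": 0.037}


def _per_nationality(value, n_groups=N_AGE_GROUPS):
    """Normalise a schedule argument to a {nationality: ndarray} map."""
    if isinstance(value, Mapping) and not all(k in NATIONALITIES for k in value):
        raise ParameterError(f"unknown nationality keys in {sorted(value)}")
    if isinstance(value, Mapping):
        out = {}
        for nat in NATIONALITIES:
            if nat not in value:
                raise ParameterError(f"schedule missing nationality {nat!r}")
            arr = np.asarray(value[nat], dtype=float)
            out[nat] = arr
        return out
    arr = np.asarray(value, dtype=float)
    return {nat: arr.copy() for nat in NATIONALITIES}


@dataclass
class SimParams:
    """Ground-truth parameters for the synthetic survey generator.

    ``asfr_target`` and ``marriage_hazard`` may be a single 7-vector
    (applied to every nationality) or a map keyed by nationality.
    """

    asfr_target: object = ASFR_2017_NATIONAL
    marriage_hazard: object = dataclasses.field(
        default_factory=lambda: {
            "jordanian": MARRIAGE_HAZARD_JORDANIAN,
            "syrian": MARRIAGE_HAZARD_SYRIAN,
            "other": MARRIAGE_HAZARD_JORDANIAN,
        }
    )
    method_mix: dict = field(default_factory=lambda: dict(METHOD_MIX_2017))
    discontinuation_rate: dict = field(
        default_factory=lambda: {m: spec["discontinuation"] for m, spec in METHODS.items()}
    )
    mean_insusceptibility_months: float = 3.1
    insusceptibility_mode: str = "geometric"      # or "fixed"
    ideal_family_size_dist: dict = field(default_factory=lambda: dict(IDEAL_DIST_DEFAULT))
    infecund_share: float = 0.145                 # classified share among married women
    termination_share: float = 0.108              # terminations / (births + terminations)
    termination_type_dist: dict = field(default_factory=lambda: dict(TERMINATION_TYPES_DEFAULT))
    mistimed_prob: float = 0.08                   # P(mistimed | wanted at conception)
    n_women: int = 5000                           # female population aged 15-49
    n_clusters: int = 150
    nationality_shares: dict = field(
        default_factory=lambda: {"jordanian": 0.869, "syrian": 0.086, "other": 0.045}
    )
    calendar_length_months: int = 72
    interview_cmc: int = cmc(2017, 11)
    weight_noise: float = 0.0                     # gamma CV of cluster-level weights
    living_with_husband_prob: float = 0.955
    sex_last_4_weeks_prob: float = 0.906
    seed: int = 0

    def __post_init__(self):
        self.asfr_target = _per_nationality(self.asfr_target)
        self.marriage_hazard = _per_nationality(self.marriage_hazard)
        self.validate()

    def validate(self) -> None:
        for nat, arr in self.asfr_target.items():
            if arr.shape != (N_AGE_GROUPS,) or (arr < 0).any():
                raise ParameterError(f"asfr_target[{nat}] must be 7 nonnegative rates")
        for nat, arr in self.marriage_hazard.items():
            if arr.shape != (N_AGE_GROUPS,) or (arr < 0).any() or (arr > 1).any():
                raise ParameterError(f"marriage_hazard[{nat}] must be 7 probabilities")
        unknown = set(self.method_mix) - set(METHODS)
        if unknown:
            raise ParameterError(f"unknown methods in mix: {sorted(unknown)}")
        mix = np.array(list(self.method_mix.values()), dtype=float)
        if (mix < 0).any() or mix.sum() > 1 + 1e-9:
            raise ParameterError("method_mix prevalences must be >=0 and sum to <=1")
        for m, d in self.discontinuation_rate.items():
            if m not in METHODS or not (0 <= d <= 1):
                raise ParameterError(f"bad discontinuation rate for {m!r}")
        if self.mean_insusceptibility_months < 0:
            raise ParameterError("mean_insusceptibility_months must be >= 0")
        if self.insusceptibility_mode not in ("geometric", "fixed"):
            raise ParameterError("insusceptibility_mode must be 'geometric' or 'fixed'")
        ideal = np.array(list(self.ideal_family_size_dist.values()), dtype=float)
        if (ideal < 0).any() or abs(ideal.sum() - 1) > 1e-9:
            raise ParameterError("ideal_family_size_dist must be a probability distribution")
        if not (0 <= self.infecund_share < 1):
            raise ParameterError("infecund_share must be in [0, 1)")
        if not (0 <= self.termination_share < 1):
            raise ParameterError("termination_share must be in [0, 1)")
        if self.n_women < 1:
            raise ParameterError("n_women must be positive")
        if self.n_clusters < 2:
            raise ParameterError("n_clusters must be >= 2")
        shares = np.array([self.nationality_shares.get(n, 0.0) for n in NATIONALITIES])
        if (shares < 0).any() or abs(shares.sum() - 1) > 1e-9:
            raise ParameterError("nationality_shares must sum to 1")
        if self.calendar_length_months < 12:
            raise ParameterError("calendar_length_months must be >= 12")
        if self.weight_noise < 0:
            raise ParameterError("weight_noise must be >= 0")

    def replace(self, **kwargs) -> "SimParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)


def jpfhs_2017_like(**overrides) -> SimParams:
    """2017-18 round conditions: published per-nationality ASFR schedules,
    2017 method mix, infecund share 14.5%."""
    base = SimParams(
        asfr_target={
            "jordanian": ASFR_2017_JORDANIAN,
            "syrian": ASFR_2017_SYRIAN,
            "other": ASFR_2017_NATIONAL,
        },
        method_mix=dict(METHOD_MIX_2017),
        infecund_share=0.145,
        interview_cmc=cmc(2017, 11),
    )
    return base.replace(**overrides) if overrides else base


def jpfhs_2012_like(**overrides) -> SimParams:
    """2012 round conditions: TFR 3.5 schedule, 2012 method mix, infecund
    share 8.7%, 2012-era nationality shares."""
    base = SimParams(
        asfr_target=ASFR_2012_NATIONAL,
        method_mix=dict(METHOD_MIX_2012),
        infecund_share=0.087,
        nationality_shares={"jordanian": 0.930, "syrian": 0.029, "other": 0.041},
        interview_cmc=cmc(2012, 6),
    )
    return base.replace(**overrides) if overrides else base


def national_2017_schedule(**overrides) -> SimParams:
    """Single national 2017 ASFR schedule applied to every nationality."""
    base = SimParams(asfr_target=ASFR_2017_NATIONAL)
    return base.replace(**overrides) if overrides else base


PRESETS = {
    "jpfhs_2017": jpfhs_2017_like,
    "jpfhs_2012": jpfhs_2012_like,
    "national_2017": national_2017_schedule,
}
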