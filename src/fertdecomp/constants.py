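"""Shared demographic constants: age groups, century-month-code helpers,
and the contraceptive method registry.

Conventions follow DHS recode practice: CMC = 12*(year-1900) + month with
month in 1..12; reproductive ages are the seven 5-year groups 15-19 .. 45-49;
the contraceptive calendar is oriented with index 1 = interview month and
increasing index = earlier months.
"""

from __future__ import annotations

import numpy as np

AGE_GROUP_LABELS = ("15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49")
N_AGE_GROUPS = 7
AGE_MIN_MONTHS = 15 * 12          # exact age at which reproductive exposure starts
AGE_MAX_MONTHS = 50 * 12          # exclusive upper bound
GROUP_WIDTH_MONTHS = 60

#: code for a non-numeric ideal-family-size response (DHS convention)
NON_NUMERIC = 96

GESTATION_MONTHS = 9              # conception month + 8 pregnant months, birth in month 9
TERMINATION_PREGNANCY_MONTHS = 3  # truncated pregnancies span 3 calendar cells


def cmc(year: int, month: int) -> int:
    """Century month code for a calendar (year, month)."""
    return 12 * (year - 1900) + month


def cmc_to_year(c):
    """Calendar year containing a CMC (vectorised)."""
    return 1900 + (np.asarray(c) - 1) // 12


def age_group_index(age_months):
    """Index 0..6 of the 5-year age group for an exact age in months.

    Ages outside 15-49 map to -1.
    """
    a = np.asarray(age_months)
    idx = (a - AGE_MIN_MONTHS) // GROUP_WIDTH_MONTHS
    return np.where((a >= AGE_MIN_MONTHS) & (a < AGE_MAX_MONTHS), idx, -1)


# ---------------------------------------------------------------------------
# Contraceptive method registry
# ---------------------------------------------------------------------------
# calendar_code: single character used in calendar strings (DHS-like codes).
# modern: modern vs traditional/folk partition.
# discontinuation: default monthly discontinuation probability.
# failure_12m: typical-use 12-month failure probability (drives the
#   use-weighted average effectiveness).
# bongaarts_e: use-effectiveness weight in the Bongaarts index of
#   contraception (sterilization 1.0, IUD 0.95, pill 0.90, others 0.70).

METHODS = {
    "pill":                 dict(calendar_code="1", modern=True,  discontinuation=0.035, failure_12m=0.07,  bongaarts_e=0.90),
    "iud":                  dict(calendar_code="2", modern=True,  discontinuation=0.008, failure_12m=0.014, bongaarts_e=0.95),
    "injectable":           dict(calendar_code="3", modern=True,  discontinuation=0.060, failure_12m=0.040, bongaarts_e=0.70),
    "condom":               dict(calendar_code="5", modern=True,  discontinuation=0.050, failure_12m=0.130, bongaarts_e=0.70),
    "female_sterilization": dict(calendar_code="6", modern=True,  discontinuation=0.000, failure_12m=0.000, bongaarts_e=1.00),
    "implant":              dict(calendar_code="N", modern=True,  discontinuation=0.010, failure_12m=0.001, bongaarts_e=0.95),
    "lam":                  dict(calendar_code="L", modern=True,  discontinuation=0.250, failure_12m=0.110, bongaarts_e=0.70),
    "periodic_abstinence":  dict(calendar_code="8", modern=False, discontinuation=0.050, failure_12m=0.240, bongaarts_e=0.70),
    "withdrawal":           dict(calendar_code="9", modern=False, discontinuation=0.040, failure_12m=0.200, bongaarts_e=0.70),
    "other_traditional":    dict(calendar_code="W", modern=False, discontinuation=0.050, failure_12m=0.200, bongaarts_e=0.70),
}

METHOD_NAMES = tuple(METHODS)
MODERN_METHODS = frozenset(m for m, spec in METHODS.items() if spec["modern"])
TRADITIONAL_METHODS = frozenset(m for m, spec in METHODS.items() if not spec["modern"])
CALENDAR_CODE_TO_METHOD = {spec["calendar_code"]: m for m, spec in METHODS.items()}

#: calendar cells that are not method-use codes
NON_METHOD_CODES = frozenset({"0", "B", "P", "T"})

DEFAULT_FAILURE_RATES = {m: spec["failure_12m"] for m, spec in METHODS.items()}
DEFAULT_DISCONTINUATION = {m: spec["discontinuation"] for m, spec in METHODS.items()}
BONGAARTS_EFFECTIVENESS = {m: spec["bongaarts_e"] for m, spec in METHODS.items()}

# ---------------------------------------------------------------------------
# Couple-years-of-protection conversion factors (USAID standard table).
# Short-term methods: commodity units per CYP.  Long-acting methods:
# protection years per insertion/procedure.
# ---------------------------------------------------------------------------
DEFAULT_CYP_TABLE = {
    "pill":                 dict(kind="short", units_per_cyp=15.0),
    "condom":               dict(kind="short", units_per_cyp=120.0),
    "injectable":           dict(kind="short", units_per_cyp=4.0),
    "iud":                  dict(kind="long", years_per_insertion=4.6),
    "implant":              dict(kind="long", years_per_insertion=2.5),
    "female_sterilization": dict(kind="long", years_per_insertion=10.0),
}
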