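"""Couple-years of protection and estimated modern use (EMU).

Service-statistics series record contraceptive commodities distributed
per year and method.  CYP converts commodity units to protection years
via standard factors (pill 15 cycles/CYP, condom 120 units/CYP,
injectable 4 doses/CYP; long-acting methods are credited with a fixed
number of years per insertion).  EMU turns distribution into a
prevalence-like trend: long-acting insertions are spread over the years
they protect, each year's implied users are summed, optionally inflated
for unobserved private-sector supply, and divided by the women of
reproductive age.  EMU tracks trends in modern use; its level need not
match survey prevalence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import DEFAULT_CYP_TABLE
from .errors import ParameterError


def _units(series: pd.DataFrame, channel: str) -> pd.DataFrame:
    col = f"commodities_to_{channel}"
    if col not in series.columns:
        raise ParameterError(f"series lacks column {col!r}")
    return series.pivot_table(index="year", columns="method", values=col, aggfunc="sum")


def cyp(series: pd.DataFrame, table: dict | None = None,
        channel: str = "clients") -> pd.DataFrame:
    """Couple-years of protection per year and method.

    Short-term methods: units / units-per-CYP.  Long-acting methods:
    insertions x years-per-insertion (credited to the insertion year, the
    reporting convention for CYP).
    """
    table = table or DEFAULT_CYP_TABLE
    units = _units(series, channel)
    unknown = [m for m in units.columns if m not in table]
    if unknown:
        raise ParameterError(f"no CYP factor for methods {unknown}")
    out = pd.DataFrame(index=units.index)
    for m in units.columns:
        spec = table[m]
        if spec["kind"] == "short":
            out[m] = units[m] / spec["units_per_cyp"]
        else:
            out[m] = units[m] * spec["years_per_insertion"]
    out["total"] = out.sum(axis=1)
    return out.reset_index()


def emu(
    series: pd.DataFrame,
    wra: pd.DataFrame,
    table: dict | None = None,
    ltm_discontinuation: float = 0.0,
    private_sector_inflation: float = 1.0,
    channel: str = "clients",
) -> pd.DataFrame:
    """Estimated modern use (% of WRA) from a commodity series.

    Short-term users each year equal that year's CYP.  Each long-acting
    insertion contributes users over a flat profile of
    ``round(years_per_insertion)`` consecutive years starting in the
    insertion year, carrying ``years_per_insertion / len(profile)``
    user-years per year, decayed geometrically by ``ltm_discontinuation``
    per elapsed year.  Years earlier than the series provide no history,
    so early years understate long-acting use (warm-up).

    ``wra`` is a DataFrame with ``year`` and ``wra_population`` (a
    ``wra_end_year`` column is accepted as an alias).
    """
    table = table or DEFAULT_CYP_TABLE
    if not (0 <= ltm_discontinuation < 1):
        raise ParameterError("ltm_discontinuation must be in [0, 1)")
    units = _units(series, channel)
    years = units.index.to_numpy()
    if len(years) > 1 and not (np.diff(years) == 1).all():
        raise ParameterError("service-statistics years must be consecutive")

    wra = wra.rename(columns={"wra_end_year": "wra_population"})
    if "wra_population" not in wra.columns:
        raise ParameterError("WRA table must provide 'wra_population'")
    wra_map = wra.set_index("year")["wra_population"].to_dict()
    missing = [int(y) for y in years if y not in wra_map]
    if missing:
        raise ParameterError(f"missing WRA counts for years {missing}")

    users = pd.Series(0.0, index=units.index)
    for m in units.columns:
        if m not in table:
            raise ParameterError(f"no CYP factor for method {m!r}")
        spec = table[m]
        u = units[m].fillna(0.0).to_numpy(dtype=float)
        if spec["kind"] == "short":
            users += pd.Series(u / spec["units_per_cyp"], index=units.index)
        else:
            span = max(int(round(spec["years_per_insertion"])), 1)
            per_year = spec["years_per_insertion"] / span
            contrib = np.zeros_like(u)
            for lag in range(span):
                decay = (1.0 - ltm_discontinuation) ** lag
                contrib[lag:] += u[: u.size - lag] * per_year * decay
            users += pd.Series(contrib, index=units.index)

    out = pd.DataFrame({"year": units.index.to_numpy(), "users": users.to_numpy()})
    out["wra_population"] = [wra_map[int(y)] for y in out["year"]]
    out["emu_pct"] = 100.0 * out["users"] * private_sector_inflation / out["wra_population"]
    return out
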