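"""Bongaarts proximate determinants of fertility.

The framework decomposes the total fertility rate as

    TFR = Tf * Cm * Cc * Ci * Ca

where Tf is total fecundity (default 15.3 births per woman, Bongaarts's
average), Cm the index of marriage, Cc the index of contraception, Ci the
index of postpartum infecundability and Ca the index of induced abortion:

    Cm = sum(m(a) g(a)) / sum(g(a))      m(a) share married, g(a) marital ASFR
    Cc = 1 - 1.08 u e                    u prevalence, e mean use-effectiveness
    Ci = 20 / (18.5 + i)                 i mean insusceptible months
    Ca = TFR / (TFR + 0.4 (1 + u) TAR)   TAR total abortion rate

When observed fertility falls short of the fertility predicted without
abortion, the implied total abortion rate is the TAR solving the Ca
relation:  TAR = (predicted - observed) / (0.4 (1 + u)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import BONGAARTS_EFFECTIVENESS
from .errors import EstimationError, ParameterError

DEFAULT_TOTAL_FECUNDITY = 15.3


@dataclass
class ProximateIndices:
    Cm: float
    Cc: float
    Ci: float
    Tf: float = DEFAULT_TOTAL_FECUNDITY
    Ca: float | None = None
    implied_tar: float | None = None

    @property
    def product(self) -> float:
        return self.Cm * self.Cc * self.Ci

    @property
    def predicted_tfr_no_abortion(self) -> float:
        return self.Tf * self.product


def index_marriage(m_a, g_a) -> float:
    """Cm = sum(m(a) g(a)) / sum(g(a)).

    ``m_a``: proportion currently married per age group;
    ``g_a``: marital age-specific fertility rates (any common scale).
    """
    m = np.asarray(m_a, dtype=float)
    g = np.asarray(g_a, dtype=float)
    if m.shape != g.shape:
        raise ParameterError("m(a) and g(a) must align")
    if ((m < 0) | (m > 1)).any() or (g < 0).any():
        raise ParameterError("need 0 <= m(a) <= 1 and g(a) >= 0")
    if not (g > 0).any():
        raise EstimationError("Cm undefined: all marital fertility rates are zero")
    return float(np.sum(m * g) / np.sum(g))


def index_contraception(u: float, e: float) -> float:
    """Cc = 1 - 1.08 u e; raises if the product exceeds the valid domain."""
    if not (0 <= u <= 1) or not (0 <= e <= 1):
        raise ParameterError("u and e must lie in [0, 1]")
    cc = 1.0 - 1.08 * u * e
    if cc < 0:
        raise EstimationError(f"Cc = {cc:.4f} < 0: u*e outside the Bongaarts domain")
    return cc


def index_postpartum(i: float) -> float:
    """Ci = 20 / (18.5 + i) for mean insusceptible duration i (months)."""
    if i < 0:
        raise ParameterError("insusceptible duration must be >= 0")
    return 20.0 / (18.5 + i)


def mean_use_effectiveness(method_mix: dict, e_table: dict | None = None) -> float:
    """Use-weighted mean effectiveness e for the Cc index."""
    e_table = e_table or BONGAARTS_EFFECTIVENESS
    total = sum(method_mix.values())
    if total <= 0:
        raise EstimationError("effectiveness undefined for an empty method mix")
    missing = [m for m in method_mix if m not in e_table]
    if missing:
        raise ParameterError(f"no effectiveness entry for {missing}")
    return sum(share * e_table[m] for m, share in method_mix.items()) / total


def mean_insusceptibility(
    women: pd.DataFrame, window_months: int = 36, weights: str | None = "sample_weight"
) -> float:
    """Current-status estimate of mean postpartum insusceptible months.

    Prevalence/incidence estimator: the weighted count of currently
    amenorrheic/insusceptible women divided by the weighted monthly rate
    of births over the last ``window_months``.  Unbiased for the mean
    duration under approximately stationary fertility.
    """
    w = np.ones(len(women)) if weights is None else women[weights].to_numpy(dtype=float)
    v008 = women["v008"].to_numpy(dtype=np.int64)
    from .fertility_rates import parse_birth_history

    births = 0.0
    for wi, bh, v in zip(w, women["bh_cmcs"], v008):
        h = parse_birth_history(bh)
        births += wi * int(((h >= v - window_months) & (h < v)).sum())
    if births <= 0:
        raise EstimationError("no births in the window: insusceptibility undefined")
    prevalence = float(np.dot(w, women["amenorrheic"].to_numpy(dtype=bool)))
    return prevalence / (births / window_months)


def predicted_fertility(tf: float, cm: float, cc: float, ci: float) -> float:
    """Predicted TFR in the absence of abortion: Tf * Cm * Cc * Ci."""
    return tf * cm * cc * ci


def implied_tar(tfr_observed: float, tfr_predicted_no_abortion: float, u: float):
    """Back-calculate (Ca, TAR) reconciling observed with predicted fertility.

    Solves TFR = predicted * Ca with
    Ca = TFR / (TFR + 0.4 (1 + u) TAR), giving
    TAR = (predicted - observed) / (0.4 (1 + u)).
    """
    if tfr_observed <= 0:
        raise ParameterError("observed TFR must be positive")
    if tfr_observed > tfr_predicted_no_abortion:
        raise EstimationError("observed exceeds predicted fertility: no abortion implied")
    ca = tfr_observed / tfr_predicted_no_abortion
    tar = (tfr_predicted_no_abortion - tfr_observed) / (0.4 * (1.0 + u))
    return ca, tar
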