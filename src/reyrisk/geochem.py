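"""REY normalization patterns, Ce/Eu anomalies and resource prospectivity.

Normalizing a REY pattern to a reference composition (upper continental
crust for enrichment plots, the North American Shale Composite for anomaly
work) removes the sawtooth abundance alternation of the lanthanides and
exposes fractionation. The cerium and europium anomalies compare each
element's normalized concentration with the geometric mean of its
neighbours:

    Ce/Ce* = Ce_N / sqrt(La_N · Pr_N)
    Eu/Eu* = Eu_N / sqrt(Sm_N · Gd_N)

A ratio above 1 is a positive anomaly, below 1 negative.

Prospectivity metrics classify an ash as a potential secondary REY source:
the critical percentage (share of the high-demand elements Eu, Tb, Nd, Dy,
Y, Er in total REY) and the outlook coefficient (critical over excessive
sum); %Critical ≥ 30 together with outlook ≥ 0.7 flags a promising source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .io import check_positive
from .reference_data import DEFAULT_ELEMENTS, ElementSet, ReferenceSet

__all__ = ["normalize", "anomalies", "prospectivity", "ProspectivityCriteria"]


def normalize(conc: pd.DataFrame, ref: ReferenceSet,
              which: str = "UCC",
              elements: ElementSet = DEFAULT_ELEMENTS) -> pd.DataFrame:
    """Element-wise sample/reference concentration ratios for the 15 REYs.

    Parameters
    ----------
    conc
        Concentration table (samples × elements, mg/kg).
    ref
        Reference set; ``which`` selects the UCC background or the NASC
        normalization values.

    Returns a samples × REYs DataFrame of dimensionless ratios.
    """
    which = which.upper()
    if which not in ("UCC", "NASC"):
        raise DataError(f"unknown normalization reference {which!r}")
    table = ref.ucc if which == "UCC" else ref.nasc
    reys = list(elements.reys)
    ref.require(reys, table=which.lower())
    check_positive(conc, reys)
    ratios = conc[reys].astype(float) / pd.Series({e: table[e] for e in reys})
    ratios.attrs["reference_name"] = which
    return ratios


def anomalies(pattern: pd.DataFrame) -> pd.DataFrame:
    """Ce and Eu anomalies from a (NASC-)normalized pattern.

    ``pattern`` must contain La, Ce, Pr, Sm, Eu, Gd columns of positive
    normalized values. Returns a DataFrame with ``ce_anomaly`` and
    ``eu_anomaly`` per sample.
    """
    needed = ["La", "Ce", "Pr", "Sm", "Eu", "Gd"]
    check_positive(pattern, needed)
    p = pattern[needed].astype(float)
    ce = p["Ce"] / np.sqrt(p["La"] * p["Pr"])
    eu = p["Eu"] / np.sqrt(p["Sm"] * p["Gd"])
    return pd.DataFrame({"ce_anomaly": ce, "eu_anomaly": eu})


@dataclass(frozen=True)
class ProspectivityCriteria:
    """Thresholds flagging a promising secondary REY source."""

    min_pct_critical: float = 30.0
    min_outlook: float = 0.7


def prospectivity(conc: pd.DataFrame,
                  elements: ElementSet = DEFAULT_ELEMENTS,
                  criteria: ProspectivityCriteria = ProspectivityCriteria(),
                  ) -> pd.DataFrame:
    """Per-sample REY partition sums and resource-prospectivity metrics.

    Returns columns: sum_rey, sum_lrey, sum_hrey, lrey_hrey_ratio,
    sum_critical, sum_excessive, pct_critical, outlook, promising.
    """
    check_positive(conc, elements.reys)
    c = conc[list(elements.reys)].astype(float)
    out = pd.DataFrame(index=conc.index)
    out["sum_rey"] = c.sum(axis=1)
    out["sum_lrey"] = c[list(elements.lreys)].sum(axis=1)
    out["sum_hrey"] = c[list(elements.hreys)].sum(axis=1)
    out["lrey_hrey_ratio"] = out["sum_lrey"] / out["sum_hrey"]
    out["sum_critical"] = c[list(elements.critical)].sum(axis=1)
    out["sum_excessive"] = c[list(elements.excessive)].sum(axis=1)
    out["pct_critical"] = 100.0 * out["sum_critical"] / out["sum_rey"]
    out["outlook"] = out["sum_critical"] / out["sum_excessive"]
    out["promising"] = (out["pct_critical"] >= criteria.min_pct_critical) & (
        out["outlook"] >= criteria.min_outlook
    )
    return out
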