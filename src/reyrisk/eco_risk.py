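"""Ecological contamination and risk indices.

Three complementary indices relate element concentrations in ash to the
upper-continental-crust background:

* Enrichment factor, with Mn as the conservative reference element:
  ``EF = (C_x / C_Mn)_sample / (C_x / C_Mn)_UCC``. Five enrichment classes
  from minimal (EF < 2) to extremely high (EF ≥ 40).
* Geoaccumulation index ``Igeo = log2(C_x / (1.5 · C_N))``, with the usual
  seven classes from unpolluted (Igeo ≤ 0) upward.
* Hakanson potential ecological risk: per-element
  ``E_r = Tr · C_x / C_N`` and their sum RI over an element panel, with the
  four risk classes low (RI < 150), moderate (150–300), high (300–600) and
  very high (RI ≥ 600).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, MissingElementError
from .io import check_positive
from .reference_data import ReferenceSet, ToxicologyTable

__all__ = [
    "enrichment_factor", "geoaccumulation", "ecological_risk",
    "classify_ef", "classify_igeo", "classify_ri",
    "EF_BINS", "IGEO_BINS", "RI_BINS", "EcoRiskResult",
]

# Ordered (upper bound, label) class tables; the last bin is open-ended.
# Overridable by passing custom bins to the classify_* helpers.
EF_BINS: tuple[tuple[float, str], ...] = (
    (2.0, "minimal"),
    (5.0, "moderate"),
    (20.0, "significant"),
    (40.0, "very high"),
    (np.inf, "extremely high"),
)

IGEO_BINS: tuple[tuple[float, str], ...] = (
    (0.0, "unpolluted"),
    (1.0, "unpolluted to moderately polluted"),
    (2.0, "moderately polluted"),
    (3.0, "moderately to heavily polluted"),
    (4.0, "heavily polluted"),
    (5.0, "heavily to extremely polluted"),
    (np.inf, "extremely polluted"),
)

# RI class boundaries: low < 150 ≤ moderate ≤ 300 < high < 600 ≤ very high.
RI_BINS: tuple[tuple[float, str], ...] = (
    (150.0, "low"),
    (300.0, "moderate"),
    (600.0, "high"),
    (np.inf, "very high"),
)


def _classify(values, bins, right_closed_last: bool = False) -> pd.Series | str:
    labels = [lab for _, lab in bins]
    edges = [b for b, _ in bins[:-1]]
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    idx = np.searchsorted(edges, arr, side="right")
    out = np.array(labels, dtype=object)[idx]
    if np.isscalar(values) or np.ndim(values) == 0:
        return out[0]
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index)
    return out


def classify_ef(ef, bins=EF_BINS):
    """Map EF values to the five enrichment class labels."""
    return _classify(ef, bins)


def classify_igeo(igeo, bins=IGEO_BINS):
    """Map Igeo values to the seven geoaccumulation class labels."""
    return _classify(igeo, bins)


def classify_ri(ri, bins=RI_BINS):
    """Map RI values to the four ecological risk class labels.

    Boundary convention: RI < 150 low; 150 ≤ RI ≤ 300 moderate;
    300 < RI < 600 high; RI ≥ 600 very high. searchsorted with
    right-open bins places exactly 150 in moderate and exactly 600 in
    very high; 300 belongs to moderate per the closed upper bound, so it
    is adjusted explicitly.
    """
    res = _classify(ri, bins)
    # 300 is inside the moderate class (closed upper bound)
    arr = np.atleast_1d(np.asarray(ri, dtype=float))
    if np.isscalar(ri) or np.ndim(ri) == 0:
        return "moderate" if arr[0] == 300.0 else res
    mask = arr == 300.0
    if isinstance(res, pd.Series):
        res[mask] = "moderate"
    else:
        res[mask] = "moderate"
    return res


def enrichment_factor(conc: pd.DataFrame, ref: ReferenceSet,
                      elements: list[str] | None = None) -> pd.DataFrame:
    """Per-sample, per-element enrichment factor against the UCC background.

    The reference element (Mn by default) must be present and positive in
    every sample and in the UCC table.
    """
    ref_el = ref.ef_reference_element
    if ref_el not in conc.columns:
        raise MissingElementError(ref_el, "the concentration table")
    if elements is None:
        elements = [c for c in conc.columns if c in ref.ucc and c != ref_el]
    ref.require(list(elements) + [ref_el], table="ucc")
    check_positive(conc, list(elements) + [ref_el])
    c = conc[list(elements)].astype(float)
    c_ref = conc[ref_el].astype(float)
    ucc = pd.Series({e: ref.ucc[e] for e in elements})
    ef = c.div(c_ref, axis=0) / (ucc / ref.ucc[ref_el])
    return ef


def geoaccumulation(conc: pd.DataFrame, ref: ReferenceSet,
                    elements: list[str] | None = None) -> pd.DataFrame:
    """Per-sample, per-element geoaccumulation index (log2 scale)."""
    if elements is None:
        elements = [c for c in conc.columns if c in ref.ucc]
    ref.require(elements, table="ucc")
    check_positive(conc, elements)
    c = conc[list(elements)].astype(float)
    background = pd.Series({e: ref.ucc[e] for e in elements})
    return np.log2(c / (1.5 * background))


@dataclass(frozen=True)
class EcoRiskResult:
    """Per-element ecological risk coefficients and the summed index.

    ``er``: samples × elements E_r values; ``ri``: per-sample sum;
    ``risk_class``: per-sample label; ``shares``: per-element fraction of RI.
    """

    er: pd.DataFrame
    ri: pd.Series
    risk_class: pd.Series
    shares: pd.DataFrame


def ecological_risk(conc: pd.DataFrame, ref: ReferenceSet,
                    tox: ToxicologyTable,
                    elements: list[str]) -> EcoRiskResult:
    """Hakanson potential ecological risk over the requested element panel.

    E_r_i = Tr_i · C_i / C_N_i (C_N the UCC background); RI = Σ E_r_i.
    Every requested element must have a Tr coefficient and a background
    value; an element lacking either raises an error naming it.
    """
    if not elements:
        raise DataError("empty element list for ecological risk")
    tox.require_tr(elements)
    ref.require(elements, table="ucc")
    check_positive(conc, elements)
    c = conc[list(elements)].astype(float)
    background = pd.Series({e: ref.ucc[e] for e in elements})
    tr = pd.Series({e: tox.tr[e] for e in elements})
    er = c / background * tr
    ri = er.sum(axis=1)
    shares = er.div(ri, axis=0)
    return EcoRiskResult(er=er, ri=ri, risk_class=classify_ri(ri), shares=shares)
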