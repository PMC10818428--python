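"""Deterministic USEPA residential soil exposure model.

Average daily doses (mg per kg body weight per day) are computed for three
pathways from an ash concentration C (mg/kg):

    ingestion:  C · IR · EF · ED / (BW · AT · 10⁶)
    dermal:     C · SA · AF · ABS · EF · ED / (BW · AT · 10⁶)
    inhalation: C · InhR · EF · ED / (PEF · BW · AT)

where the 10⁻⁶ factor converts mg of ash to kg and the particulate emission
factor (PEF, m³/kg) converts the ash concentration to an airborne one. The
averaging time AT is ED·365 days for the chronic (non-carcinogenic) dose
and 70·365 days for the lifetime (carcinogenic) dose.

Non-carcinogenic risk: hazard quotient HQ = ADD/RfD per element, summed
over the three pathways with a single oral RfD; the hazard index HI sums HQ
over elements, with HI > 1 flagging concern. Carcinogenic risk:
CR = LADD_ingestion · CSF per element; the target cancer risk TCR sums CR,
against the conventional 10⁻⁶–10⁻⁴ acceptability band. Cancer risk is
computed from the ingestion dose only — the slope factors shipped here are
oral — while hooks allow pathway-specific extensions.

All dose functions broadcast over numpy arrays, so an
:class:`~reyrisk.reference_data.ExposureProfile` whose fields are arrays of
Monte Carlo draws propagates vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError
from .io import check_positive
from .reference_data import (
    DEFAULT_ELEMENTS,
    ElementSet,
    ExposureProfile,
    ToxicologyTable,
)

__all__ = [
    "PATHWAYS", "daily_dose", "hazard", "cancer_risk", "assess",
    "group_share", "HealthRiskResult", "HI_SAFE_LIMIT", "TCR_LIMITS",
]

PATHWAYS = ("ingestion", "dermal", "inhalation")

HI_SAFE_LIMIT = 1.0
TCR_LIMITS = (1e-6, 1e-4)


def daily_dose(conc, profile: ExposureProfile, pathway: str,
               horizon: str = "chronic"):
    """Average daily dose for one pathway.

    Parameters
    ----------
    conc
        Concentration in mg/kg; scalar, array or DataFrame (broadcasts).
    pathway
        One of ``ingestion``, ``dermal``, ``inhalation``.
    horizon
        ``chronic`` uses the non-carcinogenic averaging time (ED·365 d);
        ``lifetime`` the 70-year carcinogenic one.
    """
    if pathway not in PATHWAYS:
        raise DataError(f"unknown pathway {pathway!r}")
    at = (profile.averaging_time_nc if horizon == "chronic"
          else profile.averaging_time_ca)
    if np.any(np.asarray(profile.body_weight) <= 0) or np.any(np.asarray(at) <= 0):
        raise DataError("body weight and averaging time must be positive")
    time_term = (profile.exposure_frequency * profile.exposure_duration
                 / (profile.body_weight * at))
    if pathway == "ingestion":
        intake = profile.ingestion_rate * profile.unit_conversion
    elif pathway == "dermal":
        intake = (profile.skin_area * profile.adherence_factor
                  * profile.dermal_absorption * profile.unit_conversion)
    else:  # inhalation
        intake = profile.inhalation_rate / profile.pef
    return conc * intake * time_term


@dataclass
class HealthRiskResult:
    """Per-sample risk endpoints for one receptor.

    ``hq``/``cr`` are samples × elements DataFrames; ``hi``/``tcr`` the
    element sums per sample. ``hi_by_group``/``tcr_by_group`` hold partial
    sums over the REY and HM families (keys ``rey`` and ``hm``) when the
    scored elements intersect them.
    """

    receptor: str
    hq: pd.DataFrame | None = None
    hi: pd.Series | None = None
    cr: pd.DataFrame | None = None
    tcr: pd.Series | None = None
    hi_by_group: dict[str, pd.Series] = field(default_factory=dict)
    tcr_by_group: dict[str, pd.Series] = field(default_factory=dict)


def _group_sums(per_element: pd.DataFrame,
                element_set: ElementSet) -> dict[str, pd.Series]:
    out: dict[str, pd.Series] = {}
    for name, members in (("rey", element_set.reys), ("hm", element_set.hms)):
        cols = [c for c in per_element.columns if c in members]
        if cols:
            out[name] = per_element[cols].sum(axis=1)
    return out


def hazard(conc: pd.DataFrame, profile: ExposureProfile,
           tox: ToxicologyTable, elements: Iterable[str] | None = None,
           element_set: ElementSet = DEFAULT_ELEMENTS) -> HealthRiskResult:
    """Non-carcinogenic hazard quotients and hazard index.

    HQ_element = Σ_pathway ADD_nc,pathway / RfD_element; HI = Σ HQ.
    Every scored element needs an RfD; a missing one raises an error
    naming the element.
    """
    if elements is None:
        elements = [c for c in conc.columns if c in tox.rfd]
    elements = list(elements)
    if not elements:
        raise DataError("no elements to score for hazard")
    tox.require_rfd(elements)
    check_positive(conc, elements)
    c = conc[elements].astype(float)
    add = sum(daily_dose(c, profile, p, horizon="chronic") for p in PATHWAYS)
    rfd = pd.Series({e: tox.rfd[e] for e in elements})
    hq = add / rfd
    res = HealthRiskResult(receptor=profile.receptor, hq=hq, hi=hq.sum(axis=1))
    res.hi_by_group = _group_sums(hq, element_set)
    return res


def cancer_risk(conc: pd.DataFrame, profile: ExposureProfile,
                tox: ToxicologyTable, elements: Iterable[str] | None = None,
                element_set: ElementSet = DEFAULT_ELEMENTS) -> HealthRiskResult:
    """Carcinogenic risk: CR = ingestion LADD × CSF; TCR = Σ CR.

    Elements without a cancer slope factor contribute zero rather than
    erroring, so mixed panels can be scored in one call.
    """
    if elements is None:
        elements = [c for c in conc.columns if c in tox.rfd or c in tox.csf]
    elements = list(elements)
    if not elements:
        raise DataError("no elements to score for cancer risk")
    check_positive(conc, elements)
    c = conc[elements].astype(float)
    ladd = daily_dose(c, profile, "ingestion", horizon="lifetime")
    csf = pd.Series({e: tox.csf.get(e, 0.0) for e in elements})
    cr = ladd * csf
    res = HealthRiskResult(receptor=profile.receptor, cr=cr, tcr=cr.sum(axis=1))
    res.tcr_by_group = _group_sums(cr, element_set)
    return res


def assess(conc: pd.DataFrame, profiles: Iterable[ExposureProfile],
           tox: ToxicologyTable,
           element_set: ElementSet = DEFAULT_ELEMENTS,
           elements: Iterable[str] | None = None) -> pd.DataFrame:
    """Combined HI/TCR table across receptors, one row per sample.

    Columns follow the ``HI_<receptor>``, ``HI_<receptor>_rey`` … pattern,
    mirroring the usual published layout (total plus REY and HM partial
    sums for each receptor and endpoint).
    """
    out = pd.DataFrame(index=conc.index)
    for profile in profiles:
        r = profile.receptor
        h = hazard(conc, profile, tox, elements, element_set)
        cncr = cancer_risk(conc, profile, tox, elements, element_set)
        out[f"HI_{r}"] = h.hi
        for g, s in h.hi_by_group.items():
            out[f"HI_{r}_{g}"] = s
        out[f"TCR_{r}"] = cncr.tcr
        for g, s in cncr.tcr_by_group.items():
            out[f"TCR_{r}_{g}"] = s
    return out


def group_share(risk_table: pd.DataFrame, endpoint: str = "HI",
                receptor: str = "child", group: str = "rey") -> float:
    """Fraction of the mean total endpoint attributable to one element group.

    Works on any table in the :func:`assess` column layout (including an
    externally supplied one): returns
    mean(``<endpoint>_<receptor>_<group>``) / mean(``<endpoint>_<receptor>``).
    """
    total_col = f"{endpoint}_{receptor}"
    part_col = f"{endpoint}_{receptor}_{group}"
    for col in (total_col, part_col):
        if col not in risk_table.columns:
            raise DataError(f"risk table lacks column {col!r}")
    return float(risk_table[part_col].mean() / risk_table[total_col].mean())
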