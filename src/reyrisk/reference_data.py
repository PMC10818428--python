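"""Reference constants consumed by the geochemical and risk equations.

Everything the index equations need that is not sample data lives here:
element group membership (the 15-member REY family and its light/heavy and
critical/excessive partitions, plus the heavy metal(loid) panel), crustal
background and shale normalization values, Hakanson toxicity-response
coefficients, oral reference doses and cancer slope factors, and the
receptor exposure profiles for the residential soil-exposure model.

Constants ship as CSV files under ``reyrisk/data`` (columns
``element,value,unit,source``) and can be overridden by user-supplied files
of the same layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigError, DataError, MissingElementError

__all__ = [
    "ElementSet",
    "ReferenceSet",
    "ToxicologyTable",
    "ExposureProfile",
    "DEFAULT_ELEMENTS",
    "BUILTIN_REFERENCE_TABLES",
    "load_reference_table",
    "load_reference_set",
    "load_toxicology",
    "default_exposure_profiles",
    "write_reference_table",
]

#: Element symbols recognised anywhere in the package.
KNOWN_ELEMENTS = frozenset(
    "La Ce Pr Nd Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Y "
    "As Cr V Pb Ni Mn Ba Cd Cu Mo Co Hg Zn".split()
)


@dataclass(frozen=True)
class ElementSet:
    """Fixed element groupings used throughout the analysis.

    The REY family is the 14 stable lanthanides plus yttrium (promethium is
    radioactive and excluded; scandium is not part of the family used here).
    Light/heavy and critical/excessive partitions follow the conventions of
    REY resource evaluation: the "critical" subgroup is the
    high-demand/low-supply elements, the "excessive" subgroup the oversupplied
    ones, and their balance drives the outlook coefficient.
    """

    reys: tuple[str, ...] = (
        "La", "Ce", "Pr", "Nd", "Sm", "Eu", "Gd",
        "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu", "Y",
    )
    lreys: tuple[str, ...] = ("La", "Ce", "Pr", "Nd", "Sm", "Eu", "Gd")
    hreys: tuple[str, ...] = ("Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu", "Y")
    critical: tuple[str, ...] = ("Eu", "Tb", "Nd", "Dy", "Y", "Er")
    excessive: tuple[str, ...] = ("Ce", "Yb", "Ho", "Tm", "Lu")
    hms: tuple[str, ...] = (
        "As", "Cr", "V", "Pb", "Ni", "Mn", "Ba",
        "Cd", "Cu", "Mo", "Co", "Hg", "Zn",
    )

    def __post_init__(self):
        if set(self.lreys) | set(self.hreys) != set(self.reys):
            raise ConfigError("lreys and hreys must partition reys")
        if set(self.lreys) & set(self.hreys):
            raise ConfigError("lreys and hreys overlap")
        if not set(self.critical) <= set(self.reys):
            raise ConfigError("critical group must be a subset of reys")
        if not set(self.excessive) <= set(self.reys):
            raise ConfigError("excessive group must be a subset of reys")
        if set(self.critical) & set(self.excessive):
            raise ConfigError("critical and excessive groups overlap")
        if "Pm" in self.reys or "Sc" in self.reys:
            raise ConfigError("Pm and Sc are not part of the REY set")

    def group(self, name: str) -> tuple[str, ...]:
        """Return a group by name: 'rey', 'hm', 'lrey', 'hrey', 'critical',
        'excessive', or 'all' (reys followed by hms)."""
        table = {
            "rey": self.reys, "reys": self.reys,
            "hm": self.hms, "hms": self.hms,
            "lrey": self.lreys, "hrey": self.hreys,
            "critical": self.critical, "excessive": self.excessive,
            "all": self.reys + self.hms,
        }
        try:
            return table[name.lower()]
        except KeyError:
            raise ConfigError(f"unknown element group {name!r}") from None


DEFAULT_ELEMENTS = ElementSet()

#: Builtin reference tables shipped with the package.
BUILTIN_REFERENCE_TABLES = {
    "ucc_rudnick_gao_2003": "ucc_rudnick_gao_2003.csv",
    "nasc_gromet_1984": "nasc_gromet_1984.csv",
}


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("reyrisk").joinpath("data", filename)))


def _read_element_value_csv(source: str | Path) -> tuple[dict[str, float], str]:
    """Read an ``element,value[,unit,source]`` CSV; returns (values, provenance)."""
    name = str(source)
    if name in BUILTIN_REFERENCE_TABLES:
        path = _data_path(BUILTIN_REFERENCE_TABLES[name])
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError(
                f"{source!r} is neither a file nor a builtin reference table "
                f"(builtins: {sorted(BUILTIN_REFERENCE_TABLES)})"
            )
    df = pd.read_csv(path)
    if "element" not in df.columns or "value" not in df.columns:
        raise DataError(f"{path}: expected columns 'element' and 'value'")
    unknown = set(df["element"]) - KNOWN_ELEMENTS
    if unknown:
        raise DataError(f"{path}: unknown element symbols {sorted(unknown)}")
    values = dict(zip(df["element"], df["value"].astype(float)))
    for el, v in values.items():
        if not (v > 0) or not math.isfinite(v):
            raise DataError(f"{path}: nonpositive value {v} for element {el}")
    provenance = ""
    if "source" in df.columns and len(df):
        provenance = str(df["source"].iloc[0])
    return values, provenance


def load_reference_table(source: str | Path) -> dict[str, float]:
    """Load one element → value (mg/kg) table from a builtin name or CSV path."""
    values, _ = _read_element_value_csv(source)
    return values


@dataclass(frozen=True)
class ReferenceSet:
    """Background (UCC) and normalization (NASC) concentrations.

    ``ucc`` is the crustal background used by the enrichment factor,
    geoaccumulation index and ecological risk; ``nasc`` is the shale
    composite used to normalize REY patterns for anomaly calculation.
    Indexing the set (``ref["Lu"]``) reads the UCC background.
    """

    ucc: Mapping[str, float]
    nasc: Mapping[str, float]
    ef_reference_element: str = "Mn"
    provenance: str = ""

    def __post_init__(self):
        for table_name, table in (("ucc", self.ucc), ("nasc", self.nasc)):
            for el, v in table.items():
                if el not in KNOWN_ELEMENTS:
                    raise DataError(f"{table_name}: unknown element {el!r}")
                if not v > 0:
                    raise DataError(f"{table_name}: nonpositive value for {el}")
        missing = set(DEFAULT_ELEMENTS.reys) - set(self.nasc)
        if missing:
            raise MissingElementError(sorted(missing)[0], "the NASC table")

    def __getitem__(self, element: str) -> float:
        return self.ucc[element]

    def require(self, elements: Iterable[str], table: str = "ucc") -> None:
        """Raise :class:`MissingElementError` naming the first absent element."""
        values = self.ucc if table == "ucc" else self.nasc
        for el in elements:
            if el not in values:
                raise MissingElementError(el, f"the {table.upper()} table")


def load_reference_set(
    ucc: str | Path = "ucc_rudnick_gao_2003",
    nasc: str | Path = "nasc_gromet_1984",
    ef_reference_element: str = "Mn",
) -> ReferenceSet:
    """Assemble a validated :class:`ReferenceSet` from builtin names or CSV paths."""
    ucc_values, ucc_src = _read_element_value_csv(ucc)
    nasc_values, nasc_src = _read_element_value_csv(nasc)
    ref = ReferenceSet(
        ucc=ucc_values,
        nasc=nasc_values,
        ef_reference_element=ef_reference_element,
        provenance=f"UCC: {ucc_src}; NASC: {nasc_src}",
    )
    if ef_reference_element not in ref.ucc:
        raise MissingElementError(ef_reference_element, "the UCC table")
    return ref


@dataclass(frozen=True)
class ToxicologyTable:
    """Per-element toxicity-response coefficients and dose–response parameters.

    ``tr`` is the Hakanson toxicity-response coefficient (dimensionless),
    ``rfd`` the oral reference dose (mg kg⁻¹ day⁻¹) and ``csf`` the oral
    cancer slope factor ((mg kg⁻¹ day⁻¹)⁻¹). Elements without a published
    CSF simply do not appear in ``csf`` and contribute zero cancer risk.
    """

    tr: Mapping[str, float]
    rfd: Mapping[str, float]
    csf: Mapping[str, float]

    def __post_init__(self):
        for el, v in self.rfd.items():
            if not v > 0:
                raise DataError(f"rfd: nonpositive value for {el}")

    def require_tr(self, elements: Iterable[str]) -> None:
        for el in elements:
            if el not in self.tr:
                raise MissingElementError(el, "the Tr coefficient table")

    def require_rfd(self, elements: Iterable[str]) -> None:
        for el in elements:
            if el not in self.rfd:
                raise MissingElementError(el, "the RfD table")


def load_toxicology(source: str | Path | None = None) -> ToxicologyTable:
    """Load the toxicology table (builtin by default, or a user CSV).

    The CSV has columns ``element,tr,rfd,csf``; empty cells mean
    "not defined for this element".
    """
    path = _data_path("toxicology.csv") if source is None else Path(source)
    df = pd.read_csv(path)
    for col in ("element", "tr", "rfd", "csf"):
        if col not in df.columns:
            raise DataError(f"{path}: expected column {col!r}")
    unknown = set(df["element"]) - KNOWN_ELEMENTS
    if unknown:
        raise DataError(f"{path}: unknown element symbols {sorted(unknown)}")

    def col_map(col: str) -> dict[str, float]:
        sub = df[["element", col]].dropna()
        return dict(zip(sub["element"], sub[col].astype(float)))

    return ToxicologyTable(tr=col_map("tr"), rfd=col_map("rfd"), csf=col_map("csf"))


@dataclass(frozen=True)
class ExposureProfile:
    """Receptor-specific exposure factors for the residential soil model.

    Units: ingestion_rate mg/day; exposure_frequency days/year;
    exposure_duration years; body_weight kg; averaging times days;
    skin_area cm²; adherence_factor mg/cm²; dermal_absorption fraction;
    inhalation_rate m³/day; pef (particulate emission factor) m³/kg;
    unit_conversion kg/mg.

    Fields may hold numpy arrays (one entry per Monte Carlo draw); the dose
    equations broadcast.
    """

    receptor: str
    ingestion_rate: float
    exposure_frequency: float
    exposure_duration: float
    body_weight: float
    skin_area: float
    adherence_factor: float
    dermal_absorption: float
    inhalation_rate: float
    pef: float = 1.36e9
    averaging_time_nc: float | None = None
    averaging_time_ca: float = 70 * 365.0
    unit_conversion: float = 1e-6

    def __post_init__(self):
        if self.averaging_time_nc is None:
            object.__setattr__(
                self, "averaging_time_nc", self.exposure_duration * 365.0
            )

    def replace(self, **changes) -> "ExposureProfile":
        """Copy with fields changed; averaging_time_nc tracks exposure_duration
        unless set explicitly."""
        if "exposure_duration" in changes and "averaging_time_nc" not in changes:
            changes["averaging_time_nc"] = changes["exposure_duration"] * 365.0
        return replace(self, **changes)

    @property
    def field_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in fields(self))


def default_exposure_profiles() -> tuple[ExposureProfile, ExposureProfile]:
    """Default (child, adult) residential exposure profiles.

    Values are the standard USEPA residential soil defaults: ingestion
    200/100 mg/day, exposure frequency 350 days/year, duration 6/24 years,
    body weight 15/70 kg, skin area 2373/6032 cm², adherence 0.2/0.07
    mg/cm², dermal absorption 0.001, inhalation 7.6/20 m³/day, particulate
    emission factor 1.36 × 10⁹ m³/kg, carcinogenic averaging time 70 years.
    """
    child = ExposureProfile(
        receptor="child",
        ingestion_rate=200.0,
        exposure_frequency=350.0,
        exposure_duration=6.0,
        body_weight=15.0,
        skin_area=2373.0,
        adherence_factor=0.2,
        dermal_absorption=0.001,
        inhalation_rate=7.6,
    )
    adult = ExposureProfile(
        receptor="adult",
        ingestion_rate=100.0,
        exposure_frequency=350.0,
        exposure_duration=24.0,
        body_weight=70.0,
        skin_area=6032.0,
        adherence_factor=0.07,
        dermal_absorption=0.001,
        inhalation_rate=20.0,
    )
    return child, adult


def write_reference_table(values: Mapping[str, float], path: str | Path,
                          unit: str = "mg/kg", source: str = "") -> None:
    """Write an element → value mapping in the shipped CSV layout."""
    df = pd.DataFrame(
        {"element": list(values), "value": [values[e] for e in values]}
    )
    df["unit"] = unit
    df["source"] = source
    df.to_csv(path, index=False)
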