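"""End-to-end orchestration: load → stats → geochem → eco → health → MCS.

A run is a pure function of its configuration (plus seed): every stage
writes a CSV into the output directory and the headline aggregates land in
``summary.json``. Stages are individually re-runnable through the library
functions; the pipeline only sequences them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import eco_risk, geochem, health_risk, monte_carlo, stats, synthetic
from .errors import ConfigError, DataError, ReyRiskError
from .io import element_columns, read_concentrations, write_concentrations
from .reference_data import (
    DEFAULT_ELEMENTS,
    default_exposure_profiles,
    load_reference_set,
    load_toxicology,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Exactly one of ``input`` (a concentration CSV) or ``synthetic`` (a
    generator parameter mapping) must be given; a seed is mandatory
    whenever synthesis or MCS is enabled.
    """

    output_dir: str | Path
    input: str | Path | None = None
    synthetic: dict[str, Any] | None = None
    references: dict[str, str] = field(default_factory=dict)
    toxicology: str | Path | None = None
    receptors: tuple[str, ...] = ("child", "adult")
    groups: tuple[str, ...] = ("rey", "hm")
    mcs: dict[str, Any] | None = None
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.input is None) == (self.synthetic is None):
            raise ConfigError("exactly one of 'input' or 'synthetic' required")
        if self.input is not None and not Path(self.input).exists():
            raise ConfigError(f"input file {self.input} does not exist")
        if self.toxicology is not None and not Path(self.toxicology).exists():
            raise ConfigError(f"toxicology file {self.toxicology} does not exist")
        if not self.groups:
            raise ConfigError("empty element group list")
        for g in self.groups:
            DEFAULT_ELEMENTS.group(g)  # raises ConfigError when unknown
        bad = set(self.receptors) - {"child", "adult"}
        if bad:
            raise ConfigError(f"unknown receptors {sorted(bad)}")
        needs_seed = self.synthetic is not None or (
            self.mcs is not None and self.mcs.get("enabled", True))
        if needs_seed and self.seed is None:
            raise ConfigError("seed required when synthesis or MCS is enabled")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        for tup in ("receptors", "groups"):
            if tup in raw and raw[tup] is not None:
                raw[tup] = tuple(raw[tup])
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ReyRiskError as exc:
                raise type(exc)(f"stage {name!r}: {exc}") from exc
        return wrapper
    return deco


def _write_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and return the summary dictionary.

    Writes per-stage CSVs (concentrations when synthesised, descriptives,
    correlations, normalized patterns, anomalies, prospectivity, eco
    indices, RI, health-risk table, MCS summary) plus ``summary.json``
    into ``config.output_dir``. Idempotent for a fixed config and seed.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ref = load_reference_set(**config.references)
    tox = load_toxicology(config.toxicology)
    es = DEFAULT_ELEMENTS

    # -- load or synthesise ------------------------------------------------
    if config.synthetic is not None:
        gen_cfg = synthetic.GeneratorConfig(
            seed=config.seed, **config.synthetic)
        conc = _stage("synthesise")(synthetic.generate)(gen_cfg)
        write_concentrations(conc, out_dir / "concentrations.csv")
    else:
        conc = _stage("load")(read_concentrations)(config.input)
    present = element_columns(conc)
    reys_present = [e for e in es.reys if e in present]

    summary: dict[str, Any] = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "n_samples": int(len(conc)),
        "elements": present,
        "seed": config.seed,
    }

    # -- descriptive statistics -------------------------------------------
    desc = _stage("stats")(stats.describe)(conc, present)
    desc.to_csv(out_dir / "descriptives.csv", index_label="element")
    if len(conc) >= 3:
        corr = _stage("stats")(stats.pearson_matrix)(
            conc, reys_present or present)
        corr.r.to_csv(out_dir / "correlations.csv", index_label="element")

    # -- geochemistry ------------------------------------------------------
    if set(es.reys) <= set(present):
        ucc_pattern = _stage("geochem")(geochem.normalize)(conc, ref, "UCC")
        ucc_pattern.to_csv(out_dir / "pattern_ucc.csv", index_label="sample_id")
        nasc_pattern = _stage("geochem")(geochem.normalize)(conc, ref, "NASC")
        anom = _stage("geochem")(geochem.anomalies)(nasc_pattern)
        anom.to_csv(out_dir / "anomalies.csv", index_label="sample_id")
        prosp = _stage("geochem")(geochem.prospectivity)(conc, es)
        prosp.to_csv(out_dir / "prospectivity.csv", index_label="sample_id")
        summary["mean_ce_anomaly"] = float(anom["ce_anomaly"].mean())
        summary["mean_eu_anomaly"] = float(anom["eu_anomaly"].mean())
        summary["mean_sum_rey"] = float(prosp["sum_rey"].mean())
        summary["all_samples_promising"] = bool(prosp["promising"].all())

    # -- ecological indices ------------------------------------------------
    eco_elements = [e for e in present if e in ref.ucc
                    and e != ref.ef_reference_element]
    if eco_elements and ref.ef_reference_element in present:
        ef = _stage("eco")(eco_risk.enrichment_factor)(conc, ref, eco_elements)
        igeo = _stage("eco")(eco_risk.geoaccumulation)(conc, ref, eco_elements)
        eco_table = pd.concat(
            {"EF": ef, "Igeo": igeo}, axis=1).swaplevel(axis=1).sort_index(axis=1)
        eco_table.to_csv(out_dir / "eco_indices.csv", index_label="sample_id")

    risk_elements = [e for g in config.groups for e in es.group(g)
                     if e in present and e in tox.tr]
    if risk_elements:
        eco = _stage("eco")(eco_risk.ecological_risk)(
            conc, ref, tox, risk_elements)
        ri_table = pd.DataFrame({"RI": eco.ri, "risk_class": eco.risk_class})
        rey_cols = [e for e in risk_elements if e in es.reys]
        if rey_cols:
            ri_table["RI_rey"] = eco.er[rey_cols].sum(axis=1)
        hm_cols = [e for e in risk_elements if e in es.hms]
        if hm_cols:
            ri_table["RI_hm"] = eco.er[hm_cols].sum(axis=1)
        ri_table.to_csv(out_dir / "ri.csv", index_label="sample_id")
        summary["mean_ri"] = float(eco.ri.mean())
        if rey_cols and hm_cols:
            summary["rey_share_of_ri"] = float(
                ri_table["RI_rey"].mean() / ri_table["RI"].mean())

    # -- health risk -------------------------------------------------------
    child, adult = default_exposure_profiles()
    profiles = [p for p in (child, adult) if p.receptor in config.receptors]
    hra_elements = [e for g in config.groups for e in es.group(g)
                    if e in present and e in tox.rfd]
    if hra_elements and profiles:
        risk = _stage("health")(health_risk.assess)(
            conc, profiles, tox, es, hra_elements)
        risk.to_csv(out_dir / "health_risk.csv", index_label="sample_id")
        for p in profiles:
            r = p.receptor
            summary[f"mean_hi_{r}"] = float(risk[f"HI_{r}"].mean())
            summary[f"mean_tcr_{r}"] = float(risk[f"TCR_{r}"].mean())
            summary[f"hi_{r}_exceeds_limit"] = bool(
                risk[f"HI_{r}"].mean() > health_risk.HI_SAFE_LIMIT)
            if f"HI_{r}_rey" in risk.columns:
                summary[f"rey_share_of_hi_{r}"] = health_risk.group_share(
                    risk, "HI", r, "rey")

        # -- Monte Carlo ---------------------------------------------------
        if config.mcs is not None and config.mcs.get("enabled", True):
            n = int(config.mcs.get("n", 10_000))
            endpoints = config.mcs.get("endpoints", ["HI", "TCR"])
            rows = []
            for p in profiles:
                conc_dists = monte_carlo.concentration_distributions(
                    conc, hra_elements)
                exp_dists = monte_carlo.default_exposure_distributions(p)
                for endpoint in endpoints:
                    res = _stage("mcs")(monte_carlo.run_mcs)(
                        conc_dists, exp_dists, tox, p, endpoint,
                        n=n, seed=config.seed)
                    rows.append(res.summary_frame())
                    top = monte_carlo.sensitivity_ranking(res)[:3]
                    summary[f"mcs_{endpoint.lower()}_{p.receptor}_top_factors"] = [
                        name for name, _ in top]
            mcs_table = pd.concat(rows, ignore_index=True)
            mcs_table.to_csv(out_dir / "mcs_summary.csv", index=False)

    _write_json(summary, out_dir / "summary.json")
    logger.info("pipeline complete: %s", out_dir)
    return summary
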