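"""Probabilistic risk via Monte Carlo propagation.

Exposure factors and concentrations are assigned distributions, sampled
jointly, and pushed through the deterministic dose equations of
:mod:`reyrisk.health_risk` (which broadcast over arrays), yielding the full
distribution of the hazard index or target cancer risk. The result carries
summary statistics, the probability of exceeding the safety limit, and a
sensitivity measure per input: the Spearman rank correlation between the
sampled input and the endpoint.

Default input distributions (all overridable): body weight normal with
CV 0.2 truncated at zero; ingestion rate triangular at the deterministic
mode ± 50%; exposure frequency triangular (180, 350, 365) days/year;
concentrations normal at the sample mean/SD truncated at zero; every other
factor a point mass at its deterministic value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DataError
from .health_risk import PATHWAYS, daily_dose
from .reference_data import ExposureProfile, ToxicologyTable

__all__ = [
    "DistributionSpec", "McsResult", "sample_distribution",
    "default_exposure_distributions", "concentration_distributions",
    "run_mcs", "sensitivity_ranking",
]

#: Exposure-profile fields a DistributionSpec may target.
EXPOSURE_VARIABLES = (
    "ingestion_rate", "exposure_frequency", "exposure_duration",
    "body_weight", "skin_area", "adherence_factor", "dermal_absorption",
    "inhalation_rate", "pef",
)

PERCENTILES = (5, 25, 50, 75, 95)


@dataclass(frozen=True)
class DistributionSpec:
    """One input variable's sampling distribution.

    ``family`` is one of ``point``, ``normal``, ``lognormal``,
    ``triangular``, ``uniform``. ``params`` by family: point ``value``;
    normal/lognormal ``mean``/``sd`` (arithmetic moments); triangular
    ``left``/``mode``/``right``; uniform ``low``/``high``. Optional
    truncation bounds are enforced by rejection.
    """

    name: str
    family: str
    params: Mapping[str, float]
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        p = self.params
        fam = self.family
        try:
            if fam == "point":
                float(p["value"])
            elif fam == "normal":
                if not p["sd"] > 0:
                    raise ConfigError(f"{self.name}: normal sd must be > 0")
            elif fam == "lognormal":
                if not (p["mean"] > 0 and p["sd"] > 0):
                    raise ConfigError(
                        f"{self.name}: lognormal needs positive mean and sd")
            elif fam == "triangular":
                if not (p["left"] <= p["mode"] <= p["right"]
                        and p["left"] < p["right"]):
                    raise ConfigError(
                        f"{self.name}: triangular needs left <= mode <= right")
            elif fam == "uniform":
                if not p["low"] < p["high"]:
                    raise ConfigError(f"{self.name}: uniform needs low < high")
            else:
                raise ConfigError(f"{self.name}: unknown family {fam!r}")
        except KeyError as exc:
            raise ConfigError(
                f"{self.name}: missing parameter {exc} for family {fam!r}"
            ) from None
        if (self.lower is not None and self.upper is not None
                and not self.lower < self.upper):
            raise ConfigError(f"{self.name}: truncation bounds out of order")

    @property
    def is_point(self) -> bool:
        return self.family == "point"


def _draw(spec: DistributionSpec, m: int, rng: np.random.Generator) -> np.ndarray:
    p = spec.params
    if spec.family == "point":
        return np.full(m, float(p["value"]))
    if spec.family == "normal":
        return rng.normal(p["mean"], p["sd"], m)
    if spec.family == "lognormal":
        # convert arithmetic moments to log-space parameters
        mean, sd = p["mean"], p["sd"]
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), m)
    if spec.family == "triangular":
        return rng.triangular(p["left"], p["mode"], p["right"], m)
    return rng.uniform(p["low"], p["high"], m)


def sample_distribution(spec: DistributionSpec, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` values, honouring truncation bounds by rejection."""
    spec.validate()
    out = _draw(spec, n, rng)
    lo = -np.inf if spec.lower is None else spec.lower
    hi = np.inf if spec.upper is None else spec.upper
    for _ in range(1000):
        bad = (out <= lo) | (out >= hi) if spec.family != "point" else \
            np.zeros(n, dtype=bool)
        if not bad.any():
            return out
        out[bad] = _draw(spec, int(bad.sum()), rng)
    raise ConfigError(f"{spec.name}: truncation rejected nearly all draws")


def default_exposure_distributions(
        profile: ExposureProfile) -> dict[str, DistributionSpec]:
    """Default distribution set around a deterministic exposure profile."""
    bw = profile.body_weight
    ir = profile.ingestion_rate
    specs = {
        "body_weight": DistributionSpec(
            "body_weight", "normal", {"mean": bw, "sd": 0.2 * bw}, lower=0.0),
        "ingestion_rate": DistributionSpec(
            "ingestion_rate", "triangular",
            {"left": 0.5 * ir, "mode": ir, "right": 1.5 * ir}),
        "exposure_frequency": DistributionSpec(
            "exposure_frequency", "triangular",
            {"left": 180.0, "mode": 350.0, "right": 365.0}),
    }
    for name in EXPOSURE_VARIABLES:
        if name not in specs:
            specs[name] = DistributionSpec(
                name, "point", {"value": float(getattr(profile, name))})
    return specs


def concentration_distributions(conc: pd.DataFrame,
                                elements: list[str]) -> dict[str, DistributionSpec]:
    """Normal (mean, SD) specs per element from a concentration table,
    truncated at zero; a single-sample table yields point masses."""
    out = {}
    for el in elements:
        col = conc[el].astype(float)
        mean = float(col.mean())
        sd = float(col.std(ddof=1)) if len(col) > 1 else 0.0
        if sd > 0:
            out[el] = DistributionSpec(el, "normal",
                                       {"mean": mean, "sd": sd}, lower=0.0)
        else:
            out[el] = DistributionSpec(el, "point", {"value": mean})
    return out


@dataclass
class McsResult:
    """Monte Carlo endpoint distribution and input sensitivities."""

    receptor: str
    endpoint: str
    n_iterations: int
    seed: int
    mean: float
    sd: float
    percentiles: dict[int, float]
    exceedance_prob: float
    safety_limit: float
    sensitivity: dict[str, float]
    draws: np.ndarray = field(repr=False)

    def summary_frame(self) -> pd.DataFrame:
        row = {"receptor": self.receptor, "endpoint": self.endpoint,
               "n": self.n_iterations, "mean": self.mean, "sd": self.sd,
               "exceedance_prob": self.exceedance_prob}
        row.update({f"p{p}": v for p, v in self.percentiles.items()})
        return pd.DataFrame([row])


def run_mcs(conc_dists: Mapping[str, DistributionSpec],
            exposure_dists: Mapping[str, DistributionSpec],
            tox: ToxicologyTable,
            receptor: ExposureProfile,
            endpoint: str,
            n: int = 10_000,
            seed: int | None = None,
            safety_limit: float | None = None) -> McsResult:
    """Propagate input distributions to an HI or TCR distribution.

    ``conc_dists`` maps element symbols to concentration distributions
    (mg/kg); ``exposure_dists`` maps exposure-profile field names to
    distributions (missing fields stay at the deterministic value from
    ``receptor``). The endpoint per draw is computed with the same dose
    equations as the deterministic module, so point-mass inputs reproduce
    it exactly. A seed is required; identical seed and configuration give
    identical output.
    """
    endpoint = endpoint.upper()
    if endpoint not in ("HI", "TCR"):
        raise ConfigError(f"unknown endpoint {endpoint!r}")
    if n < 1:
        raise ConfigError("n must be >= 1")
    if seed is None:
        raise ConfigError("MCS seed is mandatory")
    if not conc_dists:
        raise ConfigError("no concentration distributions supplied")
    for spec in (*conc_dists.values(), *exposure_dists.values()):
        spec.validate()
    unknown = set(exposure_dists) - set(EXPOSURE_VARIABLES)
    if unknown:
        raise ConfigError(f"unknown exposure variables {sorted(unknown)}")
    if endpoint == "HI":
        tox.require_rfd(conc_dists)
    if safety_limit is None:
        safety_limit = 1.0 if endpoint == "HI" else 1e-6

    rng = np.random.default_rng(seed)
    inputs: dict[str, np.ndarray] = {}
    profile_fields: dict[str, np.ndarray] = {}
    for name in EXPOSURE_VARIABLES:  # fixed order for reproducibility
        if name in exposure_dists:
            arr = sample_distribution(exposure_dists[name], n, rng)
        else:
            arr = np.full(n, float(getattr(receptor, name)))
        profile_fields[name] = arr
        inputs[name] = arr
    profile = receptor.replace(**profile_fields)

    conc_draws: dict[str, np.ndarray] = {}
    for el in conc_dists:  # mapping order is part of the configuration
        arr = sample_distribution(conc_dists[el], n, rng)
        conc_draws[el] = arr
        inputs[f"C_{el}"] = arr

    draws = np.zeros(n)
    if endpoint == "HI":
        for el, c in conc_draws.items():
            add = sum(daily_dose(c, profile, p, horizon="chronic")
                      for p in PATHWAYS)
            draws += add / tox.rfd[el]
    else:
        for el, c in conc_draws.items():
            csf = tox.csf.get(el, 0.0)
            if csf:
                draws += daily_dose(c, profile, "ingestion",
                                    horizon="lifetime") * csf

    sensitivity: dict[str, float] = {}
    for name, arr in inputs.items():
        if np.ptp(arr) == 0 or np.ptp(draws) == 0:
            continue
        rho = sps.spearmanr(arr, draws).statistic
        sensitivity[name] = float(rho)

    return McsResult(
        receptor=receptor.receptor,
        endpoint=endpoint,
        n_iterations=n,
        seed=seed,
        mean=float(draws.mean()),
        sd=float(draws.std(ddof=1)) if n > 1 else 0.0,
        percentiles={p: float(np.percentile(draws, p)) for p in PERCENTILES},
        exceedance_prob=float((draws > safety_limit).mean()),
        safety_limit=safety_limit,
        sensitivity=sensitivity,
        draws=draws,
    )


def sensitivity_ranking(result: McsResult) -> list[tuple[str, float]]:
    """Inputs ordered by descending absolute rank correlation with the
    endpoint; ties break alphabetically."""
    if not result.sensitivity:
        raise DataError("result carries no sensitivities")
    return sorted(
        ((name, abs(rho)) for name, rho in result.sensitivity.items()),
        key=lambda item: (-item[1], item[0]),
    )
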