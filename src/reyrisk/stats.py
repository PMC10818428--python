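"""Descriptive statistics, correlation structure and normality testing.

The Pearson correlation matrix across elements documents the shared
provenance of the REYs (strongly correlated elements co-occur and can be
recovered together). The Ryan–Joiner statistic — the correlation between
the ordered data and normal scores — justifies treating per-element
concentrations as normal for parametric simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError

__all__ = ["CorrelationMatrix", "pearson_matrix", "ryan_joiner",
           "RyanJoinerResult", "describe"]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pearson correlations between element columns.

    ``r`` is a symmetric DataFrame with unit diagonal; ``n`` the number of
    samples it was computed from. Undefined entries (constant columns) are
    NaN.
    """

    elements: tuple[str, ...]
    r: pd.DataFrame
    n: int

    def offdiag(self) -> np.ndarray:
        """Flattened strictly-upper-triangle correlations."""
        a = self.r.to_numpy()
        iu = np.triu_indices_from(a, k=1)
        return a[iu]


def pearson_matrix(conc: pd.DataFrame,
                   elements: list[str] | None = None) -> CorrelationMatrix:
    """Pearson correlation matrix over element columns.

    Requires at least 3 samples and no missing values; a constant column
    yields NaN correlations with a warning rather than an error.
    """
    if elements is None:
        from .io import element_columns
        elements = element_columns(conc)
    c = conc[list(elements)].astype(float)
    if len(c) < 3:
        raise DataError("need at least 3 samples for a correlation matrix")
    if c.isna().any().any():
        raise DataError("missing values in concentration table")
    constant = c.columns[c.std(ddof=1) == 0].tolist()
    if constant:
        warnings.warn(
            f"constant columns yield undefined correlations: {constant}",
            stacklevel=2,
        )
    r = c.corr(method="pearson")
    return CorrelationMatrix(elements=tuple(elements), r=r, n=len(c))


@dataclass(frozen=True)
class RyanJoinerResult:
    statistic: float
    critical_value: float
    alpha: float
    n: int

    @property
    def normal(self) -> bool:
        """True when normality is not rejected at the chosen level."""
        return self.statistic >= self.critical_value


def _blom_scores(n: int) -> np.ndarray:
    i = np.arange(1, n + 1)
    return sps.norm.ppf((i - 3.0 / 8.0) / (n + 1.0 / 4.0))


def _rj_critical_value(n: int, alpha: float) -> float:
    # Standard approximation of the Ryan–Joiner critical value.
    rn = np.sqrt(n)
    if alpha == 0.10:
        return 1.0071 - 0.1371 / rn - 0.3682 / n + 0.7780 / n**2
    if alpha == 0.05:
        return 1.0063 - 0.1288 / rn - 0.6118 / n + 1.3505 / n**2
    if alpha == 0.01:
        return 0.9963 - 0.0211 / rn - 1.4106 / n + 3.1791 / n**2
    raise DataError("alpha must be one of 0.10, 0.05, 0.01")


def ryan_joiner(values, alpha: float = 0.05) -> RyanJoinerResult:
    """Ryan–Joiner normality statistic with its critical value.

    The statistic is the Pearson correlation between the sorted data and
    the Blom normal scores Φ⁻¹((i − 3/8)/(n + 1/4)); values near 1 are
    consistent with normality, and normality is rejected when the
    statistic falls below the critical value for the chosen level.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 4:
        raise DataError("Ryan–Joiner test needs at least 4 observations")
    if np.ptp(x) == 0:
        raise DataError("Ryan–Joiner statistic undefined for constant data")
    b = _blom_scores(n)
    stat = float(np.corrcoef(x, b)[0, 1])
    return RyanJoinerResult(statistic=stat,
                            critical_value=_rj_critical_value(n, alpha),
                            alpha=alpha, n=n)


def describe(conc: pd.DataFrame, elements: list[str] | None = None) -> pd.DataFrame:
    """Per-element mean, SD, min, max and Ryan–Joiner statistic."""
    if elements is None:
        from .io import element_columns
        elements = element_columns(conc)
    c = conc[list(elements)].astype(float)
    out = pd.DataFrame({
        "mean": c.mean(), "sd": c.std(ddof=1),
        "min": c.min(), "max": c.max(),
    })
    if len(c) >= 4:
        out["ryan_joiner"] = [
            ryan_joiner(c[e]).statistic if c[e].nunique() > 1 else np.nan
            for e in elements
        ]
    return out
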