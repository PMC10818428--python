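"""Monte Carlo propagation: determinism, degeneracy, sensitivity."""

import numpy as np
import pandas as pd
import pytest

from reyrisk import DEFAULT_ELEMENTS, health_risk, monte_carlo as mc
from reyrisk.errors import ConfigError, DataError

REYS = list(DEFAULT_ELEMENTS.reys)


def point(name, value):
    return mc.DistributionSpec(name, "point", {"value": float(value)})


@pytest.fixture()
def point_exposure(profiles):
    child = profiles["child"]
    return {name: point(name, getattr(child, name))
            for name in mc.EXPOSURE_VARIABLES}


class TestDistributionSpec:
    def test_invalid_parameters_error_before_sampling(self):
        with pytest.raises(ConfigError):
            mc.DistributionSpec("x", "normal", {"mean": 1.0, "sd": -1.0})
        with pytest.raises(ConfigError):
            mc.DistributionSpec("x", "triangular",
                                {"left": 2.0, "mode": 1.0, "right": 3.0})
        with pytest.raises(ConfigError):
            mc.DistributionSpec("x", "weibull", {"k": 1.0})
        with pytest.raises(ConfigError):
            mc.DistributionSpec("x", "normal", {"mean": 1.0})

    def test_truncation_respected(self):
        spec = mc.DistributionSpec("x", "normal", {"mean": 0.0, "sd": 1.0},
                                   lower=0.0)
        draws = mc.sample_distribution(spec, 2000, np.random.default_rng(0))
        assert (draws > 0).all()

    def test_lognormal_matches_arithmetic_moments(self):
        spec = mc.DistributionSpec("x", "lognormal", {"mean": 10.0, "sd": 2.0})
        draws = mc.sample_distribution(spec, 200_000,
                                       np.random.default_rng(1))
        assert draws.mean() == pytest.approx(10.0, rel=0.01)
        assert draws.std() == pytest.approx(2.0, rel=0.05)


class TestRunMcs:
    def test_degenerate_equals_deterministic(self, tox, profiles,
                                             serbia_mean_conc, point_exposure):
        """All point masses: the MCS mean must equal the deterministic HI
        exactly, reproducing the published child value (~0.15)."""
        child = profiles["child"]
        conc_dists = {e: point(e, serbia_mean_conc[e].iloc[0]) for e in REYS}
        res = mc.run_mcs(conc_dists, point_exposure, tox, child, "HI",
                         n=50, seed=3)
        det = health_risk.hazard(serbia_mean_conc, child, tox).hi.iloc[0]
        assert res.mean == pytest.approx(det, rel=1e-12)
        assert res.sd == pytest.approx(0.0, abs=1e-15)
        assert det == pytest.approx(0.15, rel=0.03)

    def test_seed_reproducibility(self, tox, profiles, serbia_mean_conc):
        child = profiles["child"]
        conc_dists = {"Ce": mc.DistributionSpec(
            "Ce", "normal", {"mean": 88.0, "sd": 20.0}, lower=0.0)}
        exp = mc.default_exposure_distributions(child)
        r1 = mc.run_mcs(conc_dists, exp, tox, child, "HI", n=1, seed=99)
        r2 = mc.run_mcs(conc_dists, exp, tox, child, "HI", n=1, seed=99)
        assert r1.draws[0] == r2.draws[0]
        assert r1.mean == r2.mean

    def test_percentiles_monotone_and_bounds(self, tox, profiles):
        child = profiles["child"]
        conc_dists = {"Ce": mc.DistributionSpec(
            "Ce", "normal", {"mean": 88.0, "sd": 30.0}, lower=0.0)}
        res = mc.run_mcs(conc_dists, mc.default_exposure_distributions(child),
                         tox, child, "HI", n=4000, seed=5)
        ps = [res.percentiles[p] for p in (5, 25, 50, 75, 95)]
        assert ps == sorted(ps)
        assert 0.0 <= res.exceedance_prob <= 1.0
        assert all(abs(r) <= 1.0 for r in res.sensitivity.values())

    def test_single_varying_factor_dominates(self, tox, profiles,
                                             point_exposure):
        """With only body weight varying, its |rank correlation| is ~1
        (negative: heavier receptor, lower dose) and nothing else varies."""
        child = profiles["child"]
        exp = dict(point_exposure)
        exp["body_weight"] = mc.DistributionSpec(
            "body_weight", "normal", {"mean": 15.0, "sd": 3.0}, lower=0.0)
        conc_dists = {"Ce": point("Ce", 88.0)}
        res = mc.run_mcs(conc_dists, exp, tox, child, "HI", n=500, seed=2)
        assert res.sensitivity["body_weight"] == pytest.approx(-1.0)
        assert set(res.sensitivity) == {"body_weight"}
        assert mc.sensitivity_ranking(res)[0][0] == "body_weight"

    def test_default_top_factors(self, tox, profiles, serbia_mean_conc):
        """Under the default distribution set the exposure factors BW, IR
        and EF occupy the top sensitivity ranks (asserted as a set)."""
        child = profiles["child"]
        conc_dists = mc.concentration_distributions(
            pd.concat([serbia_mean_conc] * 3), REYS)  # point masses
        res = mc.run_mcs(conc_dists, mc.default_exposure_distributions(child),
                         tox, child, "HI", n=4000, seed=17)
        top3 = {name for name, _ in mc.sensitivity_ranking(res)[:3]}
        assert top3 == {"body_weight", "ingestion_rate", "exposure_frequency"}

    def test_convergence_to_deterministic_mean(self, tox, profiles,
                                               serbia_mean_conc):
        """With symmetric inputs (only concentration varying, normal), the
        MCS mean approaches the deterministic value at the distribution
        means within 3 standard errors at n = 10^4."""
        child = profiles["child"]
        mean_ce = 240.0
        conc_dists = {"Ce": mc.DistributionSpec(
            "Ce", "normal", {"mean": mean_ce, "sd": 24.0})}
        exp = {name: point(name, getattr(child, name))
               for name in mc.EXPOSURE_VARIABLES}
        res = mc.run_mcs(conc_dists, exp, tox, child, "HI", n=10_000, seed=23)
        det = health_risk.hazard(
            pd.DataFrame({"Ce": [mean_ce]}, index=["m"]), child, tox).hi.iloc[0]
        se = res.sd / np.sqrt(res.n_iterations)
        assert abs(res.mean - det) < 3 * se

    def test_tcr_endpoint_skips_non_carcinogens(self, tox, profiles,
                                                point_exposure):
        child = profiles["child"]
        res = mc.run_mcs({"Hg": point("Hg", 0.2)}, point_exposure, tox,
                         child, "TCR", n=10, seed=1)
        assert res.mean == 0.0

    def test_config_guards(self, tox, profiles, point_exposure):
        child = profiles["child"]
        cd = {"Ce": point("Ce", 88.0)}
        with pytest.raises(ConfigError):
            mc.run_mcs(cd, point_exposure, tox, child, "HI", n=0, seed=1)
        with pytest.raises(ConfigError):
            mc.run_mcs(cd, point_exposure, tox, child, "HI", n=10, seed=None)
        with pytest.raises(ConfigError):
            mc.run_mcs(cd, point_exposure, tox, child, "LADD", n=10, seed=1)
        with pytest.raises(ConfigError):
            mc.run_mcs(cd, {"shoe_size": point("shoe_size", 40.0)},
                       tox, child, "HI", n=10, seed=1)


class TestSensitivityRanking:
    def test_tie_breaks_alphabetically(self, tox, profiles):
        res = mc.McsResult(
            receptor="child", endpoint="HI", n_iterations=10, seed=1,
            mean=0.1, sd=0.01, percentiles={}, exceedance_prob=0.0,
            safety_limit=1.0,
            sensitivity={"b_var": 0.5, "a_var": 0.5, "c_var": 0.9},
            draws=np.zeros(10))
        ranked = mc.sensitivity_ranking(res)
        assert [name for name, _ in ranked] == ["c_var", "a_var", "b_var"]

    def test_empty_sensitivities_error(self):
        res = mc.McsResult(
            receptor="child", endpoint="HI", n_iterations=1, seed=1,
            mean=0.0, sd=0.0, percentiles={}, exceedance_prob=0.0,
            safety_limit=1.0, sensitivity={}, draws=np.zeros(1))
        with pytest.raises(DataError):
            mc.sensitivity_ranking(res)
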