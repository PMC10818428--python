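"""USEPA exposure model: doses, hazard index, cancer risk."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from reyrisk import DEFAULT_ELEMENTS, health_risk
from reyrisk.errors import DataError, MissingElementError

REYS = list(DEFAULT_ELEMENTS.reys)


def one_row(values, name="s1"):
    return pd.DataFrame([values], index=pd.Index([name], name="sample_id"))


class TestDailyDose:
    def test_child_ingestion_hand_substitution(self, profiles):
        # 240.5*200*350*6 / (15*2190*1e6)
        dose = health_risk.daily_dose(240.5, profiles["child"], "ingestion")
        assert dose == pytest.approx(3.075e-3, rel=1e-3)

    def test_zero_concentration_zero_dose(self, profiles):
        for p in ("ingestion", "dermal", "inhalation"):
            assert health_risk.daily_dose(0.0, profiles["child"], p) == 0.0

    def test_adult_child_ingestion_ratio(self, profiles):
        """Symbolic ratio: (IRa/IRc)·(BWc/BWa) for the chronic dose, since
        EF·ED/AT cancels when AT = ED·365."""
        c = health_risk.daily_dose(100.0, profiles["child"], "ingestion")
        a = health_risk.daily_dose(100.0, profiles["adult"], "ingestion")
        assert a / c == pytest.approx((100 / 200) * (15 / 70))

    def test_lifetime_dose_not_above_chronic(self, profiles):
        for p in profiles.values():
            add = health_risk.daily_dose(100.0, p, "ingestion", "chronic")
            ladd = health_risk.daily_dose(100.0, p, "ingestion", "lifetime")
            assert ladd <= add

    def test_unknown_pathway_errors(self, profiles):
        with pytest.raises(DataError):
            health_risk.daily_dose(1.0, profiles["child"], "dietary")


class TestHazard:
    def test_child_rey_hazard_index(self, tox, profiles, serbia_mean_conc):
        res = health_risk.hazard(serbia_mean_conc, profiles["child"], tox)
        # published at 2 significant figures, hence the 3% band
        assert res.hi_by_group["rey"].iloc[0] == pytest.approx(0.15, rel=0.03)

    def test_adult_rey_hazard_index(self, tox, profiles, serbia_mean_conc):
        res = health_risk.hazard(serbia_mean_conc, profiles["adult"], tox)
        assert res.hi_by_group["rey"].iloc[0] == pytest.approx(0.017, rel=0.03)

    def test_hq_one_when_dose_equals_rfd(self, tox, profiles):
        """Invert the ingestion equation for the concentration whose summed
        dose equals the RfD; HQ must then be ~1 (ingestion dominates)."""
        p = profiles["child"]
        per_unit = sum(
            health_risk.daily_dose(1.0, p, pw) for pw in health_risk.PATHWAYS)
        c = tox.rfd["Ce"] / per_unit
        res = health_risk.hazard(one_row({"Ce": c}), p, tox)
        assert res.hq.loc["s1", "Ce"] == pytest.approx(1.0)

    def test_hi_is_sum_of_hq(self, tox, profiles, group_means):
        res = health_risk.hazard(group_means, profiles["child"], tox, REYS)
        assert np.allclose(res.hi, res.hq.sum(axis=1))

    @settings(deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.1, max_value=10))
    def test_linearity(self, tox, profiles, serbia_mean_conc, scale):
        base = health_risk.hazard(serbia_mean_conc, profiles["child"], tox)
        scaled = health_risk.hazard(
            serbia_mean_conc * scale, profiles["child"], tox)
        assert scaled.hi.iloc[0] == pytest.approx(scale * base.hi.iloc[0])

    def test_ingestion_dominates(self, tox, profiles, group_means):
        p = profiles["child"]
        ing = health_risk.daily_dose(
            group_means[REYS], p, "ingestion")
        total = sum(health_risk.daily_dose(group_means[REYS], p, pw)
                    for pw in health_risk.PATHWAYS)
        assert (ing / total > 0.95).all().all()

    def test_missing_rfd_errors(self, tox, profiles):
        conc = one_row({"La": 1.0})
        slim = type(tox)(tr=tox.tr, rfd={"Ce": 0.02}, csf=tox.csf)
        with pytest.raises(MissingElementError, match="La"):
            health_risk.hazard(conc, profiles["child"], slim, ["La"])


class TestCancerRisk:
    def test_child_rey_tcr(self, tox, profiles, serbia_mean_conc):
        res = health_risk.cancer_risk(serbia_mean_conc, profiles["child"], tox)
        assert res.tcr_by_group["rey"].iloc[0] == pytest.approx(8.4e-16, rel=0.02)

    def test_adult_rey_tcr(self, tox, profiles, serbia_mean_conc):
        res = health_risk.cancer_risk(serbia_mean_conc, profiles["adult"], tox)
        assert res.tcr_by_group["rey"].iloc[0] == pytest.approx(3.6e-16, rel=0.02)

    def test_highest_sample_lumped(self, tox, profiles, lumped_rey):
        res = health_risk.cancer_risk(lumped_rey(333.0), profiles["child"], tox)
        assert res.tcr.iloc[0] == pytest.approx(1.2e-15, rel=0.03)

    def test_element_without_csf_contributes_zero(self, tox, profiles):
        conc = one_row({"Hg": 0.2, "As": 10.0})
        res = health_risk.cancer_risk(conc, profiles["adult"], tox)
        assert res.cr.loc["s1", "Hg"] == 0.0
        assert res.cr.loc["s1", "As"] > 0.0

    def test_sum_order_invariance(self, tox, profiles, group_means):
        """Summing HQ over elements then pathways equals pathways then
        elements: compare assess() totals against an explicit double sum."""
        p = profiles["child"]
        res = health_risk.hazard(group_means, p, tox, REYS)
        by_pathway = sum(
            (health_risk.daily_dose(group_means[REYS], p, pw)
             / pd.Series({e: tox.rfd[e] for e in REYS})).sum(axis=1)
            for pw in health_risk.PATHWAYS)
        assert np.allclose(res.hi, by_pathway)


class TestAssessAndShares:
    def test_partial_sums_add_up(self, tox, profiles, group_means):
        conc = group_means.copy()
        conc["As"] = 92.0
        conc["Hg"] = 0.2
        table = health_risk.assess(conc, profiles.values(), tox)
        assert np.allclose(
            table["HI_child_rey"] + table["HI_child_hm"], table["HI_child"])
        assert np.allclose(
            table["TCR_child_rey"] + table["TCR_child_hm"], table["TCR_child"])

    def test_group_share_from_published_style_table(self):
        from importlib import resources
        path = resources.files("reyrisk").joinpath("data", "study_risk_table.csv")
        table = pd.read_csv(str(path), index_col="sample_id")
        share = health_risk.group_share(table.loc[["Mean"]], "HI",
                                        "child", "rey")
        assert share == pytest.approx(0.026, abs=0.001)
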