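import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from soilrisk.io import ExposureProfile, MetalParams
from soilrisk._defaults import METALS, PATHWAYS
from soilrisk.risk import (RiskModel, add_doses, hazard_and_cancer,
                           pathway_ranking, sankey_export,
                           source_risk_apportion)

SURVEY_MEAN = pd.Series({"Hg": 0.04, "Cr": 48.3, "Cu": 54.3, "Pb": 45.7,
                         "Zn": 70.0, "As": 22.9, "Cd": 0.42, "Ni": 35.7})


def _profile(**over):
    base = dict(IngR=100.0, InhR=14.5, EF=350.0, ED=24.0, BW=60.6,
                PEF=1.36e9, SA=5700.0, AF=0.07, ABS=0.001, AT_ca=70 * 365.0)
    base.update(over)
    return ExposureProfile(cohort="adult", **base)


class TestAddDoses:
    def test_ingestion_formula_arithmetic(self):
        prof = _profile(IngR=100, EF=350, ED=24, BW=60.0)
        conc = pd.Series({"As": 100.0})
        add = add_doses(conc, prof, carcinogenic=False)
        # 100*100*350*24*1e-6 / (60*8760) = 1.598e-4
        assert add.loc["As", "ingestion"] == pytest.approx(1.598e-4, rel=1e-3)

    def test_zero_concentration_gives_zero_dose(self):
        add = add_doses(pd.Series({"Cd": 0.0}), _profile(), carcinogenic=True)
        assert (add.loc["Cd"] == 0).all()

    @settings(deadline=None, derandomize=True)
    @given(c=st.floats(1e-6, 1e4), k=st.floats(0.1, 10))
    def test_doses_linear_in_concentration(self, c, k):
        a = add_doses(pd.Series({"Pb": c}), _profile(), carcinogenic=False)
        b = add_doses(pd.Series({"Pb": k * c}), _profile(), carcinogenic=False)
        np.testing.assert_allclose(b.to_numpy(), k * a.to_numpy(), rtol=1e-9)

    def test_carcinogenic_uses_lifetime_averaging(self):
        prof = _profile()
        conc = pd.Series({"As": 10.0})
        nc = add_doses(conc, prof, carcinogenic=False)
        ca = add_doses(conc, prof, carcinogenic=True)
        ratio = prof.AT_nc / prof.AT_ca          # 8760 / 25550
        np.testing.assert_allclose(ca.to_numpy(), nc.to_numpy() * ratio,
                                   rtol=1e-12)
        assert ratio < 1


class TestHazardAndCancer:
    def test_thi_is_brute_force_sum(self, params, profiles):
        r = hazard_and_cancer(SURVEY_MEAN, profiles["adult"], params)
        add = add_doses(SURVEY_MEAN, profiles["adult"], carcinogenic=False)
        brute = sum(add.loc[m, pw] / params.rfd[m][pw]
                    for m in METALS for pw in PATHWAYS)
        assert r.thi == pytest.approx(brute, rel=1e-12)

    def test_tcr_sums_only_defined_slope_factors(self, params, profiles):
        r = hazard_and_cancer(SURVEY_MEAN, profiles["child"], params)
        add = add_doses(SURVEY_MEAN, profiles["child"], carcinogenic=True)
        brute = sum(add.loc[m, pw] * s
                    for m in METALS for pw, s in params.sf.get(m, {}).items())
        assert r.tcr == pytest.approx(brute, rel=1e-12)
        assert r.cr.loc["Zn"].sum() == 0.0    # no SF for Zn

    def test_no_carcinogens_means_negligible_tcr(self, params, profiles):
        p2 = MetalParams.defaults()
        p2.sf = {}
        r = hazard_and_cancer(SURVEY_MEAN, profiles["adult"], p2)
        assert r.tcr == 0.0
        assert r.tcr_flag == "negligible"

    def test_unit_hazard_boundary_flag(self, profiles):
        params = MetalParams.defaults()
        r = hazard_and_cancer(SURVEY_MEAN, profiles["adult"], params)
        # scale concentrations so THI is exactly 1: boundary is acceptable
        scaled = SURVEY_MEAN * (1.0 / r.thi)
        r1 = hazard_and_cancer(scaled, profiles["adult"], params)
        assert r1.thi == pytest.approx(1.0, rel=1e-9)
        assert r1.thi_flag == "acceptable"     # risk flagged only above 1

    def test_thi_linear_in_concentration(self, params, profiles):
        r1 = hazard_and_cancer(SURVEY_MEAN, profiles["adult"], params)
        r2 = hazard_and_cancer(2.5 * SURVEY_MEAN, profiles["adult"], params)
        assert r2.thi == pytest.approx(2.5 * r1.thi, rel=1e-12)
        assert r2.tcr == pytest.approx(2.5 * r1.tcr, rel=1e-12)


class TestPathwayRanking:
    def test_ingestion_dominates_with_handbook_parameters(self, params,
                                                          profiles):
        for cohort in ("adult", "child"):
            r = hazard_and_cancer(SURVEY_MEAN, profiles[cohort], params)
            rank = pathway_ranking(r)
            assert rank.index[0] == "ingestion"
            assert rank["thi_pct"].sum() == pytest.approx(100.0)

    def test_equalized_pathways_split_in_thirds(self):
        params = MetalParams.defaults()
        # same RfD on every pathway and exposure constants tuned so the
        # three pathway dose factors coincide
        for m in METALS:
            params.rfd[m] = {pw: 1.0e-3 for pw in PATHWAYS}
        prof = _profile(IngR=100.0, InhR=100.0, PEF=1e6,
                        SA=1000.0, AF=0.1, ABS=1.0)
        # ing: 100*1e-6 = 1e-4; inh: 100/1e6 = 1e-4; der: 1000*0.1*1*1e-6 = 1e-4
        r = hazard_and_cancer(SURVEY_MEAN, prof, params)
        rank = pathway_ranking(r)
        np.testing.assert_allclose(rank["thi_pct"], 100 / 3, rtol=1e-9)


class TestSourceApportionment:
    def _shares(self, rows):
        return pd.DataFrame(rows, columns=list(METALS),
                            index=[f"F{i+1}" for i in range(len(rows))])

    def test_single_source_gets_everything(self, params, profiles):
        r = hazard_and_cancer(SURVEY_MEAN, profiles["adult"], params)
        shares = self._shares([[100.0] * 8])
        out = source_risk_apportion(r, shares)
        assert out["thi_share_pct"].iloc[0] == pytest.approx(100.0)
        assert out["tcr_share_pct"].iloc[0] == pytest.approx(100.0)

    def test_shares_sum_to_100(self, params, profiles):
        rng = np.random.default_rng(0)
        raw = rng.uniform(0, 1, (4, 8))
        shares = self._shares(100 * raw / raw.sum(axis=0))
        r = hazard_and_cancer(SURVEY_MEAN, profiles["child"], params)
        out = source_risk_apportion(r, shares)
        assert out["thi_share_pct"].sum() == pytest.approx(100.0, abs=1e-9)
        assert out["tcr_share_pct"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_zero_risk_metal_contributes_nothing(self, params, profiles):
        conc = SURVEY_MEAN.copy()
        conc["Zn"] = 1e4    # huge Zn, but give it all to source 2
        r = hazard_and_cancer(conc, profiles["adult"], params)
        shares_a = self._shares([[50.0] * 8, [50.0] * 8])
        base = source_risk_apportion(r, shares_a)
        # moving Zn entirely between sources changes shares only via Zn's HQ
        shares_b = shares_a.copy()
        shares_b.loc["F1", "Zn"], shares_b.loc["F2", "Zn"] = 100.0, 0.0
        conc0 = conc.copy()
        conc0["Zn"] = 1e-12  # Zn risk ~ 0 -> its source split is irrelevant
        r0 = hazard_and_cancer(conc0, profiles["adult"], params)
        a = source_risk_apportion(r0, shares_a)
        b = source_risk_apportion(r0, shares_b)
        np.testing.assert_allclose(a["thi_share_pct"], b["thi_share_pct"],
                                   atol=1e-6)

    def test_metal_set_mismatch_rejected(self, params, profiles):
        r = hazard_and_cancer(SURVEY_MEAN, profiles["adult"], params)
        shares = pd.DataFrame([[100.0] * 7],
                              columns=[m for m in METALS if m != "Cd"],
                              index=["F1"])
        with pytest.raises(ValueError, match="Cd"):
            source_risk_apportion(r, shares)

    def test_truth_shares_recovered_through_apportionment(self, params,
                                                          profiles, cohort):
        """Apportioning with the generator's true per-metal shares equals a
        direct truth computation of source-resolved hazard."""
        samples, truth = cohort
        conc = samples.concentrations().mean()
        r = hazard_and_cancer(conc, profiles["adult"], params)
        out = source_risk_apportion(r, truth.metal_shares)
        hq_m = r.hq_by_metal()
        direct = 100.0 * (truth.metal_shares[list(METALS)] / 100.0) @ hq_m \
            / r.thi
        np.testing.assert_allclose(out["thi_share_pct"], direct, atol=1e-9)


def test_sankey_export_structure(params, profiles):
    r = hazard_and_cancer(SURVEY_MEAN, profiles["adult"], params)
    shares = pd.DataFrame([[60.0] * 8, [40.0] * 8], columns=list(METALS),
                          index=["F1", "F2"])
    payload = sankey_export({"adult": r}, shares)
    kinds = {n["kind"] for n in payload["nodes"]}
    assert kinds == {"source", "metal", "risk"}
    metal_links = [l for l in payload["links"] if l["target"].startswith("THI")]
    assert sum(l["value_pct"] for l in metal_links) == pytest.approx(100.0)


def test_risk_model_mean_first_equals_manual(params, profiles, cohort):
    samples, _ = cohort
    conc = samples.concentrations()
    res = RiskModel(conc, params, profiles).fit()
    manual = hazard_and_cancer(conc.mean(), profiles["adult"], params)
    assert res.cohorts["adult"].thi == pytest.approx(manual.thi, rel=1e-12)
    summary = res.summary()
    assert set(summary.index) == {"adult", "child"}


def test_per_sample_mode_produces_row_wise_risk(params, profiles, toy4):
    conc = toy4.concentrations()
    res = RiskModel(conc, params, profiles, per_sample=True).fit()
    per = res.per_sample["adult"]
    assert len(per) == 4
    one = hazard_and_cancer(conc.iloc[2], profiles["adult"], params)
    assert per["thi"].iloc[2] == pytest.approx(one.thi, rel=1e-12)
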