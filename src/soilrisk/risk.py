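"""USEPA-style deterministic health-risk assessment for soil heavy metals.

Three exposure pathways are quantified for each cohort (adult, child):

    ADD_ing = C · IngR · EF · ED · 10⁻⁶ / (BW · AT)
    ADD_inh = C · InhR · EF · ED / (PEF · BW · AT)
    ADD_der = C · SA · AF · ABS · EF · ED · 10⁻⁶ / (BW · AT)

with AT the non-carcinogenic averaging time ED·365 d for hazard quotients
and the lifetime averaging time for carcinogenic risk. Non-carcinogenic
hazard: HQ = ADD/RfD, THI = Σ HQ over metals and pathways (THI > 1 flags a
risk). Carcinogenic risk: CR = ADD·SF over metal–pathway pairs with a
published slope factor, TCR = Σ CR (10⁻⁶–10⁻⁴ is the conventional
acceptable band).

Risk is computed on cohort mean concentrations by default (one THI/TCR per
cohort); a per-sample mode is available. PMF per-metal factor shares
apportion THI/TCR to pollution sources, exported as a Sankey node/link
table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._defaults import METALS, PATHWAYS
from .io import ConfigError, ExposureProfile, MetalParams

__all__ = ["add_doses", "RiskModel", "RiskResults", "hazard_and_cancer",
           "pathway_ranking", "source_risk_apportion", "sankey_export"]


def add_doses(conc: pd.Series, profile: ExposureProfile,
              carcinogenic: bool) -> pd.DataFrame:
    """Average daily dose (mg·kg⁻¹·d⁻¹) per metal × pathway."""
    at = profile.AT_ca if carcinogenic else profile.AT_nc
    if min(profile.BW, at, profile.PEF) <= 0:
        raise ValueError("BW, AT and PEF must be positive")
    c = conc.astype(float)
    common = profile.EF * profile.ED / (profile.BW * at)
    ing = c * profile.IngR * common * 1e-6
    inh = c * profile.InhR * common / profile.PEF
    der = c * profile.SA * profile.AF * profile.ABS * common * 1e-6
    return pd.DataFrame({"ingestion": ing, "inhalation": inh, "dermal": der})


def hazard_and_cancer(conc: pd.Series, profile: ExposureProfile,
                      params: MetalParams) -> "CohortRisk":
    """HQ/CR tables and THI/TCR totals for one cohort at the given
    concentrations (mg·kg⁻¹ per metal)."""
    add_nc = add_doses(conc, profile, carcinogenic=False)
    add_ca = add_doses(conc, profile, carcinogenic=True)

    hq = pd.DataFrame(0.0, index=conc.index, columns=list(PATHWAYS))
    for m in conc.index:
        table = params.rfd.get(m)
        if table is None:
            raise ConfigError(f"RfD missing for {m}")
        for pw in PATHWAYS:
            if pw not in table:
                raise ConfigError(f"RfD missing for {m}/{pw}")
            hq.loc[m, pw] = add_nc.loc[m, pw] / table[pw]

    cr = pd.DataFrame(0.0, index=conc.index, columns=list(PATHWAYS))
    for m in conc.index:
        for pw, s in (params.sf.get(m) or {}).items():
            cr.loc[m, pw] = add_ca.loc[m, pw] * s

    thi = float(hq.to_numpy().sum())
    tcr = float(cr.to_numpy().sum())
    return CohortRisk(cohort=profile.cohort, add_nc=add_nc, add_ca=add_ca,
                      hq=hq, cr=cr, thi=thi, tcr=tcr)


def _tcr_flag(tcr: float) -> str:
    if tcr < 1e-6:
        return "negligible"
    if tcr <= 1e-4:
        return "acceptable"
    return "risk"


@dataclass
class CohortRisk:
    cohort: str
    add_nc: pd.DataFrame     # metal × pathway, non-carcinogenic averaging
    add_ca: pd.DataFrame     # metal × pathway, lifetime averaging
    hq: pd.DataFrame
    cr: pd.DataFrame
    thi: float
    tcr: float

    @property
    def thi_flag(self) -> str:
        return "noncarcinogenic risk" if self.thi > 1 else "acceptable"

    @property
    def tcr_flag(self) -> str:
        return _tcr_flag(self.tcr)

    def hq_by_metal(self) -> pd.Series:
        return self.hq.sum(axis=1)

    def cr_by_metal(self) -> pd.Series:
        return self.cr.sum(axis=1)


def pathway_ranking(risk: CohortRisk) -> pd.DataFrame:
    """Percent of THI and TCR by pathway, sorted descending by THI share."""
    thi_pct = 100.0 * risk.hq.sum(axis=0) / risk.thi if risk.thi > 0 else \
        risk.hq.sum(axis=0) * 0.0
    tcr_pct = 100.0 * risk.cr.sum(axis=0) / risk.tcr if risk.tcr > 0 else \
        risk.cr.sum(axis=0) * 0.0
    out = pd.DataFrame({"thi_pct": thi_pct, "tcr_pct": tcr_pct})
    return out.sort_values("thi_pct", ascending=False)


def source_risk_apportion(risk: CohortRisk,
                          metal_shares: pd.DataFrame) -> pd.DataFrame:
    """Apportion THI and TCR to pollution sources.

    ``metal_shares`` is the PMF per-metal factor share table (% of each
    metal's mass per source, columns = metals). Source k's share of THI is
    Σ_m share_km · HQ_m / THI, likewise for TCR; each column of the result
    sums to 100%.
    """
    metals = list(risk.hq.index)
    missing = set(metals) - set(metal_shares.columns)
    if missing:
        raise ValueError(f"factor shares missing metals: {sorted(missing)}")
    S = metal_shares[metals] / 100.0
    hq_m = risk.hq_by_metal()
    cr_m = risk.cr_by_metal()
    thi_share = 100.0 * (S @ hq_m) / risk.thi if risk.thi > 0 else S @ hq_m * 0
    tcr_share = 100.0 * (S @ cr_m) / risk.tcr if risk.tcr > 0 else S @ cr_m * 0
    return pd.DataFrame({"thi_share_pct": thi_share, "tcr_share_pct": tcr_share})


def sankey_export(risks: dict[str, CohortRisk],
                  metal_shares: pd.DataFrame) -> dict:
    """Node/link table for a source → metal → risk Sankey diagram.

    Link weights are the contribution of each source to each metal's HQ/CR
    and of each metal to each cohort's THI/TCR (percent of the total).
    """
    sources = list(metal_shares.index)
    metals = list(metal_shares.columns)
    nodes = ([{"id": s, "kind": "source"} for s in sources]
             + [{"id": m, "kind": "metal"} for m in metals])
    links = []
    for cohort, risk in risks.items():
        for kind, per_metal, total in (("THI", risk.hq_by_metal(), risk.thi),
                                       ("TCR", risk.cr_by_metal(), risk.tcr)):
            node_id = f"{kind} ({cohort})"
            nodes.append({"id": node_id, "kind": "risk"})
            for m in metals:
                if total <= 0:
                    continue
                for s in sources:
                    w = metal_shares.loc[s, m] / 100.0 * per_metal[m] / total * 100.0
                    links.append({"source": s, "target": m,
                                  "risk": node_id, "value_pct": float(w)})
                links.append({"source": m, "target": node_id,
                              "value_pct": float(100.0 * per_metal[m] / total)})
    return {"nodes": nodes, "links": links}


@dataclass
class RiskModel:
    """Health-risk assessment over cohorts.

    ``conc`` may be a per-metal Series (already-aggregated, e.g. cohort mean
    concentrations — the default reporting convention) or an n × metal
    DataFrame with ``per_sample=True`` to obtain per-sample THI/TCR.
    """

    conc: pd.Series | pd.DataFrame
    params: MetalParams
    profiles: dict[str, ExposureProfile]
    per_sample: bool = False

    def fit(self) -> "RiskResults":
        if isinstance(self.conc, pd.DataFrame) and not self.per_sample:
            conc = self.conc.mean(axis=0)
        else:
            conc = self.conc
        cohorts = {}
        per_sample = {}
        if self.per_sample:
            for name, prof in self.profiles.items():
                rows = {sid: (hazard_and_cancer(self.conc.loc[sid], prof,
                                                self.params))
                        for sid in self.conc.index}
                per_sample[name] = pd.DataFrame(
                    {"thi": {k: r.thi for k, r in rows.items()},
                     "tcr": {k: r.tcr for k, r in rows.items()}})
            conc = self.conc.mean(axis=0)
        for name, prof in self.profiles.items():
            cohorts[name] = hazard_and_cancer(conc, prof, self.params)
        return RiskResults(cohorts=cohorts, per_sample=per_sample or None,
                           conc=conc, params=self.params)


@dataclass
class RiskResults:
    cohorts: dict[str, CohortRisk]
    conc: pd.Series
    params: MetalParams
    per_sample: dict[str, pd.DataFrame] | None = None

    def table(self) -> pd.DataFrame:
        """Tidy per-cohort × metal × pathway table of ADD, HQ and CR."""
        rows = []
        for name, r in self.cohorts.items():
            for m in r.hq.index:
                for pw in PATHWAYS:
                    rows.append({
                        "cohort": name, "metal": m, "pathway": pw,
                        "add_nc": r.add_nc.loc[m, pw],
                        "add_ca": r.add_ca.loc[m, pw],
                        "hq": r.hq.loc[m, pw], "cr": r.cr.loc[m, pw]})
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        rows = {}
        for name, r in self.cohorts.items():
            rows[name] = {"THI": r.thi, "THI flag": r.thi_flag,
                          "TCR": r.tcr, "TCR flag": r.tcr_flag}
        return pd.DataFrame(rows).T
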