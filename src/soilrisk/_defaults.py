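"""Default parameter tables for the eight-metal soil assessment.

All concentrations are mg·kg⁻¹ dry soil. Values are the standard published
references for a north-Chinese (Inner Mongolia) agricultural setting:
regional background values, GB 15618-2018 screening/intervention thresholds
by pH band, method detection limits of the AFS/ICP-AES assay, Hakanson
toxic-response factors, Chinese exposure-handbook cohort parameters, and
USEPA reference doses / slope factors. Every default can be overridden from
the YAML config; nothing downstream reads constants from anywhere else.
"""

from __future__ import annotations

#: Canonical metal order used everywhere (columns of X, parameter tables).
METALS: tuple[str, ...] = ("Hg", "Cr", "Cu", "Pb", "Zn", "As", "Cd", "Ni")

#: Exposure pathways, in reporting order.
PATHWAYS: tuple[str, ...] = ("ingestion", "inhalation", "dermal")

# Regional soil background values (mg/kg). Cr/Cu/Pb/Zn/As/Ni follow the
# CNEMC (1990) Inner Mongolia compilation; Hg and Cd are the values
# consistent with the study region's reported background-exceedance factors.
BACKGROUND = {
    "Hg": 0.0303,
    "Cr": 41.4,
    "Cu": 14.4,
    "Pb": 17.0,
    "Zn": 59.1,
    "As": 7.5,
    "Cd": 0.0375,
    "Ni": 19.5,
}

#: Method detection limits of the analytical assay (mg/kg).
MDL = {
    "Hg": 0.002,
    "Cr": 4.0,
    "Cu": 1.0,
    "Pb": 10.0,
    "Zn": 1.0,
    "As": 0.01,
    "Cd": 0.01,
    "Ni": 3.0,
}

#: Hakanson toxic-response factors (dimensionless).
TOXIC_RESPONSE = {
    "Hg": 40.0,
    "Cr": 2.0,
    "Cu": 5.0,
    "Pb": 5.0,
    "Zn": 1.0,
    "As": 10.0,
    "Cd": 30.0,
    "Ni": 5.0,
}

#: GB 15618-2018 risk screening values for agricultural land (mg/kg),
#: keyed by soil-pH band.  Band labels: "<=5.5", "5.5-6.5", "6.5-7.5", ">7.5".
PH_BANDS: tuple[str, ...] = ("<=5.5", "5.5-6.5", "6.5-7.5", ">7.5")

SCREENING = {
    "Cd": {"<=5.5": 0.3, "5.5-6.5": 0.3, "6.5-7.5": 0.3, ">7.5": 0.6},
    "Hg": {"<=5.5": 1.3, "5.5-6.5": 1.8, "6.5-7.5": 2.4, ">7.5": 3.4},
    "As": {"<=5.5": 40.0, "5.5-6.5": 40.0, "6.5-7.5": 30.0, ">7.5": 25.0},
    "Pb": {"<=5.5": 70.0, "5.5-6.5": 90.0, "6.5-7.5": 120.0, ">7.5": 170.0},
    "Cr": {"<=5.5": 150.0, "5.5-6.5": 150.0, "6.5-7.5": 200.0, ">7.5": 250.0},
    "Cu": {"<=5.5": 50.0, "5.5-6.5": 50.0, "6.5-7.5": 100.0, ">7.5": 100.0},
    "Ni": {"<=5.5": 60.0, "5.5-6.5": 70.0, "6.5-7.5": 100.0, ">7.5": 190.0},
    "Zn": {"<=5.5": 200.0, "5.5-6.5": 200.0, "6.5-7.5": 250.0, ">7.5": 300.0},
}

#: GB 15618-2018 risk intervention values (mg/kg); the standard defines them
#: only for Cd, Hg, As, Pb and Cr — the other metals have none.
INTERVENTION = {
    "Cd": {"<=5.5": 1.5, "5.5-6.5": 2.0, "6.5-7.5": 3.0, ">7.5": 4.0},
    "Hg": {"<=5.5": 2.0, "5.5-6.5": 2.5, "6.5-7.5": 4.0, ">7.5": 6.0},
    "As": {"<=5.5": 200.0, "5.5-6.5": 150.0, "6.5-7.5": 120.0, ">7.5": 100.0},
    "Pb": {"<=5.5": 400.0, "5.5-6.5": 500.0, "6.5-7.5": 700.0, ">7.5": 1000.0},
    "Cr": {"<=5.5": 800.0, "5.5-6.5": 850.0, "6.5-7.5": 1000.0, ">7.5": 1300.0},
}

#: USEPA reference doses, mg·kg⁻¹·d⁻¹, per pathway.
RFD = {
    "Hg": {"ingestion": 3.0e-4, "inhalation": 8.57e-5, "dermal": 2.1e-5},
    "Cr": {"ingestion": 3.0e-3, "inhalation": 2.86e-5, "dermal": 6.0e-5},
    "Cu": {"ingestion": 4.0e-2, "inhalation": 4.02e-2, "dermal": 1.2e-2},
    "Pb": {"ingestion": 3.5e-3, "inhalation": 3.52e-3, "dermal": 5.25e-4},
    "Zn": {"ingestion": 3.0e-1, "inhalation": 3.0e-1, "dermal": 6.0e-2},
    "As": {"ingestion": 3.0e-4, "inhalation": 3.01e-4, "dermal": 1.23e-4},
    "Cd": {"ingestion": 1.0e-3, "inhalation": 1.0e-3, "dermal": 1.0e-5},
    "Ni": {"ingestion": 2.0e-2, "inhalation": 2.06e-2, "dermal": 5.4e-3},
}

#: Carcinogenic slope factors, (mg·kg⁻¹·d⁻¹)⁻¹; metals/pathways without a
#: published SF are simply absent and drop out of the carcinogenic sum.
SF = {
    "As": {"ingestion": 1.5, "inhalation": 15.1, "dermal": 3.66},
    "Cd": {"inhalation": 6.3},
    "Cr": {"ingestion": 0.5, "inhalation": 42.0},
    "Ni": {"inhalation": 0.84},
    "Pb": {"ingestion": 8.5e-3},
}

#: Analytical relative standard deviation per metal, used for the
#: concentration-uncertainty model of the receptor analysis. 10% reflects
#: the assay's duplicate-sample precision (recoveries 80–120%).
RSD = {m: 0.10 for m in METALS}

#: Cohort exposure parameters (Chinese population exposure handbook).
EXPOSURE = {
    "adult": {
        "IngR": 100.0,      # soil ingestion rate, mg/d
        "InhR": 14.5,       # inhalation rate, m3/d
        "EF": 350.0,        # exposure frequency, d/a
        "ED": 24.0,         # exposure duration, a
        "BW": 60.6,         # body weight, kg
        "PEF": 1.36e9,      # particle emission factor, m3/kg
        "SA": 5700.0,       # exposed skin area, cm2
        "AF": 0.07,         # skin adherence factor, mg/(cm2·d)
        "ABS": 0.001,       # dermal absorption fraction
        "AT_ca": 70.0 * 365.0,  # carcinogenic averaging time, d (lifetime)
    },
    "child": {
        "IngR": 200.0,
        "InhR": 7.5,
        "EF": 350.0,
        "ED": 6.0,
        "BW": 19.2,
        "PEF": 1.36e9,
        "SA": 2800.0,
        "AF": 0.2,
        "ABS": 0.001,
        "AT_ca": 70.0 * 365.0,
    },
}

#: Coefficient-of-variation class bounds (%), half-open upper bounds.
CV_CLASSES = ((20.0, "low"), (50.0, "moderate"), (100.0, "high"),
              (float("inf"), "extreme"))

#: Müller geoaccumulation classes: (upper bound, label), half-open (lo, hi].
IGEO_CLASSES = (
    (0.0, "unpolluted"),
    (1.0, "unpolluted to moderately polluted"),
    (2.0, "moderately polluted"),
    (3.0, "moderately to heavily polluted"),
    (4.0, "heavily polluted"),
    (5.0, "heavily to extremely polluted"),
    (float("inf"), "extremely polluted"),
)

#: Hakanson single-metal ecological risk classes.
ERI_CLASSES = (
    (40.0, "low"),
    (80.0, "moderate"),
    (160.0, "considerable"),
    (320.0, "high"),
    (float("inf"), "very high"),
)

#: Hakanson integrated risk-index classes.
RI_CLASSES = (
    (150.0, "low"),
    (300.0, "moderate"),
    (600.0, "considerable"),
    (float("inf"), "very high"),
)
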