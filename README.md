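# soilrisk

Assessment toolkit for heavy-metal contamination of agricultural soils:
pollution indices, spatial interpolation, multivariate diagnostics, receptor
modelling and human health-risk assessment, built as one tested pipeline for
the eight metals routinely surveyed in Chinese farmland monitoring
(Hg, Cr, Cu, Pb, Zn, As, Cd, Ni).

It is written for environmental scientists who have a per-sample table of
soil metal concentrations (plus coordinates and pH) and want the standard
chain of analyses that contamination surveys report:

1. **Descriptive screening** — per-metal summary statistics, coefficient-of-
   variation classes, and exceedance rates against regional background
   values and the GB 15618-2018 screening/intervention thresholds (pH-banded).
2. **Pollution indices** — the Müller geoaccumulation index
   `Igeo = log2(Ci / 1.5·Bi)` with its seven classes, and Hakanson's
   potential ecological risk: contamination factor `Cf = Ci/Cn`, per-metal
   risk `Er = Tr·Cf` (toxic-response factors 40, 2, 5, 5, 1, 10, 30, 5 for
   Hg, Cr, Cu, Pb, Zn, As, Cd, Ni) and the integrated index `RI = Σ Er`.
3. **Spatial structure** — empirical semivariograms, weighted least-squares
   spherical/exponential model fits, and ordinary kriging (unit-sum weights
   via a Lagrange multiplier; optional log-transform for skewed fields).
4. **Source diagnostics** — PCA on the correlation matrix with varimax
   rotation, KMO sampling adequacy and Bartlett's sphericity test.
5. **Source apportionment** — a from-scratch positive matrix factorization
   (PMF) receptor model: `X ≈ G·F` with non-negative contributions G and
   profiles F, minimizing the uncertainty-weighted objective
   `Q = Σ ((X − G·F)/U)²`, where `U = (5/6)·MDL` below the detection limit
   and `U = √((s·c)² + (0.5·MDL)²)` above it. Includes Q(robust)/Q(true)
   factor-number scanning, per-metal and overall source shares, and
   scaled-residual normality diagnostics.
6. **Health risk** — USEPA-style average daily doses for ingestion,
   inhalation and dermal contact, hazard quotients/index (HQ, THI) and
   carcinogenic risk (CR, TCR) for adult and child cohorts, and
   apportionment of THI/TCR to the PMF sources (Sankey-ready JSON export).

Because surveys of this kind rarely deposit their raw tables, the package
ships a calibrated synthetic-cohort generator (`soilrisk.synth`) that
emulates a 273-sample survey of farmland adjoining smelting-industry parks
in semi-arid northern China: per-metal means and dispersions matching the
published cohort moments (e.g. Cd 0.42 mg·kg⁻¹ at 166% CV), a four-source
non-negative mixing structure with overall shares near
(10, 38, 35, 17)%, correlated metal blocks (Cu–Cd, Pb–As, Cr–Zn–Ni), and
spatially clustered highs in a west mid-upper and an east mid-lower
district. Every downstream stage is validated against this generator's
ground truth.

## Worked example

```python
from soilrisk import (MetalParams, ExposureProfile, PMFModel, align_factors,
                      build_uncertainty, default_spec, generate_cohort,
                      ecological_risk, RiskModel, source_risk_apportion)

samples, truth = generate_cohort(default_spec(seed=1))
params = MetalParams.defaults()
profiles = {c: ExposureProfile.defaults(c) for c in ("adult", "child")}

idx = ecological_risk(samples, params)
print("mean RI:", round(idx.ri.mean(), 1),
      "| samples above RI=300:", round(100 * (idx.ri > 300).mean(), 1), "%")

sol = PMFModel(samples.concentrations(),
               build_uncertainty(samples, params),
               n_factors=4, restarts=10, seed=1).fit()
perm, cos = align_factors(sol.F, truth.F, sol.G, truth.G)
print("estimated source shares (%):",
      sol.overall_shares().iloc[perm].round(1).tolist(),
      "| truth:", truth.overall_shares.round(1).tolist())

risk = RiskModel(samples.concentrations(), params, profiles).fit()
print(risk.summary().to_string())
```

prints

```
mean RI: 496.2 | samples above RI=300: 43.2 %
estimated source shares (%): [10.2, 32.2, 35.2, 22.5] | truth: [9.6, 37.5, 34.2, 18.7]
            THI              THI flag       TCR    TCR flag
adult  0.190233            acceptable  0.000034  acceptable
child  1.185686  noncarcinogenic risk  0.000053  acceptable
```

The mean RI of ~500 sits in Hakanson's "considerable" band, driven almost
entirely by Cd (toxic-response factor 30 against a 0.0375 mg·kg⁻¹
background). The PMF shares recover the generator's four sources to within
a few points under the cohort's full (heavy-tailed) noise; under 10%
measurement noise they come back within ±2 points (see the test suite).
THI below 1 means no non-carcinogenic concern for adults; the child value
just above 1 reflects the cohort's higher intake-to-bodyweight ratio; both
TCR values fall inside the conventional 10⁻⁶–10⁻⁴ acceptable band.

A command-line interface mirrors the library
(`soilrisk simulate | summarize | indices | krige | pca | pmf | risk | all | report`);
`soilrisk all --seed 1 --outdir out/` runs every stage and writes tidy CSV
tables plus a JSON run manifest.

## Parameter provenance

All constants live in `soilrisk/_defaults.py` and are overridable from a
YAML config: regional background values (CNEMC 1990 Inner Mongolia series,
with Hg and Cd consistent with the study region's reported
background-exceedance factors), method detection limits of the AFS/ICP-AES
assay, GB 15618-2018 screening/intervention tables by pH band, Hakanson
toxic-response factors, Chinese exposure-handbook cohort parameters and
USEPA reference doses / slope factors. See `docs/methods.md` for the model
descriptions, calibration details and known limitations — including a
quantitative note on why the published THI/TCR totals for this study region
cannot be reproduced from the standard parameter tables.
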