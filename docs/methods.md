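# Methods

This note documents the models implemented in `soilrisk`, the choices made
where the methodology is genuinely open, and what the validation on
synthetic cohorts does and does not demonstrate.

## Pollution indices

The geoaccumulation index is `Igeo = log2(Ci / (1.5·Bi))` with background
`Bi`; the factor 1.5 absorbs lithogenic variability. Classes are half-open
intervals `(lo, hi]` over the seven Müller levels (≤0 unpolluted; >5
extremely polluted), so boundary values classify deterministically into the
lower class. Hakanson's ecological risk uses the contamination factor
`Cf = Ci/Cn`, the toxicity-weighted single-metal risk `Er = Tr·Cf`
(`Tr` = 40, 2, 5, 5, 1, 10, 30, 5 for Hg, Cr, Cu, Pb, Zn, As, Cd, Ni) and
the per-sample sum `RI = Σ Er` over all eight metals. Er classes sit at
40/80/160/320 and RI classes at 150/300/600, again half-open. A sample at
exactly background for every metal therefore has `RI = ΣTr = 98`.

All eight metals enter RI; the classic Hakanson subset is not used because
the toxic-response factors are available for the full panel.

## Background values and regulatory thresholds

Backgrounds for Cr, Cu, Pb, Zn, As, Ni follow the CNEMC (1990) Inner
Mongolia compilation (41.4, 14.4, 17.0, 59.1, 7.5, 19.5 mg·kg⁻¹). For Hg
and Cd the published compilation values are inconsistent with the study
region's reported exceedance-factor range (regional means exceed background
1.32–11.21×), so the package defaults use the values implied by those
printed ratios: Hg 0.0303 and Cd 0.0375 mg·kg⁻¹. Screening and intervention
values are the GB 15618-2018 agricultural-land tables, stored for all four
pH bands and selected row-wise by each sample's pH (the cohort mean pH of
7.7 puts most samples in the >7.5 band). Exceedance proportions use a
strict `>` comparison; the choice is documented because the convention is
often left unstated.

Values at or below the method detection limit are replaced by (5/6)·MDL —
the same constant the uncertainty model uses — so a single censoring rule
serves both the descriptive statistics and the receptor model.

## Kriging

The empirical semivariogram bins half squared differences by lag;
the spherical (default) or exponential model is fitted by weighted least
squares with bin pair-counts as weights, because the well-populated short
lags drive the kriging weights. Ordinary kriging solves the standard
constrained system with a Lagrange multiplier; with a zero nugget it
interpolates exactly. Concentrations are log-transformed by default before
kriging (CVs above 100% imply strong skew) and back-transformed with the
lognormal correction `exp(ẑ + σ²/2)`; the option can be disabled. Exactly
duplicated locations are averaged (or rejected, per config) because they
make the kriging matrix singular.

## PCA, varimax, KMO and Bartlett

PCA is an eigendecomposition of the Pearson correlation matrix; loadings
are eigenvectors scaled by √eigenvalue. Components are retained until
cumulative explained variance reaches 80% rather than by the Kaiser
eigenvalue>1 rule: in survey data of this kind a third component just below
eigenvalue 1 is routinely needed for an interpretable solution, and the
retention target is configurable. Varimax rotation maximizes the variance
of squared loadings (SVD-based update, Kaiser row normalization by
default); each loading column is sign-flipped so its largest-magnitude
entry is positive. KMO is built from the anti-image partial correlations
obtained through the inverse correlation matrix; Bartlett's sphericity
statistic is `χ² = −(n−1−(2p+5)/6)·ln det R` with `p(p−1)/2` degrees of
freedom. A singular correlation matrix falls back to a ridge-regularized
inverse with a warning.

## PMF receptor model

The concentration matrix is factorized as `X ≈ G·F`, `G ≥ 0`, `F ≥ 0`,
minimizing `Q = Σ ((X−G·F)/U)²`. Per-cell uncertainties follow the standard
error model: `U = (5/6)·MDL` for values at or below the MDL, otherwise
`U = √((s·c)² + (0.5·MDL)²)` with `s` the analytical relative SD (default
10%, matching duplicate-sample precision of 80–120% recoveries). The
second form is the quadrature (root-sum-square) reading of the error-fraction
convention; a linear product of RSD and concentration alone would ignore
the MDL floor and is dimensionally inconsistent as printed in parts of the
applied literature.

The solver alternates exact non-negative weighted least-squares block
updates: each row of G and each column of F is an independent small NNLS
problem on uncertainty-scaled design matrices. Each half-step is an exact
block minimization, so Q is monotonically non-increasing (asserted in
tests). The first start is a deterministic non-negative double-SVD
(positive parts of the leading singular vectors); the remaining restarts
draw uniform random initials from the seeded stream; the lowest-Q restart
is kept. Convergence is declared when the relative drop in Q falls below
1e-8. A factor whose contributions collapse to zero mid-iteration is
reseeded.

Diagnostics follow receptor-model practice: `Q(true)` sums all cells,
`Q(robust)` caps each cell's squared scaled residual at 4² so outlier cells
cannot dominate; the factor-count scan reports `Q(robust)/Q(true)` and
Q/dof for each candidate p and picks the ratio closest to 1, breaking
near-ties toward the smaller p. Signal-to-noise classes per species use
the EPA convention (mean of `max(0, (c−U)/U)`; ≥1 strong, 0.5–1 weak,
<0.5 bad). Scaled residuals are checked per species with Shapiro–Wilk.

The factorization's scale ambiguity is resolved by normalizing F rows to
unit sum with compensating scaling of G. Per-metal factor shares are the
column-wise percentages of reconstructed mass, and a factor's overall share
is the unweighted mean of its per-metal shares. When solutions are compared
(e.g. against a known truth), profiles are expressed as mass-weighted
per-species shares — the fraction of each metal's total mass a factor
explains — which is invariant to the normalization convention; matching is
by Hungarian assignment on cosine similarity.

## Health-risk model

Average daily doses for the three pathways:

    ADD_ing = C·IngR·EF·ED·1e-6 / (BW·AT)
    ADD_inh = C·InhR·EF·ED / (PEF·BW·AT)
    ADD_der = C·SA·AF·ABS·EF·ED·1e-6 / (BW·AT)

with `AT = ED·365` d for non-carcinogenic endpoints and a 70-year lifetime
(25 550 d) for carcinogenic ones. `HQ = ADD/RfD` over every metal–pathway
pair with a reference dose; `THI = Σ HQ`; `CR = ADD·SF` only over pairs
with a published slope factor (here As, Cd, Cr, Ni, Pb); `TCR = Σ CR`.
Flags: THI > 1 non-carcinogenic risk; TCR < 10⁻⁶ negligible, 10⁻⁶–10⁻⁴
acceptable, > 10⁻⁴ risk.

Default exposure constants are the Chinese exposure-handbook values used
throughout the farmland-survey literature (adult/child: IngR 100/200 mg/d,
InhR 14.5/7.5 m³/d, EF 350 d/a, ED 24/6 a, BW 60.6/19.2 kg, SA 5700/2800
cm², AF 0.07/0.2 mg·cm⁻²·d⁻¹, ABS 0.001, PEF 1.36×10⁹ m³/kg); RfD and SF
are the USEPA values per pathway. Everything is config-overridable. Risk is
computed on cohort mean concentrations by default because survey reports
quote one THI/TCR per cohort; a per-sample mode exists.

A reproduction caveat: for the study region this package is calibrated
against, the published THI (0.065 adult / 0.12 child) and TCR (5.67×10⁻⁵ /
6.70×10⁻⁵) totals cannot be obtained from these equations under any
standard parameter transcription. The child/adult THI ratio implied by any
handbook pairing of intake rate to body weight is ≈3–7 once ED cancels
against AT, while the published pair implies 1.85; the published TCR ratio
(1.18) is similarly outside the reachable range (≈1.5–1.6 for
ingestion-dominated risk). The package reports what the stated equations
and parameters produce (≈0.19 adult and ≈1.19 child THI at the published
mean concentrations — values typical of comparable surveys), and the
corresponding acceptance test records the discrepancy rather than adjusting
parameters to fit.

Source-to-risk apportionment multiplies each metal's HQ (or CR) total by
the PMF per-metal source shares and renormalizes by THI (TCR), so each
cohort's source shares sum to 100%; the Sankey export writes the
source→metal→risk node/link table as plain JSON.

## Synthetic cohort generator

Concentrations are generated as `X = G·F ⊙ exp(ε)`:

* `F = S ⊙ μ` where `μ` holds the target per-metal means and `S` is a
  source-by-metal share matrix with columns summing to 1. The default
  four-source design assigns Hg to an atmospheric-deposition source,
  Pb/As/Zn to traffic, Cr/Ni/Zn to a mixed natural+agricultural source and
  Cd/Cu to metal smelting, with structural zeros separating every source
  pair and overall shares ≈ (10, 38, 35, 17)%.
* `G` couples a mean-one lognormal contribution law per source (CVs 0.7,
  1.0, 1.6, 0.2) with a normalized spatial intensity field: Gaussian bumps
  over a 1000 m × 800 m survey rectangle. Traffic and smelting share the
  two district highs (west mid-upper, east mid-lower) — that shared
  geography, not profile overlap, produces the Cu–Pb–As–Cd correlation
  block. The smelting source carries its dispersion in sharp hotspots
  (55 m bumps, ~30× baseline) rather than a lognormal tail; a bounded
  high-contrast field keeps the sample CV of Cd stable near its 166%
  target at n = 273, where an equivalent-variance lognormal tail would
  make the realized CV erratic and biased low.
* `ε` is per-metal mean-one lognormal noise. Calibration solves
  `(1+cv_target²) = (1+cv_mix²)(1+cv_noise²)` for the noise CV per metal,
  with the mixing CV computed analytically from lognormal algebra and
  grid-quadrature moments of the spatial fields. Where the mixing structure
  alone exceeds the target CV (Pb and Zn under the default design) the
  noise is clamped at the 10% assay floor and the dispersion overshoot is
  accepted: the published dispersions of Pb/Zn (48%, 58%) are not jointly
  attainable with correlation blocks of r > 0.6 under a four-source
  mixing model, and the correlation structure takes precedence because the
  downstream source-apportionment stages depend on it. Cd's moments — the
  calibration's acceptance quantity — are reproduced within ±20% across
  seeds.

pH is drawn from N(7.7, 0.58) (clipped to plausible soil range) and drives
the pH-banded regulatory thresholds. A metal calibrated with target CV 0 is
emitted as an exactly constant column.

The generator emulates the survey's moments, mixing structure, correlation
blocks and spatial clustering. It does not emulate assay-specific error
structure beyond one relative SD per metal, censoring patterns at the
detection limit, co-located duplicate samples, or anisotropic spatial
continuity; tests passing on this cohort therefore demonstrate correctness
of the estimators under the stated generating model, not robustness to
every artefact of real laboratory data.

### Identifiability of the recovery testbed

The default (diffuse) layout has every source present at every location;
in the noise-free limit the exact factorization is then not unique — a
valid alternative can, for instance, shift background mass between the
atmospheric factor and the diffuse sources. Solver-correctness tests
therefore use `recovery_spec`, a four-source layout with spatially
separated districts (low shared baseline), on which the cohort contains
near-single-source samples and the truth is recoverable: the solver reaches
Q(true) ≈ 0 and cosine similarity > 0.99 per profile. On the diffuse
study-conditions cohort the same solver recovers overall source shares
within ±5 points under 10% noise — shares are far better determined than
the profiles themselves, which is the usual situation in receptor
modelling.

## Numerical choices

* Class schemes are half-open `(lo, hi]`; all boundary behaviour is tested.
* NNLS subproblems are 4–5 dimensional; the alternating solver runs a few
  hundred iterations on a 273×8 matrix in seconds.
* Problem sizes in the test suite (cohorts of 40–273 samples, restart
  counts of 2–10) are chosen so the full suite documents the estimators'
  behaviour at survey scale while remaining quick to run.
* Kriging solves the full (n+1) linear system per metal; for survey-scale
  n this is cheap and avoids neighborhood-selection artefacts.
* The pipeline manifest records seed, config hash, stage timings and every
  output file, and is written even when a stage fails.

## Known limitations

* Variogram parameters of the emulated survey are unknown; kriged surfaces
  are qualitative reproductions (two-district structure), not quantitative.
* PMF rotational ambiguity is handled by design of the test cohorts, not
  by Fpeak-style exploration; bootstrap/displacement error estimates are
  out of scope.
* The health-risk module is deterministic; no Monte-Carlo uncertainty
  propagation.
* The published THI/TCR totals for the calibration study are internally
  inconsistent with its stated equations (see above); the package
  reproduces the method, not those four numbers.
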