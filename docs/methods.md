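# Methods

This note records the models, conventions and design choices behind
`soiltrace`, in the spirit of a statistics package's methods appendix.

## Data model and validation

The central container is a site-by-element concentration matrix in mg/kg
dry soil. Concentrations must be finite and strictly positive: every
index in the package (ratios, logs, geometric means) is undefined at
zero, and the calibration survey reports no censored values, so
non-positive or missing cells are rejected with a site/element-qualified
error rather than imputed. Element symbols are case-normalized and
columns ordered canonically (Al, Cd, Co, Cr, Cu, Fe, Mn, Ni, Pb, Zn
first).

Backgrounds default to upper continental crust rather than local
pre-industrial values — the choice made by the calibration survey — and
ship, together with WSA/ESA/MAC/CSQG guideline values and the Hakanson
toxicity response coefficients, as a versioned JSON that users can
override wholesale. The guideline tables are deliberately editable
constants: published compilations differ in detail, and one parse
(`CSQG` in particular) is ambiguous in the source typography.

## Descriptive statistics

`summarize` reports mean, median, sd, se, CV% and skewness with the
conventions that reproduce the published survey summary row exactly: sd
and CV use the n−1 denominator, se = sd/√n, and skewness is the adjusted
Fisher–Pearson coefficient. Normality screening is Shapiro–Wilk (scipy's
vetted routine; the contract tested is the nominal type-I error, not the
polynomial coefficients). Rank correlation uses mid-rank ties with the
t-approximation for p-values.

Factorability diagnostics are implemented in-package (small closed
formulas): the overall KMO statistic from partial correlations via the
scaled inverse correlation matrix, and Bartlett's sphericity chi-square
−(n−1−(2m+5)/6)·ln det R on m(m−1)/2 df. Both are cross-checked in the
test suite against independent brute-force implementations (partial
correlations from residual regressions; the literal determinant form).

## Pollution and ecological risk indices

All five pollution indices and the three ecological risk indices are
computed per sample and then aggregated; headline "mean index" values
are means of per-sample values. For the linear Cf (and hence Er and RI)
the mean over samples equals the index of the mean concentration — the
identity that lets published mean concentrations stand in for the
undeposited raw table. The nonlinear Igeo, EF, PLI, NPI and NRI have no
such shortcut, and their published means are treated as qualitative
anchors only.

Classification boundaries follow the printed schemes where those close a
boundary (Igeo ≤ 0 unpolluted, NPI ≤ 0.7 unpolluted, 2 ≤ EF < 5, 40 ≤ Er
< 80, NRI ≤ 40); boundaries the schemes leave open (Cf = 1, 3, 6) are
resolved left-closed upward ([1, 3) → moderate), a deterministic and
documented convention. Classification is total over finite values. RI
and NRI run over exactly the six Tr-bearing elements (Zn, Cu, Cd, Ni,
Cr, Pb); the enrichment-factor reference element is Al, overridable.

One reporting convention matters for reproducing the published chain:
the survey prints the mean Cf of Cd at two decimals (1.96) and derives
Er(Cd) = 30 × 1.96 = 58.8 from it. Worked examples and the acceptance
computation therefore report the mean Cf at its printed precision before
scaling by Tr for Cd, while elements without a printed Cf use full
precision — which reproduces every published mean Er value.

## Health risk

The hazard-quotient and carcinogenic-risk equations are the USEPA
residential soil forms, with units as in the RSL tables: the 10^6
divisor converts mg/kg soil to intake fractions, inhalation divides the
soil concentration by the particulate emission factor (PEF, 1.36×10^9
m³/kg) to get an air concentration against RfC, and inhalation unit
risks (per µg/m³) are converted with the factor 1000. Averaging time is
ED×365 days for non-carcinogens and 70 y × 365 for carcinogens;
carcinogenic ingestion and dermal risk use the age-adjusted factors
IFS = Σ_age EFr·ED·IRS/BW and DFS = Σ_age EFr·ED·SA·AF/BW (child 6 y +
adult 20 y), and inhalation uses the lifetime ED of 26 y. The
exposure-frequency symbol is written EFr throughout to avoid collision
with the enrichment factor.

Exposure defaults are the standard RSL residential values (IRS 200/100
mg/d child/adult, EFr 350 d/y, ED 6/20 y, BW 15/80 kg, SA 2373/6032 cm²,
AF 0.2/0.07 mg/cm²); toxicity values are RSL-convention RfDo/RfC with
GIABS and a uniform dermal absorption fraction of 0.001 for inorganics.
Chromium is assessed as Cr(VI) (CSFo 0.5, IUR 0.084) — a conservative
speciation assumption flagged in the packaged table. With these defaults
the lifetime inhalation risks of Cd, Co and Ni reproduce the published
survey values to three figures, and Cr's risks match in order of
magnitude; exact per-route equality is not promised because the survey's
exposure supplement is not public. Elements lacking a route's toxicity
value are skipped with a warning, never scored as zero risk.

## APCS-MLR

The receptor model uses the standard mechanics: PCA on the correlation
matrix, Kaiser eigenvalue->1 retention, varimax rotation with Kaiser row
normalization (SVD-based updates, tolerance 1e-8, max 1000 sweeps;
cross-checked against a classical pairwise-rotation oracle), and
regression-method factor scores, which for principal components have
exactly unit variance. Loading signs are fixed so each component's
largest-|loading| element loads positively; components are ordered by
rotated explained variance. Prerequisite checks (KMO ≥ 0.5, Bartlett
p < 0.05, n ≥ m + 50) warn rather than fail.

Absolute scores subtract the score of an artificial sample with zero
concentration everywhere (standardized value −mean/sd per element),
anchoring the score scale at true zero mass. Each element is regressed
on the APCS by OLS with intercept; because OLS with an intercept passes
through the mean, predicted mean ≡ measured mean and the M/P = 1
diagnostic is an exact identity on any input — the test suite asserts it
to 1e−9. Source h's raw mean contribution to element j is
r_hj·mean(APCS_h); percentages use absolute-value normalization over the
retained components only (the intercept/unidentified mass is excluded),
so each element's row sums to 100 even with negative raw contributions,
matching the convention in which published contribution rows sum to 100.

## Synthetic data

`generate_mixing` is the recovery testbed: k sources with non-negative
signatures in which each element has one dominant source
(primary fraction 0.7 — the block structure under which distinct sources
are identifiable at all), gamma(2) right-skewed strengths, and
multiplicative lognormal noise (default CV 10%). It returns the realized
true contribution percentages so recovery can be scored exactly. The
recovery experiment (20 seeds, n = 129, 10 elements, 3 sources, 10%
noise, model fit at the true source count) recovers the dominant source
of every element and keeps the mean absolute contribution error below 10
percentage points; under Kaiser retention instead of the true count, an
occasional seed leaves the third eigenvalue just under 1, which is a
property of the retention rule, not of the contribution estimates.

`emulate_study` is the survey stand-in: per-element marginals calibrated
to the published means and CVs, coupled by a Gaussian copula with three
correlation blocks (Ni–Cr at ρ 0.93; Al–Mn–Pb; Cu–Fe–Zn–Cd–Co)
mirroring the survey's anthropogenic / lithogenic / mixed source
groupings. Most elements use lognormal marginals (the published CVs of
42–104% and skewness ≥ 1 indicate right skew); Al and Fe use normal
marginals because their published skewness (0.27, 0.24) is far below the
lognormal-implied value and the survey found exactly these two elements
normally distributed. Per-element scores are exactly standardized, the
lognormal shape parameter is solved against the realized sample so the
sample CV is exact, and each column is rescaled to the exact published
mean — so the calibration (means exact, CVs exact, Spearman r(Ni,Cr) >
0.9) holds for every seed, not on average.

What the emulation does **not** carry: the survey's spatial structure
(no coordinates are emulated), its exact per-sample index distributions
(class-percentage tables match only qualitatively), its full Spearman
matrix (only the block structure), and its multivariate tail behaviour.
Tests passing on the emulation therefore demonstrate that the pipeline
reproduces the survey's qualitative findings under a faithful marginal
and correlation structure — not that it would reproduce every printed
percentage on the real table.

## Numerical and reporting choices

Report CSVs round to 4 significant digits for byte-stable snapshots; a
full-precision JSON sidecar is kept for auditing. One integer seed
threads all randomness (generators use `numpy.random.default_rng`; no
global state). Degenerate inputs are handled explicitly: constant
columns give sd = CV = skewness = 0 with a warning and are excluded from
correlation/PCA; a near-identity correlation matrix makes KMO undefined
(raised, not NaN); collinear APCS regressors raise rather than silently
pseudo-inverting; classification rejects non-finite values.

## Known limitations

- Health-risk point estimates depend on exposure parameters that vary
  between agencies; no probabilistic (Monte Carlo) layer is provided.
- The Cr(VI) speciation assumption can overstate carcinogenic risk by
  orders of magnitude if soil chromium is mostly Cr(III).
- APCS-MLR assumes linear mixing and as many informative components as
  sources; sources with collinear signatures are not separable, and
  contribution percentages inherit the absolute-value convention's
  insensitivity to sign.
- Guideline tables are snapshots of published compilations and should be
  reviewed before regulatory use.
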