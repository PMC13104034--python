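# Methods

This note documents the models implemented in `liverpfas`, the defaults
they ship with, and what the synthetic data generator does and does not
emulate.

## Quantification and QA/QC

Quantification is isotope dilution against a matrix-matched calibration
fitted by ordinary least squares in ratio space (area ratio native/EIS vs
amount ratio native/EIS). At least five calibration levels are required; a
non-positive slope is refused and a non-monotone response is flagged for
audit but not refused. The back-calculated amount ratio is floored at zero
(a positive intercept can otherwise produce negative ratios near zero
signal). An optional 1/x-weighted calibration is deliberately not the
default: isotope-dilution ratio space largely removes the
heteroscedasticity that motivates weighting in external-standard
calibration.

Method detection limits are computed per analyte per batch from that
batch's procedural blanks: mean + 3 × sample SD of the blank *detects*,
where a blank counts as a detect only when its back-calculated
concentration is at or above the instrumental detection limit (IDL, the
concentration at signal-to-noise 10). Below the IDL there is no analyte
signal, only numerical residue of the calibration fit; treating any
positive float as a detect collapses the MDL to machine epsilon. With no
detects the IDL is used; with exactly one detect the SD is undefined and
the IDL is used with a warning. The blank mean used for correction is the
mean of the same detect set (zero when there are none).

Blank correction is gated at the MDL: it applies only when the raw value
exceeds the MDL, and a value that falls to or below the MDL after
subtraction is censored. Censoring is an explicit record-level flag carrying
the MDL — never a numeric 0 or bare NaN — so MDL/2 substitution downstream
is unambiguous.

QC acceptance: retention-time difference ≤ 0.1 min when the internal
standard is the labeled analogue of the analyte, or ≤ 0.4 min after
subtracting the mean analyte–EIS shift observed in the batch CCVs when it
is a structurally different surrogate (a missing CCV shift fails safe);
ion-abundance ratio (confirmation/quantification channel ratio normalized
to the CCV mean, offset by one) within the closed interval [−1, 1];
EIS recovery within configurable limits, default 20–150% inclusive — the
default is ours, chosen from common targeted-method practice, since
method-specific limits belong to laboratory SOPs. A record failing any
check is excluded (reported censored). A sample is wholly excluded when
the fraction of its analytes that failed QC *or gave no quantifiable
signal at all* exceeds 0.75. "No signal" means an empty channel or lost
internal standard, not an ordinary below-MDL result: counting routine
censoring against the threshold would discard a large share of low-burden
samples, which is not how batch review works — whole-sample rejection is
reserved for analytically broken samples.

## Cohort assembly and censored aggregation

Collection dates resolve to a numeric year: exact years as themselves,
ranges to their midpoint (2000–2005 → 2002.5), missing stays missing and
drops the donor from year-dependent analyses. Nondetects substitute MDL/2,
the expected value if below-MDL concentrations are uniform on (0, MDL);
no Kaplan–Meier or regression-on-order-statistics estimators are provided,
a deliberate scope match to MDL/2-based practice (noted as an extension).
Per-donor PFAS sums come in two modes: `detected_only` (uncensored values
only; the plotting/trend convention) and `substituted` (MDL/2-filled; the
regression input). Class composition per calendar year is the arithmetic
mean of class-summed concentrations across that year's donors, normalized
to 100% — the mean is unweighted within the year since every donor is one
specimen. Period summaries use linear-interpolation quantiles; the fold
range max/min is undefined (NaN, with a warning) when the minimum is 0.

## Weighted temporal trend

log10(concentration) on calendar year, weighted by the inverse of the
number of observations in that year *after* exclusions, so weights are
self-consistent with the data actually fitted. The fit is WLS (statsmodels)
with the year axis centered at the weighted mean year for conditioning;
coefficients are reported on the raw calendar scale. Slope inference is a
two-sided t test with n−2 degrees of freedom on the weighted residual
variance. Degenerate inputs are handled explicitly: a constant response
reports slope 0, p = 1, R² = 0; an exact line reports p = 0, R² = 1 rather
than trusting float-noise residuals. The fit requires ≥3 observations over
≥2 distinct years (the mathematical minimum leaving one residual degree of
freedom); the per-analyte screen additionally requires ≥3 distinct years
before an analyte is modeled, and labels fits decline/increase/no-change at
α = 0.05.

## Covariate model

OLS of log10 concentration on sampling year, age, sex (male = 0,
female = 1) and liver health (normal = 0, NAFLD = 1), entered
simultaneously, complete cases only (no covariate imputation). Analyte
eligibility requires ≥30 detected donors; the PFAS sum (substituted mode)
is always modeled. Percent changes are (10^β − 1) × 100 with year and age
scaled per decade; the transform is exactly invertible and both directions
are exposed. VIFs use the standard auxiliary-regression definition with an
intercept; perfect collinearity reports inf, and a rank-deficient design
raises an error naming the most collinear predictor pair. Residual
normality reports three p-values — Shapiro–Wilk (n ≥ 3),
D'Agostino–Pearson (n ≥ 20), and the Kolmogorov–Smirnov test in its
Lilliefors form, which calibrates for the mean and SD being estimated from
the residuals — as diagnostics only; no automatic action is taken. On
MDL/2-substituted responses these tests often reject, because substitution
piles probability mass at one value; that is a property of the substitution
convention, not a bug. α = 0.05 throughout with no multiple-testing
correction across analytes, a deliberate match to single-model reporting
practice and a known limitation.

## EOF mass balance

EOF readings are blank-corrected by subtracting the batch DI-water blank
mean when the reading exceeds it (floored at 0 and flagged otherwise); the
EOF MDL is 3 × SD of matrix extraction blanks × dilution factor.
Targeted concentrations convert to ng F/g via each analyte's fluorine mass
fraction, computed from the neutral-acid formula with IUPAC atomic masses
to three decimals (anion masses available by flag; the difference is
~0.2%). Censored analytes contribute 0 by default — a lower bound on the
explained fraction — with MDL/2 as an option. A targeted total exceeding
the EOF yields a fraction above 100% with a data-quality warning, not an
error. Donor matching between EOF and targeted tables is by explicit
sample id or a user-supplied match table; no fuzzy matching.

## Synthetic data generator

The generator's defaults are the study conditions the rest of the package
is exercised under:

- **Cohort** (n = 211): ages truncated-normal 57.51 ± 13.53 on [18, 85];
  sex Bernoulli(0.5); 85% of women drawn at age ≥ 46 (postmenopausal) via a
  two-component mixture whose location is shifted so the cohort mean age
  stays at the configured value; NAFLD prevalence 0.54 with probability a
  logistic function of collection year, calibrated analytically (nested
  root-finding on the year distribution) so the population year↔health R²
  is 0.43; collection years 2000–2024 with unequal per-year counts (heavy
  early-2000s and 2020s arms) so inverse weighting is meaningfully
  exercised. About 14% of donors carry a year *range* instead of an exact
  year, ~1.4% no date, and ~1% missing health or age, so the exact-year and
  complete-metadata analysis subsets are realistically smaller than n.
- **Truth model**: per analyte, log10 C = baseline + β_year·(year−2000)/10 +
  β_age·(age−50)/10 + β_sex·[female] + β_health·[NAFLD] + N(0, σ), σ
  defaulting to 0.4–0.6 log10 units. Effect sizes are anchored to reported
  covariate-model decade percent changes for the compounds they describe
  (e.g. strong decade declines for legacy sulfonates and 8:2 FTS, a small
  increase for the chlorinated-ether replacement, positive age slopes for
  bioaccumulative chains, lower burdens in NAFLD livers). Baselines and
  IDLs are inverted jointly from reported detected-value medians and
  detection frequencies: for a lognormal truth, the detected median is the
  1 − DF/2 quantile and the detection threshold the 1 − DF quantile.
  Because the effect sizes follow the covariate-adjusted decade changes,
  the *unadjusted* sum trend of a default cohort declines more gently
  (~60–70% over the window) than a raw two-endpoint contrast of heavily
  exposed early cohorts would suggest; the two parameterizations cannot
  coincide in one log-linear model.
- **Instrument layer**: EIS channel = response × spike × recovery × noise;
  quantification channel preserves the isotope-dilution ratio exactly under
  the shared recovery factor; confirmation channel is a fixed fraction
  (0.5) of the quantification channel. Multiplicative lognormal area noise
  (CV 5%), recovery 0.85 ± 0.08, RT jitter 0.01 min, blank contamination
  0.002 ± 0.0015 ng per procedural sample, 8 blanks / 3 CCVs / 2 positive
  controls per batch, 0.5 g specimens spiked with 4 ng EIS. `zero_noise()`
  turns every stochastic element off for round-trip identities.
- **EOF**: eight earliest-year donors; true EOF is the donor's targeted
  fluorine-equivalent total × a gap factor (13 ± lognormal CV 0.35), plus
  DI-water background; two DI and two matrix blanks.

What it does **not** emulate: chromatograms or spectra (only integrated
areas), matrix effects varying across donors, branched-isomer resolution,
batch-to-batch drift, geographic or dietary exposure structure, and
heavy-tailed exposure outliers beyond the lognormal (real cohorts show
within-year spreads up to ~3 orders of magnitude; the default σ ≈ 0.5
yields roughly 1.5). Passing tests therefore demonstrate correctness of
the estimators and rules under the stated generating model, not robustness
to every pathology of real tissue data.

## Numerical choices and problem sizes

Random draws all flow from `numpy.random.default_rng` seeded per run;
identical seed and parameters give byte-identical outputs, and derived
seeds stay below 2^31. Statistical backends are statsmodels (WLS/OLS, VIF,
Lilliefors) and scipy (truncated normal, Shapiro–Wilk, D'Agostino); tests
verify the fits against independent hand-rolled normal-equation oracles at
1e−8. Simulation-based checks use 200 replicates for parameter-recovery
coverage (slope and all four covariate coefficients within 3 SE in ≥95% of
cohorts at n = 178/205) and 1000 null fits for type-I calibration
(5% ± 2% per predictor) — sizes chosen so binomial noise on the checked
proportions is a few tenths of a percent while the whole suite runs in
about a minute.

## Known limitations

MDL/2 substitution biases low-detection analytes (no censored-likelihood
estimators); no multiple-testing correction across analyte models; no
mixed effects for tissue-bank clustering; the sample-exclusion threshold
and recovery limits are configurable conventions, not universal constants;
EOF support assumes fluoride-equivalent readings are already integrated
per sample.
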