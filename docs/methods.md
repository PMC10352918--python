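# Methods

This note documents the models, numerical conventions and design choices
behind `salspec`, and what the synthetic data generator does and does not
emulate.

## Problem setting

The quantity of interest is root-zone soil salinity in a drip-irrigated
cotton field, measured as the electrical conductivity of a 1:5 soil–water
extract (EC₁:₅, dS m⁻¹) and summarised as cumulative layer averages:
S1 = EC(0–20 cm), S2 = mean of the 0–20 and 20–40 cm layers, S3 = mean of
all three layers to 60 cm. Under canopy cover the soil is not directly
visible, so salinity is inferred from (i) canopy reflectance, 350–2500 nm at
1 nm spacing, and (ii) aboveground growth parameters — plant height H (cm),
aboveground biomass AGB (g plant⁻¹) and shoot water content SWC (fraction) —
which respond negatively to root-zone salinity.

## Preprocessing

Bands 350–399 and 2401–2500 nm (instrument noise) and 1361–1489 and
1811–1959 nm (atmospheric water vapour) are removed; on the full grid this
retains 1723 bands in three contiguous segments. Smoothing and
differentiation are Savitzky–Golay (window 13 points = 13 nm, polynomial
order 2; order configurable) applied **per contiguous segment** so that no
filter window spans a trimmed gap; a segment shorter than the window raises
an error rather than silently shrinking the window. Segment edges use the
one-sided polynomial fit (scipy's `interp` mode), which keeps polynomials up
to the filter order exact everywhere — the property the test suite asserts.
The derivative defaults to the Savitzky–Golay derivative with the same
window and order, so R and FDR share noise behaviour; a central-difference
alternative is available. Raw reflectance must be non-negative and below
1.5; values in (1, 1.5] are tolerated with a warning (calibration-panel
artefacts).

## PLS1 core

All regression runs on a hand-written NIPALS PLS1 (single response). For one
response the weight vector per component is X'y up to normalisation, so each
component is a single pass, and one fitted model yields predictions for
every component count 1..A incrementally. This makes the cross-validated
RMSE (RMSE_CV) scan over latent-variable (LV) counts cost one fit per fold.
X columns are mean-centred; covariate columns are autoscaled (spectral bands
share units, covariates do not); y is centred. Fold assignment is a seeded
permutation split into contiguous blocks, reproducible given the seed. The
LV count minimises RMSE_CV with ties broken toward the smaller count.
scikit-learn's `PLSRegression` is used in the tests as an independent
cross-check of predictions (to 1e-8), never as the implementation.

## Wavelength selection

All three selectors score candidate band subsets by RMSE_CV of a PLS1 model
with a scanned LV count.

**VIP.** For an A-component fit, VIPⱼ = √(K·Σₐ SSYₐ(wⱼₐ/‖wₐ‖)²/Σₐ SSYₐ),
with SSYₐ the response variance captured by component a. The identity
Σⱼ VIPⱼ² = K holds exactly and is asserted; bands above the threshold 1 are
selected. The LV count defaults to the RMSE_CV optimum.

**CARS.** N = 50 Monte-Carlo runs (configurable), each fitting PLS on a
random 80% sample draw of the current band set. The enforced retention
ratio at run i is rᵢ = a·e^(−k·i) with a = (p/2)^(1/(N−1)),
k = ln(p/2)/(N−1), so run 1 keeps all p bands and run N keeps exactly 2.
After the top-rᵢ·p cap by |regression coefficient|, adaptive reweighted
sampling draws p times with replacement proportional to the weights; the
unique draws survive. Drawing p times (not rᵢ·p times) matters: a smaller
draw count would halve the subset every run and exhaust the schedule early.
The weight-model LV follows the RMSE_CV-chosen LV of the current subset —
a fixed deep LV concentrates coefficients on noise bands and collapses the
subset prematurely. The subset with minimal RMSE_CV wins; ties break to the
smaller subset, then the earlier run.

**Random frog.** A subset-size random walk: a normal proposal q* ≈
N(q, θq) with θ = 0.3; shrinking keeps the bands with the largest
|coefficient|, growing samples an ω = 3-fold candidate pool and keeps the
best candidates by a trial fit; a worse subset is accepted with probability
η·(RMSE_CV,old/RMSE_CV,new), η = 0.1. Selection probabilities are inclusion
frequencies over the post-burn-in chain, pooled across restarts. Two
safeguards keep the stochastic search honest: (i) the chain's evaluations
are capped at the LV depth the full spectrum supports plus one, because an
unconstrained deep-LV scan lets the walk mine cross-validation structure
that does not generalise; (ii) each restart's returned candidate is the set
of bands the chain included more than half the time — returning the raw
best-of-chain subset would reward whichever of the thousands of CV
evaluations got lucky. The protocol-scale defaults are 100 restarts × 1000
iterations (100 burn-in); grid-scale runs default to 10 × 250, a problem
size chosen so a full experiment grid completes in well under a minute per
selector without changing the algorithm.

## Calibration protocol

The calibration/validation split is stratified by growth stage: 20 of the
28 records per stage go to calibration (100/40 on the default layout),
reproducible under the master seed. Wavelength selection runs inside the
calibration partition only (a whole-dataset mode exists for comparison);
covariates are autoscaled with calibration statistics; validation rows never
contribute to any statistic, which the suite asserts by permuting validation
responses and checking that calibration metrics and selected bands are
byte-identical. For a selector cell the spectra-only model reuses the LV the
selector's own RMSE_CV bookkeeping chose, and covariate-augmented cells
re-scan on the same fold stream the selector optimised against; re-deriving
the LV on fresh folds makes flat CV curves flip to deeper, worse-validating
choices. Negative salinity predictions are reported as-is and counted, never
clipped. A single master seed fans out to stage-specific seeds via
`SeedSequence([master, crc32(label)])`, so any stage can be rerun in
isolation.

## Synthetic data generator

The generator provides data with the structure the analysis assumes; its
defaults are the study conditions of the package.

* **Salinity.** Per-layer EC means by treatment × stage are inverted from
  the bundled field-trial table of cumulative layer averages (four
  amelioration treatments ordered T2 < T1 < T3 < T4 in overall root-zone
  salinity; stage trajectories dipping to a minimum at 124 days after sowing
  and rising once irrigation stops). Replicate scatter is N(0, 0.35 dS m⁻¹)
  per layer, resampled (up to 5 times, then floored at 0.05 dS m⁻¹ with a
  warning) to keep EC positive.
* **Growth.** H follows a logistic curve in DAS (asymptote 90 cm, midpoint
  90 DAS, scale 18 DAS) that plateaus after 142 DAS, minus a salinity slope
  of 6 cm per dS m⁻¹; AGB rises logistically (max 130 g, midpoint 108 DAS)
  and declines past a peak that comes earlier (124 vs 142 DAS) for the
  saltier treatments, with a relative suppression of 12% per dS m⁻¹; SWC
  declines linearly from 0.82. All three salinity couplings attenuate
  linearly by 60% from the first to the last stage, reproducing the
  weakening salinity–growth correlations over the season; noise levels
  (3 cm, 10% CV, 0.015) set within-stage correlation magnitudes near −0.8
  early and −0.4 late.
* **Spectra.** A parametric vegetation baseline (green peak at 550 nm, red
  edge at ~715 nm, NIR plateau 0.46 scaled by biomass, water troughs at
  1450/1940 nm deepened by shoot water) on the full 1-nm grid. Salinity acts
  through a *canopy-effective* value — the record's S2 plus N(0, 0.35 dS m⁻¹)
  perception noise, reflecting root-zone heterogeneity the canopy integrates
  over; this latent is stored per record (`ec_canopy`) so tests can compute
  the generative accuracy ceiling. The broad response is relative to the
  local reflectance level: +10% per dS m⁻¹ across 400–780 nm, −5% per
  dS m⁻¹ across 1100–2400 nm. Four narrow Gaussian features (745, 1000,
  1180, 2200 nm; width 12 nm; ±6–10% per dS m⁻¹) carry stage-modulated
  signal, spreading the information over several latent directions. Noise
  has three components: fine additive instrument noise (sd 0.01, 10 nm
  correlation), and two multiplicative nuisance terms (10% at 120 nm, 10% at
  600 nm) imitating canopy-structure variation and illumination/scatter
  drift — strong on the bright NIR plateau, weak in the dark visible.
  Reflectance is clipped to [0, 1.2].

The nuisance terms are what make the benchmark meaningful: they mask the
broad salinity response (so full-spectrum models do not saturate), are
largely removed by differentiation (so FDR outperforms smoothed R), and are
avoided by concentrating on the narrow diagnostic bands (so selection pays).
Effect sizes are synthetic choices, not field estimates; they were fixed
once so that the qualitative orderings the method is built around emerge at
the default settings, and they are not tuned per test. What passing tests
show is that the pipeline recovers structure of this kind at realistic
signal-to-noise — not that any particular field accuracy is guaranteed;
real canopies add nonlinearity, directional effects and soil-background
mixing that the generator does not model.

Determinism: all draws derive from the master seed through labelled
`SeedSequence` children; two runs with the same seed produce byte-identical
CSV output.

## Evaluation metrics

R² = 1 − SSE/SST (undefined for constant measurements), RMSE in dS m⁻¹, and
Lin's concordance correlation coefficient with the standard bias term
(μ_y − μ_ŷ)² and population (1/n) variances (the sample-variance convention
is available). LCCC is symmetric, bounded by |ρ|, and invariant to a shared
positive affine rescaling of both arguments. Reported percentages round
half-up to two decimals. The percent-decrease helper returns the min/max
over treatments of the stage-to-stage salinity drop; on the bundled table
between 76 and 124 DAS it gives (3.77, 16.01)% for S1, (5.00, 13.89)% for
S2 and (5.69, 11.90)% for S3.

## Problem sizes and known limitations

The multi-seed studies (accuracy orderings, recovery against the generative
ceiling, informative-band recall) use 10 seeds, 140 samples, and the
grid-scale selector settings above; these sizes were chosen as the smallest
at which the directional claims are stable. The CARS-over-full-spectrum
margin is real but thin (≈0.01 in mean validation R² at default settings) —
single-seed comparisons can go either way, which mirrors how selector
rankings behave on real recalibrations. The recovery criterion compares
against a deliberately conservative ceiling (an oracle regression on the
exact latent canopy salinity plus covariates), so the measured gap (~0.09)
understates the pipeline's efficiency relative to any realisable method.
Random frog remains the weakest selector on the synthetic benchmark; its
accuracy depends strongly on chain settings, and the scaled-down defaults
favour runtime over exhaustive search.
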