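# Methods

This note documents the models, parameter choices and numerical decisions
behind `s2trait`, and what the synthetic-season validation does and does
not demonstrate.

## Forward simulation of the training database

The training domain is a 12-parameter uniform box sampled by Latin
hypercube (one sample per equal-width stratum per marginal, random
position within the stratum; `scipy.stats.qmc` provides the design). The
ranges are the canonical wheat parameterization: Cab 5–75 μg cm⁻²,
Nstruct 1–2, Cxc 0–15 μg cm⁻², EWT 0.0002–0.05 cm, CBC 0.001–0.01 g cm⁻²,
Canth 0–2, Cp 0.001–0.0025, Cm 0.0001–0.03, LAI 0.1–7 m² m⁻², ALIA
30–70°, soil brightness 0–1, SZA 20–40°; hot spot (0.01), observer zenith
(0°), diffuse/direct ratio (80%), relative azimuth (0°) and brown pigment
(0) are fixed.

Two forward backends exist behind one interface:

* **`surrogate`** (default): an analytic two-stream caricature of a
  coupled leaf–canopy model. Gap fraction P₀ = exp(−cos(ALIA)·LAI);
  leaf reflectance ρ_leaf,b = ρ∞,b·exp(−(α_b·Cab + β_b·EWT + γ_b·dm))
  with dm = (Cm+CBC)·10⁴; canopy reflectance
  R_b = (1−P₀)·ρ_leaf,b + P₀·soil·ρ_soil,b. The per-band coefficient
  tables live in `s2trait/_surrogate.py` (version-tagged, chosen by this
  package) and obey the qualitative physics asserted by the test suite:
  chlorophyll absorbs in the blue/red and not in the SWIR, water absorbs
  in the SWIR, the NIR plateau is brightest, soil brightens towards the
  SWIR. Nstruct, Cxc, Canth, Cp and the fixed geometry parameters are
  accepted but ignored by the surrogate. The surrogate is not a
  radiative-transfer model: it has no hot spot, no multiple scattering,
  no bidirectional effects, and delta-function bands (no SRF
  convolution).
* **`prosail_pro`**: an adapter delegating to an installed coupled
  leaf–canopy RTM implementation, sampled at the ten band centers. It
  raises a clear ImportError when the library is absent; all shipped
  tests use the surrogate.

**FVC rule.** The design needs fractional cover to build VWC labels but
has no FVC axis, so cover is derived from canopy structure by
Beer–Lambert gap fraction, FVC = 1 − exp(−cos(ALIA)·LAI). This is the
simplest rule consistent with the extinction geometry already used by the
surrogate and is monotone in LAI, which the tests assert.

**Augmentation.** Bare-soil records (LAI = 0, random soil brightness,
all labels zero) and senescent records (Cab ∈ [1, 5] μg cm⁻², EWT ∈
[0.0002, 0.002] cm, LAI ∈ [1, 5]) extend the database outside the green
period. The senescent recipe keeps canopy structure while removing
pigment and water; brown pigment stays at its fixed zero, so yellowing is
represented by absence of absorbers rather than an extra constituent.

## Gaussian process regressor

Bands and labels are standardized with training statistics (zero prior
mean on the standardized label). The isotropic RBF kernel is the default;
per-band (ARD) length scales sit behind the `ard` flag. Hyperparameters
(σ_f², ℓ, σ_n²) are optimized in log space with analytic gradients of the
log marginal likelihood, L-BFGS-B, one default start plus 5 seeded random
restarts, each parameter bounded to [10⁻⁶, 10⁶]. A jitter ladder
(0, 10⁻¹⁰, 10⁻⁸, 10⁻⁶, 10⁻⁴) escalates on Cholesky failure; exhausting it
raises a diagnostic error. Predictive variance uses the stored Cholesky
factor only (no explicit inverse at predict time); the reported SD
includes σ_n², i.e. observation-level uncertainty, because the maps and
scatter plots display the spread expected of a new measurement. Negative
variances from round-off are clamped at zero. Model archives are single
JSON containers (hyperparameters, standardizer, training arrays); a
reload reproduces predictions bit-exactly, which the suite asserts.

## Active learning

Diversity selection uses the max–min rule: the candidate whose *minimum*
squared Euclidean distance (in pool-standardized band space) to the
current training set is largest, ties to the lowest index. Acceptance
requires a strict (< , ε = 0) decrease of validation RMSE; rejected
candidates leave the pool permanently, otherwise the same farthest point
would be re-proposed forever. R² is logged but never drives acceptance.

Refitting hyperparameters for every trial would dominate runtime, so
trial fits reuse the current hyperparameters (a Cholesky-only refit,
O(n³) with n a few hundred), and a warm-started single-restart
re-optimization runs every 10 accepted additions, kept only if it further
lowers validation RMSE. This preserves the strictly decreasing RMSE
trajectory while keeping a full 1000-iteration loop in the seconds range.
The validation set doubles as the acceptance criterion and the reported
score, mirroring common practice with small campaigns; the resulting
optimism is documented here, and a genuinely held-out split is used in
the synthetic recovery experiment.

## In-situ formulas and units

SPAD → Cab uses the exponential calibration 12.23·e^(0.0279·SPAD)
[μg cm⁻²]. CCC = Cab·LAI/100 [g m⁻²]; EWT = (FW−DW)/Al [g cm⁻²];
CWC = EWT·LAI·10⁴ [g m⁻²]; VWC_h = (FW−DW)/A [g m⁻²] with default
sampling area A = 0.02 m²; VWC = VWC_h·FVC. The 10⁴ factors convert
per-cm² leaf mass to per-m² ground area. Campaign CSVs carry FVC as
percent; it is stored as a fraction internally. Derivation happens per
plot record first and is aggregated by date afterwards, so date-level
means of derived traits are means of per-plot products, not products of
means. Scene/field matching pairs each field date with the nearest
acquisition within ±6 days (ties to the earlier scene).

## Mapping

NRMSE is normalized by the observed range. Point extraction is
nearest-pixel (plots are sized to one 10 m pixel); bilinear smoothing
would mix neighbouring parcels. Negative trait predictions are clipped at
zero and the clip count is logged and stored in the map metadata. Rasters
are written as plain multiband TIFF with a JSON sidecar holding the
affine transform, CRS, band list and nodata value.

## Synthetic season

The generator emulates an irrigated winter-wheat campaign: 3 paddocks ×
3 plots on a 60 × 60 grid of 10 m pixels, 8 scene dates from late August
to late December, sowing 25 June. LAI follows a double logistic
(amplitude 5.0 m² m⁻², green-up midpoint day 95 at 0.065 d⁻¹, senescence
midpoint day 170 at 0.15 d⁻¹ after sowing), peaking ≈ 4.7 m² m⁻² in
mid-November. Cab holds a 42 μg cm⁻² plateau through greenness and loses
60% of it through senescence; EWT tracks canopy development between
0.006 and 0.028 cm with +0.002 cm irrigation steps (17 September,
17 November) and a 50% senescence decline. Within-paddock variability is
a smooth field interpolating per-plot lognormal factors (CV 0.10);
reflectance carries 2% multiplicative Gaussian noise by default and
campaign "measurements" carry 5% relative instrument noise, with fresh/
dry weights back-computed so the in-situ formulas reproduce the noisy
traits exactly.

The default recovery experiment is an inverse-crime configuration: truth
scenes use the same surrogate as the training database, so it validates
the *pipeline* (sampling, GP, active learning, mapping, bookkeeping), not
the radiative realism of the forward model. A mismatched-backend run
(truth via the reference RTM adapter) is possible wherever that library
is installed. Recovery pass levels on held-out plots are R² ≥ 0.90 (LAI),
0.80 (CCC), 0.70 (VWC) at 2% noise; the defaults achieve ≈ 0.97–0.99.
Problem sizes (1000-sample pool, 60 × 60 grid, 8 dates, up to 1000 AL
iterations) keep a full three-trait recovery under ten seconds on one
CPU.

## Known limitations

* The surrogate's coefficient tables are qualitative fixtures, not
  calibrated absorption spectra; absolute reflectance levels are
  plausible but not validated against measured spectra.
* Senescent optics (brown pigments, structural collapse) are represented
  only by absorber removal.
* The AL validation-set reuse inflates reported validation scores; the
  held-out metrics in the recovery experiment are the honest ones.
* Single-output GPs per trait; no cross-trait covariance.
* No atmospheric correction, resampling or cloud masking: inputs are
  assumed preprocessed bottom-of-atmosphere stacks with the fixed 10-band
  layout.
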