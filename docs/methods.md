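# Methods

This note records the models implemented by `radeff`, their assumptions,
the defaults and why, and the design choices made where the design was
genuinely open.

## Weather and thermal time

Daily weather is described by incident PAR (MJ m⁻² d⁻¹) and min/max air
temperature.  Thermal time accumulates as max(0, (T_min + T_max)/2 − T_b)
per day with base temperature T_b = 2 °C, a common value for potato;
it is configurable everywhere it enters (`t_base`).  Integration is daily;
sub-daily radiation geometry and diffuse/direct partitioning are out of
scope.

The bundled climate profile is the 2017 winter growing season of coastal
Lima, Peru (planting 5 July): monthly means ± standard errors of PAR,
temperatures, solar radiation, humidity and VPD.  The synthetic weather
generator draws each day from a normal distribution around its month's mean
with daily SD reconstructed as SE·√(days in month) — the profile publishes
only the SE of the monthly mean, and this inversion assumes independent
days.  Draws are truncated at physical bounds (PAR ≥ 0, T_min ≤ T_max).
Under this profile the cumulative incident PAR from day 1 after planting is
565.4 MJ m⁻² to a 121-day harvest and 701.4 MJ m⁻² to 141 days.

## Canopy cover and NDVI

Plot rasters carry (green, red, NIR) reflectance in [0, 1].  Canopy cover
is the fraction of pixels whose SAVI = (NIR − Red)(1 + L)/(NIR + Red + L)
strictly exceeds a threshold; pixels exactly at the threshold count as
soil (documented tie rule).  Defaults L = 0.5 (the standard soil factor)
and threshold 0.3, with an Otsu bimodal option; both are configuration
parameters because segmentation thresholds are sensor- and site-specific.
Plot NDVI is the per-pixel mean.  When only plot-mean reflectance tables
are available, cover is obtained by inverting the linear two-endmember
mixture on the NIR band.

## Canopy dynamics and interception

Cover as a function of thermal time t follows the determinate beta growth
function up to its peak (t_e, cc_max), with maximum growth rate at t_m:

    cc(t) = cc_max (1 + (t_e − t)/(t_e − t_m)) (t/t_e)^(t_e/(t_e−t_m)),  t ≤ t_e.

The beta form never declines, yet interception must be integrated to
harvest, after canopy senescence has begun; the post-peak phase is
therefore a fitted linear segment cc_max + s·(t − t_e), s ≤ 0, clipped to
[0, 1].  Fitting is joint bounded least squares over all four parameters
and all flights (3 seeded starts, parameter tolerance 1e−14).  An earlier
two-phase variant (rising-phase-only fit, then a slope through the fitted
peak) proved fragile: observation noise can shift the empirical maximum,
leaving t_e unconstrained from the right and stranding the fit at cc_max = 1.
The joint fit constrains the peak from both sides and recovers noiseless
parameters to machine precision.

The interception fraction f is equated with canopy cover — a standard
approximation for potato canopies — so PAR_int = Σ f(t)·PAR_inc(t) daily,
and ε_i = 100·PAR_int/PAR_inc.  By construction PAR_int ≤ PAR_inc.

## Tuber growth and calibration

Total biomass grows linearly in intercepted radiation (dTB = RUE·f·PAR_inc,
g m⁻² d⁻¹) and tuber mass is TB times a Gompertz partition fraction
a_max·exp(−exp(−b(tt − t_u))).  t_u, the thermal time of maximum partition
rate, is the tuberization-precocity statistic; a_max ≤ 1 guarantees tuber
mass never exceeds total biomass, and the harvest index at harvest equals
the partition fraction there.  No maintenance respiration, frost or
photoperiod terms are modelled: only TB, HI and t_u are consumed
downstream.  Internal state is per m²; per-plant masses use the plant area
(default 0.78 m², the averaged maximum area per plant of the reference
trial).

Calibration minimizes the mean relative error |sim − obs|/obs over all
observations: a series of dry tuber masses and, when recorded, the total
dry biomass of the destructive final harvest.  Each of 5 seeded starts is
pre-solved with smooth bounded least squares on the signed relative
residuals and then refined with bounded Nelder–Mead on the mean-relative-
error criterion itself (the criterion by which a calibrated accession is
accepted, threshold 5 %).  Bounds: RUE ∈ [0.2, 6] g MJ⁻¹, a_max ∈ [0.3, 1],
b ∈ [0.002, 0.05] per °C d, t_u ∈ [150, 1500] °C d.

An identifiability constraint shaped this design: from tuber mass alone,
RUE and a_max enter the trajectory only through their product (biomass is
linear in RUE and partition is multiplicative), so the likelihood has an
exact ridge and neither RUE nor HI is separately estimable.  The final
destructive harvest therefore also records total dry biomass (tubers plus
dried haulm, standard practice at final harvest), which anchors RUE in
closed form through RUE = TB/PAR_int and leaves a well-posed fit.  Without
a biomass record the calibration still runs and the tuber-mass fit quality
is unaffected, but reported RUE and HI are then product-identified only.

## Efficiencies and the cross-crop comparison

ε_c = 100·RUE/57.14 with 57.14 g MJ⁻¹ ≡ 17.5 MJ kg⁻¹ biomass energy
content; ε_p = 100·HI.  Relative efficiencies divide an observed percentage
by the theoretical maximum for the crop's type: ε_i max 90 % (all crops),
ε_c max 9.4 % (C3) / 12.3 % (C4), ε_p max 65 % for grain and seed crops and
90 % for tuber, root and stem-harvested crops.  Reported relative
efficiencies round half-up to two decimals.  The bundled literature table
of maximum published efficiencies for nine major crops enables the ranking;
the seed energy content (23 MJ kg⁻¹) is carried as metadata only — it
affects how literature values were derived, not any computation here.

## Trait statistics

- **NDVI senescence slope**: OLS slope of plot NDVI versus days after
  planting from the flight of maximum NDVI to the last flight (≥ 3 usable
  flights).  Days after planting, not thermal time, is the regressor; under
  the mild reference climate the two are nearly proportional.  Internal
  units are NDVI per day.
- **Augmented design analysis**: block effects are estimated from the
  replicated checks; the adjusted value of a test entry in block j is its
  raw value minus (check mean in block j − grand check mean); check means
  are their replicate means.  The error mean square comes from the
  checks-in-blocks two-way residual with (b−1)(c−1) df.  The treatment sum
  of squares is partitioned into checks, augmented entries and the
  checks-vs-augmented group contrast — with unreplicated test entries a
  literal check×entry interaction is inestimable, so the group contrast is
  the partition tested.  Tukey letter groups on adjusted means use the
  studentized range with Federer's variance formulas for each pair class
  (check–check, check–new, new–new same/different block).
- **PCA**: eigendecomposition of the correlation matrix of z-standardized
  traits (the 7 ordination traits: ε_i, ε_c, ε_p, A, Δleaf, NDVIslp, t_u);
  eigenvalues sum to 7, cumulative variance is Σλ/7·100, and each
  component's sign is fixed so its largest-|loading| trait loads positively.
  Accessions with missing physiological traits are excluded with a logged
  warning, never silently.
- **Clustering**: Ward linkage (scipy) on the retained component scores
  (default 3 PCs), cut at k = 3 groups.
- **Yield regression**: OLS of adjusted tuber yield on the retained PC
  scores; with centred orthogonal regressors the intercept is the mean
  yield and each slope is cov(TY, PC)/var(PC).

## The synthetic trial generator

The generator emulates the reference trial design: 20 test accessions plus
4 improved-variety checks in 4 blocks of 5 + 4 plots, harvests at 121 or
141 days after planting, 13 weekly flights (days 28–112), 0.78 m² per
plant.  True parameters are drawn uniformly inside the observed ranges —
RUE 1.0–3.6 g MJ⁻¹, t_u 356.3–556.3 °C d, partition asymptote 0.6–0.9,
NDVI slope −0.006 to −0.002 per day, photosynthesis 17–26.6 µmol m⁻² s⁻¹,
Δleaf 21–23 ‰ — with canopy timing (peak cover at 850–1250 °C d ≈ days
60–85) chosen to put expansion and senescence inside the flight window.
Senescence delay and RUE are linked by a Gaussian copula (ρ = 0.7),
reflecting the observed trait structure in which accessions that stay
green longer also convert radiation better; this is what makes the
yield–senescence-delay correlation reproducible in simulation.  The drawn
NDVI slope is converted to a cover decline rate through the mean daily
thermal-time increment and the NDVI contrast of the endmember spectra.

Reflectance is a two-endmember mixture — vegetation (0.10, 0.08, 0.50) and
soil (0.18, 0.20, 0.25) for (green, red, NIR), giving NDVI ≈ 0.72 against
≈ 0.11, cleanly separable by SAVI — weighted by the true cover, with
truncated Gaussian noise (SD 0.01 in reflectance units) on plot means, and
optional toy rasters in which round(cc·n) randomly placed pixels carry the
vegetation spectrum (so segmentation recovers cover to one pixel quantum).
Harvest observations are forward-simulated tuber masses at days 25, 45, 70
and harvest — the early points bracket the partition inflection, which
falls near days 25–40 — with 10 % multiplicative noise truncated to stay
positive, plus the final-harvest total biomass.  Photosynthesis and Δleaf
are noisy per-plot constants without within-season dynamics, since the
analysis uses season averages.

What the generator does **not** emulate: spatial field trends beyond
additive block effects, genotype×environment interaction, measurement
drift between flights, radiometric/geometric imaging artefacts, pest or
water stress, and any biomass–canopy feedback.  Passing recovery tests
therefore demonstrates the correctness of the estimation chain under the
stated noise model, not robustness to real-world imaging or agronomic
artefacts.

## Numerical choices and degenerate inputs

Optimizers are deterministic under seeds; multi-start counts (3 canopy, 5
growth) are fixed.  NDVI is undefined when NIR + Red = 0 (error).  RUE is
undefined at zero PAR_int (error).  All-zero tuber observations are
rejected.  A check missing from any block or zero error df aborts the
augmented analysis.  Zero-variance columns in correlation are flagged;
exact ties in Tukey letters resolve by ascending mean order.  Problem
sizes in the test battery (a 10-accession 2-block trial for end-to-end
recovery, the full 24-accession trial for the statistics stage) were chosen
as the smallest designs that exercise every stage meaningfully.

## Known limitations

- The reduced growth model omits SOLANUM-class physiology (respiration,
  temperature/photoperiod response, fresh-to-dry conversion); RUE absorbs
  whatever those processes would explain.
- Equating interception fraction with canopy cover ignores canopy
  architecture and diffuse-light effects.
- The augmented analysis is the classical fixed-effects one; no REML/mixed
  alternative is provided.
- t_u is well identified only when observations bracket the partition
  inflection; late-season-only sampling leaves it ridge-identified with b.
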