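# radeff

Radiation interception, conversion and partitioning efficiencies for potato
field trials, estimated from multispectral canopy time series, daily weather
and harvest observations.

## The problem

Potential yield can be decomposed into three efficiencies: how much of the
incident photosynthetically active radiation (PAR) the canopy intercepts
(ε<sub>i</sub>), how efficiently intercepted radiation is converted into dry
biomass (ε<sub>c</sub>), and what share of that biomass ends up in the
harvested organ (ε<sub>p</sub>).  For a potato trial the chain is

- ε<sub>i</sub> (%) = 100 · PAR<sub>int</sub> / PAR<sub>inc</sub>, with
  PAR<sub>int</sub> = Σ<sub>days</sub> f(t) · PAR<sub>inc</sub>(t), where the
  interception fraction *f* is equated with canopy cover;
- RUE (g MJ⁻¹) = TB / PAR<sub>int</sub> and
  ε<sub>c</sub> (%) = 100 · RUE / 57.14, where 57.14 g MJ⁻¹ is the biomass
  equivalent of an energy content of 17.5 MJ kg⁻¹;
- ε<sub>p</sub> (%) = 100 · HI, the harvest index.

Canopy cover is extracted from multispectral plot imagery by thresholding
the soil-adjusted vegetation index (SAVI) and its dynamics are fitted on the
thermal-time scale with the determinate beta growth function
cc(t) = cc_max · (1 + (t_e − t)/(t_e − t_m)) · (t/t_e)^(t_e/(t_e−t_m)) plus a
linear post-peak senescence segment.  Total biomass accumulates daily as
RUE · f(t) · PAR<sub>inc</sub>(t) and is partitioned to tubers by a Gompertz
curve a_max · exp(−exp(−b(tt − t_u))); the inflection abscissa t_u is the
tuberization-precocity statistic, and the slope of post-peak NDVI decline
(NDVI<sub>slp</sub>) is the senescence-delay statistic.  Trait tables from the
augmented block design (unreplicated test accessions, replicated checks) are
analysed with Federer-adjusted means, Tukey groups, Pearson correlations,
correlation-matrix PCA, Ward clustering and regression of tuber yield on
principal components.

The package is aimed at crop physiologists and phenotyping groups who want
the full chain — imagery to efficiency table to multivariate
characterization — as tested, scriptable code.  A synthetic trial generator
with known ground truth (weather from monthly climate normals, mixture
reflectance, forward-simulated harvests) makes every stage verifiable by
parameter recovery.

## Worked example

```python
import radeff as r

trial = r.generate_trial(r.TrialConfig(seed=1))       # synthetic 24-accession trial
results = r.analyze_trial(trial, r.PipelineConfig(seed=1))
print(results.summary())
```

```
Radiation-efficiency trial analysis
============================================================
plots analysed      36
accessions          24

Adjusted trait means (first rows):
               ty  epsilon_i  epsilon_c  epsilon_p      a  delta_leaf  ndvi_slp      tu
accession
CHK1      377.435     45.478      3.666     64.346 24.521      22.239    -0.004 528.463
CHK2      153.999     24.580      2.681     77.255 22.223      22.184    -0.005 380.906
CHK3      282.024     50.891      2.461     84.277 22.181      22.702    -0.005 524.637
CHK4      856.072     53.460      6.007     77.165 20.747      21.413    -0.005 411.199
ACC017    640.561     39.693      5.227     85.045 21.548      21.708    -0.003 457.741

PCA cumulative variance (first 3 PCs): 34.9%, 52.7%, 67.9%
Ward clusters (k=3): G1: n=5, G2: n=7, G3: n=12
TY ~ PCs regression: const=446.3  PC1=86.4  PC2=11.6  PC3=50.4
  R^2 = 0.393, F = 4.3, p = 0.017
```

Reading the output: `ty` is the block-adjusted dry tuber yield (g plant⁻¹),
the three efficiencies are percentages, `tu` is in °C d (lower = earlier
tuberization) and `ndvi_slp` in NDVI units per day (closer to zero = longer
senescence delay).  The regression intercept equals the mean adjusted yield
because PC scores are centred and orthogonal.

Per-plot model fits are available as Model/Results pairs, e.g.

```python
fit = r.TuberGrowthModel(trial.weather, beta_params, observations).fit()
print(fit.summary())        # RUE, Gompertz parameters, mean relative error
```

A thin CLI mirrors the library: `radeff simulate`, `radeff run`,
`radeff extract-canopy`, `radeff stats`, `radeff crops`, `radeff all-in-one`.

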