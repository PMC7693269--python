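# marshwave

Salt-marsh green-wave phenology and the annual-cycle timing of a
long-distance migratory shorebird.

## The problem

Eastern willets (*Tringa semipalmata semipalmata*) breed in *Spartina
alterniflora* salt marsh along a steep latitudinal climate gradient on the
North American Atlantic coast, winter together on the coast of northern
South America, and share stopover regions.  If breeding-habitat phenology
sets the timetable, birds breeding further north should run their entire
annual cycle — wintering-site departure, breeding-site arrival, nesting,
southbound departure — correspondingly later, and nesting should fall at
the *same* stage of local marsh green-up everywhere: a phenological
"green wave".

`marshwave` implements the full analysis chain for testing that
hypothesis, together with synthetic-data generators that emulate every
input stream with known ground truth, so the whole pipeline is testable
end to end without any external download.

## What is in the box

| module | contents |
|---|---|
| `marshwave.synthetic` | generators: latitude-graded sinusoidal climate; logistic seasonal *Spartina* biomass studies; scripted geolocator tracks (light + wet/dry conductivity); observation-frequency arrival ramps |
| `marshwave.degree_days` | single-sine growing degree days (base 10 °C), multi-year climatologies, the **GDD jerk** (third derivative of cumulative GDD) and its spring peak as an onset-of-spring statistic, matched-pairs onset-shift test |
| `marshwave.geolocator` | twilight detection and the 35-min outlier rule, threshold geolocation (solar noon → longitude, day length → latitude), ±40 d equinox masking, flight classification from extended dry periods, incubation detection from daytime shading, per-individual annual-cycle event tables |
| `marshwave.greenwave` | standardization of biomass to *stage* (fraction of within-study seasonal maximum) and the inverse-variance weighted GEE `stage = β₀ + β_d·doy + β_l·lat + β_dl·doy·lat` with AR(1) working correlation and Mancl–DeRouen cluster-robust errors; stage prediction and closed-form stage-date inversion |
| `marshwave.timing` | random-intercept (REML) mixed-model site marginal means, timing-vs-latitude regressions, slope-homogeneity tests, tail-alignment and cumulative-2 % arrival estimators, maximally selected cutpoint statistics with permutation p |
| `marshwave.pipeline` / `marshwave.cli` | the coupled end-to-end study (`run_all`) and a thin `marshwave` command-line wrapper |

The core statistical objects:

* **GDD jerk.** With cumulative degree days `G(d)` above 10 °C (single
  sine method), the jerk is `G'''(d)` estimated by a centred moving
  average followed by the 5-point third central difference; its maximum in
  Jan–Jun is the spring onset date.
* **Green-wave GEE.** Stage is modelled on the 0–1 fraction scale with an
  identity link; observations are weighted by `1/SE²`, repeated measures
  within a study follow an AR(1) working correlation whose ρ is
  re-estimated from lag-1 standardized residuals between GLS steps.
  Inverting the fitted plane gives `stage_date(target, lat)`, the date a
  target stage (e.g. 29.5 %) is reached at a latitude.
* **Maxstat cutpoint.** Over all latitude cutpoints leaving ≥ 10 % of
  sites on each side, the standardized two-group statistic
  `T = (S − E)/√V` is maximized; `T_max` gets a seeded permutation p.

## Worked example

```python
from marshwave import pipeline as pl

res = pl.run_all(pl.RunConfig(seed=7), output_dir="results/run7")
print(res["fig3"].round(2))
print("mean stage at nesting:", round(res["target_stage_recomputed"], 3))
print("later at northern sites by",
      round(res["timing_offsets"]["mean_offset_days"], 1), "days")
```

prints (seed 7):

```
          site  latitude  nest_marginal_mean  onset_doy  stage_date_doy
0           NJ     39.20               93.18       93.0           92.91
1     MA_south     41.38              105.26      104.0          104.36
2  MA_north_ME     43.03              111.58      112.0          113.04
mean stage at nesting: 0.351
later at northern sites by 16.5 days
```

Reading this: for each simulated deployment site, the marginal-mean nest
initiation date recovered from raw geolocator light/conductivity series
(`nest_marginal_mean`) sits within about a day of both phenological
indicators — the spring temperature-acceleration peak (`onset_doy`) and
the date the fitted green-wave model reaches the mean nesting stage
(`stage_date_doy`).  Nesting happens at the same biomass stage (~0.35 of
seasonal maximum on the fitted model scale) at every latitude, while the
absolute calendar timetable shifts ~16 days later from New Jersey to
Maine: the green wave, recovered end to end from synthetic raw data.

The same chain is scriptable per stage:

```bash
marshwave simulate --kind track --seed 3 --out scratch/tag
marshwave events --light scratch/tag/bird_00_light.csv \
    --cond scratch/tag/bird_00_conductivity.csv \
    --site-lat 39.2 --site-lon -75.24 --out scratch/events.csv
marshwave run-all --seed 7 --out scratch/full_run
```

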