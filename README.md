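# rangeshift

Analysis of *resource-manipulation experiments* on home-ranging herbivores:
GPS-collared animals (e.g. winter roe deer) that feed at discrete
supplemental feeding sites, one of which — the *manipulated* site M, the
animal's most familiar feeder — is closed for a two-week middle phase and
then re-opened, while *alternate* sites A stay open. The package turns
hourly GPS fixes, feeding-site coordinates and the per-animal phase
schedule into:

- **feeding-site preference** h<sub>FS</sub>: the proportion of an
  animal-year's pre-closure fixes within a buffer (radius *l*, the
  population mean hourly displacement) of any feeding site;
- **resource-state time series**: each fix classified M / A / V
  (vegetation matrix) with precedence M > A and a closed-disc boundary;
- **utilization distributions**: fixed-bandwidth (σ = *l*/2) Gaussian
  kernel densities on a 10 m grid per animal-year × phase, with 95%
  (home-range) and 50% (core-area) isopleth areas and the
  volume-of-intersection overlap VI = Σ min(p₁, p₂) between phases;
- **movement metrics**: hourly step lengths s<sub>t</sub> and turning
  angles θ<sub>t</sub>, modelled as log s<sub>t</sub> and
  φ<sub>t</sub> = logit(|θ<sub>t</sub>|/π);
- **mixed-model inference**: maximum-likelihood linear mixed models for
  log areas, logit VI and movement metrics, and binomial (logit) mixed
  models for the three presence/absence series, all with an animal-year
  random intercept, fixed effects built progressively
  (Phase, h<sub>FS</sub>, Phase:h<sub>FS</sub>, Sex, Phase:Sex, plus lag
  covariates at 1, 2 and 24 h where serial dependence demands it),
  likelihood-ratio p-values, marginality-respecting backward elimination,
  and marginal/conditional R² by variance partitioning.

Because field data of this kind are rarely redistributable, the package
ships a first-class **synthetic experiment generator**: a three-mode
(attend / forage / relocate) biased-correlated-random-walk mover over a
feeding-site landscape, with per-animal latent preference p<sub>i</sub>,
availability-gated site choice, and a closure that actually removes the
manipulated site's availability. Its defaults are calibrated to the
regime of the field system it emulates (25 animal-years, three 14-day
phases, hourly fixes, ~4 alternates at ~700 m, mean preference ~0.34,
~60 m mean hourly displacement), so every stage of the pipeline is
testable end to end with no download.

## Worked example

```python
from rangeshift import SimConfig, simulate_experiment, run_analysis

bundle = simulate_experiment(SimConfig(n_animal_years=25, rng_seed=1))
res = run_analysis(bundle.trajectories, bundle.sites, bundle.schedules,
                   lrt_pvalues=False)
print(f"l = {res.l:.1f} m; mean h_FS = {res.preferences['h_fs'].mean():.3f}")
print(res.phase_summary().round(2).to_string())
print(res.overlaps.groupby('contrast', observed=True)['vi'].mean().round(3).to_string())
fit = res.fits["home_range"]
print(f"closure coef = {fit.params['phase[T.closure]']:.3f}, "
      f"closure:h_FS = {fit.params['phase[T.closure]:h_fs']:.3f}, "
      f"cR2 = {fit.r2_conditional:.2f}")
```

prints

```
l = 64.8 m; mean h_FS = 0.353
        home_range_ha        core_area_ha       step_m        resource_use            
                 mean    std         mean   std   mean    std          u_M   u_A   u_V
phase                                                                                 
pre             23.48   5.14         4.06  1.79  62.03  57.36         0.31  0.04  0.65
closure         34.31  12.83         6.24  1.57  69.86  59.04         0.01  0.13  0.86
post            23.61   6.21         3.98  1.81  62.44  57.51         0.31  0.04  0.65
contrast
pre/closure     0.533
closure/post    0.537
pre/post        0.777
closure coef = -0.090, closure:h_FS = 1.343, cR2 = 0.61
```

Reading this: closing the familiar feeder inflates home ranges
(23.5 → 34.3 ha) and step lengths (62 → 70 m/h), collapses use of M
(31% → 1%) with partial compensation at alternates (4% → 13%), and shifts
space use (overlap across the closure, 0.533, is lower than between the
temporally separated pre and post phases, 0.777); everything reverts once
the site re-opens. The home-range model shows the response is carried by
feeder-attached animals: the closure main effect at h_FS = 0 is ~0 while
the Phase:h<sub>FS</sub> interaction is strongly positive.

## Command line

```sh
rangeshift simulate --n-animal-years 25 --seed 1 --out data/
rangeshift prepare  --fixes data/fixes.csv --schedule data/schedule.csv --out prep/
rangeshift classify --fixes data/fixes.csv --sites data/sites.csv \
                    --schedule data/schedule.csv --out states/
rangeshift spaceuse --fixes data/fixes.csv --sites data/sites.csv \
                    --schedule data/schedule.csv --out spaceuse/
rangeshift fit      --fixes data/fixes.csv --sites data/sites.csv \
                    --schedule data/schedule.csv --out models/
```

Input formats are plain CSV: `fixes.csv`
(`animal_year_id,animal_id,sex,timestamp,x,y`, ISO-8601 UTC, projected
meters), `sites.csv` (`site_id,x,y,managed`) and `schedule.csv`
(phase boundary instants plus optional capture location and manipulated
site id).

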