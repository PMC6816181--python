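# stormbird

Behavioral-state analysis of GPS-tracked coastal seabirds during tropical
cyclones.

Large coastal seabirds such as brown pelicans appear to ride out hurricanes
by sheltering in place rather than fleeing. Testing that idea from satellite
telemetry requires a chain of standard-but-fiddly steps: cleaning duty-cycled
GPS fixes, discretizing trajectories into behavioral states, restricting the
sample to birds actually exposed to the storm, carving a study window out of
the weather record, and regressing behavior on meteorology. `stormbird`
implements that chain as a tested, reusable pipeline for movement ecologists,
together with a ground-truthed synthetic-data generator so every stage can be
validated without access to any deposited tracking data.

## The analysis

1. **Ingestion & QC** (`stormbird.io`): tracking CSVs and hourly NOAA-style
   station exports are validated, normalized to canonical units (kPa, km/h,
   UTC), filtered with an iterative ≥65 km/h speed filter, and split into
   bursts at gaps > 6 h (the transmitters record 10 fixes/day at 90-min
   intervals on an 8 h on / 36 h off duty cycle).
2. **Kinematics** (`stormbird.kinematics`): great-circle step lengths,
   speeds, bearings and turning angles (absolute bearing change wrapped to
   [0, π]), plus net displacement.
3. **Core range** (`stormbird.core_range`): a pooled monthly utilization
   distribution by Gaussian product-kernel density with a two-stage plug-in
   bandwidth (grid 400 × 400, 0.4° padding); the 25 % highest-density region
   is the core range, and individuals outside it at cyclone passage — or with
   incomplete coverage — are excluded.
4. **EMbC** (`stormbird.embc`): Expectation–Maximization binary Clustering of
   (velocity, turning angle) into the four quadrant states LL/LH/HL/HH
   (inactive, localized search, commuting, dispersive search), with
   likelihood-weighted single-point smoothing and pooling to
   active (LH∪HL∪HH) vs inactive (LL).
5. **Storm window** (`stormbird.stormwin`): anomalous hours are pressure
   readings ≥ 1 monthly SD from the monthly mean; the study window runs from
   the end of the last pre-cyclone anomaly run to the start of the first
   post-cyclone run; fixes are matched to the nearest hourly weather record.
6. **State model** (`stormbird.state_model`): the four-model multinomial
   logit set {null, wind, pressure, global} of P(active) with inactive as the
   reference level, fitted by Newton–Raphson with z-standardized covariates,
   ranked by AIC (ΔAIC < 2 = co-best), with odds ratios exp(β) and
   Kruskal–Wallis / Wilcoxon rank-sum comparisons between events.

The fit-shaped pieces are scikit-learn style estimators (`EMbC`,
`MultinomialLogit`, `CoreRangeKDE`) that compose with sklearn tooling;
module-level functions wrap them for script use. A hidden-Markov-model
decoder would be the modern comparator to EMbC; it is deliberately out of
scope here.

## Worked example

```python
import pandas as pd
from stormbird.synthetic import MetSimConfig, MoveSimConfig, simulate_weather, simulate_tracks
from stormbird.pipeline import RunConfig, run_event

station, wx_truth = simulate_weather(MetSimConfig(seed=42))
fixes, truth = simulate_tracks(MoveSimConfig(seed=43), station)
fixes_by_id = {i: g.reset_index(drop=True) for i, g in fixes.groupby("individual_id")}
cfg = RunConfig(event_name="Irma-like", landfall=str(wx_truth["storm_centre_t"]))
rep = run_event(cfg, fixes_by_id=fixes_by_id, station=station)
```

which prints (via the report tables):

```
retained: 32 of 40
  cyclone  bp_monthly_mean_kpa  bp_monthly_sd_kpa  bp_minimum_kpa  wv_monthly_mean_kmh  wv_monthly_sd_kmh  wv_maximum_kmh         study_period  locations_n
Irma-like               101.29               0.33           99.49                 11.3                9.1            61.1 04 Sep - 24 Sep 2017         1760
   model  k   logLik     AIC   dAIC  co_best
  global  3 -1062.84 2131.67   0.00     True
pressure  2 -1064.12 2132.24   0.57     True
    wind  2 -1064.74 2133.49   1.82     True
    null  1 -1177.26 2356.53 224.86    False
activity budget: 61.9 +/- 4.4 % active, 38.1 +/- 4.4 % inactive
```

Reading the output: 8 of the 40 simulated birds were planted > 300 km from
the colony and are correctly excluded from the core range, leaving 32. The
meteorology row shows the cyclone month (mean pressure 101.29 ± 0.33 kPa,
storm minimum 99.49 kPa, peak wind 61 km/h) and the anomaly-bracketed study
window (4–24 Sep). All three weather models beat the null decisively
(ΔAIC ≈ 225), confirming that behavioral state tracks the storm covariates
the generator planted; pressure and wind are strongly collinear during a
cyclone, so the three weather models are co-best and their single-covariate
odds ratios should be read jointly. The activity budget (≈ 62 % active)
recovers the planted inverse-logit(0.6) ≈ 65 % baseline activity.

A CLI covers the same flow from a shell:

```bash
stormbird simulate --scenario irma_like --seed 42 --out sim/
stormbird ingest --tracks sim/tracks.csv --weather sim/station.csv
stormbird window --weather sim/station.csv --event Irma-like
stormbird run --config cfg.yaml
```

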