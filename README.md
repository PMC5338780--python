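# foragespec

Quantifying **individual foraging specialisation** in central-place-foraging
seabirds from four complementary data streams: GPS tracks, time-depth
records, stable isotopes (δ¹³C / δ¹⁵N in blood and feathers) and regurgitate
diets. The motivating system is a resident benthic diver (a blue-eyed-shag
type cormorant) breeding at a colony and making repeated foraging trips, so
the same individual can be observed many times and its repeatability
measured directly.

The package is organised as an analysis project: the library under
`src/foragespec/` implements every computational step, the numbered scripts
under `analysis/` run the study end to end on a synthetic colony with known
ground truth, and `scripts/acceptance.py` recomputes the headline numbers.

## What it computes

- **Trip processing** — an 18 m s⁻¹ speed filter, automatic segmentation of
  deployments into colony-to-colony trips, linear interpolation to 1 Hz, and
  per-trip metrics: duration, total and maximum distance (great-circle,
  R = 6371 km), and heading as the initial bearing from the colony to the
  most distal point, reported in (−180°, 180°].
- **Dive processing** — rolling-quantile zero-offset correction of 1-Hz depth
  records, dives as maximal excursions deeper than 1 m (start/end at the
  interpolated threshold crossings), max depth, duration, summed vertical
  distance, and georeferencing onto the interpolated track.
- **Space-use consistency index** — trips are rasterized onto a
  colony-anchored km grid; for an individual with trips T₁…Tₙ the index is

      I = mean over pairs |Tᵢ ∩ Tⱼ|  /  mean over trips |Tᵢ|,

  the average number of grid cells shared by a pair of trips divided by the
  average number of cells used per trip (1 = always the same cells,
  0 = never the same cell).
- **Specialisation statistic** — REML variance components of the nested
  random-effects model y = μ + a_ind + b_trip(ind) + e; the percentage of
  total variance at the individual level is the specialisation estimate.
  The same profiled-likelihood core fits random-intercept covariate models
  and the likelihood-ratio cluster comparisons.
- **Foraging strategies** — Ward clustering (Euclidean distance, merge
  heights as within-cluster sum-of-squares increase) of standardized
  per-individual profiles, cluster count chosen at the largest relative
  merge-height jump.
- **Isotopes & diet** — C:N < 3.5 lipid QC for blood, consistency
  regressions between stages and tissues, and the standard four-column diet
  composition table (items, % items, samples containing, % samples; half-up
  rounding at one decimal). The published 13-species × 26-sample
  regurgitate composition marginals ship as a package fixture.
- **Synthetic colony** — a seeded simulator with per-individual von Mises
  headings, lognormal trip distances, exactly-nested dive-depth noise,
  correlated isotope tissues and Dirichlet–multinomial diets, so every
  estimator can be checked against known truth.

## Worked example

```sh
python analysis/01_simulate_colony.py --seed 1
python analysis/02_process_tracks.py
python analysis/03_detect_dives.py
python analysis/04_build_profiles.py
python analysis/05_variance_components.py
python analysis/06_cluster_strategies.py
python analysis/07_isotopes_diet.py
```

which prints, among other things:

```
simulated 12 individuals, 82 trips, 22381 GPS fixes, 1640 scheduled dives -> results/data
82 trips from 12 deployments
  duration_h              4.4 +- 1.4 h
  max_distance_km        12.0 +- 3.8 km
  total_distance_km      24.3 +- 7.9 km
1640 dives detected (100% georeferenced); simulator scheduled 1640
12 profiles; consistency index 0.35 +- 0.14 on the 1-km grid
index rank correlation between 0.5-km and 5-km grids: rho = 0.85
total_distance_km: individual share 66.7%
heading_deg: individual share 68.7%
max_depth_m: individual share 36.1% (simulator truth 58.2%)
12 profiles grouped into k = 3 strategies
published diet: Notothenia cyanobrancha dominates with 92 items (41.4% of items, 80.8% of samples)
```

Reading: every simulated dive is detected and placed; trip metrics sit at
the intended colony scale (~12 km maximum range, ~4.4 h trips); the
individual variance share for distance and heading is high (strong
specialisation); the depth share of 36% equals the share realised in this
particular 12-bird draw (the nominal 58% is a population parameter — see
`docs/methods.md`); and the dominant prey carries 41.4% of items and occurs
in 80.8% of samples, exactly as in the published composition table.

The same chain is available as one configuration-driven command:

```sh
foragespec run --config config.yaml --seed 1
```

where the YAML either points at GPS/TDR/isotope/diet CSVs or contains a
`simulate:` block; outputs (trips.csv, dives.csv, profiles.csv,
variance_components.csv, clusters.csv, diet_composition.csv,
tracks.geojson, report.json) are byte-identical across reruns with the same
seed and config.

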