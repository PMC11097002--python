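# weedclim

Parasitic weeds of the genera *Striga* (witchweeds), *Orobanche* and
*Phelipanche* (broomrapes) devastate cereal and legume crops across
Africa, Asia and the Mediterranean. Their seeds germinate only after a
temperature- and moisture-dependent preconditioning phase, so where and
when warm and wet soil coincide shapes where these species can
establish. `weedclim` is a Python library and command-line pipeline for
analysing species occurrence records against gridded monthly
land-surface temperature (LST), root-zone soil-moisture percentile
(RZSM) and elevation data, built around a **heat-moisture coupling**
statistic and a set of temporal trend analyses, for ecologists and
agronomists studying the range dynamics of these weeds.

## What it computes

* **Heat-moisture coupling.** A coupling event at a location-month is
  LST ≥ 25 °C *and* RZSM percentile ≥ 70 in the same month. An
  occurrence is *coupled* when an event happened at lag k ∈ {0, 1, 2}
  months before the observation; per species the pipeline reports
  the percentage of decidable occurrences that were coupled.
* **Occurrence cleaning** (duplicates, junk coordinates, unusable
  dates, with a reconciling report) and **lagged raster extraction**
  (nearest-cell, calendar-correct lags, per-cell climatology
  percentiles, per-analysis completeness flags).
* **Altitudinal trends.** Per species, a logistic regression of the
  montane indicator 1{elevation > 1000 m} on observation year:
  logit P(high | t) = α + βt, reported as log-odds estimate, SE, Wald
  *z* and *p*, plus the total odds ratio e^{β(t₁−t₀)} and probability
  change over the span. Complete separation is flagged and reported,
  not fatal.
* **Per-location trends.** At every occupied grid cell, Mann-Kendall
  tests (tie-corrected variance, continuity-corrected *z*) on the
  monthly LST and RZSM series, and a logistic trend of the monthly
  coupling indicator classified increase / decrease / none at α = 0.05,
  stratified above/below 1000 m.
* **Host-crop cross-referencing.** Presence of any host crop
  (harvested area > 0 at the nearest cell) at each occurrence, compared
  between two crop-census epochs, overall and at ≥ 1000 m.
* **ANOVA + Tukey HSD compact letters** for per-species environmental
  summaries, and **standardized 3-variable PCA** (elevation, LST, RZSM)
  with time-windowed comparison.

A first-class synthetic-data module generates a full study world —
seasonal, trending environmental grids, eight species with contrasting
niches, two-epoch crop layers — with known planted structure, so every
analysis can be validated against ground truth.

## Worked example

```python
from weedclim.pipeline import RunConfig, run_all
from weedclim.synthetic import default_scenario
import pandas as pd, json

art = run_all(RunConfig(output_dir="demo", seed=1, scenario=default_scenario(1)))
print(pd.read_csv(art / "coupling_association.csv")[["species", "n_complete", "pct_coupled"]])
print(json.load(open(art / "stratified_trends.json")))
```

```
                  species  n_complete  pct_coupled
0       Orobanche crenata         299    12.040134
1        Orobanche cumana         244    18.852459
...
5         Striga asiatica         390    47.692308
6     Striga gesnerioides         289    56.747405
7      Striga hermonthica         294    60.884354
{'above': {'n': 45, 'pct_increase': 100.0, 'pct_decrease': 0.0},
 'below': {'n': 80, 'pct_increase': 2.5, 'pct_decrease': 2.5}, ...}
```

Reading: witchweed-like species (generated from hot, wet niches) are
followed by a preceding coupling event in ~48–61 % of decidable
occurrences versus ~12–19 % for the broomrape-like species, and every
montane location carrying the planted rising coupling frequency is
classified "increase" while lowland stationary locations stay at the
test's false-positive level. The same artifacts include the cleaning
report, per-species environmental summary tables with significance
letters, the log-odds trend table, per-location Mann-Kendall results,
the host-presence table and windowed PCA loadings.

The same pipeline runs from the shell:

```bash
weedclim run-all --seed 1 --out demo
weedclim coupling --enriched demo/enriched.csv --out assoc.csv
```

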