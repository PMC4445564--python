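# spawnfeast

Quantitative analysis of a pulsed marine subsidy: Pacific herring spawn
deposits eggs (and supports talitrid amphipod populations) on beaches, and
American black bears emerge from dens in spring to feed on them. `spawnfeast`
implements the full analysis chain a field study of this system needs —
standing-stock estimation from beach surveys, egg-mass dynamics, camera-trap
activity statistics, scat-based diet reconstruction, and random-forest
predictor importance — together with a synthetic-data generator so every
stage can be exercised and validated without field data.

It is aimed at quantitative field ecologists working on cross-ecosystem
subsidies, camera trapping, or scat-based diet analysis; each stage is usable
on its own.

## The methods

**Standing stocks** (`spawnfeast.survey`). Quadrat percent cover of loose and
attached herring eggs is converted to egg counts by dividing covered area by
one egg's projected footprint πr² (r = 0.74 mm) and multiplying by the mean
layer count (attached eggs also by the mean macrophyte-layer count); counts
become dry mass at 0.27 mg per egg. Amphipod sediment cores (Ø 10.6 cm, 30%
sorted) scale to g/m². Per-stratum densities times user-supplied stratum
widths give kg dry weight per 1-m-wide beach strip.

**Egg dynamics** (`spawnfeast.dynamics`). Daily loss from repeat surveys as
`1 − (m₂/m₁)^(1/Δt)`, pooled to mean ± SE (study-wide default 6.9%/day).
Per-beach trajectories load eggs linearly over 5 days (20% of the maximum per
day) then decay geometrically; a 14-day trailing mean aligns egg mass with
scat-collection dates.

**Camera events** (`spawnfeast.events`). Detections collapse into independent
events by the 30-minute rule (gap to the previous detection < 30 min chains,
≥ 30 min splits), sum to daily per-beach counts with malfunction days
excluded, and classify into day/twilight/night from a sun table.

**Diet correction** (`spawnfeast.diet`). From five 6-ml subsamples per scat:
frequency of occurrence (FO), percent faecal volume (FV), then the two-stage
correction — `EDC_x ∝ FV_x·CF1_x` (digestibility) and `EDEC_x ∝ EDC_x·CF2_x`
(energy density, kJ/g), each renormalized to 100% over energetically relevant
items. The shipped factor table uses the whole-trout CF1 (40.8) for herring
eggs and the graminoid CF1 (0.24) for macroalgae and seagrasses.

**Predictor importance** (`spawnfeast.importance`). Two regression random
forests (700 trees, 2 predictors tried per split): daily bear activity ~ day
of year + year + location + wolf activity + amphipod mass + daily egg mass;
herring-egg EDC ~ the same with the 14-day mean egg mass. Reported per
predictor: permutation importance (out-of-bag MSE increase, mean/sd over
trees — the %IncMSE convention) and RSS node-impurity importance, plus an
out-of-bag pseudo-R² and partial-dependence curves.

**Synthetic seasons** (`spawnfeast.simulate`). Beaches, spawn timing,
log-normal standing stocks, Poisson activity with a log-linear resource
response and logistic spring emergence, diurnally biased detection streams,
and Dirichlet-multinomial scats whose egg share tracks the local 14-day egg
mass. Presets `null` / `moderate` / `strong` control effect sizes.

## Worked example

Generate a strong-effect synthetic season and run the pipeline from the
shell:

```bash
spawnfeast simulate --preset strong --seed 17 --outdir synthetic
# -> 11 beaches, 1728 detections, 66 scats -> synthetic
spawnfeast survey --quadrats synthetic/quadrats.csv --cores synthetic/cores.csv \
    --layout synthetic/layout.yaml --year 2012 --out stock.csv
# -> wrote 11 beaches to stock.csv
spawnfeast events --detections synthetic/detections.csv \
    --calendar synthetic/calendar.csv --out daily.csv
# -> 862 events on valid days -> daily.csv
spawnfeast diet --scats synthetic/scats.csv --out diet_summary.csv \
    --response egg_edc.csv
# -> wrote diet summary for 66 scats to diet_summary.csv
```

Assembling the activity model table (see
`spawnfeast.importance.assemble_activity_table`) and fitting:

```bash
spawnfeast importance --table model_table.csv --response bear_count \
    --seed 17 --out importance.json
# -> pseudo-R2 0.526; wrote importance.json
```

`importance.json` then contains (abridged):

```json
"permutation_importance": {
  "egg_mass": 1.889, "day_of_year": 1.166, "amphipod_mass": 0.631,
  "location": 0.569, "wolf_activity": 0.088, "year": 0.0
},
"pseudo_r2": 0.526
```

Egg mass ranks first: the forest recovered the generative signal (this
season was simulated with a strong egg effect on bear activity). The
permutation score is the mean per-tree out-of-bag error increase divided by
its standard deviation, so values are comparable across predictors; `year`
is 0 because a single-year table makes it constant.

A pure-library session (no CLI):

```python
from spawnfeast.diet import (load_diet_items, estimated_dietary_content,
                             estimated_dietary_energy)
items = load_diet_items()
fv = {"brown_algae": 38.6, "red_algae": 0.6, "amphipods": 5.4,
      "herring_eggs": 1.1, "seagrasses": 39.5, "graminoids": 5.9, "forbs": 1.1}
edc = estimated_dietary_content(fv, items)
edec = estimated_dietary_energy(edc, items)
print(round(edc["herring_eggs"], 1), round(edec["herring_eggs"], 1))
# 62.8 70.1
```

A 1.1% faecal volume of herring eggs becomes ~63% of the reconstructed diet
and ~70% of dietary energy — the digestibility correction is what turns a
trace faecal item into the dominant food.

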