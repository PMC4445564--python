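# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations of `spawnfeast`. It states no empirical result beyond
what the test suite and `scripts/acceptance.py` themselves compute.

## Standing stocks from stratified surveys

Beaches are stratified into low (1–2 m), mid (2–3 m), high (3–4 m) tidal
zones plus fresh and old supratidal wrack lines. Egg quadrats (0.25 m²,
overridable) record percent cover of loose and attached eggs and up to five
layer counts each.

Cover converts to eggs by **projected-area division**: covered area divided
by one egg's footprint πr², with r = 0.74 mm, times the mean layer count
(attached eggs additionally times the mean egg-bearing macrophyte layer
count). No packing-fraction correction is applied: percent cover is read as
the fraction of substrate covered by egg material, so the minimal reading is
area division. Because hexagonal close packing would multiply counts by
~0.9069, `EggGeometry.packing_fraction` exposes the correction for
sensitivity analysis (default 1.0). Egg dry mass uses 0.27 mg per egg; note
that 0.27 mg = 2.7·10⁻⁷ kg.

Amphipod cores (Ø 10.6 cm) are sieved and a 30% aliquot sorted; scaling
divides by the sorted fraction, which assumes the sample is homogeneously
mixed before subsampling. Per-stratum mean densities times user-supplied
stratum widths, summed, give kg dry weight per 1-m-wide beach strip. Stratum
widths are field geometry and must be supplied per beach; a stratum with
observations but no width raises rather than assuming a default. Amphipod
mass is treated as constant per beach within a season (overwintered adults;
juveniles pass the 0.75-mm sieve).

An empty layer list is valid only with zero cover; positive cover without
layer counts is an error naming the offending quadrat, since silently
treating it as zero would bias stocks downward.

## Egg dynamics

Loss between repeat surveys is modelled as constant proportional removal:
`daily_loss = 1 − (m₂/m₁)^(1/Δt)`. A geometric (not linear) model matches
the notion of a constant daily loss *rate*; intervals over which mass
increased clip to zero with a warning, because loss is defined as removal.
Interval estimates pool across beaches and pre/post-hatch periods into an
arithmetic mean ± SE (sd/√n); per-period pooling is available via
`by_period=True`. The package default rate is 0.069/day.

Trajectories ramp linearly for 5 days — day *k* holds *k*/5 of the maximum,
so the spawn-start day already carries 20% — then decay geometrically. Days
before the spawn are zeros. The 14-day trailing mean used as the diet-model
predictor includes the reference day and divides by the full window length,
with pre-spawn days contributing zero.

Degenerate inputs: a horizon ending before the spawn start yields an empty
series; `estimate_daily_loss_rate` refuses a zero starting mass (the rate is
undefined).

## Camera events

Independence is **gap-chained**: each detection is compared to the previous
detection, a gap under 30 minutes chains, and a gap of 30 minutes or more
starts a new event. The boundary case (exactly 30 min) is unstated in the
usual phrasing of the rule; we resolve it as independent. A windowed variant
(every gap measured from the event's first detection) is available via
`anchor="first"` for sensitivity analysis. Events are dated by their start
timestamp, so a visit straddling midnight counts once, on the day it began.

Daily tables carry explicit zero rows for operational days so that models
see true absences; non-operational (malfunction) days are excluded, and an
event recorded on one is treated as inconsistent input and raises. A female
with cubs is one detection; wolf events are likewise counted without regard
to group size.

Diel classification uses a user-supplied sun table (per-date nautical dawn,
sunrise, sunset, nautical dusk) rather than computing ephemerides, keeping
the module dependency-free and bit-reproducible. Twilight is the union of
civil and nautical twilight; intervals are closed on the left, so an event
exactly at sunset is twilight.

## Scat diet correction

Item volumes are averaged over the five 6-ml subsamples (absent items
contribute zero; scats with fewer subsamples are accepted with a warning).
FO is the percent of scats whose mean item volume is positive. Annual FV
divides the summed item volume by the summed total volume, so FV sums to
100% over all items.

The two-stage correction is

    EDC_x  = 100 · FV_x·CF1_x / Σ_y FV_y·CF1_y      (percent of diet dry mass)
    EDEC_x = 100 · EDC_x·CF2_x / Σ_y EDC_y·CF2_y    (percent of dietary energy)

over *included* items only. Excluded items — molluscs, bryozoa, bear hair,
feathers, trees/shrubs, bryophyta, gravel, garbage — are judged to
contribute negligible energy and are dropped before renormalization. The
shipped factor table substitutes the whole-trout CF1 (40.8) for herring eggs
and the graminoid CF1 (0.24) for macroalgae and seagrasses, as no measured
factors exist for those items; ants carry their own energy density (17.7
kJ/g) distinct from other arthropods (11.3), and talitrid amphipods use a
measured 10.8. Factors live in `data/diet_items.yaml`, not code, and any
user table can be passed instead.

Both normalizations are scale-invariant in FV, and EDC→FV is invertible on
included items (divide by CF1 and renormalize) — both properties are tested.

Two response paths are deliberately distinct: annual summary tables compute
EDC from annual pooled FV, while the model response is per-scat EDC averaged
within beach × collection date. A scat containing only excluded items has an
undefined composition; its egg EDC is taken as 0 for the response. Display
rendering writes values under 0.5% as "tr." and absences as "–", but all
internal arithmetic is full precision.

## Random forests

Both models use bagged regression trees with 700 trees, 2 predictors tried
per split, and a minimum leaf size of 5 (the customary regression node
size). The backend is scikit-learn's `RandomForestRegressor`; the
importance and diagnostic layers are computed by this package from per-tree
out-of-bag (OOB) membership, reconstructed from each tree's bootstrap seed
and cross-checked in the tests against the backend's own OOB score.

* **Permutation importance**: for each tree, the OOB MSE with the predictor's
  OOB values permuted minus the unpermuted OOB MSE; the score is the mean of
  those per-tree differences divided by their standard deviation. Permutation
  uses a dedicated RNG derived from the fit seed, so results are
  bit-reproducible.
* **Impurity importance**: the decrease in residual sum of squares at each
  split, summed per tree over splits on the predictor and averaged over
  trees (node weight × node MSE is the node's RSS).
* **Pseudo-R²**: 1 − OOB-MSE / Var(y), with OOB predictions averaged over
  the trees that did not see each observation; observations never OOB (a
  vanishing set at 700 trees) are excluded from the MSE.

Categorical predictors (year, location) enter as integer codes because the
tree backend has no unordered-factor support; with the handful of levels
used here this only restricts which partitions a single split can express,
and the limitation is documented rather than worked around. Perfectly
collinear predictors split their importance — expected behaviour, tested
only for non-negativity. Partial dependence replaces the predictor column
wholesale with each grid value (25-point grid over the observed range;
category levels for categoricals) and averages predictions.

Exact replication of any single published forest fit is not claimed: a
forest's scores depend on its RNG stream, and only seeded reproducibility
within this package is guaranteed.

## Synthetic seasons

The generator emulates the study system's structure at its reported
magnitudes: 11 beaches over day-of-year 61–126, ~60% spawning with start
days uniform on 79–92, spawn maxima log-normal with mean ≈ 1.1 kg d.w. per
1-m strip, amphipod masses log-normal with mean ≈ 0.06 kg, 6.9%/day loss,
and a 5-day ramp.

* **Activity**: bear counts per beach-day are Poisson with log-mean
  `β₀ + β_egg·log1p(egg) + β_amph·log1p(amph) + β_doy·σ(k·(doy − mid))`.
  The log link keeps counts positive, log1p gives diminishing returns in
  resource mass, and the logistic term is spring emergence (midpoint day 85,
  steepness 0.2). Wolves are independent Poisson (0.3/day).
* **Detections**: each true event becomes 1–3 detections with 2–15 minute
  gaps (a chain never self-splits under the 30-minute rule); start hours are
  drawn from diurnal weights peaking in late afternoon. Because a "true
  independent event" is only meaningful relative to the 30-minute rule,
  same-day event starts are rejection-sampled to at least 45 minutes apart;
  the sampler gives up after 20 tries on crowded days, and a chain can still
  stretch to within 30 minutes of the next start, so occasional merges
  remain and daily-count recovery is a round-trip property (tested at ≥95%
  of beach-days exact) rather than an identity.
* **Scats**: compositions are Dirichlet-multinomial — per-scat proportions
  from a Dirichlet whose herring-egg concentration is the base value plus
  `egg_scat_gain` times the local 14-day mean egg mass, discretized into
  five 6-ml subsamples of 60 multinomial grains. The item set includes
  excluded fillers (gravel, woody debris) to exercise the exclusion list.
* **Surveys**: the generative standing stocks are inverted into quadrat
  cover/layer records and core masses with mean-one multiplicative noise
  (lognormal, σ = 0.25), so survey-derived stocks are unbiased noisy
  estimates of the truth and the full pipeline can run from raw records.

Presets: `moderate` (defaults), `strong` (egg effects dominate:
β_egg = 1.8, scat gain 6), and `null` (all effect terms zero; constant
Poisson(1) activity). Parameter-recovery experiments run the *entire*
pipeline — survey inversion, trajectory building, event collapsing, diet
correction, forest fitting — on observed records only, never the generative
truth.

What the generator does **not** emulate: spatial autocorrelation among
beaches, weather-driven egg redistribution, individual bear identity or
behavioural states, wolf–bear interaction, multi-year beach effects, and
observer error in cover estimation beyond multiplicative noise. Passing
recovery tests therefore demonstrates that the pipeline's statistics recover
signals of the modelled form at field-realistic sizes — not that real data
meet these assumptions.

## Problem sizes and determinism

Recovery experiments use 20 seeds of one 11-beach, 66-day season per preset
with the default 700-tree forests; round-trip detection recovery pools three
seasons; oracle equivalence for event collapsing checks 1,000 random streams
of up to 12 detections against exhaustive grouping. All randomness flows
from explicit seeds (`numpy.random.default_rng` in the generator; the forest
seed plus a derived permutation seed in the importance module), and every
bundle is bit-reproducible given its config.

## Known limitations

* The projected-area egg conversion ignores packing and egg deformation;
  the optional packing fraction bounds the effect but no field calibration
  is shipped.
* The loss model is a single geometric constant; storm-driven episodic loss
  is not representable.
* Integer-coded categoricals mildly disadvantage high-cardinality location
  effects relative to native factor splitting.
* Annual EDC/EDEC from pooled FV treats the scat collection as one
  composite sample; no scat-level uncertainty is propagated into the annual
  table.
* The sun table is caller-supplied; no ephemeris computation or timezone
  handling is performed.
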