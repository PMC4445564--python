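"""End-to-end pipeline: surveys -> trajectories -> events/diet -> importance.

Chains the individual modules exactly the way a field season is analysed:
standing stocks from the quadrat/core surveys, egg trajectories from the
survey maxima and the pooled loss rate, camera detections collapsed to daily
activity, scat records reduced to the egg-EDC response, and the two
random-forest importance fits.  Used by the parameter-recovery experiments
and the command-line interface.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping

import pandas as pd

from . import diet, dynamics, events, importance, simulate, survey

__all__ = [
    "standing_stock_from_surveys",
    "run_importance_from_bundle",
]


def standing_stock_from_surveys(
    quadrats: Iterable[survey.QuadratObservation],
    cores: Iterable[survey.SedimentCore],
    layouts: Mapping[str, survey.StratumLayout],
    *,
    year: int,
    geom: survey.EggGeometry = survey.EggGeometry(),
) -> pd.DataFrame:
    """Per-beach egg and amphipod standing stock from raw survey records.

    Quadrats are assumed to describe a single survey (the spawn maximum) per
    beach; the egg figure is therefore the peak strip mass.
    """
    quads_by_beach: Dict[str, list] = {}
    for q in quadrats:
        quads_by_beach.setdefault(q.beach_id, []).append(q)
    cores_by_beach: Dict[str, list] = {}
    for c in cores:
        cores_by_beach.setdefault(c.beach_id, []).append(c)

    rows = []
    for beach in sorted(set(quads_by_beach) | set(cores_by_beach)):
        layout = layouts[beach]
        egg = (
            survey.strip_egg_mass(quads_by_beach[beach], layout, geom)
            if beach in quads_by_beach
            else 0.0
        )
        amph = (
            survey.strip_amphipod_mass(cores_by_beach[beach], layout)
            if beach in cores_by_beach
            else 0.0
        )
        rows.append(
            {"beach_id": beach, "year": year, "egg_mass_kg": egg, "amphipod_mass_kg": amph}
        )
    return pd.DataFrame(rows)


def run_importance_from_bundle(
    bundle: simulate.SyntheticBundle,
    *,
    n_trees: int = importance.DEFAULT_N_TREES,
    mtry: int = importance.DEFAULT_MTRY,
    seed: int = 0,
    items: Mapping[str, diet.DietItemDefinition] | None = None,
) -> Dict[str, importance.ImportanceResult]:
    """Run the full analysis on a synthetic season and fit both forests.

    Every stage uses only what a field crew would observe: survey records,
    the spawn start dates, camera detections, the operational calendar, and
    scats — never the generative truth — so the result measures end-to-end
    parameter recovery.
    """
    cfg = bundle.config
    if items is None:
        items = diet.load_diet_items()

    stock = standing_stock_from_surveys(
        bundle.quadrats, bundle.cores, bundle.layouts, year=cfg.year
    )
    stock = stock.set_index("beach_id")

    trajectories: Dict[str, dynamics.EggTrajectory] = {}
    spawned = bundle.beaches[bundle.beaches["spawned"]]
    for _, b in spawned.iterrows():
        beach = b["beach_id"]
        trajectories[beach] = dynamics.build_trajectory(
            spawn_start_day=int(b["spawn_start_doy"]),
            max_mass=float(stock.loc[beach, "egg_mass_kg"]),
            daily_loss=cfg.daily_loss,
            horizon_last_day=cfg.season[1],
            horizon_first_day=cfg.season[0],
            ramp_days=cfg.ramp_days,
            beach_id=beach,
        )
    amph_mass = stock["amphipod_mass_kg"].to_dict()

    by_group: Dict[tuple, list] = {}
    for det in bundle.detections:
        by_group.setdefault((det.beach_id, det.species), []).append(det)
    all_events = []
    for group in by_group.values():
        all_events.extend(events.collapse_detections(group))
    daily = events.daily_activity(
        all_events, bundle.calendar, species=["black_bear", "gray_wolf"]
    )

    activity_table = importance.assemble_activity_table(
        daily, trajectories, amph_mass, year=cfg.year
    )
    activity_fit = importance.fit_importance(
        activity_table, "bear_count", n_trees=n_trees, mtry=mtry, seed=seed
    )

    egg_edc = diet.egg_edc_by_site_date(bundle.scats, items)
    edc_table = importance.assemble_edc_table(
        egg_edc, trajectories, amph_mass, year=cfg.year
    )
    edc_fit = importance.fit_importance(
        edc_table, "egg_edc", n_trees=n_trees, mtry=mtry, seed=seed
    )
    return {"activity": activity_fit, "egg_edc": edc_fit}
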