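"""Readers for the tabular interchange formats used by the CLI.

All inputs are plain CSV/YAML: quadrat and core survey records, per-beach
stratum layouts, camera detections with an operational calendar, and long-form
scat subsample volumes.  Layer-count sequences are semicolon-separated
integers inside a CSV cell.
"""

from __future__ import annotations

from datetime import datetime
from typing import Dict, List

import pandas as pd
import yaml

from .diet import ScatRecord
from .events import Detection
from .survey import QuadratObservation, SedimentCore, StratumLayout

__all__ = [
    "read_quadrats",
    "read_cores",
    "read_layouts",
    "read_detections",
    "read_scats",
]


def _parse_layers(cell) -> tuple:
    if cell is None or (isinstance(cell, float) and cell != cell) or str(cell).strip() == "":
        return ()
    return tuple(float(x) for x in str(cell).split(";"))


def read_quadrats(path) -> List[QuadratObservation]:
    df = pd.read_csv(path)
    return [
        QuadratObservation(
            beach_id=str(r["beach_id"]),
            survey_date=str(r["survey_date"]),
            stratum=str(r["stratum"]),
            quadrat_area_m2=float(r.get("quadrat_area_m2", 0.25)),
            loose_cover_pct=float(r.get("loose_cover_pct", 0.0)),
            loose_layer_counts=_parse_layers(r.get("loose_layers")),
            attached_cover_pct=float(r.get("attached_cover_pct", 0.0)),
            attached_egg_layer_counts=_parse_layers(r.get("attached_egg_layers")),
            macrophyte_layer_counts=_parse_layers(r.get("macrophyte_layers")),
        )
        for r in df.to_dict(orient="records")
    ]


def read_cores(path) -> List[SedimentCore]:
    df = pd.read_csv(path)
    return [
        SedimentCore(
            beach_id=str(r["beach_id"]),
            stratum=str(r["stratum"]),
            core_diameter_cm=float(r.get("core_diameter_cm", 10.6)),
            sorted_fraction=float(r.get("sorted_fraction", 0.30)),
            sorted_dry_mass_g=float(r["sorted_dry_mass_g"]),
        )
        for r in df.to_dict(orient="records")
    ]


def read_layouts(path) -> Dict[str, StratumLayout]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        beach: StratumLayout(beach_id=beach, widths={k: float(v) for k, v in widths.items()})
        for beach, widths in raw.items()
    }


def read_detections(path) -> List[Detection]:
    df = pd.read_csv(path)
    out = []
    for r in df.to_dict(orient="records"):
        note = r.get("group_note", "")
        out.append(
            Detection(
                beach_id=str(r["beach_id"]),
                species=str(r["species"]),
                timestamp=datetime.fromisoformat(str(r["timestamp"])),
                group_note="" if note != note or note is None else str(note),
            )
        )
    return out


def read_scats(path) -> List[ScatRecord]:
    """Long-form scats.csv (one row per scat x subsample x item) to records."""
    df = pd.read_csv(path)
    records = []
    for (scat_id, beach_id, date), grp in df.groupby(
        ["scat_id", "beach_id", "collection_date"], sort=True
    ):
        n_sub = int(grp["subsample_index"].max())
        subsamples: list[dict] = [dict() for _ in range(n_sub)]
        for r in grp.to_dict(orient="records"):
            subsamples[int(r["subsample_index"]) - 1][str(r["item"])] = float(r["volume_ml"])
        records.append(
            ScatRecord(
                scat_id=str(scat_id),
                beach_id=str(beach_id),
                collection_date=str(date),
                subsamples=tuple(subsamples),
            )
        )
    return records
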