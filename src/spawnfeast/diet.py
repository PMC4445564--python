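"""Scat-content analysis: FO, FV, and the two-stage diet correction.

Each scat is washed, mixed, and five 6-ml subsamples are taken; item volumes
are averaged over subsamples.  Items are summarized per year as

* **FO** (frequency of occurrence): percent of scats containing the item;
* **FV** (faecal volume): the item's share of total mean scat volume;
* **EDC** (estimated dietary content): FV corrected by per-item digestibility
  factors CF1 and renormalized over the energetically relevant items, giving
  percent of original diet dry mass;
* **EDEC** (estimated dietary energy content): EDC weighted by energy
  densities CF2 (kJ/g dry weight) and renormalized.

Correction factors and the inclusion list ship as an editable YAML table
(:func:`load_diet_items`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "DietItemDefinition",
    "ScatRecord",
    "load_diet_items",
    "scat_item_volume",
    "frequency_of_occurrence",
    "faecal_volume",
    "faecal_volume_table",
    "estimated_dietary_content",
    "estimated_dietary_energy",
    "per_scat_edc",
    "egg_edc_by_site_date",
    "render_summary",
    "format_display",
]

SUBSAMPLE_ML = 6.0
N_SUBSAMPLES = 5
TRACE_THRESHOLD_PCT = 0.5


@dataclass(frozen=True)
class DietItemDefinition:
    """One diet item with its correction factors and inclusion flag.

    ``cf1`` maps faecal volume to original dry-mass intake; ``cf2`` is energy
    density in kJ/g dry weight.  Excluded items (shell fragments, hair, woody
    debris, gravel, garbage...) appear in FO/FV but never in EDC/EDEC and
    need no factors.
    """

    name: str
    group: str
    included: bool
    cf1: float | None = None
    cf2: float | None = None

    def __post_init__(self) -> None:
        if self.included:
            if self.cf1 is None or self.cf1 <= 0:
                raise ValueError(f"included item {self.name!r} needs cf1 > 0")
            if self.cf2 is None or self.cf2 <= 0:
                raise ValueError(f"included item {self.name!r} needs cf2 > 0")


def load_diet_items(path=None) -> Dict[str, DietItemDefinition]:
    """Load item definitions from YAML; default is the shipped table."""
    if path is None:
        text = resources.files("spawnfeast.data").joinpath("diet_items.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    items = {}
    for name, cfg in raw.items():
        items[name] = DietItemDefinition(
            name=name,
            group=cfg.get("group", "other"),
            included=bool(cfg.get("included", False)),
            cf1=cfg.get("cf1"),
            cf2=cfg.get("cf2"),
        )
    return items


@dataclass(frozen=True)
class ScatRecord:
    """Per-scat item volumes (ml) from up to five 6-ml subsamples.

    ``subsamples`` is a sequence of ``{item: volume_ml}`` maps, one per
    subsample; items absent from a subsample contribute 0 to the scat mean.
    """

    scat_id: str
    beach_id: str
    collection_date: str
    subsamples: Sequence[Mapping[str, float]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.subsamples) == 0:
            raise ValueError(f"scat {self.scat_id}: at least one subsample required")
        if len(self.subsamples) < N_SUBSAMPLES:
            warnings.warn(
                f"scat {self.scat_id}: only {len(self.subsamples)} of "
                f"{N_SUBSAMPLES} subsamples recorded",
                stacklevel=2,
            )
        for i, sub in enumerate(self.subsamples, 1):
            if any(v < 0 for v in sub.values()):
                raise ValueError(f"scat {self.scat_id} subsample {i}: negative volume")
            total = sum(sub.values())
            if total > SUBSAMPLE_ML + 1e-9:
                raise ValueError(
                    f"scat {self.scat_id} subsample {i}: volumes sum to {total:.2f} ml "
                    f"> {SUBSAMPLE_ML} ml"
                )


def scat_item_volume(record: ScatRecord) -> Dict[str, float]:
    """Mean volume (ml) of each item across the scat's subsamples."""
    items = sorted({it for sub in record.subsamples for it in sub})
    n = len(record.subsamples)
    return {it: sum(sub.get(it, 0.0) for sub in record.subsamples) / n for it in items}


def frequency_of_occurrence(scats: Sequence[ScatRecord], item: str) -> float:
    """Percent of scats whose mean volume of ``item`` is positive."""
    if not scats:
        raise ValueError("frequency of occurrence needs at least one scat")
    n_with = sum(1 for s in scats if scat_item_volume(s).get(item, 0.0) > 0)
    return 100.0 * n_with / len(scats)


def faecal_volume_table(scats: Sequence[ScatRecord]) -> Dict[str, float]:
    """Percent faecal volume of every item over a pooled scat collection.

    Each item's mean volume per scat is divided by the mean total scat volume,
    so the shares sum to 100 over all items.
    """
    if not scats:
        raise ValueError("faecal volume needs at least one scat")
    item_sums: Dict[str, float] = {}
    total = 0.0
    for s in scats:
        means = scat_item_volume(s)
        for it, v in means.items():
            item_sums[it] = item_sums.get(it, 0.0) + v
            total += v
    if total <= 0:
        raise ValueError("total faecal volume is zero")
    return {it: 100.0 * v / total for it, v in sorted(item_sums.items())}


def faecal_volume(scats: Sequence[ScatRecord], item: str) -> float:
    """Percent faecal volume of one item (see :func:`faecal_volume_table`)."""
    return faecal_volume_table(scats).get(item, 0.0)


def estimated_dietary_content(
    fv: Mapping[str, float], items: Mapping[str, DietItemDefinition]
) -> Dict[str, float]:
    """EDC: CF1-corrected faecal volumes renormalized over included items.

    ``EDC_x = 100 * FV_x * CF1_x / sum_y FV_y * CF1_y`` over included items;
    excluded items are dropped.  Scale-invariant in FV.  An included item with
    positive FV but no definition raises rather than silently vanishing.
    """
    corrected: Dict[str, float] = {}
    for it, v in fv.items():
        if v < 0:
            raise ValueError(f"negative faecal volume for {it!r}")
        if it not in items:
            if v > 0:
                raise ValueError(f"item {it!r} has positive FV but no definition")
            continue
        d = items[it]
        if not d.included:
            continue
        corrected[it] = v * d.cf1
    total = sum(corrected.values())
    if total <= 0:
        raise ValueError("no included item with positive faecal volume")
    return {it: 100.0 * v / total for it, v in corrected.items()}


def estimated_dietary_energy(
    edc: Mapping[str, float], items: Mapping[str, DietItemDefinition]
) -> Dict[str, float]:
    """EDEC: EDC weighted by CF2 energy densities and renormalized."""
    weighted: Dict[str, float] = {}
    for it, v in edc.items():
        if it not in items or not items[it].included:
            raise ValueError(f"EDC contains non-included item {it!r}")
        weighted[it] = v * items[it].cf2
    total = sum(weighted.values())
    if total <= 0:
        raise ValueError("EDC carries no positive included item")
    return {it: 100.0 * v / total for it, v in weighted.items()}


def per_scat_edc(scat: ScatRecord, items: Mapping[str, DietItemDefinition]) -> Dict[str, float]:
    """EDC of a single scat from its own item volumes.

    A scat containing no included items (e.g. pure gravel) has an undefined
    composition and returns an empty map — callers treat target items as 0%.
    """
    means = scat_item_volume(scat)
    total = sum(means.values())
    if total <= 0:
        return {}
    fv = {it: 100.0 * v / total for it, v in means.items()}
    try:
        return estimated_dietary_content(fv, items)
    except ValueError:
        return {}


def egg_edc_by_site_date(
    scats: Sequence[ScatRecord],
    items: Mapping[str, DietItemDefinition],
    *,
    egg_item: str = "herring_eggs",
) -> pd.DataFrame:
    """Mean herring-egg EDC per beach and collection date.

    EDC is computed per scat, the egg entry extracted (0 when absent), and
    averaged within each beach x collection-date group.  This is the response
    variable for the diet-predictor model.
    """
    rows = []
    for s in scats:
        edc = per_scat_edc(s, items)
        rows.append(
            {
                "beach_id": s.beach_id,
                "collection_date": s.collection_date,
                "egg_edc": edc.get(egg_item, 0.0),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["beach_id", "collection_date", "egg_edc"])
    df = pd.DataFrame(rows)
    return (
        df.groupby(["beach_id", "collection_date"], as_index=False)["egg_edc"]
        .mean()
        .sort_values(["beach_id", "collection_date"])
        .reset_index(drop=True)
    )


def render_summary(
    scats_by_year: Mapping[int, Sequence[ScatRecord]],
    items: Mapping[str, DietItemDefinition],
) -> pd.DataFrame:
    """Annual FO / FV / EDC / EDEC table at full precision.

    One row per item, one column per (statistic, year).  EDC/EDEC are NaN for
    excluded items.  Group-level rows (index ``group:<name>``) sum their
    member items.  Use :func:`format_display` for the trace-threshold
    rendering.
    """
    years = sorted(scats_by_year)
    all_items = sorted(items)
    cols: Dict[tuple, Dict[str, float]] = {}
    for year in years:
        scats = list(scats_by_year[year])
        fv = faecal_volume_table(scats)
        edc = estimated_dietary_content(fv, items)
        edec = estimated_dietary_energy(edc, items)
        cols[("FO", year)] = {it: frequency_of_occurrence(scats, it) for it in all_items}
        cols[("FV", year)] = {it: fv.get(it, 0.0) for it in all_items}
        cols[("EDC", year)] = {
            it: edc.get(it, 0.0) if items[it].included else float("nan") for it in all_items
        }
        cols[("EDEC", year)] = {
            it: edec.get(it, 0.0) if items[it].included else float("nan") for it in all_items
        }
    table = pd.DataFrame(cols, index=all_items)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["statistic", "year"])

    groups = sorted({d.group for d in items.values()})
    group_rows = {}
    for g in groups:
        members = [it for it in all_items if items[it].group == g]
        group_rows[f"group:{g}"] = table.loc[members].sum(min_count=1)
    return pd.concat([table, pd.DataFrame(group_rows).T])


def format_display(value: float) -> str:
    """Render one table cell: absences as a dash, <0.5% as trace."""
    if value != value:  # NaN: statistic not defined for this item
        return "–"
    if value == 0.0:
        return "–"
    if value < TRACE_THRESHOLD_PCT:
        return "tr."
    return f"{value:.1f}"
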